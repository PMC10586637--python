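# omnidiet

Two-track diet analysis for omnivorous consumers, built for studies that
pair DNA metabarcoding of fecal samples with stable-isotope analysis of
consumer tissue — the combination used to work out what an invasive
predator (e.g. island house mice) actually eats, and in what proportions,
ahead of an eradication campaign.

**Track 1 — what is eaten.** Annotated amplicon-sequence-variant (ASV)
read-count tables are reduced to presence/absence through a fixed filtering
ladder (target phylum, genus-level assignment, bait exclusion, relative
read abundance ≥ 1%), summarized as percent frequency of occurrence
(%FOO), and tested for spatial/temporal structure with permutation-based
multivariate statistics: Sørensen dissimilarity, PCoA, two-way crossed
PERMANOVA (Type III sums of squares via the McArdle–Anderson trace
identities, permutation of residuals under the reduced model), PERMDISP,
and pairwise tests.

**Track 2 — how much.** Food taxa detected in ≥ 5% of samples are grouped
into isotopically coherent sources (a-priori groups plus Ward "ward.D2"
clustering), screened with Monte-Carlo mixing polygons (consumers outside
the 95% mixing region are excluded), and fed to a concentration-dependent
hierarchical Bayesian mixing model.  With K sources, tracers
j ∈ {δ¹³C, δ¹⁵N}, concentrations c_kj and discrimination factor
Δ_j ± Δsd_j:

    p ~ Dirichlet(α),   p_i = ilr⁻¹( ilr(p) + Σ_f ε_{f, level_f(i)} ),
    ε_{f,ℓ} ~ N(0, σ_f²),   σ_f ~ U(0, 20),   ξ_j ~ U(0, 20)

    δ_ij ~ N( Σ_k p̃_ikj (μ_kj + Δ_j),  √( ξ_j Σ_k p̃²_ikj (s²_kj + Δsd²_j) ) ),
    p̃_ikj = p_ik c_kj / Σ_l p_il c_lj

Inference is a self-contained adaptive Metropolis-within-Gibbs sampler;
convergence is monitored with Gelman–Rubin statistics (target < 1.1).
Results objects carry posterior draws, diagnostics, credible-interval
summaries, a-posteriori source aggregation, and a variance partition of the
habitat and season random effects.  A synthetic-data module generates both
kinds of input with known truth, so every stage is testable end to end.

## Worked example

Simulate an isotope study with a known diet (45/25/18/12% over four
sources) and three planted infeasible consumers, screen feasibility, and
fit the mixing model:

```python
import numpy as np
import omnidiet as od
from omnidiet.datatypes import McmcConfig
from omnidiet.simulate import default_source_truth

cfg = od.IsotopeSimConfig(
    source_truth=default_source_truth(4),
    p_true=np.array([0.45, 0.25, 0.18, 0.12]),
    n_consumers=60, n_infeasible=3, seed=42,
)
records, meta, truth = od.simulate_isotope_study(cfg)
consumers = records[records["role"] == "consumer"].set_index("specimen_id")

report = od.simulate_mixing_region(truth["sample_sources"], cfg.dtdf,
                                   consumers, n_iter=5000, seed=1)
excluded = od.flag_outliers(report)
print("excluded consumers:", excluded)

model = od.IsotopeMixingModel.from_frames(
    records, truth["sample_sources"], cfg.dtdf, exclude=tuple(excluded))
res = model.fit(McmcConfig(chains=3, iterations=20_000,
                           burn_in=10_000, thin=10), seed=2)
print(res.summary().round(3).to_string(index=False))
print("max Rhat:", round(res.rhat.max(), 3))
```

Output:

```
excluded consumers: ['mouse_out_1', 'mouse_out_2', 'mouse_out_3']
   group   scope  mean    sd  2.5%   25%   75%  97.5%
source_a overall 0.443 0.022 0.402 0.427 0.459  0.484
source_b overall 0.151 0.091 0.005 0.076 0.224  0.320
source_c overall 0.163 0.014 0.134 0.154 0.173  0.188
source_d overall 0.243 0.118 0.022 0.149 0.342  0.436
max Rhat: 1.001
```

The three planted outliers are exactly the consumers flagged by the
mixing-polygon screen.  The posterior mean for `source_a` recovers the true
0.45 closely; `source_b` and `source_d` carry wide, overlapping intervals
because with two tracers a four-source mixture is only partially identified
— the credible intervals (not the point estimates) are the honest summary,
and both cover their true values.  `max Rhat` < 1.1 indicates the three
chains agree.

The same analysis from the shell, plus the metabarcoding track:

```bash
omnidiet --seed 42 --out run1 simulate --kind asv
omnidiet --seed 42 --out run1 run-all \
    --plant-asv run1/plant_asv.csv --metadata run1/metadata.csv
```

which writes occurrence and %FOO tables, PCoA coordinates,
PERMANOVA/PERMDISP tables, and a JSON manifest recording the seed and
config hash (identical seed ⇒ byte-identical outputs).

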