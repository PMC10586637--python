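"""Self-validation benchmarks: each function recomputes, from scratch, one
of the checkable properties of the pipeline (exact occurrence statistics on
the packaged tables, calibration of the permutation tests against classical
and brute-force oracles, Monte-Carlo polygon accuracy, mixing-model
parameter recovery, variance-partition recovery, and output determinism).

They are used by the acceptance tests and by ``scripts/acceptance.py``; all
randomness flows from an explicit seed.
"""

from __future__ import annotations

import hashlib
import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import io as odio
from .community import DissimilarityMatrix, permanova, sorensen_matrix
from .datatypes import Dtdf, McmcConfig, RunConfig
from .mixing import IsotopeMixingModel
from .occurrence import OccurrenceMatrix, select_sources
from .pipeline import run_pipeline
from .polygon import flag_outliers, simulate_mixing_region
from .simulate import (
    RECOVERY_P_TRUE,
    AsvSimConfig,
    IsotopeSimConfig,
    default_source_truth,
    fixture_foo_summary,
    recovery_source_truth,
    simulate_asv_table,
    simulate_isotope_study,
)

REDUCED_MCMC = McmcConfig(chains=3, iterations=20_000, burn_in=10_000, thin=10)


# ---------------------------------------------------------------------------
# Occurrence statistics on the packaged tables


def occurrence_fixture_stats() -> dict[str, float]:
    """Exact occurrence statistics recomputed from the packaged tables."""
    out: dict[str, float] = {}
    for key, tag in (("arthropod", "arthropod"), ("plant", "plant")):
        foo = fixture_foo_summary(key)
        out[f"{tag}_asv_count"] = len(foo)
        out[f"{tag}_sources_at_5pct"] = len(select_sources(foo, 0.05))
        out[f"{tag}_below_5pct"] = int((foo["foo_percent"] < 5.0).sum())
        out[f"{tag}_at_30pct"] = int((foo["foo_percent"] >= 30.0).sum())
        out[f"{tag}_top_foo_percent"] = round(float(foo["foo_percent"].max()), 1)
    return out


# ---------------------------------------------------------------------------
# Permutation statistics


def anova_equivalence_error(seed: int) -> float:
    """|pseudo-F - classical ANOVA F| on univariate Euclidean data."""
    rng = np.random.default_rng(seed)
    groups = [rng.normal(mu, 1.0, size=8) for mu in (0.0, 0.8, 0.3)]
    y = np.concatenate(groups)
    D = squareform(pdist(y[:, None]))
    dm = DissimilarityMatrix(ids=[f"s{i}" for i in range(len(y))], D=D)
    meta = pd.DataFrame({"group": np.repeat([0, 1, 2], 8)}, index=dm.ids)
    res = permanova(dm, meta, ("group",), n_perm=9, seed=seed)
    F_classic = stats.f_oneway(*groups).statistic
    return float(abs(res.table.loc["group", "pseudo_F"] - F_classic))


def enumeration_gap(seed: int, n: int = 6) -> float:
    """|sampled permutation p - exhaustive-enumeration p| at small n."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    y[n // 2:] += 1.2
    codes = np.array([0] * (n // 2) + [1] * (n - n // 2))
    D = squareform(pdist(y[:, None]))
    dm = DissimilarityMatrix(ids=[f"s{i}" for i in range(n)], D=D)
    meta = pd.DataFrame({"group": codes}, index=dm.ids)
    res = permanova(dm, meta, ("group",), n_perm=9_999, seed=seed)
    F_obs = res.table.loc["group", "pseudo_F"]
    d2 = D**2
    count = total = 0
    for perm in itertools.permutations(range(n)):
        c = codes[list(perm)]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in (0, 1):
            idx = np.nonzero(c == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        F_p = (ss_between / 1) / (ss_within / (n - 2))
        total += 1
        if F_p >= F_obs - 1e-12:
            count += 1
    return float(abs(res.table.loc["group", "p_perm"] - count / total))


def type_one_error_rate(seed: int, n_reps: int = 500, n_perm: int = 99) -> float:
    """Null rejection rate of the one-way permutation test at alpha=0.05."""
    rng = np.random.default_rng(seed)
    n = 20
    codes = np.repeat([0, 1, 2, 3], 5)
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({"group": codes}, index=ids)
    rejections = 0
    for _ in range(n_reps):
        presence = (rng.uniform(size=(n, 10)) < 0.4).astype(int)
        presence[presence.sum(axis=1) == 0, 0] = 1
        occ = OccurrenceMatrix(
            presence=pd.DataFrame(presence, index=ids,
                                  columns=[f"t{j}" for j in range(10)]),
            zero_total_samples=[],
        )
        res = permanova(sorensen_matrix(occ), meta, ("group",), n_perm=n_perm,
                        seed=int(rng.integers(2**31)))
        if res.table.loc["group", "p_perm"] <= 0.05:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# Mixing polygon


def polygon_oracle_gap(seed: int, n_iter: int = 10_000) -> float:
    """Max |MC inclusion probability - brute-force oracle| on a triangle."""
    from .isotopes import SourceGroupSet

    mean = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    stats_df = pd.DataFrame(
        {
            "n": 5,
            "mean_d13C": mean[:, 0],
            "sd_d13C": 0.1,
            "mean_d15N": mean[:, 1],
            "sd_d15N": 0.1,
            "mean_pctC": 45.0,
            "mean_pctN": 5.0,
        },
        index=pd.Index([f"s{i}" for i in range(3)], name="group"),
    )
    src = SourceGroupSet(groups={f"s{i}": [f"s{i}"] for i in range(3)},
                         stats=stats_df)
    zero = Dtdf(d13C_mean=0, d13C_sd=0, d15N_mean=0, d15N_sd=0)
    consumers = pd.DataFrame(
        [(3.0, 3.0), (4.9, 4.9), (5.2, 5.2), (-0.05, 3.0), (0.5, 0.5)],
        columns=["d13C", "d15N"],
        index=[f"c{i}" for i in range(5)],
    )
    rep = simulate_mixing_region(src, zero, consumers, n_iter=n_iter, seed=seed)

    # independent oracle: sign-of-cross-product point-in-triangle test on
    # the identical vertex stream
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(size=(n_iter, 3, 2))
    pts = consumers.to_numpy()
    inside = np.zeros(len(pts))
    for i in range(n_iter):
        a, b, c = mean + 0.1 * draws[i]
        s = np.empty((3, len(pts)))
        for row, (p, q) in enumerate(((a, b), (b, c), (c, a))):
            s[row] = (q[0] - p[0]) * (pts[:, 1] - p[1]) - (q[1] - p[1]) * (
                pts[:, 0] - p[0]
            )
        inside += ((s >= -1e-12).all(axis=0)) | ((s <= 1e-12).all(axis=0))
    oracle = inside / n_iter
    return float(np.abs(rep.consumer_probabilities.to_numpy() - oracle).max())


def planted_outlier_agreement(seed: int) -> dict[str, float]:
    """Feasibility screening on a cohort with 3 planted infeasible consumers."""
    cfg = IsotopeSimConfig(
        source_truth=default_source_truth(4), n_consumers=40,
        n_infeasible=3, seed=seed,
    )
    records, _, truth = simulate_isotope_study(cfg)
    consumers = records[records["role"] == "consumer"].set_index("specimen_id")
    rep = simulate_mixing_region(
        truth["sample_sources"], cfg.dtdf, consumers, n_iter=5_000, seed=seed + 1
    )
    flagged = set(flag_outliers(rep))
    return {
        "n_flagged": len(flagged),
        "flagged_match_planted": float(flagged == set(truth["excluded"])),
    }


# ---------------------------------------------------------------------------
# Mixing-model recovery


def recovery_replicates(
    seed: int, n_reps: int = 20, mcmc: McmcConfig = REDUCED_MCMC
) -> dict[str, float]:
    """K=4 parameter recovery under the symmetric well-separated design.

    Per replicate: simulate n=100 consumers at the known truth, fit with the
    reduced schedule, record the worst posterior-mean deviation, the worst
    Gelman-Rubin statistic, and whether all 95% intervals cover the truth.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    devs, rhats, covered = [], [], []
    for rs in rep_seeds:
        cfg = IsotopeSimConfig(
            source_truth=recovery_source_truth(), p_true=RECOVERY_P_TRUE,
            n_consumers=100, n_specimens_per_source=25, seed=rs,
        )
        records, _, truth = simulate_isotope_study(cfg)
        model = IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf
        )
        res = model.fit(mcmc, seed=rs + 1)
        m = res.p_global.mean(axis=0)
        devs.append(float(np.abs(m - RECOVERY_P_TRUE).max()))
        rhats.append(float(res.rhat.max()))
        s = res.summary()
        covered.append(
            bool(
                np.all(
                    (s["2.5%"].to_numpy() <= RECOVERY_P_TRUE)
                    & (s["97.5%"].to_numpy() >= RECOVERY_P_TRUE)
                )
            )
        )
    return {
        "max_abs_error": max(devs),
        "mean_abs_error": float(np.mean(devs)),
        "max_rhat": max(rhats),
        "coverage": float(np.mean(covered)),
        "n_replicates": n_reps,
    }


def variance_ratio_recovery(
    seed: int, mcmc: McmcConfig = REDUCED_MCMC
) -> dict[str, float]:
    """Habitat:session variance-ratio recovery at a true ratio of 4."""
    cfg = IsotopeSimConfig(
        source_truth=default_source_truth(3), n_consumers=200,
        sigma_habitat=0.4, sigma_session=0.2, seed=seed,
    )
    records, meta, truth = simulate_isotope_study(cfg)
    model = IsotopeMixingModel.from_frames(
        records, truth["sample_sources"], cfg.dtdf,
        metadata=meta, factors=("habitat", "session"),
    )
    res = model.fit(mcmc, seed=seed + 1)
    vp = res.variance_partition()
    return {
        "ratio_median": float(vp.loc["habitat", "variance_ratio_vs_session"]),
        "max_rhat": float(res.rhat.max()),
        "n_consumers": cfg.n_consumers,
    }


# ---------------------------------------------------------------------------
# Determinism


def pipeline_determinism(seed: int, workdir: str | Path | None = None) -> float:
    """1.0 if two same-seed pipeline runs produce byte-identical outputs."""
    ctx = (
        tempfile.TemporaryDirectory() if workdir is None else None
    )
    root = Path(ctx.name) if ctx else Path(workdir)
    try:
        table, meta, _ = simulate_asv_table(AsvSimConfig(n_samples=40, seed=seed))
        iso_cfg = IsotopeSimConfig(
            source_truth=default_source_truth(4), n_consumers=24, seed=seed + 1
        )
        records, iso_meta, _ = simulate_isotope_study(iso_cfg)
        odio.write_asv_table(table, root / "plant_asv.csv")
        odio.write_metadata(pd.concat([meta, iso_meta]), root / "metadata.csv")
        odio.write_isotopes(records, root / "isotopes.csv")
        paths = {
            "plant_asv": root / "plant_asv.csv",
            "metadata": root / "metadata.csv",
            "isotopes": root / "isotopes.csv",
        }
        digests = []
        for run in ("a", "b"):
            cfg = RunConfig(
                n_permutations=49,
                polygon_iterations=1_000,
                mcmc=McmcConfig(chains=2, iterations=600, burn_in=300, thin=3),
                seed=seed,
            )
            out = root / run
            run_pipeline(cfg, paths, out)
            digest = {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.iterdir())
            }
            digests.append(digest)
        return float(digests[0] == digests[1])
    finally:
        if ctx:
            ctx.cleanup()
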