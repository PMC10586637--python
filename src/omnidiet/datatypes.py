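"""Core containers for the two-track diet analysis.

The pipeline moves through three kinds of evidence:

* annotated amplicon sequence variant (ASV) read counts per fecal sample,
* binary occurrence matrices and frequency-of-occurrence summaries derived
  from them, and
* stable-isotope measurements (delta13C, delta15N, %C, %N) of consumers and
  candidate food sources.

All containers are thin dataclasses around :class:`pandas.DataFrame` so the
usual pandas idioms (indexing, joins, CSV round trips) remain available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("phylum", "order", "family", "genus", "species")
HABITATS = ("forest", "herbland", "shrub", "wetland")
SESSIONS = tuple(range(1, 8))
MARKERS = ("arthropod_COI", "plant_ITS2")
TRACERS = ("d13C", "d15N")


class ValidationError(ValueError):
    """Structured parse/validation failure naming the offending location."""


@dataclass
class AnnotatedASVTable:
    """Per-sample read counts per ASV plus taxonomic annotation.

    Parameters
    ----------
    counts : DataFrame
        Samples (rows) by ASVs (columns), non-negative integer read counts.
    taxonomy : DataFrame
        One row per ASV (index = ASV id) with columns ``phylum`` through
        ``species``.  Unassigned ranks are stored as empty strings so rank
        filters are total functions.
    marker : str
        ``"arthropod_COI"`` or ``"plant_ITS2"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    marker: str

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(
                f"unknown marker {self.marker!r}; expected one of {MARKERS}"
            )
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate ASV id {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                bad = np.argwhere(np.mod(vals, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.counts.index[bad[0]]!r}, "
                    f"ASV {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[bad[0]]!r}, "
                f"ASV {self.counts.columns[bad[1]]!r}"
            )
        missing_ranks = [r for r in TAXONOMY_RANKS if r not in self.taxonomy.columns]
        if missing_ranks:
            raise ValidationError(f"taxonomy missing rank columns {missing_ranks}")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValidationError(f"ASVs without taxonomy record: {list(missing)[:5]}")
        self.taxonomy = (
            self.taxonomy.loc[self.counts.columns, list(TAXONOMY_RANKS)]
            .fillna("")
            .astype(str)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_asvs(self, keep: list[str]) -> "AnnotatedASVTable":
        return AnnotatedASVTable(
            counts=self.counts.loc[:, keep].copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
            marker=self.marker,
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample id).

    ``habitat`` must be one of the four habitat types, ``session`` an integer
    trapping session 1-7.  ``sex`` and ``age`` are pass-through.
    """
    required = {"habitat", "session", "sex", "age"}
    missing = required.difference(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r} in metadata")
    bad_hab = set(meta["habitat"]) - set(HABITATS)
    if bad_hab:
        raise ValidationError(
            f"unknown habitat label(s) {sorted(bad_hab)}; expected {HABITATS}"
        )
    sessions = pd.to_numeric(meta["session"], errors="coerce")
    if sessions.isna().any() or not set(sessions.astype(int)) <= set(SESSIONS):
        bad = meta["session"][~sessions.isin(SESSIONS)].iloc[0]
        raise ValidationError(f"session {bad!r} outside 1-7")
    out = meta.copy()
    out["session"] = sessions.astype(int)
    return out


ISOTOPE_COLUMNS = ("specimen_id", "role", "label", "d13C", "d15N", "pctC", "pctN")


def validate_isotopes(records: pd.DataFrame) -> pd.DataFrame:
    """Validate isotope measurements of consumers and sources."""
    missing = set(ISOTOPE_COLUMNS).difference(records.columns)
    if missing:
        raise ValidationError(f"isotope table missing columns {sorted(missing)}")
    bad_role = set(records["role"]) - {"consumer", "source"}
    if bad_role:
        raise ValidationError(f"unknown role(s) {sorted(bad_role)}")
    for col in ("d13C", "d15N", "pctC", "pctN"):
        vals = pd.to_numeric(records[col], errors="coerce")
        if vals.isna().any():
            row = records.index[vals.isna()][0]
            raise ValidationError(f"non-numeric or missing {col} at row {row}")
        records = records.assign(**{col: vals.astype(float)})
    for col in ("pctC", "pctN"):
        bad = (records[col] <= 0) | (records[col] > 100)
        if bad.any():
            row = records.index[bad][0]
            raise ValidationError(f"{col} outside (0, 100] at row {row}")
    if not np.isfinite(records[["d13C", "d15N"]].to_numpy()).all():
        raise ValidationError("non-finite delta value")
    return records


@dataclass
class Dtdf:
    """Diet-tissue discrimination factor: mean +/- SD offset per tracer (permil)."""

    d13C_mean: float = 1.7
    d13C_sd: float = 1.3
    d15N_mean: float = 3.2
    d15N_sd: float = 1.1
    name: str = "hair"

    def __post_init__(self) -> None:
        if self.d13C_sd < 0 or self.d15N_sd < 0:
            raise ValidationError("DTDF SD must be >= 0")

    def mean(self, tracer: str) -> float:
        return {"d13C": self.d13C_mean, "d15N": self.d15N_mean}[tracer]

    def sd(self, tracer: str) -> float:
        return {"d13C": self.d13C_sd, "d15N": self.d15N_sd}[tracer]


@dataclass
class McmcConfig:
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValidationError("mcmc.burn_in must be < mcmc.iterations")
        if self.chains < 1 or self.thin < 1:
            raise ValidationError("mcmc.chains and mcmc.thin must be >= 1")


# The study's published schedule: 3 chains x 1,000,000 iterations,
# 500,000 burn-in, thinned by 500.
FULL_MCMC = McmcConfig(chains=3, iterations=1_000_000, burn_in=500_000, thin=500)


@dataclass
class RunConfig:
    """Run configuration for the full pipeline.

    Defaults follow the study conditions: presence at >=1% relative read
    abundance, mixing-model sources at >=5% frequency of occurrence, 9,999
    permutations, hair-tissue DTDF of 1.7 +/- 1.3 permil (d13C) and
    3.2 +/- 1.1 permil (d15N).
    """

    rra_presence_threshold: float = 0.01
    foo_source_threshold: float = 0.05
    n_permutations: int = 9_999
    dtdf: Dtdf = field(default_factory=Dtdf)
    polygon_iterations: int = 10_000
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    dirichlet_alpha: float = 1.0
    aggregation_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rra_presence_threshold", "foo_source_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.dirichlet_alpha <= 0:
            raise ValidationError("dirichlet_alpha must be > 0")

    def check_aggregation(self, sources: list[str]) -> None:
        """Pre-flight: the aggregation map must cover every source exactly once."""
        if not self.aggregation_map:
            return
        missing = set(sources) - set(self.aggregation_map)
        extra = set(self.aggregation_map) - set(sources)
        if missing:
            raise ValidationError(f"aggregation_map missing source(s) {sorted(missing)}")
        if extra:
            raise ValidationError(f"aggregation_map has unknown source(s) {sorted(extra)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "dtdf" in d and isinstance(d["dtdf"], Mapping):
            d["dtdf"] = Dtdf(**d["dtdf"])
        if "mcmc" in d and isinstance(d["mcmc"], Mapping):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the top-level seed and a stable stage name.

    Keying the stream on the stage name makes each stage's randomness
    independent of the order stages run in.
    """
    ss = np.random.SeedSequence([root_seed, int.from_bytes(stage.encode(), "little") % (2**63)])
    return int(ss.generate_state(1)[0] % (2**31))
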