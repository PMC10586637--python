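"""Stable-isotope arithmetic and source grouping.

delta values are per-mil deviations from an international standard
(Vienna PeeDee Belemnite for carbon, atmospheric N2 for nitrogen).  Before a
mixing model can run, the candidate food taxa must be reduced to a small set
of isotopically coherent source groups: some groups are fixed a priori
(C3 plants, C4 plants, seabird tissue), the remaining arthropod taxa are
clustered with Ward's method (ward.D2, i.e. Ward on Euclidean distances of
the per-taxon mean (d13C, d15N) vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import TRACERS, Dtdf, ValidationError

__all__ = [
    "SourceGroupSet",
    "delta_from_ratios",
    "apply_dtdf_to_consumer",
    "ward_cluster_sources",
    "summarize_source_groups",
    "build_source_design",
]


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """delta X = (R_sample / R_standard - 1) x 1000, in per mil."""
    if r_standard <= 0:
        raise ValidationError("R_standard must be > 0")
    return (r_sample / r_standard - 1.0) * 1000.0


def apply_dtdf_to_consumer(
    consumer: pd.DataFrame | pd.Series, dtdf: Dtdf
) -> pd.DataFrame | pd.Series:
    """Subtract the mean discrimination factor from consumer delta values.

    This is the display / mixing-polygon convention (consumers shifted back
    towards diet space).  The mixing model itself instead adds the DTDF to
    source means and its variance to source variances; consumer data are
    never pre-corrected there.
    """
    out = consumer.copy()
    for tracer in TRACERS:
        if tracer in (out.index if isinstance(out, pd.Series) else out.columns):
            out[tracer] = out[tracer] - dtdf.mean(tracer)
    return out


@dataclass
class SourceGroupSet:
    """Grouped sources with the statistics the mixing model consumes.

    ``groups`` maps group name -> member taxa; ``stats`` has one row per
    group with per-tracer mean/SD, mean elemental concentrations, and n.
    """

    groups: dict[str, list[str]]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


def _taxon_means(source_records: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon mean (d13C, d15N) over specimens, sorted by taxon name."""
    means = source_records.groupby("label")[["d13C", "d15N"]].mean()
    return means.sort_index()


def ward_cluster_sources(
    source_records: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
) -> SourceGroupSet:
    """Cluster candidate source taxa into isotopically coherent groups.

    Agglomerative Ward clustering (ward.D2) on per-taxon mean (d13C, d15N)
    vectors in raw per-mil units.  The number of groups is chosen within
    ``k_range`` by the within-versus-among variance principle: among the k
    for which every group's within-group variance (pooled over both tracers,
    specimen level) is smaller than the among-group variance of group means,
    the cut with the largest relative jump in Ward merge heights is selected
    (the bare smallest-k rule accepts any coarse split of well-separated
    data, so the dendrogram gap arbitrates).  Ties and structureless data
    resolve to the smallest admissible k.  Tie-breaking is stable: taxa are
    processed in name order, groups are named cluster_1..cluster_k by the
    name of their first member.
    """
    means = _taxon_means(source_records)
    if len(means) < 2:
        raise ValidationError("clustering needs >= 2 taxa")
    lo, hi = k_range
    lo = max(lo, 1)
    hi = min(hi, len(means))
    if lo > hi:
        raise ValidationError(f"k_range {k_range} infeasible for {len(means)} taxa")
    X = means.to_numpy()
    n = len(X)
    if np.allclose(X, X[0]):
        # no isotopic structure at all: arbitrary even split into lo groups
        labels = np.arange(n) * lo // n + 1
        return _labelled_groups(means, labels)
    Z = linkage(X, method="ward")
    heights = np.concatenate([[0.0], Z[:, 2]])  # heights[m] after m merges
    eps = 1e-12 * max(heights.max(), 1.0)

    scores: dict[int, float] = {}
    admissible: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if labels.max() != k:
            continue
        # ratio of the first excluded merge height to the last included one;
        # the all-singletons cut has no included merge and gets no credit
        if 1 < k < n:
            score = (heights[n - k + 1] + eps) / (heights[n - k] + eps)
        else:
            score = 0.0
        scores[k] = score
        if _within_below_among(source_records, means, labels):
            admissible[k] = score
    pool = admissible or scores
    if not pool:
        raise ValidationError(f"no valid clustering in k_range {k_range}")
    chosen = min(sorted(pool), key=lambda k: (-pool[k], k))
    labels = fcluster(Z, t=chosen, criterion="maxclust")
    return _labelled_groups(means, labels)


def _labelled_groups(means: pd.DataFrame, labels: np.ndarray) -> SourceGroupSet:
    groups: dict[str, list[str]] = {}
    seen: dict[int, str] = {}
    for taxon, lab in zip(means.index, labels):
        if lab not in seen:
            seen[lab] = f"cluster_{len(seen) + 1}"
        groups.setdefault(seen[lab], []).append(taxon)
    return SourceGroupSet(groups=groups)



def _within_below_among(
    records: pd.DataFrame, means: pd.DataFrame, labels: np.ndarray
) -> bool:
    """Check the grouping criterion: every within-group variance < among."""
    k = labels.max()
    if k < 2:
        return False
    taxon_to_group = dict(zip(means.index, labels))
    rec_groups = records["label"].map(taxon_to_group)
    centroids = np.array(
        [means.to_numpy()[labels == g].mean(axis=0) for g in range(1, k + 1)]
    )
    among = centroids.var(axis=0, ddof=1).mean()
    for g in range(1, k + 1):
        sub = records.loc[rec_groups == g, ["d13C", "d15N"]].to_numpy()
        if len(sub) < 2:
            within = 0.0
        else:
            within = sub.var(axis=0, ddof=1).mean()
        if within >= among:
            return False
    return True


def summarize_source_groups(
    groups: dict[str, list[str]], isotope_records: pd.DataFrame
) -> SourceGroupSet:
    """Per-group mean/SD per tracer and mean %C/%N over member specimens.

    SDs use the n-1 denominator.  A single-specimen group gets SD 0 with a
    warning rather than NaN.
    """
    sources = isotope_records[isotope_records["role"] == "source"]
    rows = []
    for name, members in groups.items():
        sub = sources[sources["label"].isin(members)]
        if sub.empty:
            raise ValidationError(f"group {name!r} has no specimens")
        if len(sub) == 1:
            warnings.warn(f"group {name!r} has a single specimen; SD set to 0",
                          stacklevel=2)
        row = {"group": name, "n": len(sub)}
        for tracer in TRACERS:
            row[f"mean_{tracer}"] = sub[tracer].mean()
            row[f"sd_{tracer}"] = sub[tracer].std(ddof=1) if len(sub) > 1 else 0.0
        row["mean_pctC"] = sub["pctC"].mean()
        row["mean_pctN"] = sub["pctN"].mean()
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("group")
    return SourceGroupSet(groups=dict(groups), stats=stats)


def build_source_design(
    clustered: SourceGroupSet,
    a_priori_groups: dict[str, list[str]],
    isotope_records: pd.DataFrame,
) -> SourceGroupSet:
    """Concatenate a-priori groups (e.g. C3/C4 plants, seabird) with clusters.

    The study design yields eight sources (five clustered arthropod groups
    plus three a-priori groups), or seven when the seabird source is left
    out.  Group names must not collide and member taxa must be disjoint.
    """
    collisions = set(clustered.groups) & set(a_priori_groups)
    if collisions:
        raise ValidationError(f"group name collision(s): {sorted(collisions)}")
    members_a = {t for m in clustered.groups.values() for t in m}
    members_b = {t for m in a_priori_groups.values() for t in m}
    overlap = members_a & members_b
    if overlap:
        raise ValidationError(f"taxa in both clustered and a-priori groups: {sorted(overlap)}")
    combined = {**a_priori_groups, **clustered.groups}
    return summarize_source_groups(combined, isotope_records)
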