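"""Permutation-based multivariate analysis of diet occurrence data.

The spatial/temporal structure of diet composition is tested on a Sorensen
dissimilarity matrix with a two-way crossed PERMANOVA (habitat x trapping
session, Type III sums of squares, permutation of residuals under the
reduced model) and a PERMDISP test of multivariate dispersion.  All sums of
squares come from trace identities on the Gower-centred matrix
G = -1/2 J D^2 J, following the McArdle-Anderson formulation, so no raw
coordinates are ever needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .occurrence import OccurrenceMatrix

__all__ = [
    "DissimilarityMatrix",
    "PcoaResult",
    "PermanovaResults",
    "PermdispResult",
    "sorensen_matrix",
    "pcoa",
    "permanova",
    "permanova_two_way",
    "permdisp",
    "pairwise_permanova",
]


@dataclass
class DissimilarityMatrix:
    ids: list
    D: np.ndarray
    flagged_pairs: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        self.D = D

    def subset(self, keep_idx: np.ndarray) -> "DissimilarityMatrix":
        ids = [self.ids[i] for i in keep_idx]
        return DissimilarityMatrix(ids=ids, D=self.D[np.ix_(keep_idx, keep_idx)])


def sorensen_matrix(occ: OccurrenceMatrix) -> DissimilarityMatrix:
    """Sorensen dissimilarity (b+c)/(2a+b+c) between binary sample profiles.

    Pairs where both samples are all-absent have an empty denominator; they
    are set to 0 and reported in ``flagged_pairs``.
    """
    X = occ.presence.to_numpy(dtype=float)
    shared = X @ X.T                      # a
    richness = X.sum(axis=1)              # a + b per sample
    denom = richness[:, None] + richness[None, :]   # 2a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        D = (denom - 2 * shared) / denom
    flagged = []
    empty = denom == 0
    if empty.any():
        ii, jj = np.nonzero(np.triu(empty, k=1))
        flagged = [(occ.sample_ids[i], occ.sample_ids[j]) for i, j in zip(ii, jj)]
        D[empty] = 0.0
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(ids=occ.sample_ids, D=D, flagged_pairs=flagged)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


@dataclass
class PcoaResult:
    ids: list
    coordinates: np.ndarray        # n x n axis scores (signed-sqrt scaling)
    eigenvalues: np.ndarray        # descending; negatives retained
    proportion_explained: np.ndarray  # over non-negative eigenvalues only

    def as_frame(self, n_axes: int = 2) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(n_axes)]
        return pd.DataFrame(self.coordinates[:, :n_axes], index=self.ids, columns=cols)


def pcoa(dm: DissimilarityMatrix) -> PcoaResult:
    """Principal coordinates analysis with all eigenvalues retained.

    Negative eigenvalues (metric violations of the dissimilarity) are kept,
    and their axes carry coordinates scaled by sqrt(|lambda|); the dispersion
    test needs them to correct squared distances.  No Lingoes/Cailliez
    correction is applied.
    """
    G = _gower_center(dm.D)
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = np.abs(eigvals).max() * 1e-10 if len(eigvals) else 0.0
    eigvals[np.abs(eigvals) < tol] = 0.0
    coords = eigvecs * np.sqrt(np.abs(eigvals))[None, :]
    pos = eigvals[eigvals > 0]
    prop = pos / pos.sum() if pos.sum() > 0 else pos
    return PcoaResult(
        ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _sum_contrasts(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n x (L-1)."""
    X = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(R)) > np.abs(R).max() * 1e-10)
    if rank < X.shape[1]:
        raise ValidationError("singular design matrix (inestimable term)")
    return Q @ Q.T


def _design(metadata: pd.DataFrame, ids: list, factors: tuple[str, ...]):
    """Build per-term design blocks with sum-to-zero contrasts."""
    missing = [i for i in ids if i not in metadata.index]
    if missing:
        raise ValidationError(f"metadata missing sample(s) {missing[:5]}")
    blocks: dict[str, np.ndarray] = {}
    level_codes = {}
    for f in factors:
        vals = metadata.loc[ids, f]
        levels = sorted(pd.unique(vals), key=str)
        if len(levels) < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels")
        codes = np.array([levels.index(v) for v in vals])
        level_codes[f] = (codes, levels)
        blocks[f] = _sum_contrasts(codes, len(levels))
    if len(factors) == 2:
        a, b = factors
        ca, la = level_codes[a]
        cb, lb = level_codes[b]
        # Every cell of the crossed design must be occupied.
        cells = set(zip(ca, cb))
        for i, j in itertools.product(range(len(la)), range(len(lb))):
            if (i, j) not in cells:
                raise ValidationError(
                    f"empty design cell ({a}={la[i]!r}, {b}={lb[j]!r})"
                )
        Xa, Xb = blocks[a], blocks[b]
        inter = np.einsum("ni,nj->nij", Xa, Xb).reshape(len(ids), -1)
        blocks[f"{a} x {b}"] = inter
    n_cells = {f: len(level_codes[f][1]) for f in factors}
    if len(factors) == 2:
        n_cells[f"{factors[0]} x {factors[1]}"] = (
            n_cells[factors[0]] * n_cells[factors[1]]
        )
    return blocks, n_cells


@dataclass
class PermanovaResults:
    """PERMANOVA table with components of variation.

    ``table`` rows are the model terms plus Residual and Total; columns
    follow the conventional layout (df, SS, MS, pseudo-F, permutation p,
    component of variation and its square root, in dissimilarity units).
    """

    table: pd.DataFrame
    n_permutations: int
    n_samples: int

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:.4g}".format):
            head = (
                f"PERMANOVA ({self.n_samples} samples, "
                f"{self.n_permutations} permutations)\n"
            )
            return head + self.table.to_string()


def permanova(
    dm: DissimilarityMatrix,
    metadata: pd.DataFrame,
    factors: tuple[str, ...],
    n_perm: int = 9_999,
    seed: int | None = None,
) -> PermanovaResults:
    """Crossed PERMANOVA with Type III SS via trace identities.

    For each term the SS is tr((H_full - H_drop)G) where H_drop is the hat
    matrix of the design without that term (partial, order-independent =
    Type III under sum-to-zero contrasts).  p-values use permutation of
    residuals under the reduced model (Freedman-Lane): the residual Gower
    matrix G_r = (I-H_red) G (I-H_red) is row/column permuted and the
    pseudo-F statistic recomputed, p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not 1 <= len(factors) <= 2:
        raise ValidationError("one or two factors supported")
    ids = list(dm.ids)
    n = len(ids)
    G = _gower_center(dm.D)
    blocks, n_cells = _design(metadata, ids, tuple(factors))
    terms = list(blocks)
    ones = np.ones((n, 1))
    X_full = np.hstack([ones] + [blocks[t] for t in terms])
    H_full = _hat(X_full)
    I = np.eye(n)
    ss_res = float(np.trace((I - H_full) @ G))
    ss_total = float(np.trace(G))
    df_model = sum(blocks[t].shape[1] for t in terms)
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    ms_res = ss_res / df_res

    # Deterministic given (seed, sorted ids): the permutation stream is keyed
    # to the sorted id order, so reordering samples cannot change p-values.
    sort_order = np.argsort(np.array(ids, dtype=str))
    inv_sort = np.argsort(sort_order)
    rng = np.random.default_rng(seed)

    rows = []
    for t in terms:
        df_t = blocks[t].shape[1]
        X_red = np.hstack([ones] + [blocks[u] for u in terms if u != t])
        H_red = _hat(X_red)
        A = H_full - H_red
        ss_t = float(np.trace(A @ G))
        ms_t = ss_t / df_t
        F_t = ms_t / ms_res
        R = I - H_red
        G_r = R @ G @ R
        B = I - H_full
        # permute in sorted-id space for reorder invariance
        A_s = A[np.ix_(sort_order, sort_order)]
        B_s = B[np.ix_(sort_order, sort_order)]
        G_s = G_r[np.ix_(sort_order, sort_order)]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G_s[np.ix_(perm, perm)]
            ss_t_p = float((A_s * Gp).sum())
            ss_res_p = float((B_s * Gp).sum())
            if ss_res_p <= 0:
                count += 1
                continue
            F_p = (ss_t_p / df_t) / (ss_res_p / df_res)
            if F_p >= F_t - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        k_t = n / n_cells[t]  # mean cell size: EMS multiplier (exact if balanced)
        comp_var = (ms_t - ms_res) / k_t
        rows.append(
            {
                "source": t,
                "df": df_t,
                "SS": ss_t,
                "MS": ms_t,
                "pseudo_F": F_t,
                "p_perm": p,
                "component": "Fixed",
                "component_var": comp_var,
                "component_sd": math.sqrt(max(comp_var, 0.0)),
            }
        )
    rows.append(
        {
            "source": "Residual",
            "df": df_res,
            "SS": ss_res,
            "MS": ms_res,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
            "component": "Random",
            "component_var": ms_res,
            "component_sd": math.sqrt(ms_res),
        }
    )
    rows.append(
        {
            "source": "Total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "pseudo_F": np.nan,
            "p_perm": np.nan,
            "component": "",
            "component_var": np.nan,
            "component_sd": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("source")
    return PermanovaResults(table=table, n_permutations=n_perm, n_samples=n)


def permanova_two_way(
    dm: DissimilarityMatrix,
    metadata: pd.DataFrame,
    factors: tuple[str, str] = ("habitat", "session"),
    n_perm: int = 9_999,
    seed: int | None = None,
) -> PermanovaResults:
    """Two-way crossed PERMANOVA (main effects + interaction)."""
    if len(factors) != 2:
        raise ValidationError("permanova_two_way needs exactly two factors")
    return permanova(dm, metadata, factors, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PERMDISP


@dataclass
class PermdispResult:
    group_means: pd.Series     # mean distance-to-centroid per group
    distances: pd.Series       # per-sample distance to its group centroid
    F: float
    df1: int
    df2: int
    p_perm: float

    def summary(self) -> str:
        lines = ["PERMDISP (homogeneity of multivariate dispersion)"]
        for g, m in self.group_means.items():
            lines.append(f"  {g}: mean distance to centroid = {m:.4f}")
        lines.append(
            f"  F({self.df1}, {self.df2}) = {self.F:.4f}, p = {self.p_perm:.4f}"
        )
        return "\n".join(lines)


def _dispersion_distances(dm: DissimilarityMatrix, groups: pd.Series) -> pd.Series:
    """Distances to group centroids on PCoA axes.

    Squared distances on negative-eigenvalue axes are subtracted from those
    on positive axes (Anderson's correction for semi-metric dissimilarities);
    the difference is floored at 0 before the square root.
    """
    res = pcoa(dm)
    pos = res.eigenvalues > 0
    neg = res.eigenvalues < 0
    C_pos = res.coordinates[:, pos]
    C_neg = res.coordinates[:, neg]
    ids = list(dm.ids)
    z = np.empty(len(ids))
    g = groups.loc[ids]
    for level in pd.unique(g):
        idx = np.nonzero((g == level).to_numpy())[0]
        cen_pos = C_pos[idx].mean(axis=0)
        cen_neg = C_neg[idx].mean(axis=0)
        d2_pos = ((C_pos[idx] - cen_pos) ** 2).sum(axis=1)
        d2_neg = ((C_neg[idx] - cen_neg) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2_pos - d2_neg, 0.0))
    return pd.Series(z, index=ids)


def permdisp(
    dm: DissimilarityMatrix,
    groups: pd.Series,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> PermdispResult:
    """Permutation test of homogeneity of multivariate dispersions.

    Distance-to-centroid is computed in PCoA space with the negative-axis
    correction; the F statistic is a one-way ANOVA F on those distances and
    its p-value comes from permuting distances among groups.
    """
    ids = list(dm.ids)
    g = groups.loc[ids]
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValidationError("PERMDISP needs >= 2 groups")
    sizes = g.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index[0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    z = _dispersion_distances(dm, g)

    codes = pd.Categorical(g).codes
    n = len(ids)
    k = len(levels)
    zv = z.to_numpy()
    F_obs = _anova_F_static(zv, codes, k, n)
    # permutation stream keyed to sorted ids for reorder invariance
    sort_order = np.argsort(np.array(ids, dtype=str))
    z_sorted = zv[sort_order]
    codes_sorted = codes[sort_order]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        F_p = _anova_F_static(z_sorted[perm], codes_sorted, k, n)
        if F_p >= F_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    means = z.groupby(g).mean()
    return PermdispResult(
        group_means=means, distances=z, F=F_obs, df1=k - 1, df2=n - k, p_perm=p
    )


def _anova_F_static(values: np.ndarray, codes: np.ndarray, k: int, n: int) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for c in range(k):
        sel = values[codes == c]
        m = sel.mean()
        ss_between += len(sel) * (m - grand) ** 2
        ss_within += ((sel - m) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def pairwise_permanova(
    dm: DissimilarityMatrix,
    groups: pd.Series,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way PERMANOVA for each pair of groups; t = sqrt(pseudo-F).

    p-values are reported raw (no multiplicity correction), matching the
    convention of the software this mirrors.
    """
    ids = list(dm.ids)
    g = groups.loc[ids]
    levels = sorted(pd.unique(g), key=str)
    if len(levels) < 2:
        raise ValidationError("pairwise tests need >= 2 groups")
    meta = pd.DataFrame({"group": g})
    rows = []
    for x, y in itertools.combinations(levels, 2):
        keep = np.nonzero(((g == x) | (g == y)).to_numpy())[0]
        sub = dm.subset(keep)
        res = permanova(sub, meta, ("group",), n_perm=n_perm, seed=seed)
        F = res.table.loc["group", "pseudo_F"]
        rows.append(
            {
                "group_1": x,
                "group_2": y,
                "t": math.sqrt(max(F, 0.0)),
                "p_perm": res.table.loc["group", "p_perm"],
            }
        )
    return pd.DataFrame(rows)
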