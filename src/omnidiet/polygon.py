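"""Monte-Carlo mixing-region feasibility screening.

A linear two-tracer mixing model can only explain a consumer that lies
inside the convex hull (mixing polygon) of the discrimination-corrected
source signatures.  Because both the source means and the discrimination
factor are uncertain, the hull itself is uncertain: each Monte-Carlo
iteration draws every source's corrected signature from
Normal(mean + DTDF_mean, sqrt(sd^2 + DTDF_sd^2)) per tracer, builds the
hull, and tests every consumer for membership.  The fraction of iterations
in which a consumer falls inside is its inclusion probability; consumers
below 5% (outside the "95% mixing region") are flagged as infeasible and
excluded from the mixing model.  The same machinery ranks candidate
discrimination factors by how well they cover the consumers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .datatypes import TRACERS, Dtdf, ValidationError
from .isotopes import SourceGroupSet

__all__ = ["PolygonReport", "simulate_mixing_region", "flag_outliers",
           "rank_dtdf_candidates"]


@dataclass
class PolygonReport:
    """Per-consumer inclusion probabilities under one DTDF candidate."""

    consumer_probabilities: pd.Series   # id -> inside fraction
    n_iterations: int
    dtdf: Dtdf
    alpha: float = 0.05

    @property
    def mean_probability(self) -> float:
        return float(self.consumer_probabilities.mean())

    @property
    def n_inside(self) -> int:
        return int((self.consumer_probabilities >= self.alpha).sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inclusion_probability": self.consumer_probabilities,
                "excluded": self.consumer_probabilities < self.alpha,
            }
        ).rename_axis("consumer_id")


def _points_in_hull(points: np.ndarray, vertices: np.ndarray,
                    tol: float = 1e-9) -> np.ndarray:
    """Membership of ``points`` in the convex hull of ``vertices`` (2-D).

    Boundary points count as inside.  Degenerate vertex sets (collinear or
    coincident) fall back to a segment/point test, again inclusive.
    """
    uniq = np.unique(vertices, axis=0)
    if len(uniq) == 1:
        return np.all(np.abs(points - uniq[0]) <= tol, axis=1)
    try:
        hull = ConvexHull(vertices)
    except QhullError:
        return _points_on_segment(points, uniq, tol)
    # hull.equations: outward normals; inside iff all n.x + b <= 0
    vals = points @ hull.equations[:, :2].T + hull.equations[:, 2]
    return np.all(vals <= tol, axis=1)


def _points_on_segment(points: np.ndarray, uniq: np.ndarray,
                       tol: float) -> np.ndarray:
    # principal direction of the collinear vertex set
    center = uniq.mean(axis=0)
    d = uniq - center
    direction = d[np.argmax((d**2).sum(axis=1))]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return np.all(np.abs(points - center) <= tol, axis=1)
    direction = direction / norm
    rel = points - center
    t = rel @ direction
    t_all = (uniq - center) @ direction
    perp = rel - np.outer(t, direction)
    on_line = np.linalg.norm(perp, axis=1) <= tol
    return on_line & (t >= t_all.min() - tol) & (t <= t_all.max() + tol)


def simulate_mixing_region(
    sources: SourceGroupSet,
    dtdf: Dtdf,
    consumers: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PolygonReport:
    """Monte-Carlo mixing polygons; per-consumer inclusion probability.

    ``consumers`` needs columns ``d13C``/``d15N`` indexed by consumer id.
    Requires >= 3 sources (the hull must be able to be two-dimensional) and
    >= 1000 iterations for a stable probability estimate.
    """
    if len(sources) < 3:
        raise ValidationError("mixing polygon needs >= 3 sources")
    if n_iter < 1000:
        raise ValidationError("n_iter must be >= 1000")
    stats = sources.stats
    mean = np.column_stack(
        [stats[f"mean_{t}"].to_numpy() + dtdf.mean(t) for t in TRACERS]
    )
    sd = np.column_stack(
        [np.sqrt(stats[f"sd_{t}"].to_numpy() ** 2 + dtdf.sd(t) ** 2) for t in TRACERS]
    )
    pts = consumers[list(TRACERS)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    inside = np.zeros(len(pts), dtype=np.int64)
    K = len(stats)
    draws = rng.standard_normal(size=(n_iter, K, 2))
    for i in range(n_iter):
        verts = mean + sd * draws[i]
        inside += _points_in_hull(pts, verts)
    probs = pd.Series(inside / n_iter, index=consumers.index, name="inclusion_probability")
    return PolygonReport(consumer_probabilities=probs, n_iterations=n_iter,
                         dtdf=dtdf, alpha=alpha)


def flag_outliers(report: PolygonReport, alpha: float = 0.05) -> list:
    """Consumers with inclusion probability strictly below ``alpha``.

    These lie outside the 95% mixing region and are excluded from the
    mixing model; a probability exactly at the threshold is retained.
    """
    p = report.consumer_probabilities
    return list(p.index[p < alpha])


def rank_dtdf_candidates(
    candidates: list[Dtdf],
    sources: SourceGroupSet,
    consumers: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate discrimination factors by consumer coverage.

    Primary key: number of consumers with inclusion probability >= alpha;
    secondary: mean inclusion probability.  The sort is stable so identical
    candidates keep their input order.  Each candidate is scored with an
    independent, seed-derived stream, deterministic given ``seed``.
    """
    if not candidates:
        raise ValidationError("need at least one DTDF candidate")
    # stream keyed to the candidate's values: identical candidates score
    # identically, so the stable sort preserves their input order
    child_seeds = []
    for cand in candidates:
        key = [int(abs(v) * 1e6) % (2**31) for v in
               (cand.d13C_mean, cand.d13C_sd, cand.d15N_mean, cand.d15N_sd)]
        ss = np.random.SeedSequence([seed or 0, *key])
        child_seeds.append(int(ss.generate_state(1)[0] % (2**31)))
    rows = []
    for i, (cand, s) in enumerate(zip(candidates, child_seeds)):
        rep = simulate_mixing_region(sources, cand, consumers, n_iter=n_iter,
                                     seed=s, alpha=alpha)
        rows.append(
            {
                "candidate": i,
                "name": cand.name,
                "n_consumers_inside": rep.n_inside,
                "mean_inclusion_probability": rep.mean_probability,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["n_consumers_inside", "mean_inclusion_probability"],
        ascending=False,
        kind="mergesort",
    ).reset_index(drop=True)
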