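"""Concentration-dependent hierarchical Bayesian stable-isotope mixing model.

The model estimates the proportional contribution of K food-source groups to
consumer diet from two tracers (d13C, d15N), in the style of MixSIAR:

* global diet proportions ``p`` get a Dirichlet(alpha) prior (alpha = 1 is
  the "uninformative"/generalist choice);
* random effects (habitat, trapping session) act additively on the
  isometric log-ratio (ILR) transform of ``p``:
  ``p_i = ilr_inv(ilr(p) + sum_f eps[f, level_f(i)])`` with
  ``eps[f, l, m] ~ Normal(0, sigma_f_m^2)`` and a weak Uniform(0, 20) prior
  on each sigma;
* the likelihood is Normal with concentration-dependent moments.  With
  ``c_kj`` the mean elemental concentration (%C or %N) of source k for
  tracer j, the concentration-weighted proportions are
  ``ptilde_kj = p_k c_kj / sum_l p_l c_lj`` and

      mean_j = sum_k ptilde_kj (mu_kj + DTDF_j)
      var_j  = xi_j * sum_k ptilde_kj^2 (s_kj^2 + DTDFsd_j^2)

  the multiplicative residual factor ``xi_j ~ Uniform(0, 20)`` is the
  process*residual error structure: xi_j = 1 is pure process error, larger
  values inflate it to absorb unexplained consumer variability.

Inference is by a self-contained adaptive block Metropolis-within-Gibbs
sampler (no probabilistic-programming dependency); convergence is judged by
the Gelman-Rubin potential scale reduction factor (target < 1.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import helmert

from .datatypes import TRACERS, Dtdf, McmcConfig, ValidationError
from .isotopes import SourceGroupSet

__all__ = [
    "IsotopeMixingModel",
    "MixingResults",
    "ilr",
    "ilr_inv",
    "mixture_mean",
    "mixture_variance",
    "gelman_rubin",
    "aggregate_sources",
    "summarize_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# ILR transform (fixed orthonormal Helmert basis; sources in name order)


def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal (K-1) x K contrast matrix; rows orthogonal to 1."""
    if k < 2:
        raise ValidationError("ILR needs K >= 2 parts")
    return helmert(k, full=False)


def ilr(p: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio transform of composition(s) ``p`` (last axis)."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    psi = ilr_basis(k) if basis is None else basis
    return np.log(p) @ psi.T


def ilr_inv(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Inverse ILR: map real coordinates back to the simplex."""
    x = np.asarray(x, dtype=float)
    k = x.shape[-1] + 1
    psi = ilr_basis(k) if basis is None else basis
    y = x @ psi
    y -= y.max(axis=-1, keepdims=True)
    e = np.exp(y)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Mixing moments


def _source_arrays(sources: SourceGroupSet, dtdf: Dtdf):
    stats = sources.stats
    mu = np.column_stack([stats[f"mean_{t}"].to_numpy() + dtdf.mean(t) for t in TRACERS])
    s2 = np.column_stack(
        [stats[f"sd_{t}"].to_numpy() ** 2 + dtdf.sd(t) ** 2 for t in TRACERS]
    )
    conc = np.column_stack([stats["mean_pctC"].to_numpy(), stats["mean_pctN"].to_numpy()])
    if np.all(conc == 0):
        raise ValidationError("all elemental concentrations are zero")
    return mu, s2, conc


def _conc_weights(p: np.ndarray, conc_j: np.ndarray) -> np.ndarray:
    denom = p @ conc_j
    return p * conc_j / denom[..., None]


def mixture_mean(
    p: np.ndarray, sources: SourceGroupSet, dtdf: Dtdf, tracer: str
) -> float | np.ndarray:
    """Concentration-weighted mixture mean for one tracer, in per mil."""
    j = TRACERS.index(tracer)
    mu, _, conc = _source_arrays(sources, dtdf)
    w = _conc_weights(np.asarray(p, dtype=float), conc[:, j])
    out = w @ mu[:, j]
    return float(out) if out.ndim == 0 else out


def mixture_variance(
    p: np.ndarray, sources: SourceGroupSet, dtdf: Dtdf, tracer: str, xi: float = 1.0
) -> float | np.ndarray:
    """Process variance scaled by the residual multiplier xi, in per mil^2."""
    if xi <= 0:
        raise ValidationError("xi must be > 0")
    j = TRACERS.index(tracer)
    _, s2, conc = _source_arrays(sources, dtdf)
    w = _conc_weights(np.asarray(p, dtype=float), conc[:, j])
    out = xi * (w**2 @ s2[:, j])
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Gelman-Rubin


def gelman_rubin(chain_draws: np.ndarray) -> float:
    """Potential scale reduction factor from m chains of n draws each.

    Classic between/within formulation: with W the mean within-chain
    variance and B the between-chain variance of chain means (times n),
    Rhat = sqrt(((n-1)/n W + B/n) / W).
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("gelman_rubin needs >= 2 chains (m x n array)")
    m, n = x.shape
    if n < 10:
        raise ValidationError("gelman_rubin needs >= 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Model


class IsotopeMixingModel:
    """Bayesian mixing model for diet proportions of K source groups.

    Parameters
    ----------
    consumers : DataFrame
        Indexed by consumer id with columns ``d13C`` and ``d15N`` (raw,
        uncorrected tissue values; the DTDF is applied to sources inside the
        likelihood).  Feasibility outliers should already be excluded.
    sources : SourceGroupSet
        Grouped sources with mean/SD per tracer and mean %C/%N.
    dtdf : Dtdf
        Diet-tissue discrimination factor, mean and SD per tracer.
    random_factors : mapping, optional
        Factor name -> Series mapping consumer id to factor level (e.g.
        habitat, trapping session).  Factors act additively in ILR space.
    alpha : float
        Dirichlet concentration of the prior on global proportions.
    sigma_upper, xi_upper : float
        Upper bounds of the Uniform priors on random-effect SDs (ILR units)
        and residual multipliers.
    """

    def __init__(
        self,
        consumers: pd.DataFrame,
        sources: SourceGroupSet,
        dtdf: Dtdf,
        random_factors: Mapping[str, pd.Series] | None = None,
        alpha: float = 1.0,
        sigma_upper: float = 20.0,
        xi_upper: float = 20.0,
    ) -> None:
        if len(sources) < 2:
            raise ValidationError("mixing model needs >= 2 sources")
        if alpha <= 0:
            raise ValidationError("Dirichlet alpha must be > 0")
        missing = [t for t in TRACERS if t not in consumers.columns]
        if missing:
            raise ValidationError(f"consumers missing tracer column(s) {missing}")
        # sources pinned to name order so the ILR basis is reproducible
        order = sorted(sources.names)
        self.sources = SourceGroupSet(
            groups={k: sources.groups[k] for k in order},
            stats=sources.stats.loc[order],
        )
        self.source_names = order
        self.K = len(order)
        self.dtdf = dtdf
        self.alpha = float(alpha)
        self.sigma_upper = float(sigma_upper)
        self.xi_upper = float(xi_upper)
        self.consumers = consumers
        self.delta = consumers[list(TRACERS)].to_numpy(dtype=float)
        if not np.isfinite(self.delta).all():
            raise ValidationError("non-finite consumer delta values")
        self.n = len(consumers)
        self.basis = ilr_basis(self.K)
        self.mu_src, self.s2_src, self.conc = _source_arrays(self.sources, dtdf)

        self.factor_names: list[str] = []
        self.factor_levels: dict[str, list] = {}
        self.factor_codes: dict[str, np.ndarray] = {}
        for name, series in (random_factors or {}).items():
            levels = sorted(pd.unique(series.loc[consumers.index]), key=str)
            codes = series.loc[consumers.index].map({l: i for i, l in enumerate(levels)})
            if codes.isna().any():
                raise ValidationError(f"factor {name!r} missing level for some consumer")
            self.factor_names.append(name)
            self.factor_levels[name] = levels
            self.factor_codes[name] = codes.to_numpy(dtype=int)

    @classmethod
    def from_frames(
        cls,
        isotope_records: pd.DataFrame,
        sources: SourceGroupSet,
        dtdf: Dtdf,
        metadata: pd.DataFrame | None = None,
        factors: tuple[str, ...] = (),
        exclude: tuple = (),
        **kwargs,
    ) -> "IsotopeMixingModel":
        """Build from a validated isotope table (+ optional sample metadata)."""
        cons = isotope_records[isotope_records["role"] == "consumer"].set_index(
            "specimen_id"
        )
        cons = cons.drop(index=[e for e in exclude if e in cons.index])
        random_factors = {}
        if metadata is not None:
            for f in factors:
                random_factors[f] = metadata.loc[cons.index, f]
        return cls(cons, sources, dtdf, random_factors=random_factors, **kwargs)

    # -- log densities -----------------------------------------------------

    def _loglik_subset(self, idx: np.ndarray, eta: np.ndarray,
                       xi: np.ndarray) -> np.ndarray:
        """Per-consumer, per-tracer log likelihood (len(idx) x 2)."""
        p = ilr_inv(eta, self.basis)
        out = np.empty((len(idx), 2))
        for j in range(2):
            w = _conc_weights(p, self.conc[:, j])
            mean = w @ self.mu_src[:, j]
            var = xi[j] * ((w**2) @ self.s2_src[:, j])
            out[:, j] = -0.5 * ((self.delta[idx, j] - mean) ** 2 / var
                                + np.log(var) + _LOG_2PI)
        return out

    def _eta(self, phi: np.ndarray, eps: dict[str, np.ndarray],
             idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            eta = np.broadcast_to(phi, (self.n, self.K - 1)).copy()
            for f in self.factor_names:
                eta += eps[f][self.factor_codes[f]]
        else:
            eta = np.broadcast_to(phi, (len(idx), self.K - 1)).copy()
            for f in self.factor_names:
                eta += eps[f][self.factor_codes[f][idx]]
        return eta

    def _log_prior_phi(self, phi: np.ndarray) -> float:
        # Dirichlet(alpha) on p plus the ILR Jacobian collapses to
        # sum_k alpha * log p_k (orthonormal basis).
        p = ilr_inv(phi, self.basis)
        return float(self.alpha * np.log(p).sum())

    # -- sampling ----------------------------------------------------------

    def fit(
        self,
        mcmc: McmcConfig | None = None,
        seed: int | None = None,
        prior_only: bool = False,
    ) -> "MixingResults":
        """Run the adaptive block Metropolis-within-Gibbs sampler.

        ``prior_only=True`` disables the likelihood (prior predictive runs,
        used to validate the prior implementation).
        """
        mcmc = mcmc or McmcConfig()
        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(mcmc.chains)
        keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
        if keep < 1:
            raise ValidationError("MCMC schedule keeps no draws")
        chains = [
            self._run_chain(np.random.default_rng(s), mcmc, prior_only)
            for s in chain_seeds
        ]
        draws = {
            key: np.stack([c[key] for c in chains]) for key in chains[0]
        }
        return MixingResults(model=self, draws=draws, mcmc=mcmc, seed=seed)

    def _run_chain(self, rng: np.random.Generator, mcmc: McmcConfig,
                   prior_only: bool) -> dict[str, np.ndarray]:
        K, n = self.K, self.n
        F = self.factor_names
        # overdispersed initials from the prior
        phi = ilr(rng.dirichlet(np.full(K, self.alpha)), self.basis)
        eps = {f: rng.normal(0.0, 0.1, size=(len(self.factor_levels[f]), K - 1))
               for f in F}
        sigma = {f: rng.uniform(0.2, 2.0, size=K - 1) for f in F}
        xi = rng.uniform(0.5, 2.0, size=2)

        like_on = not prior_only
        row_ll = (self._loglik_subset(np.arange(n), self._eta(phi, eps), xi)
                  if like_on else np.zeros((n, 2)))
        lp_phi = self._log_prior_phi(phi)

        # The phi block learns an empirical proposal covariance (Haario-style
        # adaptive Metropolis, continuing for the whole run with naturally
        # diminishing updates) so weakly identified directions of the
        # simplex mix well even when burn-in under-explores them.
        sc_phi = 0.2
        phi_hist = np.empty((mcmc.iterations, K - 1))
        L_phi = np.eye(K - 1)
        sc_eps = {f: np.full(len(self.factor_levels[f]), 0.2) for f in F}
        sc_sig = {f: np.full(K - 1, 0.5) for f in F}
        sc_xi = np.full(2, 0.3)
        acc = {"phi": 0.0}
        acc_xi = np.zeros(2)
        acc_eps = {f: np.zeros(len(self.factor_levels[f])) for f in F}
        acc_sig = {f: np.zeros(K - 1) for f in F}
        batch = 50
        n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
        out = {
            "p_global": np.empty((n_keep, K)),
            "xi": np.empty((n_keep, 2)),
        }
        for f in F:
            out[f"eps_{f}"] = np.empty((n_keep, len(self.factor_levels[f]), K - 1))
            out[f"sigma_{f}"] = np.empty((n_keep, K - 1))
        kept = 0

        level_rows = {
            f: [np.nonzero(self.factor_codes[f] == l)[0]
                for l in range(len(self.factor_levels[f]))]
            for f in F
        }

        for it in range(mcmc.iterations):
            # -- global proportions block (several sweeps: phi carries the
            # weakly identified simplex directions, so it gets extra moves)
            for _ in range(4):
                prop = phi + sc_phi * (L_phi @ rng.standard_normal(K - 1))
                lp_prop = self._log_prior_phi(prop)
                if like_on:
                    new_ll = self._loglik_subset(np.arange(n), self._eta(prop, eps), xi)
                    log_r = lp_prop - lp_phi + new_ll.sum() - row_ll.sum()
                else:
                    new_ll = row_ll
                    log_r = lp_prop - lp_phi
                if math.log(rng.uniform()) < log_r:
                    phi, lp_phi, row_ll = prop, lp_prop, new_ll
                    acc["phi"] += 0.25

            # -- random-effect level blocks
            for f in F:
                sig2 = sigma[f] ** 2
                for l, rows in enumerate(level_rows[f]):
                    e_old = eps[f][l].copy()
                    e_new = e_old + sc_eps[f][l] * rng.standard_normal(K - 1)
                    dprior = -0.5 * float(((e_new**2 - e_old**2) / sig2).sum())
                    if like_on and len(rows):
                        eps[f][l] = e_new
                        ll_new = self._loglik_subset(rows, self._eta(phi, eps, rows), xi)
                        eps[f][l] = e_old
                        dlike = ll_new.sum() - row_ll[rows].sum()
                    else:
                        ll_new = None
                        dlike = 0.0
                    if math.log(rng.uniform()) < dprior + dlike:
                        eps[f][l] = e_new
                        if ll_new is not None:
                            row_ll[rows] = ll_new
                        acc_eps[f][l] += 1

            # -- recentering moves: eta = phi + sum_f eps_f is likelihood-
            # invariant under phi -> phi - c, eps_f -> eps_f + c.  The shift
            # c is proposed from its Gaussian full conditional under the
            # eps prior (an independence proposal), so only the Dirichlet
            # prior on phi enters the acceptance ratio.  This removes the
            # slow drift along the phi/random-effect flat direction.
            for f in F:
                L = eps[f].shape[0]
                c = (-eps[f].mean(axis=0)
                     + (sigma[f] / math.sqrt(L)) * rng.standard_normal(K - 1))
                lp_new = self._log_prior_phi(phi - c)
                if math.log(rng.uniform()) < lp_new - lp_phi:
                    phi = phi - c
                    lp_phi = lp_new
                    eps[f] = eps[f] + c

            # -- random-effect SDs (prior-only conditional, Uniform(0, U))
            for f in F:
                e2 = (eps[f] ** 2).sum(axis=0)
                L = eps[f].shape[0]
                for m in range(K - 1):
                    s_old = sigma[f][m]
                    s_new = s_old + sc_sig[f][m] * rng.standard_normal()
                    if not 0.0 < s_new < self.sigma_upper:
                        continue
                    log_r = (
                        -L * math.log(s_new) - 0.5 * e2[m] / s_new**2
                        + L * math.log(s_old) + 0.5 * e2[m] / s_old**2
                    )
                    if math.log(rng.uniform()) < log_r:
                        sigma[f][m] = s_new
                        acc_sig[f][m] += 1

            # -- residual multipliers (tracer likelihoods are separable)
            for j in range(2):
                xj = xi[j] + sc_xi[j] * rng.standard_normal()
                if not 0.0 < xj < self.xi_upper:
                    continue
                if like_on:
                    prop_xi = xi.copy()
                    prop_xi[j] = xj
                    new_ll = self._loglik_subset(
                        np.arange(n), self._eta(phi, eps), prop_xi
                    )
                    log_r = new_ll[:, j].sum() - row_ll[:, j].sum()
                else:
                    new_ll = row_ll
                    log_r = 0.0
                if math.log(rng.uniform()) < log_r:
                    xi[j] = xj
                    row_ll = row_ll.copy()
                    row_ll[:, j] = new_ll[:, j]
                    acc_xi[j] += 1

            # -- adaptation: the phi proposal covariance updates from the
            # second half of the chain's history (diminishing by construction
            # as the history grows); scalar scales keep adapting with a
            # diminishing Robbins-Monro step (towards ~30%, 44% 1-D blocks)
            phi_hist[it] = phi
            if it >= 500 and (it + 1) % 200 == 0:
                cov = np.cov(phi_hist[it // 2: it + 1].T)
                cov = np.atleast_2d(cov) + 1e-8 * np.eye(K - 1)
                try:
                    L_phi = np.linalg.cholesky(cov / np.trace(cov) * (K - 1))
                except np.linalg.LinAlgError:  # pragma: no cover
                    pass
            if (it + 1) % batch == 0:
                step = min(0.1, 1.0 / math.sqrt((it + 1) / batch))
                sc_phi *= math.exp(step * (acc["phi"] / batch - 0.3))
                sc_xi *= np.exp(step * (acc_xi / batch - 0.44))
                acc["phi"] = 0.0
                acc_xi[:] = 0
                for f in F:
                    sc_eps[f] *= np.exp(step * (acc_eps[f] / batch - 0.3))
                    sc_sig[f] *= np.exp(step * (acc_sig[f] / batch - 0.44))
                    acc_eps[f][:] = 0
                    acc_sig[f][:] = 0

            # -- storage
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                out["p_global"][kept] = ilr_inv(phi, self.basis)
                out["xi"][kept] = xi
                for f in F:
                    out[f"eps_{f}"][kept] = eps[f]
                    out[f"sigma_{f}"][kept] = sigma[f]
                kept += 1
        return out


# ---------------------------------------------------------------------------
# Results


@dataclass
class MixingResults:
    """Posterior draws, diagnostics and summaries of a fitted mixing model.

    ``draws`` arrays are indexed (chain, kept iteration, ...).  Proportion
    vectors always sum to one; aggregation sums member proportions within
    each draw, preserving their covariation.
    """

    model: IsotopeMixingModel
    draws: dict[str, np.ndarray]
    mcmc: McmcConfig
    seed: int | None = None
    _rhat: pd.Series | None = field(default=None, repr=False)

    @property
    def source_names(self) -> list[str]:
        return self.model.source_names

    @property
    def p_global(self) -> np.ndarray:
        """Global diet proportions, flattened over chains: (draws, K)."""
        d = self.draws["p_global"]
        return d.reshape(-1, d.shape[-1])

    def level_proportions(self, factor: str, level) -> np.ndarray:
        """Per-draw proportion simplex at one level of a random factor."""
        if factor not in self.model.factor_names:
            raise ValidationError(f"unknown factor {factor!r}")
        li = self.model.factor_levels[factor].index(level)
        phi = ilr(self.draws["p_global"], self.model.basis)
        eta = phi + self.draws[f"eps_{factor}"][:, :, li, :]
        p = ilr_inv(eta, self.model.basis)
        return p.reshape(-1, p.shape[-1])

    @property
    def rhat(self) -> pd.Series:
        """Gelman-Rubin statistic for every monitored scalar."""
        if self._rhat is None:
            vals = {}
            for k, name_fn in self._monitored():
                arr = self.draws[k]
                for idx, label in name_fn(arr):
                    vals[label] = gelman_rubin(arr[(slice(None), slice(None)) + idx])
            self._rhat = pd.Series(vals, name="rhat")
        return self._rhat

    def _monitored(self):
        def p_names(arr):
            return [((k,), f"p[{self.source_names[k]}]") for k in range(arr.shape[-1])]

        def xi_names(arr):
            return [((j,), f"xi[{t}]") for j, t in enumerate(TRACERS)]

        items = [("p_global", p_names), ("xi", xi_names)]
        for f in self.model.factor_names:
            def sig_names(arr, f=f):
                return [((m,), f"sigma[{f},{m}]") for m in range(arr.shape[-1])]
            items.append((f"sigma_{f}", sig_names))
        return items

    @property
    def converged(self) -> bool:
        return bool((self.rhat < 1.1).all())

    def effective_sample_size(self) -> pd.Series:
        """Crude ESS per monitored scalar from lag-autocorrelations."""
        vals = {}
        for k, name_fn in self._monitored():
            arr = self.draws[k]
            for idx, label in name_fn(arr):
                x = arr[(slice(None), slice(None)) + idx]
                vals[label] = _ess(x)
        return pd.Series(vals, name="ess")

    def summary(
        self,
        by: str | None = None,
        aggregation_map: Mapping[str, str] | None = None,
    ) -> pd.DataFrame:
        """Posterior mean, SD and equal-tailed 50%/95% credible intervals.

        ``by`` adds one block per level of a random factor (diet proportions
        at that level); ``aggregation_map`` combines sources a posteriori.
        """
        blocks = [("overall", self.p_global, self.source_names)]
        if by is not None:
            for level in self.model.factor_levels[by]:
                blocks.append(
                    (f"{by}={level}", self.level_proportions(by, level),
                     self.source_names)
                )
        rows = []
        for scope, draws, names in blocks:
            if aggregation_map is not None:
                draws, names = _aggregate(draws, names, aggregation_map)
            rows.append(summarize_posterior(draws, names).assign(scope=scope))
        out = pd.concat(rows).reset_index()
        return out[["group", "scope", "mean", "sd", "2.5%", "25%", "75%", "97.5%"]]

    def aggregate(self, aggregation_map: Mapping[str, str]) -> "MixingResults":
        """A-posteriori aggregation of sources into combined groups."""
        draws, names = _aggregate(
            self.draws["p_global"], self.source_names, aggregation_map
        )
        new = dict(self.draws)
        new["p_global"] = draws
        res = MixingResults(model=self.model, draws=new, mcmc=self.mcmc, seed=self.seed)
        res._agg_names = names  # type: ignore[attr-defined]
        return res

    def variance_partition(self) -> pd.DataFrame:
        """Relative importance of the random factors.

        Two per-factor variance summaries are reported, each averaged over
        ILR coordinates and summarized by its posterior median:

        * ``hyper_var`` - the hierarchical variance sigma_f_m^2, the spread
          a hypothetical new factor level would have.  With few levels its
          posterior is strongly right-skewed.
        * ``level_effect_var`` - the realized variance of the fitted level
          effects (per draw, variance over levels of eps).  This is the
          amount of diet variation actually attributable to the observed
          levels and is the basis of the between-factor ratio.

        With two or more factors, the ratio of each factor's realized
        variance to the last factor's is reported with a 95% interval.
        """
        F = self.model.factor_names
        if not F:
            raise ValidationError("no random factors fitted")
        hyper = {}
        realized = {}
        for f in F:
            sig = self.draws[f"sigma_{f}"]
            hyper[f] = (sig**2).mean(axis=-1).reshape(-1)
            e = self.draws[f"eps_{f}"]
            e = e.reshape(-1, *e.shape[2:])           # draws x levels x coords
            centred = e - e.mean(axis=1, keepdims=True)
            realized[f] = (centred**2).mean(axis=(1, 2))
        rows = []
        ref = F[-1]
        for f in F:
            row = {
                "factor": f,
                "hyper_var": float(np.median(hyper[f])),
                "level_effect_var": float(np.median(realized[f])),
            }
            if len(F) > 1 and f != ref:
                ratio = realized[f] / realized[ref]
                row["variance_ratio_vs_" + ref] = float(np.median(ratio))
                row["ratio_2.5%"] = float(np.quantile(ratio, 0.025))
                row["ratio_97.5%"] = float(np.quantile(ratio, 0.975))
            rows.append(row)
        return pd.DataFrame(rows).set_index("factor")

    def diagnostics(self) -> dict:
        return {
            "rhat": self.rhat.to_dict(),
            "ess": self.effective_sample_size().to_dict(),
            "converged": self.converged,
            "chains": self.mcmc.chains,
            "kept_draws_per_chain": int(self.draws["p_global"].shape[1]),
        }


def _aggregate(
    draws: np.ndarray, names: list[str], aggregation_map: Mapping[str, str]
) -> tuple[np.ndarray, list[str]]:
    missing = set(names) - set(aggregation_map)
    extra = set(aggregation_map) - set(names)
    if missing or extra:
        raise ValidationError(
            f"aggregation map must partition sources (missing {sorted(missing)}, "
            f"unknown {sorted(extra)})"
        )
    targets = list(dict.fromkeys(aggregation_map[n] for n in names))
    M = np.zeros((len(names), len(targets)))
    for i, n in enumerate(names):
        M[i, targets.index(aggregation_map[n])] = 1.0
    return draws @ M, targets


def aggregate_sources(
    results: MixingResults, aggregation_map: Mapping[str, str]
) -> MixingResults:
    """Functional alias for :meth:`MixingResults.aggregate`."""
    return results.aggregate(aggregation_map)


def summarize_posterior(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Mean, SD and equal-tailed 50%/95% intervals of columns of ``draws``."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != len(names):
        raise ValidationError("draws must be (n_draws, n_groups)")
    q = np.quantile(draws, [0.025, 0.25, 0.75, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1) if len(draws) > 1 else 0.0,
            "2.5%": q[0],
            "25%": q[1],
            "75%": q[2],
            "97.5%": q[3],
        },
        index=pd.Index(names, name="group"),
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    m, n = x.shape
    if np.allclose(x.var(), 0):
        return float(m * n)
    acf_sum = 0.0
    for c in range(m):
        v = x[c] - x[c].mean()
        denom = (v**2).sum()
        if denom == 0:
            continue
        rho_prev = 1.0
        s = 0.0
        for lag in range(1, n):
            rho = (v[:-lag] * v[lag:]).sum() / denom
            if rho + rho_prev < 0:
                break
            s += rho
            rho_prev = rho
        acf_sum += s
    tau = 1.0 + 2.0 * acf_sum / m
    return float(m * n / max(tau, 1.0))
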