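"""Shared Bayesian machinery.

Everything model-agnostic lives here: the MCMC configuration, the covariate
standardization rule, an adaptive random-walk Metropolis-within-Gibbs sampler
(scalar updates for fixed effects, vectorised per-level updates for random
effects), split-chain Gelman-Rubin diagnostics, and the sign-credibility rule
(an effect is "credible" when at least 97.5% of its posterior mass lies on one
side of zero).

The sampler is deliberately self-contained: it targets hierarchical GLMM-style
posteriors in which every data row receives a single additive random-effect
offset, which covers all the models in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

TARGET_ACCEPT = 0.44  # optimal scalar random-walk acceptance rate
CREDIBILITY_LEVEL = 0.975


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.

    Defaults follow the tactic-transition analysis (3 chains, 20 000
    iterations, burn-in 2 500, thinning 100); each model exposes its own
    published defaults through its ``fit`` method.
    """

    chains: int = 3
    iterations: int = 20_000
    burnin: int = 2_500
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        """Post-burn-in draws kept per chain."""
        return (self.iterations - self.burnin) // self.thin


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults; overridable per model."""

    coef_sd: float = 10.0       # Normal(0, coef_sd^2) on regression coefficients
    sd_scale: float = 5.0       # half-Normal(0, sd_scale^2) on random-effect SDs


# ---------------------------------------------------------------------------
# covariate standardization


def standardize_covariates(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score numeric covariates whose observed range leaves [0, 1].

    Columns entirely inside [0, 1] (proportions, indicators) are left alone.
    Returns the transformed table and per-column ``(mean, sd)`` metadata so
    posterior curves can be drawn back on the original scale; unscaled columns
    get ``(0.0, 1.0)``.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    meta: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        if finite.size == 0:
            meta[col] = (0.0, 1.0)
            continue
        if finite.min() >= 0.0 and finite.max() <= 1.0:
            meta[col] = (0.0, 1.0)
            continue
        sd = float(finite.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"column {col!r} has zero variance; left unscaled")
            meta[col] = (0.0, 1.0)
            continue
        mean = float(finite.mean())
        out[col] = (x - mean) / sd
        meta[col] = (mean, sd)
    return out, meta


def apply_scaling(x: np.ndarray | float, meta: tuple[float, float]) -> np.ndarray | float:
    """Map raw covariate values onto the fitted (standardized) scale."""
    mean, sd = meta
    return (x - mean) / sd


def back_transform(x: np.ndarray | float, meta: tuple[float, float]) -> np.ndarray | float:
    """Inverse of :func:`apply_scaling`."""
    mean, sd = meta
    return x * sd + mean


# ---------------------------------------------------------------------------
# diagnostics and credibility


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape ``(chains, n, dim)`` (a 2-D array is treated as one
    parameter). Each chain is split in half, so R-hat also flags trending
    single chains. Values are floored at 1.0, so identical chains give
    exactly 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.shape[0] < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = draws.shape[1]
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, n_s, dim = split.shape
    chain_means = split.mean(axis=1)                       # (m, dim)
    chain_vars = split.var(axis=1, ddof=1)                 # (m, dim)
    w = chain_vars.mean(axis=0)
    b = n_s * chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n_s - 1) / n_s * w + b / n_s
        rhat = np.sqrt(np.maximum(1.0, var_hat / w))
    rhat = np.where(w == 0.0, 1.0, rhat)
    return rhat


def credibility(draws: np.ndarray) -> tuple[float, float, bool]:
    """95% equal-tail interval plus the sign-credibility flag.

    Credible iff the share of draws above zero is >= 0.975 or <= 0.025
    (boundary inclusive). Percentiles use linear interpolation so summaries
    are exactly reproducible from saved draws.
    """
    flat = np.asarray(draws, dtype=float).ravel()
    if flat.size < 40:
        raise ValueError("need at least 40 draws for a stable 95% interval")
    lci, hci = np.percentile(flat, [2.5, 97.5], method="linear")
    share_pos = float(np.mean(flat > 0))
    share_neg = float(np.mean(flat < 0))
    credible = share_pos >= CREDIBILITY_LEVEL or share_neg >= CREDIBILITY_LEVEL
    return float(lci), float(hci), credible


@dataclass
class PosteriorSummary:
    """Per-parameter posterior: draws plus the derived summary statistics."""

    name: str
    draws: np.ndarray  # (chains, n)
    mean: float
    lci: float
    hci: float
    rhat: float
    credible: bool

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray) -> "PosteriorSummary":
        draws = np.asarray(draws, dtype=float)
        lci, hci, credible = credibility(draws)
        return cls(
            name=name,
            draws=draws,
            mean=float(draws.mean()),
            lci=lci,
            hci=hci,
            rhat=float(gelman_rubin(draws)[0]),
            credible=credible,
        )


def summary_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [s.name for s in summaries],
            "mean": [s.mean for s in summaries],
            "lci": [s.lci for s in summaries],
            "hci": [s.hci for s in summaries],
            "rhat": [s.rhat for s in summaries],
            "credible": [s.credible for s in summaries],
        }
    )


# ---------------------------------------------------------------------------
# generic sampler (plain log-posterior over a flat vector)


def run_mcmc(
    log_posterior: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: McmcConfig,
) -> np.ndarray:
    """Adaptive scalar random-walk Metropolis on an arbitrary log-posterior.

    Returns post-burn-in thinned draws of shape ``(chains, n_draws, dim)``.
    Proposal scales adapt toward a 44% acceptance rate during burn-in only,
    so the retained draws come from a fixed Markov kernel. Deterministic
    given ``config.seed``.
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    dim = init.size
    all_draws = np.empty((config.chains, config.n_draws, dim))
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        theta = init + 0.1 * rng.standard_normal(dim)
        lp = log_posterior(theta)
        if not np.isfinite(lp):
            theta = init.copy()
            lp = log_posterior(theta)
        if not np.isfinite(lp):
            raise ValueError("log-posterior not finite at the initial point")
        lscale = np.zeros(dim)
        kept = 0
        for it in range(config.iterations):
            adapting = it < config.burnin
            for j in range(dim):
                prop = theta.copy()
                prop[j] += np.exp(lscale[j]) * rng.standard_normal()
                lp_prop = log_posterior(prop)
                accept = np.log(rng.uniform()) < lp_prop - lp
                if accept:
                    theta, lp = prop, lp_prop
                if adapting:
                    gamma = min(0.25, (it + 1.0) ** -0.6)
                    lscale[j] += gamma * ((1.0 if accept else 0.0) - TARGET_ACCEPT)
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                if kept < config.n_draws:
                    all_draws[chain, kept] = theta
                    kept += 1
        if kept != config.n_draws:  # pragma: no cover - arithmetic guard
            raise RuntimeError("draw bookkeeping error")
        if not np.isfinite(lp):
            raise RuntimeError("non-finite log-posterior during sampling")
    return all_draws


# ---------------------------------------------------------------------------
# hierarchical sampler (fixed effects + additive random-effect offsets)


@dataclass
class REFactor:
    """One crossed random-effect factor: a level index per data row."""

    name: str
    index: np.ndarray  # (n_rows,) integer level codes
    n_levels: int

    @classmethod
    def from_labels(cls, name: str, labels: Sequence) -> "REFactor":
        codes, uniques = pd.factorize(np.asarray(labels))
        return cls(name=name, index=codes.astype(np.intp), n_levels=len(uniques))


class HierarchicalSpec:
    """Interface the blocked sampler expects.

    Subclasses provide a row-wise log-likelihood ``row_loglik(theta, offset,
    rows)`` where ``offset`` is the summed random-effect contribution per row,
    plus a log-prior over the fixed-effect vector ``theta``. ``theta_row_subsets``
    may map each coordinate to the rows it affects (``None`` = all rows) so
    scalar updates only recompute the likelihood where it changes.
    """

    theta_names: list[str]
    theta_init: np.ndarray
    re_factors: list[REFactor]
    n_rows: int
    priors: Priors = Priors()

    def row_loglik(self, theta: np.ndarray, offset: np.ndarray,
                   rows: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def theta_logprior(self, theta: np.ndarray) -> float:
        return float(-0.5 * np.sum((theta / self.priors.coef_sd) ** 2))

    @property
    def theta_row_subsets(self) -> list[np.ndarray | None]:
        return [None] * len(self.theta_names)


@dataclass
class HierarchicalDraws:
    """Raw output of :func:`sample_hierarchical`."""

    theta: np.ndarray                 # (chains, n_draws, dim)
    sigma: np.ndarray                 # (chains, n_draws, n_factors)
    theta_names: list[str]
    sigma_names: list[str]
    re: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (chains, n_draws, levels)

    def named(self, name: str) -> np.ndarray:
        """Draws (chains, n) for a fixed effect or RE standard deviation."""
        if name in self.theta_names:
            return self.theta[:, :, self.theta_names.index(name)]
        if name in self.sigma_names:
            return self.sigma[:, :, self.sigma_names.index(name)]
        raise KeyError(name)

    def all_names(self) -> list[str]:
        return list(self.theta_names) + list(self.sigma_names)

    def summaries(self) -> list[PosteriorSummary]:
        return [PosteriorSummary.from_draws(n, self.named(n)) for n in self.all_names()]


def _halfnormal_logpdf(s: float, scale: float) -> float:
    return -0.5 * (s / scale) ** 2


def sample_hierarchical(
    spec: HierarchicalSpec,
    config: McmcConfig,
    store_re: bool = False,
) -> HierarchicalDraws:
    """Blocked adaptive Metropolis-within-Gibbs for hierarchical models.

    Fixed effects update one coordinate at a time (recomputing only the rows
    that coordinate touches); each random-effect vector updates all levels at
    once with element-wise accept/reject, which is valid because levels are
    conditionally independent given everything else; RE standard deviations
    update on the log scale under their half-Normal prior.
    """
    n = spec.n_rows
    factors = spec.re_factors
    nf = len(factors)
    dim = len(spec.theta_names)
    subsets = spec.theta_row_subsets
    sd_scale = spec.priors.sd_scale

    theta_out = np.empty((config.chains, config.n_draws, dim))
    sigma_out = np.empty((config.chains, config.n_draws, nf))
    re_out = (
        {f.name: np.empty((config.chains, config.n_draws, f.n_levels)) for f in factors}
        if store_re
        else {}
    )

    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        theta = spec.theta_init + 0.1 * rng.standard_normal(dim)
        u = [np.zeros(f.n_levels) for f in factors]
        log_sigma = np.full(nf, np.log(0.5))
        offset = np.zeros(n)
        row_ll = spec.row_loglik(theta, offset)
        if not np.all(np.isfinite(row_ll)):
            theta = spec.theta_init.copy()
            row_ll = spec.row_loglik(theta, offset)
        if not np.all(np.isfinite(row_ll)):
            raise ValueError("log-likelihood not finite at the initial point")
        lp_prior = spec.theta_logprior(theta)

        theta_lscale = np.full(dim, -1.0)
        u_lscale = [np.full(f.n_levels, -1.0) for f in factors]
        sig_lscale = np.full(nf, -1.5)
        rescale_lscale = np.full(nf, -1.5)
        kept = 0

        for it in range(config.iterations):
            adapting = it < config.burnin
            gamma = min(0.25, (it + 1.0) ** -0.6) if adapting else 0.0

            # --- fixed effects, scalar adaptive RWM -----------------------
            for j in range(dim):
                rows = subsets[j]
                prop = theta.copy()
                prop[j] += np.exp(theta_lscale[j]) * rng.standard_normal()
                prior_prop = spec.theta_logprior(prop)
                if rows is None:
                    new_ll = spec.row_loglik(prop, offset)
                    delta = new_ll.sum() - row_ll.sum()
                else:
                    new_ll = spec.row_loglik(prop, offset, rows)
                    delta = new_ll.sum() - row_ll[rows].sum()
                delta += prior_prop - lp_prior
                accept = np.isfinite(delta) and np.log(rng.uniform()) < delta
                if accept:
                    theta = prop
                    lp_prior = prior_prop
                    if rows is None:
                        row_ll = new_ll
                    else:
                        row_ll[rows] = new_ll
                if adapting:
                    theta_lscale[j] += gamma * ((1.0 if accept else 0.0) - TARGET_ACCEPT)

            # --- random effects, vectorised per-level accept/reject -------
            for fi, f in enumerate(factors):
                sigma = np.exp(log_sigma[fi])
                eps = np.exp(u_lscale[fi]) * rng.standard_normal(f.n_levels)
                u_new = u[fi] + eps
                offset_new = offset + eps[f.index]
                ll_new = spec.row_loglik(theta, offset_new)
                cur_lev = np.bincount(f.index, weights=row_ll, minlength=f.n_levels)
                new_lev = np.bincount(f.index, weights=ll_new, minlength=f.n_levels)
                logr = (
                    new_lev
                    - cur_lev
                    - 0.5 * (u_new**2 - u[fi] ** 2) / sigma**2
                )
                acc = np.log(rng.uniform(size=f.n_levels)) < logr
                if acc.any():
                    eps_acc = np.where(acc, eps, 0.0)
                    u[fi] = u[fi] + eps_acc
                    acc_rows = acc[f.index]
                    offset = offset + eps_acc[f.index]
                    row_ll = np.where(acc_rows, ll_new, row_ll)
                if adapting:
                    u_lscale[fi] += gamma * (acc.astype(float) - TARGET_ACCEPT)

                # --- RE standard deviation on the log scale ---------------
                prop_ls = log_sigma[fi] + np.exp(sig_lscale[fi]) * rng.standard_normal()
                s0, s1 = np.exp(log_sigma[fi]), np.exp(prop_ls)
                ssq = float(np.sum(u[fi] ** 2))
                lvl = f.n_levels
                logr_s = (
                    (-lvl * np.log(s1) - 0.5 * ssq / s1**2 + _halfnormal_logpdf(s1, sd_scale) + prop_ls)
                    - (-lvl * np.log(s0) - 0.5 * ssq / s0**2 + _halfnormal_logpdf(s0, sd_scale) + log_sigma[fi])
                )
                acc_s = np.log(rng.uniform()) < logr_s
                if acc_s:
                    log_sigma[fi] = prop_ls
                if adapting:
                    sig_lscale[fi] += gamma * ((1.0 if acc_s else 0.0) - TARGET_ACCEPT)

                # interweaving move: rescale the whole RE vector with its SD
                # (walks along the funnel; prior and Jacobian terms cancel)
                eps_r = np.exp(rescale_lscale[fi]) * rng.standard_normal()
                scale_r = np.exp(eps_r)
                u_resc = u[fi] * scale_r
                offset_resc = offset + (u_resc - u[fi])[f.index]
                ll_resc = spec.row_loglik(theta, offset_resc)
                s0 = np.exp(log_sigma[fi])
                s1 = s0 * scale_r
                logr_r = (
                    ll_resc.sum() - row_ll.sum()
                    + _halfnormal_logpdf(s1, sd_scale) - _halfnormal_logpdf(s0, sd_scale)
                    + eps_r
                )
                acc_r = np.log(rng.uniform()) < logr_r
                if acc_r:
                    u[fi] = u_resc
                    offset = offset_resc
                    row_ll = ll_resc
                    log_sigma[fi] += eps_r
                if adapting:
                    rescale_lscale[fi] += gamma * ((1.0 if acc_r else 0.0) - TARGET_ACCEPT)

            if it >= config.burnin and (it - config.burnin) % config.thin == 0 and kept < config.n_draws:
                theta_out[chain, kept] = theta
                sigma_out[chain, kept] = np.exp(log_sigma)
                if store_re:
                    for fi, f in enumerate(factors):
                        re_out[f.name][chain, kept] = u[fi]
                kept += 1

        if kept != config.n_draws:  # pragma: no cover
            raise RuntimeError("draw bookkeeping error")

    return HierarchicalDraws(
        theta=theta_out,
        sigma=sigma_out,
        theta_names=list(spec.theta_names),
        sigma_names=[f"sigma_{f.name}" for f in factors],
        re=re_out,
    )
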