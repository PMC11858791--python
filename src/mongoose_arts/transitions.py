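"""Multi-state model of between-oestrus reproductive-tactic transitions.

Males occupy one of four states at each oestrus event of their group:
``subordinate`` (reproductively inactive), ``sneaker``, ``guard`` or ``dead``.
The transition kernel factorises as

    P(dead | origin)   = 1 - survival[origin]
    P(m    | origin)   = survival[origin] * softmax_m(eta[origin, m])

with ``subordinate`` the reference live destination (eta fixed at 0) and

    eta[origin, m] = x' beta[origin, m] + u_male + u_group + u_event

for the two non-reference destinations, where x holds an intercept, age rank,
group-centred weight and group sex ratio. The single additive random effect
per male/group/event enters both non-reference predictors; adding it to every
destination would cancel in the softmax. Once dead, a male stays dead with
probability 1.

``TacticTransitionModel`` is the statsmodels-style entry point: build it from
a per-male-per-event dataframe, call :meth:`TacticTransitionModel.fit`, and
read estimates off the returned :class:`TransitionResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .mcmc import (
    HierarchicalSpec,
    McmcConfig,
    PosteriorSummary,
    Priors,
    REFactor,
    sample_hierarchical,
    standardize_covariates,
    summary_frame,
)

STATES = ("subordinate", "sneaker", "guard", "dead")
LIVE_STATES = ("subordinate", "sneaker", "guard")
DEAD = 3
DEFAULT_COVARIATES = ("age_rank", "group_centred_weight", "sex_ratio")
RHAT_THRESHOLD = 1.1


def state_index(state: int | str) -> int:
    if isinstance(state, str):
        return STATES.index(state)
    if state not in (0, 1, 2, 3):
        raise ValueError(f"unknown state {state!r}")
    return int(state)


@dataclass
class TacticHistory:
    """Ordered per-oestrus tactic sequence for one male; ``dead`` is terminal."""

    male_id: str
    events: list[tuple[str, str]]  # (oestrus_event_id, state name), in event order

    def __post_init__(self) -> None:
        seen_dead = False
        for _, state in self.events:
            idx = state_index(state)
            if seen_dead:
                raise ValueError(
                    f"male {self.male_id}: live state recorded after death"
                )
            seen_dead = idx == DEAD


@dataclass
class TransitionParams:
    """Everything needed to build a transition-probability row.

    ``beta[n, m, k]``: coefficient on covariate k (column 0 = intercept) for
    the transition from live state n to non-reference destination m
    (m = 0 -> sneaker, m = 1 -> guard). ``survival[n]``: per-origin
    probability of surviving to the next oestrus event.
    """

    beta: np.ndarray                       # (3, 2, 1 + n_covariates)
    survival: np.ndarray                   # (3,)
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    sigma_male: float = 0.0
    sigma_group: float = 0.0
    sigma_event: float = 0.0
    re_male: dict = field(default_factory=dict)
    re_group: dict = field(default_factory=dict)
    re_event: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.beta.shape[:2] != (3, 2):
            raise ValueError("beta must have shape (3, 2, 1 + n_covariates)")
        if self.beta.shape[2] != 1 + len(self.covariate_names):
            raise ValueError("beta covariate dimension does not match names")
        if self.survival.shape != (3,):
            raise ValueError("survival must have one entry per live state")
        if np.any(self.survival <= 0) or np.any(self.survival > 1):
            raise ValueError("survival probabilities must lie in (0, 1]")
        if min(self.sigma_male, self.sigma_group, self.sigma_event) < 0:
            raise ValueError("random-effect SDs must be non-negative")


def _covariate_vector(params: TransitionParams, cov: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(cov, Mapping):
        x = [float(cov[name]) for name in params.covariate_names]
    else:
        x = [float(v) for v in cov]
        if len(x) != len(params.covariate_names):
            raise ValueError("covariate vector length mismatch")
    return np.concatenate([[1.0], x])


def transition_probs(
    params: TransitionParams,
    cov: Mapping[str, float] | Sequence[float],
    origin: int | str,
    re_offset: float = 0.0,
) -> np.ndarray:
    """One row of the transition kernel, ordered (subordinate, sneaker, guard, dead).

    The dead origin returns (0, 0, 0, 1) exactly.
    """
    o = state_index(origin)
    if o == DEAD:
        return np.array([0.0, 0.0, 0.0, 1.0])
    x = _covariate_vector(params, cov)
    eta = np.array([0.0, x @ params.beta[o, 0] + re_offset, x @ params.beta[o, 1] + re_offset])
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    s = params.survival[o]
    live = s * np.exp(eta - logsumexp(eta))
    return np.concatenate([live, [1.0 - s]])


def _re_offset(params: TransitionParams, male_id, group_id, event_id) -> float:
    return (
        params.re_male.get(male_id, 0.0)
        + params.re_group.get(group_id, 0.0)
        + params.re_event.get(event_id, 0.0)
    )


def transition_loglik(
    params: TransitionParams,
    histories: Sequence[TacticHistory],
    covariates: Mapping,
) -> float:
    """Log-likelihood of observed tactic sequences.

    ``covariates`` maps ``(male_id, oestrus_event_id)`` to a covariate mapping
    (and optionally carries ``group_id`` used for the group random effect).
    Additive over males; dead-to-dead steps contribute log 1 = 0 and are
    skipped by history construction.
    """
    total = 0.0
    for hist in histories:
        for (ev_a, st_a), (ev_b, st_b) in itertools.pairwise(hist.events):
            o = state_index(st_a)
            d = state_index(st_b)
            if o == DEAD:
                raise ValueError(f"male {hist.male_id}: transition out of dead state")
            cov = covariates[(hist.male_id, ev_a)]
            group_id = cov.get("group_id") if isinstance(cov, Mapping) else None
            off = _re_offset(params, hist.male_id, group_id, ev_a)
            row = transition_probs(params, cov, o, re_offset=off)
            p = row[d]
            total += float(np.log(p)) if p > 0 else -np.inf
    return total


def params_on_standardized_scale(
    params: TransitionParams, scaling: Mapping[str, tuple[float, float]]
) -> TransitionParams:
    """Re-express raw-scale transition coefficients on the z-scored covariate
    scale a fitted model reports (an exact linear map: slopes scale by the
    covariate SD, intercepts absorb the means)."""
    beta = params.beta.copy()
    for k, name in enumerate(params.covariate_names, start=1):
        mean, sd = scaling[name]
        beta[:, :, 0] += params.beta[:, :, k] * mean
        beta[:, :, k] = params.beta[:, :, k] * sd
    return TransitionParams(
        beta=beta,
        survival=params.survival.copy(),
        covariate_names=params.covariate_names,
        sigma_male=params.sigma_male,
        sigma_group=params.sigma_group,
        sigma_event=params.sigma_event,
    )


# ---------------------------------------------------------------------------
# model


class _TransitionSpec(HierarchicalSpec):
    """Sampler-facing view of the transition data."""

    def __init__(self, origin, dest, X, free_mask, factors, priors, column_names):
        self.origin = origin
        self.dest = dest
        self.X = X
        self.free_mask = free_mask          # (3, 2, p) free beta entries
        self.n_free = int(free_mask.sum())
        self.re_factors = factors
        self.n_rows = len(origin)
        self.priors = priors
        self.column_names = list(column_names)
        p = X.shape[1]
        self._beta_template = np.zeros((3, 2, p))
        names = []
        free_origin = []
        for o, m, k in zip(*np.where(free_mask)):
            names.append(f"beta[{LIVE_STATES[o]}->{LIVE_STATES[m + 1]}][{self.column_names[k]}]")
            free_origin.append(o)
        for o in range(3):
            names.append(f"survival_logit[{LIVE_STATES[o]}]")
            free_origin.append(o)
        self.theta_names = names
        self.theta_init = np.zeros(len(names))
        self.theta_init[self.n_free :] = 2.0  # start near high survival
        self._subsets = [
            np.flatnonzero(self.origin == o).astype(np.intp) for o in range(3)
        ]
        self._subset_per_theta = [self._subsets[o] for o in free_origin]
        # per-origin blocks so likelihood evaluations are plain matmuls
        self._X_o = [self.X[idx] for idx in self._subsets]
        self._dest_o = [self.dest[idx] for idx in self._subsets]

    @property
    def theta_row_subsets(self):
        return self._subset_per_theta

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = self._beta_template.copy()
        beta[self.free_mask] = theta[: self.n_free]
        survival = expit(theta[self.n_free :])
        return beta, survival

    @staticmethod
    def _block_loglik(eta, d, s):
        """Per-row log-likelihood for one origin block (survival prob s)."""
        mx = np.maximum(0.0, eta.max(axis=1))
        lse = mx + np.log(
            np.exp(-mx) + np.exp(eta[:, 0] - mx) + np.exp(eta[:, 1] - mx)
        )
        with np.errstate(divide="ignore"):
            log_s = np.log(s)
            log_dead = np.log1p(-s)
        out = np.full(len(eta), log_s)
        out -= lse
        is1 = d == 1
        is2 = d == 2
        out[is1] += eta[is1, 0]
        out[is2] += eta[is2, 1]
        out[d == DEAD] = log_dead
        return out

    def row_loglik(self, theta, offset, rows=None):
        beta, survival = self.unpack(theta)
        if rows is not None:
            # scalar updates always touch exactly one origin's block
            for o in range(3):
                if rows is self._subsets[o]:
                    eta = self._X_o[o] @ beta[o].T + offset[rows][:, None]
                    return self._block_loglik(eta, self._dest_o[o], survival[o])
            o, d, Xr = self.origin[rows], self.dest[rows], self.X[rows]
            eta = np.einsum("np,nmp->nm", Xr, beta[o]) + offset[rows][:, None]
            mx = np.maximum(0.0, eta.max(axis=1))
            lse = mx + np.log(
                np.exp(-mx) + np.exp(eta[:, 0] - mx) + np.exp(eta[:, 1] - mx)
            )
            s = survival[o]
            with np.errstate(divide="ignore"):
                log_s = np.log(s)
                log_dead = np.log1p(-s)
            live_ll = np.select(
                [d == 0, d == 1, d == 2],
                [-lse, eta[:, 0] - lse, eta[:, 1] - lse],
                default=0.0,
            )
            return np.where(d == DEAD, log_dead, log_s + live_ll)
        out = np.empty(self.n_rows)
        for o in range(3):
            idx = self._subsets[o]
            if len(idx) == 0:
                continue
            eta = self._X_o[o] @ beta[o].T + offset[idx][:, None]
            out[idx] = self._block_loglik(eta, self._dest_o[o], survival[o])
        return out


class TacticTransitionModel:
    """Bayesian multi-state tactic-transition model with crossed random effects.

    Parameters
    ----------
    data
        One row per male per oestrus event with columns ``male_id``,
        ``oestrus_event_id``, ``group_id``, ``tactic`` (state name), the
        covariate columns, and an ordering column (default ``event_order``;
        an event start date works).
    covariate_names
        Covariates entering every live-destination linear predictor.
    interactions
        ``"none"`` (default), ``"keep"`` (always include sex-ratio x age-rank
        and sex-ratio x weight products) or ``"auto"`` (fit them, drop the
        ones that are not sign-credible, refit — the published procedure).
    standardize
        Apply the range-outside-[0,1] z-scoring rule before fitting.
    random_effects
        Subset of ("male", "group", "event"); pass ``()`` for a pure
        fixed-effects model.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariate_names: Sequence[str] = DEFAULT_COVARIATES,
        *,
        order_col: str = "event_order",
        interactions: str = "none",
        standardize: bool = True,
        random_effects: Sequence[str] = ("male", "group", "event"),
        priors: Priors = Priors(),
    ) -> None:
        if interactions not in ("none", "keep", "auto"):
            raise ValueError("interactions must be 'none', 'keep' or 'auto'")
        self.covariate_names = tuple(covariate_names)
        self.interactions = interactions
        self.priors = priors
        self.random_effects = tuple(random_effects)

        df = data.sort_values(["male_id", order_col], kind="stable").reset_index(drop=True)
        if standardize:
            df, self.scaling = standardize_covariates(df, list(self.covariate_names))
        else:
            self.scaling = {c: (0.0, 1.0) for c in self.covariate_names}

        origins, dests, rows = [], [], []
        for male_id, grp in df.groupby("male_id", sort=False):
            states = [state_index(s) for s in grp["tactic"]]
            for i in range(len(states) - 1):
                if states[i] == DEAD:
                    raise ValueError(f"male {male_id}: live state after death")
                origins.append(states[i])
                dests.append(states[i + 1])
                rows.append(grp.index[i])
        if not rows:
            raise ValueError("no transitions: every male needs >= 2 events")
        sub = df.loc[rows]
        self.origin = np.asarray(origins, dtype=np.intp)
        self.dest = np.asarray(dests, dtype=np.intp)

        cols = ["intercept"] + list(self.covariate_names)
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in self.covariate_names]
        )
        self._interaction_cols: list[str] = []
        if interactions in ("keep", "auto"):
            sr = sub["sex_ratio"].to_numpy(dtype=float)
            for other in ("age_rank", "group_centred_weight"):
                if other in self.covariate_names:
                    name = f"sex_ratio:{other}"
                    X = np.column_stack([X, sr * sub[other].to_numpy(dtype=float)])
                    cols.append(name)
                    self._interaction_cols.append(name)
        self.X = X
        self.column_names = cols

        label_cols = {"male": "male_id", "group": "group_id", "event": "oestrus_event_id"}
        self.factors = [
            REFactor.from_labels(name, sub[label_cols[name]].to_numpy())
            for name in self.random_effects
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "TacticTransitionModel":
        return cls(data, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _fit_once(self, free_mask, config, store_re):
        spec = _TransitionSpec(
            self.origin, self.dest, self.X, free_mask, self.factors, self.priors,
            self.column_names,
        )
        try:  # start chains near the posterior mode (random effects at zero)
            from scipy.optimize import minimize

            zeros = np.zeros(spec.n_rows)
            mode = minimize(
                lambda th: -(spec.row_loglik(th, zeros).sum() + spec.theta_logprior(th)),
                spec.theta_init,
                method="L-BFGS-B",
            )
            if np.all(np.isfinite(mode.x)):
                spec.theta_init = mode.x
        except Exception:
            pass
        draws = sample_hierarchical(spec, config, store_re=store_re)
        return spec, draws

    def fit(
        self,
        config: McmcConfig | None = None,
        store_re: bool = False,
    ) -> "TransitionResults":
        """Run MCMC; with ``interactions='auto'`` apply the two-stage fit in
        which non-credible sex-ratio interaction terms are removed and the
        model refitted."""
        config = config or McmcConfig(chains=3, iterations=20_000, burnin=2_500, thin=100)
        p = self.X.shape[1]
        free = np.ones((3, 2, p), dtype=bool)
        spec, draws = self._fit_once(free, config, store_re)
        dropped: list[str] = []
        if self.interactions == "auto" and self._interaction_cols:
            for k, col in enumerate(self.column_names):
                if col not in self._interaction_cols:
                    continue
                for o in range(3):
                    for m in range(2):
                        name = f"beta[{LIVE_STATES[o]}->{LIVE_STATES[m + 1]}][{col}]"
                        if not PosteriorSummary.from_draws(name, draws.named(name)).credible:
                            free[o, m, k] = False
                            dropped.append(name)
            if dropped:
                spec, draws = self._fit_once(free, config, store_re)
        return TransitionResults(self, spec, draws, dropped_terms=dropped)

    def map_fit(self) -> TransitionParams:
        """Posterior-mode point estimate with random effects held at zero.

        With flat-ish priors this is effectively the multinomial-logit /
        survival maximum-likelihood fit, useful as a fast point estimate and
        for cross-checks against standard GLM maximisers.
        """
        from scipy.optimize import minimize

        p = self.X.shape[1]
        free = np.ones((3, 2, p), dtype=bool)
        spec = _TransitionSpec(
            self.origin, self.dest, self.X, free, [], self.priors, self.column_names
        )

        def neg(theta):
            ll = spec.row_loglik(theta, np.zeros(spec.n_rows)).sum()
            return -(ll + spec.theta_logprior(theta))

        res = minimize(neg, spec.theta_init, method="L-BFGS-B")
        beta, survival = spec.unpack(res.x)
        return TransitionParams(beta=beta[:, :, : 1 + len(self.covariate_names)],
                                survival=survival,
                                covariate_names=self.covariate_names)


class TransitionResults:
    """Posterior draws and summaries for a fitted transition model."""

    def __init__(self, model, spec, draws, dropped_terms=()):
        self.model = model
        self._spec = spec
        self.draws = draws
        self.dropped_terms = list(dropped_terms)
        self.summaries = draws.summaries()
        self.rhat_max = max(s.rhat for s in self.summaries)
        self.converged = self.rhat_max < RHAT_THRESHOLD

    def summary(self) -> pd.DataFrame:
        """Parameter table: mean, 95% interval, R-hat and credibility flag."""
        tab = summary_frame(self.summaries)
        tab.attrs["converged"] = self.converged
        return tab

    # -- posterior transition kernel ----------------------------------------

    def _theta_flat(self) -> np.ndarray:
        th = self.draws.theta
        return th.reshape(-1, th.shape[-1])

    def _probs_for_draws(self, x_rows: np.ndarray, origin: int) -> np.ndarray:
        """(n_draws, n_points, 4) transition rows for design-matrix rows."""
        out = []
        for theta in self._theta_flat():
            beta, survival = self._spec.unpack(theta)
            eta = np.column_stack(
                [
                    np.zeros(len(x_rows)),
                    x_rows @ beta[origin, 0],
                    x_rows @ beta[origin, 1],
                ]
            )
            live = survival[origin] * np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
            dead = np.full((len(x_rows), 1), 1.0 - survival[origin])
            out.append(np.hstack([live, dead]))
        return np.asarray(out)

    def _reference_row(self) -> np.ndarray:
        return self.model.X.mean(axis=0)

    def transition_matrix(
        self, covariates: Mapping[str, float] | None = None
    ) -> dict[str, np.ndarray]:
        """Posterior mean and 95% CI of the 4x4 kernel at a covariate point.

        ``covariates`` are on the raw scale (defaults to the sample mean
        point). The dead row is (0, 0, 0, 1) by construction.
        """
        x = self._reference_row().copy()
        if covariates is not None:
            for i, name in enumerate(self.model.covariate_names, start=1):
                if name in covariates:
                    mean, sd = self.model.scaling[name]
                    x[i] = (covariates[name] - mean) / sd
            for k, col in enumerate(self.model.column_names):
                if ":" in col:
                    a, b = col.split(":")
                    x[k] = x[self.model.column_names.index(a)] * x[self.model.column_names.index(b)]
        mean = np.zeros((4, 4))
        lci = np.zeros((4, 4))
        hci = np.zeros((4, 4))
        for o in range(3):
            probs = self._probs_for_draws(x[None, :], o)[:, 0, :]  # (draws, 4)
            mean[o] = probs.mean(axis=0)
            lci[o] = np.percentile(probs, 2.5, axis=0)
            hci[o] = np.percentile(probs, 97.5, axis=0)
        mean[DEAD, DEAD] = lci[DEAD, DEAD] = hci[DEAD, DEAD] = 1.0
        return {"mean": mean, "lci": lci, "hci": hci, "states": STATES}

    def transition_curves(
        self,
        covariate: str,
        grid: np.ndarray,
        origins: Sequence[str] = LIVE_STATES,
    ) -> pd.DataFrame:
        """Posterior mean and 95% ribbon of each transition probability along
        a raw-scale covariate grid, other covariates held at the sample mean."""
        if len(self._theta_flat()) == 0:
            raise ValueError("no posterior draws")
        idx = self.model.column_names.index(covariate)
        mean_sd = self.model.scaling[covariate]
        ref = self._reference_row()
        x_rows = np.tile(ref, (len(grid), 1))
        x_rows[:, idx] = (np.asarray(grid, dtype=float) - mean_sd[0]) / mean_sd[1]
        for k, col in enumerate(self.model.column_names):
            if ":" in col:
                a, b = col.split(":")
                x_rows[:, k] = (
                    x_rows[:, self.model.column_names.index(a)]
                    * x_rows[:, self.model.column_names.index(b)]
                )
        records = []
        for origin in origins:
            o = state_index(origin)
            probs = self._probs_for_draws(x_rows, o)  # (draws, grid, 4)
            mu = probs.mean(axis=0)
            lo = np.percentile(probs, 2.5, axis=0)
            hi = np.percentile(probs, 97.5, axis=0)
            for g, xval in enumerate(grid):
                for d, dest in enumerate(STATES):
                    records.append(
                        {
                            "origin": origin,
                            "dest": dest,
                            covariate: xval,
                            "mean": mu[g, d],
                            "lci": lo[g, d],
                            "hci": hi[g, d],
                        }
                    )
        return pd.DataFrame(records)

    def plot_curves(self, covariate: str, grid: np.ndarray, ax=None):
        """Mean-and-ribbon transition curves, one panel per live origin."""
        import matplotlib.pyplot as plt

        curves = self.transition_curves(covariate, grid)
        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
        else:
            axes = np.atleast_1d(ax)
        colours = {"subordinate": "tab:blue", "sneaker": "tab:orange", "guard": "black"}
        for a, origin in zip(axes, LIVE_STATES):
            sub = curves[curves["origin"] == origin]
            for dest, col in colours.items():
                dd = sub[sub["dest"] == dest]
                a.plot(dd[covariate], dd["mean"], color=col, label=f"to {dest}")
                a.fill_between(dd[covariate], dd["lci"], dd["hci"], color=col, alpha=0.2)
            a.set_title(f"from {origin}")
            a.set_xlabel(covariate)
        axes[0].set_ylabel("transition probability")
        axes[0].legend(frameon=False)
        return axes
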