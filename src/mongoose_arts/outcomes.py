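"""Outcome models for reproductive tactics.

Three hierarchical models quantify what a tactic costs and buys a male:

* :class:`WeightLossModel` — Gaussian model of percentage body-weight change
  over an oestrus event with a three-level tactic factor (subordinate,
  sneaker, guard) and crossed random effects for male, group and event.
* :class:`SiringModel` — Bernoulli GLMM for whether a male who pursued a
  female sired her litter, with tactic (guard = 1, sneaker = 0), the number
  of competing suitors, and the proportion of competitors using the same
  tactic (negative frequency dependence).
* :class:`MateChoiceModel` — Bernoulli GLMM for whether an interacting male
  pursued a particular female on a given day, with group-centred relatedness,
  male and female age ranks, their interaction and tactic interactions
  (assortative mating and the sneaker rank-lag), plus the number of adult
  females present.

All three follow the same conventions as the transition model: covariates
whose range leaves [0, 1] are z-scored, effects are "credible" when >= 97.5%
of the posterior sits on one side of zero, and optional interaction terms are
fitted first and dropped when not credible (``interactions="auto"``).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

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

RHAT_THRESHOLD = 1.1

TACTIC_LEVELS = ("subordinate", "sneaker", "guard")


# ---------------------------------------------------------------------------
# design-matrix helper


class Design:
    """Named design matrix with scaling metadata and product columns.

    Columns are either ``"intercept"``, the name of a base (already
    standardized) covariate, or a ``":"``-joined product of base covariates;
    products are built after scaling so a prediction at raw covariate values
    goes through exactly the same transform as the training data.
    """

    def __init__(
        self,
        columns: Sequence[str],
        base: Mapping[str, np.ndarray],
        scaling: Mapping[str, tuple[float, float]],
    ) -> None:
        self.columns = list(columns)
        self.scaling = dict(scaling)
        n = len(next(iter(base.values())))
        mat = []
        for col in self.columns:
            if col == "intercept":
                mat.append(np.ones(n))
            elif ":" in col:
                parts = col.split(":")
                prod = np.ones(n)
                for p in parts:
                    prod = prod * np.asarray(base[p], dtype=float)
                mat.append(prod)
            else:
                mat.append(np.asarray(base[col], dtype=float))
        self.X = np.column_stack(mat)

    def drop(self, names: Sequence[str]) -> "Design":
        keep = [c for c in self.columns if c not in set(names)]
        new = Design.__new__(Design)
        new.columns = keep
        new.scaling = self.scaling
        idx = [self.columns.index(c) for c in keep]
        new.X = self.X[:, idx]
        return new

    def row(self, raw: Mapping[str, float]) -> np.ndarray:
        scaled = {}
        for name, value in raw.items():
            mean, sd = self.scaling.get(name, (0.0, 1.0))
            scaled[name] = (float(value) - mean) / sd
        out = np.empty(len(self.columns))
        for i, col in enumerate(self.columns):
            if col == "intercept":
                out[i] = 1.0
            elif ":" in col:
                prod = 1.0
                for p in col.split(":"):
                    prod *= scaled[p]
                out[i] = prod
            else:
                out[i] = scaled[col]
        return out


# ---------------------------------------------------------------------------
# shared GLMM sampler spec


class _GlmmSpec(HierarchicalSpec):
    """Bernoulli or Gaussian likelihood with one additive RE offset per row."""

    def __init__(self, family, y, X, coef_names, factors, priors):
        if family not in ("bernoulli", "gaussian"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.re_factors = list(factors)
        self.n_rows = len(self.y)
        self.priors = priors
        self.theta_names = list(coef_names)
        if family == "gaussian":
            self.theta_names = self.theta_names + ["log_residual_sd"]
        self.theta_init = np.zeros(len(self.theta_names))
        if family == "gaussian":
            self.theta_init[-1] = float(np.log(self.y.std(ddof=0) + 1e-6))
        self._sign = 1.0 - 2.0 * self.y  # bernoulli: -eta if y=1 else +eta
        # scalar updates only touch rows where the column is non-zero
        self._subsets: list[np.ndarray | None] = []
        for j in range(self.X.shape[1]):
            nz = np.flatnonzero(self.X[:, j])
            self._subsets.append(nz if len(nz) < 0.8 * self.n_rows else None)
        if family == "gaussian":
            self._subsets.append(None)

    @property
    def theta_row_subsets(self):
        return self._subsets

    def row_loglik(self, theta, offset, rows=None):
        p = self.X.shape[1]
        beta = theta[:p]
        if rows is None:
            Xr, yr, off, sign = self.X, self.y, offset, self._sign
        else:
            Xr, yr, off, sign = self.X[rows], self.y[rows], offset[rows], self._sign[rows]
        eta = Xr @ beta + off
        if self.family == "bernoulli":
            return -np.logaddexp(0.0, sign * eta)
        sd = np.exp(theta[-1])
        resid = yr - eta
        return -theta[-1] - 0.5 * (resid / sd) ** 2 - 0.5 * np.log(2 * np.pi)


class GlmmResults:
    """Posterior draws plus summaries; base class for the outcome results."""

    def __init__(self, model, design, draws, dropped_terms=()):
        self.model = model
        self.design = design
        self.draws = draws
        self.dropped_terms = list(dropped_terms)
        self.summaries = draws.summaries()
        self._by_name = {s.name: s for s in self.summaries}
        self.rhat_max = max(s.rhat for s in self.summaries)
        self.converged = self.rhat_max < RHAT_THRESHOLD

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self._by_name[name]

    def summary(self) -> pd.DataFrame:
        tab = summary_frame(self.summaries)
        tab.attrs["converged"] = self.converged
        return tab

    def _beta_draws(self) -> np.ndarray:
        """(n_total_draws, n_coef) fixed-effect draws."""
        th = self.draws.theta.reshape(-1, self.draws.theta.shape[-1])
        return th[:, : len(self.design.columns)]

    def _predict_prob(self, raw: Mapping[str, float]) -> dict[str, float]:
        x = self.design.row(raw)
        p = expit(self._beta_draws() @ x)
        return {
            "mean": float(p.mean()),
            "lci": float(np.percentile(p, 2.5)),
            "hci": float(np.percentile(p, 97.5)),
        }


def _make_spec(family, y, design, factors, priors):
    spec = _GlmmSpec(family, y, design.X, design.columns, factors, priors)
    try:  # start chains near the posterior mode: cheap and robust
        mode = _map_fit(design, family, y, priors)
        spec.theta_init = np.array([mode[n] for n in spec.theta_names])
    except Exception:
        pass
    return spec


def _fit_glmm(model, design, family, y, factors, config, priors, store_re,
              droppable: Sequence[str], results_cls):
    """Fit once; if any droppable interaction term is not credible, remove it
    and refit (the two-stage credibility-pruning procedure)."""
    spec = _make_spec(family, y, design, factors, priors)
    draws = sample_hierarchical(spec, config, store_re=store_re)
    dropped = []
    if droppable:
        for name in droppable:
            if name in design.columns:
                if not PosteriorSummary.from_draws(name, draws.named(name)).credible:
                    dropped.append(name)
        if dropped:
            design = design.drop(dropped)
            spec = _make_spec(family, y, design, factors, priors)
            draws = sample_hierarchical(spec, config, store_re=store_re)
    return results_cls(model, design, draws, dropped_terms=dropped)


def _map_fit(design, family, y, priors) -> dict[str, float]:
    """Posterior mode with random effects at zero (near-ML point estimate)."""
    from scipy.optimize import minimize

    spec = _GlmmSpec(family, y, design.X, design.columns, [], priors)

    def neg(theta):
        return -(spec.row_loglik(theta, np.zeros(spec.n_rows)).sum()
                 + spec.theta_logprior(theta))

    res = minimize(neg, spec.theta_init, method="L-BFGS-B")
    return dict(zip(spec.theta_names, res.x))


# ---------------------------------------------------------------------------
# weight loss


class WeightLossModel:
    """Gaussian model of percentage weight change over an oestrus event.

    Expects one row per male per event with columns ``male_id``, ``group_id``,
    ``oestrus_event_id``, ``tactic`` and ``pct_change``. The tactic factor is
    cell-means coded, so the posterior reports the mean percentage change per
    tactic directly; contrasts between tactics come from the draws.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        random_effects: Sequence[str] = ("male", "group", "event"),
        priors: Priors = Priors(),
    ) -> None:
        # canonical row order: summaries do not depend on input record order
        df = data.sort_values(["male_id", "oestrus_event_id"], kind="stable").reset_index(drop=True)
        if not np.all(np.isfinite(df["pct_change"].to_numpy(dtype=float))):
            raise ValueError("pct_change must be finite")
        levels = [t for t in TACTIC_LEVELS if (df["tactic"] == t).any()]
        if len(levels) < 2:
            raise ValueError("need at least two tactics for a contrast")
        self.levels = levels
        self.priors = priors
        base = {
            f"mean_pct_change[{t}]": (df["tactic"] == t).to_numpy(dtype=float)
            for t in levels
        }
        self.design = Design(list(base), base, scaling={})
        self.y = df["pct_change"].to_numpy(dtype=float)
        label_cols = {"male": "male_id", "group": "group_id", "event": "oestrus_event_id"}
        self.factors = [
            REFactor.from_labels(name, df[label_cols[name]].to_numpy())
            for name in random_effects
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "WeightLossModel":
        return cls(data, **kwargs)

    def fit(self, config: McmcConfig | None = None, store_re: bool = False) -> "WeightLossResults":
        config = config or McmcConfig(chains=3, iterations=50_000, burnin=5_000, thin=100)
        return _fit_glmm(self, self.design, "gaussian", self.y, self.factors,
                         config, self.priors, store_re, (), WeightLossResults)

    def map_fit(self) -> dict[str, float]:
        return _map_fit(self.design, "gaussian", self.y, self.priors)


class WeightLossResults(GlmmResults):
    def tactic_means(self) -> pd.DataFrame:
        rows = [s for s in self.summaries if s.name.startswith("mean_pct_change")]
        return summary_frame(rows)

    def contrast(self, tactic_a: str, tactic_b: str) -> PosteriorSummary:
        """Posterior of mean(tactic_a) - mean(tactic_b)."""
        da = self.draws.named(f"mean_pct_change[{tactic_a}]")
        db = self.draws.named(f"mean_pct_change[{tactic_b}]")
        return PosteriorSummary.from_draws(f"{tactic_a} - {tactic_b}", da - db)


# ---------------------------------------------------------------------------
# siring success


class SiringModel:
    """Bernoulli GLMM for siring success of guarding vs sneaking suitors.

    One row per (male, female, oestrus event) trial with columns
    ``oestrus_event_id``, ``female_id``, ``male_id``, ``tactic`` (guard or
    sneaker), ``n_competitors``, ``prop_same_tactic`` and ``sired``. Guard is
    coded 1 and sneaker 0. ``interactions="auto"`` fits tactic x competitors
    and tactic x proportion-same-tactic terms and drops the non-credible ones.
    """

    DROPPABLE = ("tactic:n_competitors", "tactic:prop_same_tactic")

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        interactions: str = "auto",
        random_effects: Sequence[str] = ("female", "male", "event"),
        priors: Priors = Priors(),
    ) -> None:
        if interactions not in ("none", "keep", "auto"):
            raise ValueError("interactions must be 'none', 'keep' or 'auto'")
        df = data.sort_values(
            ["oestrus_event_id", "litter_id", "male_id"], kind="stable"
        ).reset_index(drop=True)
        bad = set(df["tactic"]) - {"guard", "sneaker"}
        if bad:
            raise ValueError(f"siring trials must be guard/sneaker, got {bad}")
        self.interactions = interactions
        self.priors = priors
        self.y = df["sired"].to_numpy(dtype=float)
        if self.y.min() == self.y.max():
            warnings.warn("all siring trials share one outcome; "
                          "estimates may be separated")
        scaled, scaling = standardize_covariates(
            df[["n_competitors", "prop_same_tactic"]].astype(float)
        )
        base = {
            "tactic": (df["tactic"] == "guard").to_numpy(dtype=float),
            "n_competitors": scaled["n_competitors"].to_numpy(),
            "prop_same_tactic": scaled["prop_same_tactic"].to_numpy(),
        }
        cols = ["intercept", "tactic", "n_competitors", "prop_same_tactic"]
        if interactions in ("keep", "auto"):
            cols += list(self.DROPPABLE)
        self.design = Design(cols, base, scaling)
        label_cols = {"female": "female_id", "male": "male_id", "event": "oestrus_event_id"}
        self.factors = [
            REFactor.from_labels(name, df[label_cols[name]].to_numpy())
            for name in random_effects
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SiringModel":
        return cls(data, **kwargs)

    def fit(self, config: McmcConfig | None = None, store_re: bool = False) -> "SiringResults":
        config = config or McmcConfig(chains=3, iterations=100_000, burnin=10_000, thin=100)
        droppable = self.DROPPABLE if self.interactions == "auto" else ()
        return _fit_glmm(self, self.design, "bernoulli", self.y, self.factors,
                         config, self.priors, store_re, droppable, SiringResults)

    def map_fit(self) -> dict[str, float]:
        return _map_fit(self.design, "bernoulli", self.y, self.priors)


class SiringResults(GlmmResults):
    def predict(self, tactic: str, n_competitors: float, prop_same_tactic: float) -> dict[str, float]:
        """Posterior siring probability for a population-typical male/female."""
        return self._predict_prob(
            {
                "tactic": 1.0 if tactic == "guard" else 0.0,
                "n_competitors": n_competitors,
                "prop_same_tactic": prop_same_tactic,
            }
        )


# ---------------------------------------------------------------------------
# mate choice


class MateChoiceModel:
    """Bernoulli GLMM for which female an active male pursues.

    One row per (male-day with >= 1 interaction) x (adult female present),
    with columns ``male_id``, ``female_id``, ``oestrus_event_id``, ``day``,
    ``tactic`` (the male's tactic that day), ``male_age_rank``,
    ``female_age_rank``, ``gc_relatedness`` (group-centred relatedness),
    ``n_adult_females`` and ``interacted``.

    The linear predictor carries relatedness, both age ranks, the male x
    female rank product (assortative mating), tactic and its rank
    interactions up to the three-way term (the sneaker rank-lag), the
    droppable tactic x relatedness term, and the number of adult females.
    ``unit="event"`` collapses repeated days to one record per event-dyad.
    """

    DROPPABLE = ("tactic:gc_relatedness",)

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        unit: str = "day",
        interactions: str = "auto",
        random_effects: Sequence[str] = ("male", "female", "event"),
        priors: Priors = Priors(),
    ) -> None:
        if unit not in ("day", "event"):
            raise ValueError("unit must be 'day' or 'event'")
        if interactions not in ("none", "keep", "auto"):
            raise ValueError("interactions must be 'none', 'keep' or 'auto'")
        df = data.sort_values(
            ["oestrus_event_id", "day", "male_id", "female_id"], kind="stable"
        ).reset_index(drop=True)
        if unit == "event":
            df = (
                df.sort_values("day", kind="stable")
                .groupby(["oestrus_event_id", "male_id", "female_id"], as_index=False)
                .agg(
                    tactic=("tactic", lambda s: "guard" if (s == "guard").any() else "sneaker"),
                    male_age_rank=("male_age_rank", "first"),
                    female_age_rank=("female_age_rank", "first"),
                    gc_relatedness=("gc_relatedness", "first"),
                    n_adult_females=("n_adult_females", "first"),
                    interacted=("interacted", "any"),
                )
            )
        if df["female_id"].nunique() < 2 or df["female_age_rank"].nunique() < 2:
            raise ValueError("female age-rank effects are unidentifiable with a single female")
        self.interactions = interactions
        self.priors = priors
        self.unit = unit
        self.y = df["interacted"].to_numpy(dtype=float)
        numeric = ["male_age_rank", "female_age_rank", "gc_relatedness", "n_adult_females"]
        scaled, scaling = standardize_covariates(df[numeric].astype(float))
        base = {c: scaled[c].to_numpy() for c in numeric}
        base["tactic"] = (df["tactic"] == "guard").to_numpy(dtype=float)
        cols = [
            "intercept",
            "gc_relatedness",
            "male_age_rank",
            "female_age_rank",
            "male_age_rank:female_age_rank",
            "tactic",
            "tactic:male_age_rank",
            "tactic:female_age_rank",
            "tactic:male_age_rank:female_age_rank",
            "n_adult_females",
        ]
        if interactions in ("keep", "auto"):
            cols += list(self.DROPPABLE)
        self.design = Design(cols, base, scaling)
        label_cols = {"male": "male_id", "female": "female_id", "event": "oestrus_event_id"}
        self.factors = [
            REFactor.from_labels(name, df[label_cols[name]].to_numpy())
            for name in random_effects
        ]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MateChoiceModel":
        return cls(data, **kwargs)

    def fit(self, config: McmcConfig | None = None, store_re: bool = False) -> "MateChoiceResults":
        config = config or McmcConfig(chains=3, iterations=20_000, burnin=2_000, thin=100)
        droppable = self.DROPPABLE if self.interactions == "auto" else ()
        return _fit_glmm(self, self.design, "bernoulli", self.y, self.factors,
                         config, self.priors, store_re, droppable, MateChoiceResults)

    def map_fit(self) -> dict[str, float]:
        return _map_fit(self.design, "bernoulli", self.y, self.priors)


class MateChoiceResults(GlmmResults):
    def predict(
        self,
        male_rank: float,
        female_rank: float,
        tactic: str,
        relatedness: float,
        n_females: float,
    ) -> dict[str, float]:
        """Posterior probability that the male pursues this female."""
        return self._predict_prob(
            {
                "male_age_rank": male_rank,
                "female_age_rank": female_rank,
                "tactic": 1.0 if tactic == "guard" else 0.0,
                "gc_relatedness": relatedness,
                "n_adult_females": n_females,
            }
        )
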