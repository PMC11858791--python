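"""Synthetic study populations with known true parameters.

Forward-simulates banded-mongoose-style social groups — male-biased groups, a
handful of breeding females, roughly quarterly multi-day oestrus events —
through the same generative structure the models assume: per-event tactics
follow the covariate-dependent multinomial-logit transition kernel with
status-specific survival and an absorbing dead state; body weights follow an
individual logistic growth curve plus Gaussian measurement noise, with a
tactic-dependent percentage weight change after each event; guards pick one
female per day and sneakers pursue females through a logistic mate-choice
rule; litters arrive about nine weeks after the event and sires are drawn
among the mother's suitors with a guard advantage and negative frequency
dependence.

Everything downstream (preprocessing rules, the transition model, the three
outcome models) can therefore be tested by parameter recovery against the
stored truth. Direct trial-level simulators (``simulate_siring_trials``,
``simulate_dyad_observations``, ``simulate_weight_changes``) draw from each
outcome model's own sampling distribution for focused recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .transitions import (
    DEAD,
    LIVE_STATES,
    STATES,
    TransitionParams,
    transition_probs,
)

EPOCH = pd.Timestamp("2004-01-01")
ADULT_AGE = 365          # days; enters the sex-ratio denominator/numerator
SUBADULT_AGE = 180       # days; minimum age to appear in any analysis


class DegenerateDemographyError(ValueError):
    """No oestrus event has both a living adult male and an adult female."""


# ---------------------------------------------------------------------------
# true-parameter containers


def default_transition_truth() -> TransitionParams:
    """Raw-scale generating values: older (lower age rank) and heavier males
    transition into guarding; sneaking peaks among mid-ranked, lighter males;
    sex ratio has no effect; survival is high and slightly lower for active
    males."""
    beta = np.zeros((3, 2, 4))  # (origin, dest sneaker/guard, [1, rank, weight, sexratio])
    intercepts = {  # origin -> (to sneaker, to guard)
        0: (-1.3, -0.6),
        1: (-0.6, 0.3),
        2: (-0.7, 0.6),
    }
    for o, (b_s, b_g) in intercepts.items():
        beta[o, 0, 0] = b_s
        beta[o, 1, 0] = b_g
        beta[o, 0, 1] = -0.04   # age rank -> sneaker
        beta[o, 1, 1] = -0.15   # age rank -> guard (older males guard)
        beta[o, 0, 2] = 0.001   # group-centred weight (g) -> sneaker
        beta[o, 1, 2] = 0.004   # heavier males guard
    return TransitionParams(
        beta=beta,
        survival=np.array([0.98, 0.96, 0.96]),
        sigma_male=0.3,
        sigma_group=0.2,
        sigma_event=0.2,
    )


@dataclass(frozen=True)
class SiringTruth:
    """Softmax sire assignment among a female's suitors."""

    beta_tactic: float = 1.5        # guard advantage on the logit scale
    beta_propsame: float = -1.5     # negative frequency dependence
    litter_prob: float = 0.55       # attended female produces a litter
    multiple_paternity_prob: float = 0.05


@dataclass(frozen=True)
class MateChoiceTruth:
    """Logistic day-level mate choice; rank 1 = oldest."""

    intercept: float = -0.4
    b_relatedness: float = -3.0       # inbreeding avoidance
    b_female_rank: float = -0.10      # older females attended more
    b_male_rank: float = 0.0
    b_rank_assort: float = 0.03       # baseline (sneaker) rank matching
    b_guard_assort_extra: float = 0.12  # guards assort far more strongly
    b_n_females: float = -0.25
    centre_male_rank: float = 6.0
    centre_female_rank: float = 3.0

    def eta(self, male_rank, female_rank, relatedness, guard, n_females):
        dm = np.asarray(male_rank, dtype=float) - self.centre_male_rank
        df = np.asarray(female_rank, dtype=float) - self.centre_female_rank
        assort = self.b_rank_assort + self.b_guard_assort_extra * np.asarray(guard, dtype=float)
        return (
            self.intercept
            + self.b_relatedness * np.asarray(relatedness, dtype=float)
            + self.b_male_rank * dm
            + self.b_female_rank * df
            + assort * dm * df
            + self.b_n_females * (np.asarray(n_females, dtype=float) - 4.0)
        )


@dataclass(frozen=True)
class WeightLossTruth:
    """Mean percentage weight change per tactic and its biological spread."""

    means: tuple[float, float, float] = (0.3, -2.3, -2.3)  # subordinate, sneaker, guard
    sd: float = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic population."""

    n_groups: int = 8
    males_per_group: tuple[int, int] = (3, 25)
    females_per_group: tuple[int, int] = (1, 7)
    n_events_per_group: int = 10
    days_per_event: tuple[int, int] = (1, 7)
    event_spacing_days: int = 91
    true_transition_params: TransitionParams = field(default_factory=default_transition_truth)
    true_siring_params: SiringTruth = SiringTruth()
    true_matechoice_params: MateChoiceTruth = MateChoiceTruth()
    true_weightloss_params: WeightLossTruth = WeightLossTruth()
    weight_missing_frac: float = 0.066
    sex_ratio_target: float = 2.2
    weight_noise_sd: float = 25.0
    weight_cadence_days: int = 15
    male_age_range_days: tuple[int, int] = (60, 3000)    # at study start
    female_age_range_days: tuple[int, int] = (400, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_events_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("males_per_group", "females_per_group", "days_per_event"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be an increasing range of counts >= 1")
        if not (1 <= self.days_per_event[0] and self.days_per_event[1] <= 7):
            raise ValueError("days_per_event must lie within [1, 7]")
        if not 0.0 <= self.weight_missing_frac <= 1.0:
            raise ValueError("weight_missing_frac must be a proportion")
        if self.sex_ratio_target <= 0:
            raise ValueError("sex_ratio_target must be positive")


@dataclass
class SyntheticDataset:
    """The five study tables plus the generating truth."""

    focal_table: pd.DataFrame
    weight_table: pd.DataFrame
    demography_table: pd.DataFrame
    relatedness_table: pd.DataFrame
    litter_table: pd.DataFrame
    truth: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "focals": self.focal_table,
            "weights": self.weight_table,
            "demography": self.demography_table,
            "relatedness": self.relatedness_table,
            "litters": self.litter_table,
        }

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        names = {
            "focals": self.focal_table,
            "weights": self.weight_table,
            "demography": self.demography_table,
            "relatedness": self.relatedness_table,
            "litters": self.litter_table,
        }
        for name, df in names.items():
            df.to_csv(path / f"{name}.csv", index=False)
        with open(path / "truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# tactic sequences


def simulate_tactic_sequence(
    params: TransitionParams,
    covariates: Sequence[Mapping[str, float]],
    seed: int | np.random.Generator = 0,
    re_offset: float = 0.0,
) -> list[str]:
    """Forward-simulate one male's state sequence.

    The male starts as a subordinate; each step samples the transition row
    for the current state and the covariates of the current event. Returns
    ``len(covariates) + 1`` state names; dead is absorbing.
    """
    if len(covariates) == 0:
        raise ValueError("need at least one covariate record")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = ["subordinate"]
    current = 0
    for cov in covariates:
        row = transition_probs(params, cov, current, re_offset=re_offset)
        current = int(rng.choice(4, p=row))
        states.append(STATES[current])
    return states


def _growth_curve(age_days: np.ndarray, asymptote: float) -> np.ndarray:
    return asymptote / (1.0 + np.exp(-(np.asarray(age_days, dtype=float) - 250.0) / 160.0))


def _date(day: int) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(days=int(day))


# ---------------------------------------------------------------------------
# full population generator


def generate_population(config: SimConfig) -> SyntheticDataset:
    """Generate one complete synthetic study dataset.

    Deterministic given ``config.seed``. Raises
    :class:`DegenerateDemographyError` when no oestrus event has both a
    living adult male and an adult female.
    """
    rng = np.random.default_rng(config.seed)
    # separate stream so the missingness mechanism does not perturb the rest
    # of the realisation (datasets differing only in weight_missing_frac
    # share all other data)
    rng_miss = np.random.default_rng([config.seed, 104729])
    tp = config.true_transition_params
    mc = config.true_matechoice_params
    si = config.true_siring_params
    wl = config.true_weightloss_params

    focal_rows, weight_rows, demog_rows, rel_rows, litter_rows = [], [], [], [], []
    re_male, re_group, re_event = {}, {}, {}
    true_states: dict[tuple[str, str], str] = {}
    true_litter_event: dict[str, str] = {}
    horizon = 30 + config.n_events_per_group * config.event_spacing_days + 120

    any_viable_event = False
    litter_counter = 0

    for g in range(config.n_groups):
        group_id = f"G{g:02d}"
        re_group[group_id] = rng.normal(0.0, tp.sigma_group)

        n_females = int(rng.integers(config.females_per_group[0], config.females_per_group[1] + 1))
        n_males = int(np.clip(
            round(config.sex_ratio_target * n_females + rng.normal(0, 1)),
            config.males_per_group[0], config.males_per_group[1],
        ))

        male_ids = [f"{group_id}M{i:02d}" for i in range(n_males)]
        female_ids = [f"{group_id}F{i:02d}" for i in range(n_females)]

        # ages at study start; some males mature mid-study
        a_lo, a_hi = config.male_age_range_days
        male_age0 = rng.integers(a_lo, a_hi + 1, size=n_males)
        if a_hi > 400:
            # keep a core of adults so the group is viable from the first event
            core = max(2, n_males // 3)
            male_age0[:core] = rng.integers(max(400, a_lo), a_hi + 1, size=core)
        f_lo, f_hi = config.female_age_range_days
        female_age0 = rng.integers(f_lo, f_hi + 1, size=n_females)

        asym = rng.normal(1800.0, 120.0, size=n_males)
        for m in male_ids:
            re_male[m] = rng.normal(0.0, tp.sigma_male)

        # event calendar
        starts, ends, event_days = [], [], []
        day = 30
        for t in range(config.n_events_per_group):
            start = day + int(rng.integers(-8, 9))
            dur = int(np.clip(1 + rng.binomial(6, 1.0 / 3.0), *config.days_per_event))
            starts.append(start)
            ends.append(start + dur - 1)
            event_days.append(list(range(start, start + dur)))
            day += config.event_spacing_days

        # relatedness: male-female dyads within the group
        rel_g: dict[tuple[str, str], float] = {}
        for m in male_ids:
            for f in female_ids:
                r = float(rng.choice([0.0, 0.125, 0.25, 0.5], p=[0.35, 0.2, 0.3, 0.15]))
                rel_g[(m, f)] = r
                rel_rows.append({"id_a": m, "id_b": f, "r": r})

        state = {m: None for m in male_ids}       # None = not yet entered
        death_day: dict[str, float] = {}
        wl_factor_windows: list[tuple[str, int, float]] = []  # (male, start_day, pct)

        for t in range(config.n_events_per_group):
            event_id = f"{group_id}E{t:02d}"
            re_event[event_id] = rng.normal(0.0, tp.sigma_event)
            start, end = starts[t], ends[t]

            alive = [m for m in male_ids if m not in death_day]
            age_at = {m: int(male_age0[male_ids.index(m)] + start) for m in alive}
            present = [m for m in alive if age_at[m] >= SUBADULT_AGE]
            for m in present:
                if state[m] is None:
                    state[m] = 0  # enters as a subordinate
            f_ages = {f: int(female_age0[female_ids.index(f)] + start) for f in female_ids}
            adult_females = [f for f in female_ids if f_ages[f] >= ADULT_AGE]
            adult_males = [m for m in present if age_at[m] >= ADULT_AGE]
            if not present or not adult_females:
                continue
            any_viable_event = True

            # true covariates at this event
            ranks = _min_tie_ranks({m: age_at[m] for m in present})
            curve_w = {
                m: float(_growth_curve(np.array([age_at[m]]), asym[male_ids.index(m)])[0])
                for m in present
            }
            mean_w = np.mean(list(curve_w.values()))
            sex_ratio = len(adult_males) / len(adult_females)
            f_ranks = _min_tie_ranks(f_ages)
            rel = {(m, f): rel_g[(m, f)] for m in present for f in adult_females}

            # daily focal behaviour consistent with each male's event tactic
            suitors_of: dict[str, dict[str, str]] = {f: {} for f in adult_females}
            for d in event_days[t]:
                for m in present:
                    st = state[m]
                    if st == 0:
                        focal_rows.append(_focal(d, event_id, group_id, m, "", "none"))
                        continue
                    guard = st == 2
                    mean_rel = np.mean([rel[(m, f)] for f in adult_females])
                    eta = mc.eta(
                        [ranks[m]] * len(adult_females),
                        [f_ranks[f] for f in adult_females],
                        [rel[(m, f)] - mean_rel for f in adult_females],
                        guard,
                        len(adult_females),
                    )
                    if guard:
                        p = np.exp(eta - eta.max())
                        chosen = [adult_females[rng.choice(len(adult_females), p=p / p.sum())]]
                    else:
                        picks = rng.uniform(size=len(adult_females)) < expit(eta)
                        if not picks.any():
                            p = np.exp(eta - eta.max())
                            picks = np.zeros(len(adult_females), dtype=bool)
                            picks[rng.choice(len(adult_females), p=p / p.sum())] = True
                        chosen = [f for f, hit in zip(adult_females, picks) if hit]
                    behaviour = "guard" if guard else "sneak"
                    for f in chosen:
                        focal_rows.append(_focal(d, event_id, group_id, m, f, behaviour))
                        suitors_of[f][m] = behaviour

            # litters and sires
            for f, suitors in suitors_of.items():
                if not suitors or rng.uniform() >= si.litter_prob:
                    continue
                males_f = list(suitors)
                tactics_f = np.array([1.0 if suitors[m] == "guard" else 0.0 for m in males_f])
                n_s = len(males_f)
                prop_same = np.array([
                    ((tactics_f == tactics_f[j]).sum() - 1) / (n_s - 1) if n_s > 1 else 0.0
                    for j in range(n_s)
                ])
                eta = si.beta_tactic * tactics_f + si.beta_propsame * prop_same
                p = np.exp(eta - eta.max())
                sires = {males_f[rng.choice(n_s, p=p / p.sum())]}
                if n_s > 1 and rng.uniform() < si.multiple_paternity_prob:
                    others = [m for m in males_f if m not in sires]
                    sires.add(others[int(rng.integers(len(others)))])
                litter_id = f"L{litter_counter:04d}"
                litter_counter += 1
                birth = end + int(np.clip(round(rng.normal(59, 6)), 45, 73))
                litter_rows.append(
                    {
                        "litter_id": litter_id,
                        "mother_id": f,
                        "birth_date": _date(birth).date().isoformat(),
                        "sire_ids": ";".join(sorted(sires)),
                    }
                )
                true_litter_event[litter_id] = event_id

            # record truth and advance states
            for m in present:
                true_states[(m, event_id)] = LIVE_STATES[state[m]]
                pct = rng.normal(wl.means[state[m]], wl.sd)
                wl_factor_windows.append((m, end, pct))
                cov = {
                    "age_rank": ranks[m],
                    "group_centred_weight": curve_w[m] - mean_w,
                    "sex_ratio": sex_ratio,
                }
                off = re_male[m] + re_group[group_id] + re_event[event_id]
                row = transition_probs(tp, cov, state[m], re_offset=off)
                nxt = int(rng.choice(4, p=row))
                if nxt == DEAD:
                    upper = starts[t + 1] if t + 1 < config.n_events_per_group else end + 60
                    death_day[m] = int(rng.integers(end + 1, max(end + 2, upper)))
                    state[m] = DEAD
                else:
                    state[m] = nxt

        # death rows in the tactic truth: first event after death
        for m, dday in death_day.items():
            for t in range(config.n_events_per_group):
                if starts[t] > dday:
                    true_states[(m, f"{group_id}E{t:02d}")] = "dead"
                    break

        # weight measurement streams (males only; weights drive male covariates)
        for i, m in enumerate(male_ids):
            last = int(death_day.get(m, horizon))
            day_w = int(rng.integers(0, config.weight_cadence_days))
            days = []
            while day_w < last:
                days.append(day_w)
                day_w += int(rng.integers(
                    max(5, config.weight_cadence_days - 5), config.weight_cadence_days + 6
                ))
            for t in range(config.n_events_per_group):
                if ends[t] < last and rng.uniform() < 0.9:
                    days.append(ends[t] + int(rng.integers(1, 6)))
            days = sorted(set(days))
            for d in days:
                age = male_age0[i] + d
                if age < 30:
                    continue
                grams = float(_growth_curve(np.array([age]), asym[i])[0])
                for mm, w_end, pct in wl_factor_windows:
                    if mm == m and w_end < d <= w_end + 21:
                        # full loss right after the event, linear recovery
                        grams *= 1.0 + (pct / 100.0) * (1.0 - (d - w_end - 1) / 21.0)
                grams += rng.normal(0.0, config.weight_noise_sd)
                weight_rows.append(
                    {"individual_id": m, "date": _date(d).date().isoformat(), "grams": round(grams, 1)}
                )

            demog_rows.append(_demog(m, "m", -int(male_age0[i]), death_day.get(m), group_id, horizon))
        for i, f in enumerate(female_ids):
            demog_rows.append(_demog(f, "f", -int(female_age0[i]), None, group_id, horizon))

        # delete completely-at-random oestrus weight windows
        if config.weight_missing_frac > 0:
            drop_windows = []
            for m in male_ids:
                for t in range(config.n_events_per_group):
                    if (m, f"{group_id}E{t:02d}") in true_states and rng_miss.uniform() < config.weight_missing_frac:
                        drop_windows.append((m, starts[t] - 60, ends[t] + 60))
            if drop_windows:
                kept = []
                for row in weight_rows:
                    if row["individual_id"].startswith(group_id):
                        d = (pd.Timestamp(row["date"]) - EPOCH).days
                        if any(m == row["individual_id"] and lo <= d <= hi for m, lo, hi in drop_windows):
                            continue
                    kept.append(row)
                weight_rows = kept

    if not any_viable_event:
        raise DegenerateDemographyError(
            "no oestrus event with a living adult male and an adult female"
        )

    truth = {
        "transition": config.true_transition_params,
        "siring": config.true_siring_params,
        "matechoice": config.true_matechoice_params,
        "weightloss": config.true_weightloss_params,
        "re_male": re_male,
        "re_group": re_group,
        "re_event": re_event,
        "states": {f"{m}|{e}": s for (m, e), s in true_states.items()},
        "litter_events": true_litter_event,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k
            not in (
                "true_transition_params",
                "true_siring_params",
                "true_matechoice_params",
                "true_weightloss_params",
            )
        },
    }

    return SyntheticDataset(
        focal_table=pd.DataFrame(
            focal_rows, columns=["date", "event_id", "group_id", "male_id", "female_id", "behaviour"]
        ),
        weight_table=pd.DataFrame(weight_rows, columns=["individual_id", "date", "grams"]),
        demography_table=pd.DataFrame(
            demog_rows,
            columns=["individual_id", "sex", "birth_date", "death_date", "group_id", "entry_date", "exit_date"],
        ),
        relatedness_table=pd.DataFrame(rel_rows, columns=["id_a", "id_b", "r"]),
        litter_table=pd.DataFrame(
            litter_rows, columns=["litter_id", "mother_id", "birth_date", "sire_ids"]
        ),
        truth=truth,
    )


def _focal(day, event_id, group_id, male_id, female_id, behaviour):
    return {
        "date": _date(day).date().isoformat(),
        "event_id": event_id,
        "group_id": group_id,
        "male_id": male_id,
        "female_id": female_id,
        "behaviour": behaviour,
    }


def _demog(ind, sex, birth_day, death_day, group_id, horizon):
    return {
        "individual_id": ind,
        "sex": sex,
        "birth_date": _date(birth_day).date().isoformat(),
        "death_date": _date(int(death_day)).date().isoformat() if death_day is not None else "",
        "group_id": group_id,
        "entry_date": _date(max(birth_day, 0)).date().isoformat(),
        "exit_date": _date(int(death_day) if death_day is not None else horizon).date().isoformat(),
    }


def _min_tie_ranks(ages: Mapping[str, int]) -> dict[str, int]:
    """Rank 1 = oldest; ties share the minimum rank and leave gaps."""
    items = sorted(ages.items(), key=lambda kv: -kv[1])
    ranks: dict[str, int] = {}
    for pos, (ind, age) in enumerate(items):
        if pos > 0 and age == items[pos - 1][1]:
            ranks[ind] = ranks[items[pos - 1][0]]
        else:
            ranks[ind] = pos + 1
    return ranks


# ---------------------------------------------------------------------------
# direct trial-level simulators (each outcome model's own sampling law)


def simulate_weight_changes(
    truth: WeightLossTruth = WeightLossTruth(),
    n_groups: int = 6,
    males_per_group: int = 12,
    n_events: int = 8,
    re_sds: tuple[float, float, float] = (0.5, 0.3, 0.3),  # male, group, event
    seed: int = 0,
) -> pd.DataFrame:
    """Percentage weight changes drawn directly from the Gaussian model."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u_g = rng.normal(0, re_sds[1])
        males = [f"G{g}M{i}" for i in range(males_per_group)]
        u_m = {m: rng.normal(0, re_sds[0]) for m in males}
        for t in range(n_events):
            event = f"G{g}E{t}"
            u_e = rng.normal(0, re_sds[2])
            for m in males:
                k = int(rng.choice(3, p=[0.6, 0.18, 0.22]))
                rows.append(
                    {
                        "male_id": m,
                        "group_id": f"G{g}",
                        "oestrus_event_id": event,
                        "tactic": ("subordinate", "sneaker", "guard")[k],
                        "pct_change": truth.means[k] + u_m[m] + u_g + u_e
                        + rng.normal(0, truth.sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_siring_trials(
    coef: Mapping[str, float] | None = None,
    n_litters: int = 160,
    n_males: int = 60,
    re_sds: tuple[float, float, float] = (0.3, 0.3, 0.3),  # female, male, event
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli siring trials drawn directly from the logistic model.

    ``coef`` keys: intercept, tactic (guard = 1), n_competitors (per extra
    suitor), prop_same_tactic. Suitors are drawn from a shared pool of
    ``n_males`` males so the male random effect is identifiable, mirroring
    the repeated appearance of the same suitors across litters.
    """
    coef = dict(coef or {"intercept": -0.2, "tactic": 1.5,
                         "n_competitors": -0.6, "prop_same_tactic": -1.5})
    rng = np.random.default_rng(seed)
    u_male = rng.normal(0, re_sds[1], size=n_males)
    rows = []
    for lit in range(n_litters):
        event = f"E{lit % max(1, n_litters // 4)}"
        female = f"F{lit % max(1, n_litters // 3)}"
        u_f = rng.normal(0, re_sds[0])
        u_e = rng.normal(0, re_sds[2])
        n_s = min(2 + int(rng.poisson(1.2)), n_males)
        males = rng.choice(n_males, size=n_s, replace=False)
        guard = rng.uniform(size=n_s) < 0.5
        guard[int(rng.integers(n_s))] = True
        guard[int(rng.integers(n_s))] = False  # keep both tactics common
        for j in range(n_s):
            same = ((guard == guard[j]).sum() - 1) / (n_s - 1)
            eta = (
                coef["intercept"]
                + coef["tactic"] * guard[j]
                + coef["n_competitors"] * (n_s - 2.66)
                + coef["prop_same_tactic"] * same
                + u_f + u_e + u_male[males[j]]
            )
            rows.append(
                {
                    "oestrus_event_id": event,
                    "litter_id": f"L{lit}",
                    "female_id": female,
                    "male_id": f"M{males[j]}",
                    "tactic": "guard" if guard[j] else "sneaker",
                    "n_competitors": n_s,
                    "prop_same_tactic": same,
                    "sired": bool(rng.uniform() < expit(eta)),
                }
            )
    return pd.DataFrame(rows)


def simulate_dyad_observations(
    truth: MateChoiceTruth = MateChoiceTruth(),
    n_events: int = 60,
    males_per_event: int = 10,
    females_range: tuple[int, int] = (3, 7),
    days_per_event: int = 3,
    re_sds: tuple[float, float, float] = (0.3, 0.3, 0.3),  # male, female, event
    seed: int = 0,
) -> pd.DataFrame:
    """Day-level dyad records drawn directly from the mate-choice model.

    The number of adult females varies between events (as in real groups) so
    its effect is identifiable alongside the intercept.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_events):
        event = f"E{t}"
        u_e = rng.normal(0, re_sds[2])
        females_per_event = int(rng.integers(females_range[0], females_range[1] + 1))
        males = [f"E{t}M{i}" for i in range(males_per_event)]
        females = [f"F{i}" for i in range(females_per_event)]
        u_m = {m: rng.normal(0, re_sds[0]) for m in males}
        u_f = {f: rng.normal(0, re_sds[1]) for f in females}
        m_rank = {m: i + 1 for i, m in enumerate(males)}
        f_rank = {f: i + 1 for i, f in enumerate(females)}
        rel = {(m, f): rng.choice([0.0, 0.125, 0.25, 0.5]) for m in males for f in females}
        for m in males:
            mean_rel = np.mean([rel[(m, f)] for f in females])
            guard = rng.uniform() < 0.5
            for day in range(days_per_event):
                any_hit = False
                recs = []
                for f in females:
                    gc_rel = rel[(m, f)] - mean_rel
                    eta = truth.eta(m_rank[m], f_rank[f], gc_rel, guard, females_per_event)
                    eta += u_m[m] + u_f[f] + u_e
                    hit = bool(rng.uniform() < expit(eta))
                    any_hit = any_hit or hit
                    recs.append(
                        {
                            "oestrus_event_id": event,
                            "day": day,
                            "male_id": m,
                            "female_id": f,
                            "tactic": "guard" if guard else "sneaker",
                            "male_age_rank": m_rank[m],
                            "female_age_rank": f_rank[f],
                            "gc_relatedness": gc_rel,
                            "n_adult_females": females_per_event,
                            "interacted": hit,
                        }
                    )
                if any_hit:  # the model conditions on days with >= 1 interaction
                    rows.extend(recs)
    return pd.DataFrame(rows)
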