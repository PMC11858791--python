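"""Derivation rules: from raw study tables to model-ready data.

Turns the five study tables (daily focal observations, weights, demography,
pairwise relatedness, litters) into the per-oestrus quantities the models
consume:

* one summarized tactic per male per oestrus event (guard / sneaker /
  subordinate, with the tie rule configurable);
* age ranks (1 = oldest; ties share the minimum rank and leave gaps);
* oestrus weights averaged over a +/-60-day window, group-centred, with
  missing windows imputed from each male's own age-weight relationship;
* percentage weight change per event (60-day prior average vs the single
  nearest post-event weight within 9 days; imputed weights never used);
* group-centred relatedness of each male to the adult females present;
* litters linked to the oestrus event that ended 44-74 days before birth;
* the day-level male x female dyad table for mate choice and the per-litter
  siring trials.

Males under 180 days of age never enter any derived table. Dates are whole
days and all intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUBADULT_AGE = 180
ADULT_AGE = 365
WEIGHT_WINDOW = 60       # days either side of an event for the oestrus weight
POST_WEIGHT_MAX = 9      # latest usable post-event weight, inclusive
LITTER_GAP = (44, 74)    # event end precedes birth by 44-74 days (59 +/- 15)


# ---------------------------------------------------------------------------
# elementary rules


def summarize_tactic(daily: pd.DataFrame, tie_rule: str = "sneaker") -> str:
    """One tactic per male per oestrus event from his daily records.

    A male who guarded on any day and never sneaked is a guard; one who
    sneaked and never guarded is a sneaker; if both occurred, the behaviour
    shown on more days wins and a day-count tie goes to ``tie_rule``
    (default sneaker). A male inactive throughout is a subordinate.
    """
    if tie_rule not in ("sneaker", "guard"):
        raise ValueError("tie_rule must be 'sneaker' or 'guard'")
    if len(daily) == 0:
        raise ValueError("no observations: male not present at this event")
    by_day = daily.groupby("date")["behaviour"]
    g_days = int(by_day.apply(lambda s: (s == "guard").any()).sum())
    s_days = int(by_day.apply(lambda s: (s == "sneak").any()).sum())
    if g_days == 0 and s_days == 0:
        return "subordinate"
    if g_days > s_days:
        return "guard"
    if s_days > g_days:
        return "sneaker"
    return tie_rule


def assign_age_ranks(ages: Mapping[str, float]) -> dict[str, int]:
    """Within-group age ranks: 1 = oldest, ties share the minimum rank and the
    next-younger individual's rank skips by the size of the tie group."""
    if not ages:
        raise ValueError("ages must be non-empty")
    items = sorted(ages.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks: dict[str, int] = {}
    for pos, (ind, age) in enumerate(items):
        if pos > 0 and age == items[pos - 1][1]:
            ranks[ind] = ranks[items[pos - 1][0]]
        else:
            ranks[ind] = pos + 1
    return ranks


def oestrus_weight(
    weights: pd.DataFrame,
    start: pd.Timestamp,
    end: pd.Timestamp,
    window: int = WEIGHT_WINDOW,
) -> float:
    """Mean of all weights within [start - window, end + window]; NaN if none.

    The window is anchored at the event start (backwards) and event end
    (forwards), closed on both sides.
    """
    if len(weights) == 0:
        return float("nan")
    d = weights["date"]
    mask = (d >= start - pd.Timedelta(days=window)) & (d <= end + pd.Timedelta(days=window))
    if not mask.any():
        return float("nan")
    return float(weights.loc[mask, "grams"].mean())


def centre_weights(weights: Mapping[str, float]) -> dict[str, float]:
    """Centre each male's oestrus weight on the group-event mean over observed
    males; the centred values sum to zero exactly."""
    observed = {k: v for k, v in weights.items() if np.isfinite(v)}
    if not observed:
        raise ValueError("no observed weights in this group-event; impute or drop")
    mean = float(np.mean(list(observed.values())))
    return {k: v - mean for k, v in observed.items()}


def impute_missing_weights(
    oestrus: pd.DataFrame,
    weights: pd.DataFrame,
    demography: pd.DataFrame,
) -> pd.DataFrame:
    """Fill missing oestrus weights from each male's age-weight relationship.

    ``oestrus`` has one row per male-event with columns ``male_id``,
    ``age_mid`` (age in days at the window midpoint) and ``oestrus_weight``
    (NaN where the window held no data). Males with >= 3 usable weights get
    their own least-squares weight-on-age line, fitted locally (weights
    within 120 days of the target age, widening to 240 days and then the
    whole lifetime until 3 points are found) because growth trajectories are
    only locally linear; males with 1-2 weights get a pooled-slope line
    through their own mean; males with no weights stay missing. Adds an
    ``imputed`` flag; imputed values are for covariate use only and are
    never fed into weight-loss analyses.
    """
    birth = demography.set_index("individual_id")["birth_date"]
    w = weights.copy()
    w["age"] = (w["date"] - w["individual_id"].map(birth)).dt.days.astype(float)
    hist = {ind: grp for ind, grp in w.groupby("individual_id")}

    # pooled slope over individuals with >= 2 measurements
    num = 0.0
    den = 0.0
    for grp in hist.values():
        if len(grp) >= 2:
            a = grp["age"].to_numpy()
            g = grp["grams"].to_numpy(dtype=float)
            num += float(np.sum((a - a.mean()) * (g - g.mean())))
            den += float(np.sum((a - a.mean()) ** 2))
    pooled_slope = num / den if den > 0 else 0.0

    out = oestrus.copy()
    out["imputed"] = False
    missing = out.index[~np.isfinite(out["oestrus_weight"].to_numpy(dtype=float))]
    for i in missing:
        male = out.at[i, "male_id"]
        age = float(out.at[i, "age_mid"])
        grp = hist.get(male)
        if grp is None or len(grp) == 0:
            continue
        a = grp["age"].to_numpy(dtype=float)
        g = grp["grams"].to_numpy(dtype=float)
        if len(grp) >= 3:
            sel = np.ones(len(a), dtype=bool)
            for half_width in (120.0, 240.0):
                local = np.abs(a - age) <= half_width
                if local.sum() >= 3:
                    sel = local
                    break
            slope, icept = np.polyfit(a[sel], g[sel], 1)
            pred = slope * age + icept
        else:
            pred = g.mean() + pooled_slope * (age - a.mean())
        out.at[i, "oestrus_weight"] = pred
        out.at[i, "imputed"] = True
    return out


def extract_weight_change(
    weights: pd.DataFrame,
    start: pd.Timestamp,
    end: pd.Timestamp,
    max_days_post: int = POST_WEIGHT_MAX,
) -> dict | None:
    """Percentage weight change over one event, or None.

    Prior weight: mean of raw weights in the 60 days before the event start.
    Post weight: the single nearest weight after the event end, usable only
    within ``max_days_post`` days (day 9 inclusive).
    """
    if len(weights) == 0:
        return None
    d = weights["date"]
    prior_mask = (d >= start - pd.Timedelta(days=WEIGHT_WINDOW)) & (d < start)
    if not prior_mask.any():
        return None
    post = weights.loc[d > end].sort_values("date")
    if len(post) == 0:
        return None
    days_to_post = int((post["date"].iloc[0] - end).days)
    if days_to_post > max_days_post:
        return None
    prior = float(weights.loc[prior_mask, "grams"].mean())
    post_w = float(post["grams"].iloc[0])
    return {
        "prior_weight": prior,
        "post_weight": post_w,
        "pct_change": 100.0 * (post_w - prior) / prior,
        "days_to_post": days_to_post,
    }


def group_centred_relatedness(
    male_id: str,
    females: Sequence[str],
    relatedness: Mapping[tuple[str, str], float],
) -> dict[str, float]:
    """Relatedness of one male to each adult female present, centred on his
    mean over those females; dyads with unknown relatedness are dropped (the
    caller logs them). Per-male outputs average to zero exactly."""
    known = {}
    for f in females:
        r = relatedness.get((male_id, f), relatedness.get((f, male_id)))
        if r is not None and np.isfinite(r):
            known[f] = float(r)
    if not known:
        return {}
    mean = float(np.mean(list(known.values())))
    return {f: r - mean for f, r in known.items()}


def compute_sex_ratio(roster: pd.DataFrame) -> float:
    """Adult males per adult female (both at least one year old) on the group
    roster at an event; undefined without adult females."""
    adult = roster[roster["age_days"] >= ADULT_AGE]
    n_f = int((adult["sex"] == "f").sum())
    if n_f == 0:
        raise ValueError("no adult females: sex ratio undefined")
    return float((adult["sex"] == "m").sum()) / n_f


def link_litters(
    litters: pd.DataFrame,
    events: pd.DataFrame,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Link each litter to the oestrus event of the mother's group whose end
    fell 44-74 days (59 +/- 15, a gestation) before the birth date; with two
    candidates the nearer event end wins; unlinked litters are excluded."""
    ev = events.copy()
    rows = []
    for _, lit in litters.iterrows():
        cand = ev[ev["group_id"] == lit["group_id"]] if "group_id" in lit else ev
        gap = (lit["birth_date"] - cand["end"]).dt.days
        ok = cand[(gap >= LITTER_GAP[0]) & (gap <= LITTER_GAP[1])]
        if len(ok) == 0:
            if log is not None:
                log.append(f"litter {lit['litter_id']}: no event 44-74 d before birth")
            continue
        if len(ok) > 1 and log is not None:
            log.append(f"litter {lit['litter_id']}: {len(ok)} candidate events; nearest end used")
        chosen = ok.loc[(lit["birth_date"] - ok["end"]).dt.days.idxmin()]
        rows.append({"litter_id": lit["litter_id"], "oestrus_event_id": chosen["event_id"]})
    return pd.DataFrame(rows, columns=["litter_id", "oestrus_event_id"])


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class DerivedData:
    """Everything the four models need, plus the processing log."""

    events: pd.DataFrame          # event_id, group_id, start, end, event_order
    transitions: pd.DataFrame     # per male-event: tactic + covariates (model-ready)
    weight_changes: pd.DataFrame  # per male-event pct change records
    dyads: pd.DataFrame           # day-level male x female records
    siring_trials: pd.DataFrame   # per-suitor Bernoulli trials
    log: list[str] = field(default_factory=list)


def _parse_dates(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = pd.to_datetime(out[c], errors="coerce")
    return out


def _relatedness_lookup(rel: pd.DataFrame) -> dict[tuple[str, str], float]:
    lut: dict[tuple[str, str], float] = {}
    for a, b, r in rel[["id_a", "id_b", "r"]].itertuples(index=False):
        lut[(a, b)] = float(r)
        lut[(b, a)] = float(r)
    return lut


def derive_all(tables: Mapping[str, pd.DataFrame], tie_rule: str = "sneaker") -> DerivedData:
    """Run every derivation rule over the five raw tables.

    ``tables`` holds ``focals``, ``weights``, ``demography``, ``relatedness``
    and ``litters`` with the documented CSV schemas (dates ISO strings or
    datetimes).
    """
    log: list[str] = []
    focals = _parse_dates(tables["focals"], ["date"])
    weights = _parse_dates(tables["weights"], ["date"])
    demography = _parse_dates(
        tables["demography"], ["birth_date", "death_date", "entry_date", "exit_date"]
    )
    litters = _parse_dates(tables["litters"], ["birth_date"])
    rel_lut = _relatedness_lookup(tables["relatedness"])

    events = (
        focals.groupby("event_id")
        .agg(group_id=("group_id", "first"), start=("date", "min"), end=("date", "max"))
        .reset_index()
        .sort_values(["group_id", "start"], kind="stable")
        .reset_index(drop=True)
    )
    events["event_order"] = events.groupby("group_id").cumcount()

    birth = demography.set_index("individual_id")["birth_date"]
    weight_hist = {ind: grp.sort_values("date") for ind, grp in weights.groupby("individual_id")}

    trans_rows: list[dict] = []
    wc_rows: list[dict] = []
    dyad_rows: list[dict] = []
    event_meta: dict[str, dict] = {}

    for ev in events.itertuples(index=False):
        start, end = ev.start, ev.end
        ev_focals = focals[focals["event_id"] == ev.event_id]

        # roster from demography (presence intervals overlapping the event)
        in_group = demography[demography["group_id"] == ev.group_id]
        present = in_group[
            (in_group["entry_date"] <= end)
            & (in_group["exit_date"] >= start)
            & (in_group["death_date"].isna() | (in_group["death_date"] >= start))
        ].copy()
        present["age_days"] = (start - present["birth_date"]).dt.days

        try:
            sex_ratio = compute_sex_ratio(present[["sex", "age_days"]])
        except ValueError:
            log.append(f"event {ev.event_id}: no adult females; event excluded")
            continue

        adult_females = present[(present["sex"] == "f") & (present["age_days"] >= ADULT_AGE)]
        female_ranks = assign_age_ranks(
            dict(zip(adult_females["individual_id"], adult_females["age_days"]))
        )

        # tactic per male with focal records, age filter at 180 days
        male_obs = ev_focals[ev_focals["male_id"] != ""]
        ages = {}
        tactics = {}
        for male, grp in male_obs.groupby("male_id"):
            b = birth.get(male)
            if b is None or pd.isna(b):
                log.append(f"event {ev.event_id}: male {male} missing birth date; dropped")
                continue
            age = int((start - b).days)
            if age < SUBADULT_AGE:
                continue
            ages[male] = age
            tactics[male] = summarize_tactic(grp, tie_rule=tie_rule)
        if not ages:
            continue
        ranks = assign_age_ranks(ages)

        # oestrus weights (raw), later imputed and centred
        o_weights = {
            m: oestrus_weight(weight_hist.get(m, pd.DataFrame(columns=["date", "grams"])), start, end)
            for m in ages
        }

        event_meta[ev.event_id] = {
            "group_id": ev.group_id,
            "start": start,
            "end": end,
            "order": ev.event_order,
        }
        mid_age_off = (end - start).days / 2.0
        for m in ages:
            trans_rows.append(
                {
                    "male_id": m,
                    "oestrus_event_id": ev.event_id,
                    "group_id": ev.group_id,
                    "event_order": ev.event_order,
                    "tactic": tactics[m],
                    "age_days": ages[m],
                    "age_mid": ages[m] + mid_age_off,
                    "age_rank": ranks[m],
                    "oestrus_weight": o_weights[m],
                    "sex_ratio": sex_ratio,
                }
            )

            # weight change record (raw weights only, never imputed)
            wc = extract_weight_change(
                weight_hist.get(m, pd.DataFrame(columns=["date", "grams"])), start, end
            )
            if wc is not None:
                wc_rows.append(
                    {
                        "male_id": m,
                        "group_id": ev.group_id,
                        "oestrus_event_id": ev.event_id,
                        "tactic": tactics[m],
                        **wc,
                    }
                )

        # day-level dyad records for active males
        female_list = list(adult_females["individual_id"])
        n_females = len(female_list)
        for m in ages:
            gc_rel = group_centred_relatedness(m, female_list, rel_lut)
            dropped = set(female_list) - set(gc_rel)
            if dropped:
                log.append(
                    f"event {ev.event_id}: male {m}: {len(dropped)} dyads with unknown relatedness dropped"
                )
            m_rows = male_obs[male_obs["male_id"] == m]
            for day, day_rows in m_rows.groupby("date"):
                behav = set(day_rows["behaviour"])
                if not behav & {"guard", "sneak"}:
                    continue  # inactive day: not a choice opportunity
                day_tactic = "guard" if "guard" in behav else "sneaker"
                pursued = set(day_rows.loc[day_rows["behaviour"].isin(["guard", "sneak"]), "female_id"])
                for f in female_list:
                    if f not in gc_rel:
                        continue
                    dyad_rows.append(
                        {
                            "oestrus_event_id": ev.event_id,
                            "day": day,
                            "male_id": m,
                            "female_id": f,
                            "tactic": day_tactic,
                            "male_age_rank": ranks[m],
                            "female_age_rank": female_ranks[f],
                            "gc_relatedness": gc_rel[f],
                            "n_adult_females": n_females,
                            "interacted": f in pursued,
                        }
                    )

    transitions = pd.DataFrame(trans_rows)
    if len(transitions) == 0:
        raise ValueError("no usable male-events after filtering")

    # imputation of missing oestrus weights, then group-event centring
    transitions = impute_missing_weights(transitions, weights, demography)
    transitions["group_centred_weight"] = np.nan
    for _, idx in transitions.groupby("oestrus_event_id").groups.items():
        block = transitions.loc[idx]
        observed = block.loc[~block["imputed"], "oestrus_weight"]
        observed = observed[np.isfinite(observed)]
        if len(observed) > 0:
            mean = float(observed.mean())
        else:
            filled = block["oestrus_weight"][np.isfinite(block["oestrus_weight"])]
            if len(filled) == 0:
                log.append(
                    f"event {block['oestrus_event_id'].iloc[0]}: no weights even after imputation"
                )
                continue
            mean = float(filled.mean())
        transitions.loc[idx, "group_centred_weight"] = transitions.loc[idx, "oestrus_weight"] - mean

    # append the absorbing dead state at the first event after death
    death = demography.set_index("individual_id")["death_date"]
    extra = []
    for male, grp in transitions.groupby("male_id"):
        dd = death.get(male)
        if dd is None or pd.isna(dd):
            continue
        group_id = grp["group_id"].iloc[0]
        later = events[(events["group_id"] == group_id) & (events["start"] > dd)]
        if len(later) == 0:
            continue
        nxt = later.sort_values("start").iloc[0]
        extra.append(
            {
                "male_id": male,
                "oestrus_event_id": nxt["event_id"],
                "group_id": group_id,
                "event_order": nxt["event_order"],
                "tactic": "dead",
                "age_days": np.nan,
                "age_mid": np.nan,
                "age_rank": np.nan,
                "oestrus_weight": np.nan,
                "sex_ratio": np.nan,
                "imputed": False,
                "group_centred_weight": np.nan,
            }
        )
    if extra:
        transitions = pd.concat([transitions, pd.DataFrame(extra)], ignore_index=True)
    transitions = transitions.sort_values(
        ["male_id", "event_order"], kind="stable"
    ).reset_index(drop=True)

    dyads = pd.DataFrame(
        dyad_rows,
        columns=[
            "oestrus_event_id", "day", "male_id", "female_id", "tactic",
            "male_age_rank", "female_age_rank", "gc_relatedness",
            "n_adult_females", "interacted",
        ],
    )

    # litters -> events -> siring trials
    lit = litters.copy()
    mother_group = demography.set_index("individual_id")["group_id"]
    lit["group_id"] = lit["mother_id"].map(mother_group)
    links = link_litters(lit, events, log=log)
    siring = build_siring_trials(lit, links, focals, transitions, log=log)

    return DerivedData(
        events=events,
        transitions=transitions,
        weight_changes=pd.DataFrame(
            wc_rows,
            columns=[
                "male_id", "group_id", "oestrus_event_id", "tactic",
                "prior_weight", "post_weight", "pct_change", "days_to_post",
            ],
        ),
        dyads=dyads,
        siring_trials=siring,
        log=log,
    )


def build_siring_trials(
    litters: pd.DataFrame,
    links: pd.DataFrame,
    focals: pd.DataFrame,
    transitions: pd.DataFrame,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """One Bernoulli trial per male who pursued the mother during the linked
    event. A litter enters only when the mother was attended by at least one
    guard and one sneaker; the litter is excluded (and logged) when no
    assigned sire is among her suitors."""
    tactic_of = transitions.set_index(["male_id", "oestrus_event_id"])["tactic"]
    rows = []
    linked = litters.merge(links, on="litter_id")
    for _, lit in linked.iterrows():
        event_id = lit["oestrus_event_id"]
        mother = lit["mother_id"]
        ev_rows = focals[
            (focals["event_id"] == event_id)
            & (focals["female_id"] == mother)
            & (focals["behaviour"].isin(["guard", "sneak"]))
        ]
        suitors = sorted(set(ev_rows["male_id"]))
        tactics = {}
        for m in suitors:
            t = tactic_of.get((m, event_id))
            if t in ("guard", "sneaker"):
                tactics[m] = t
        if len(tactics) == 0:
            continue
        values = set(tactics.values())
        if values != {"guard", "sneaker"}:
            if log is not None:
                log.append(f"litter {lit['litter_id']}: mother lacked both tactics; excluded")
            continue
        sires = set(str(lit["sire_ids"]).split(";")) if lit["sire_ids"] else set()
        if not sires & set(tactics):
            if log is not None:
                log.append(f"litter {lit['litter_id']}: sire never interacted with mother; excluded")
            continue
        males = sorted(tactics)
        n = len(males)
        for m in males:
            same = sum(1 for o in males if o != m and tactics[o] == tactics[m])
            rows.append(
                {
                    "oestrus_event_id": event_id,
                    "litter_id": lit["litter_id"],
                    "female_id": mother,
                    "male_id": m,
                    "tactic": tactics[m],
                    "n_competitors": n,
                    "prop_same_tactic": same / (n - 1) if n > 1 else 0.0,
                    "sired": m in sires,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "oestrus_event_id", "litter_id", "female_id", "male_id",
            "tactic", "n_competitors", "prop_same_tactic", "sired",
        ],
    )


def histories_from_transitions(transitions: pd.DataFrame):
    """Per-male ordered tactic sequences (state matrix form) from the derived
    transitions table."""
    from .transitions import TacticHistory

    out = []
    for male, grp in transitions.sort_values(["male_id", "event_order"], kind="stable").groupby(
        "male_id"
    ):
        out.append(
            TacticHistory(
                male_id=male,
                events=list(zip(grp["oestrus_event_id"], grp["tactic"])),
            )
        )
    return out
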