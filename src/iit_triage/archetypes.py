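"""Rule-based client archetypes and combinatorial segment discovery.

An archetype is a named, human-readable subgroup defined by a conjunction of
atomic conditions over client covariates and visit history — e.g. "adolescent
girls and young women" (female, 15 <= age < 25 at the visit) or "returning
after disengagement" (at least one prior visit interrupted). The 16 built-in
archetypes span three categories:

* 4 demographic (mutually exclusive age/sex cells),
* 4 behavioral (visit-attendance patterns, available from any EMR),
* 8 socio-behavioral (require survey covariates such as household size,
  travel time, disclosure and readiness to start treatment).

Operational conventions, configurable via module constants:

* AGYW/ABYM are 15 <= age < 25; adults are age >= 25 (exactly 25 is adult).
* "On time" / "prompt" reuse the 3-day lateness boundary of the percent-late
  feature: a visit is on time when attended no more than 3 days late.
* "Regularly prompt" needs >= 2 prior visits, all within 3 days;
  "regularly late" needs >= 2 prior visits more than 3 days late.
* "Lives alone" means zero other household members; "lives more than 20
  minutes away" is strict (exactly 20 matches neither side).

Beyond the fixed rules, :func:`discover_archetypes` reproduces the procedure
that found them: enumerate every value configuration of every pair (or larger
tuple) of discretized key variables, drop empty/unsatisfiable or undersized
segments, and rank the rest by how far their IIT rate departs from the
population baseline.
"""

from __future__ import annotations

import itertools
import logging
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TwoByTwo, crude_rr

__all__ = [
    "Condition",
    "ArchetypeRule",
    "DiscoveredSegment",
    "builtin_rules",
    "build_archetype_frame",
    "assign_archetypes",
    "archetype_table",
    "discover_archetypes",
]

logger = logging.getLogger(__name__)

YOUTH_MIN_AGE = 15
ADULT_AGE = 25
ON_TIME_MAX_DAYS_LATE = 3
PROMPT_MIN_PRIOR_VISITS = 2
NEARBY_TRAVEL_MIN = 20
PAYDAY_WINDOW_DAYS = 7

_OPS = {
    "eq": operator.eq,
    "ne": operator.ne,
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
}


@dataclass(frozen=True)
class Condition:
    """One atomic predicate ``field <op> value`` over the archetype frame."""

    field: str
    op: str
    value: object

    def evaluate(self, frame: pd.DataFrame) -> pd.Series:
        if self.field not in frame.columns:
            raise KeyError(f"condition references unknown field {self.field!r}")
        s = frame[self.field]
        if self.op == "is_true":
            return s.fillna(False).astype(bool)
        if self.op == "is_false":
            return (~s.astype("boolean")).fillna(False).astype(bool)
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        return _OPS[self.op](s, self.value).fillna(False).astype(bool)


@dataclass(frozen=True)
class ArchetypeRule:
    """A named conjunction of conditions with its category and data needs."""

    name: str
    category: str  # demographic | behavioral | socio_behavioral
    conditions: tuple[Condition, ...]
    data_requirement: str = "emr_only"  # or "survey_required"
    evaluation_time: str = "each_visit"  # or "at_initiation"

    def match(self, frame: pd.DataFrame) -> pd.Series:
        out = pd.Series(True, index=frame.index)
        for cond in self.conditions:
            out &= cond.evaluate(frame)
        return out


def _c(field: str, op: str, value: object = None) -> Condition:
    return Condition(field, op, value)


def builtin_rules() -> list[ArchetypeRule]:
    """The 16 built-in archetype definitions (4 demographic, 4 behavioral,
    8 socio-behavioral)."""
    demo = [
        ArchetypeRule("adult_female", "demographic",
                      (_c("sex", "eq", "F"), _c("age_at_visit", "ge", ADULT_AGE))),
        ArchetypeRule("adult_male", "demographic",
                      (_c("sex", "eq", "M"), _c("age_at_visit", "ge", ADULT_AGE))),
        ArchetypeRule("agyw", "demographic",
                      (_c("sex", "eq", "F"), _c("age_at_visit", "ge", YOUTH_MIN_AGE),
                       _c("age_at_visit", "lt", ADULT_AGE))),
        ArchetypeRule("abym", "demographic",
                      (_c("sex", "eq", "M"), _c("age_at_visit", "ge", YOUTH_MIN_AGE),
                       _c("age_at_visit", "lt", ADULT_AGE))),
    ]
    behav = [
        # attended on time (<= 3 d late) and never seen at another facility
        ArchetypeRule("prompt_and_loyal", "behavioral",
                      (_c("current_on_time", "is_true"),
                       _c("multi_facility", "is_false"))),
        # previous two visits both attended after the scheduled date (or missed)
        ArchetypeRule("late_twice", "behavioral",
                      (_c("prev_two_late", "is_true"),)),
        ArchetypeRule("shopper_no_number", "behavioral",
                      (_c("multi_facility", "is_true"),
                       _c("phone_number_on_file", "is_false"))),
        # at least one prior visit was interrupted (> 28 d late or never attended)
        ArchetypeRule("returning_after_disengagement", "behavioral",
                      (_c("n_prior_gt28d_late", "ge", 1),)),
    ]
    socio = [
        ArchetypeRule("super_green", "socio_behavioral",
                      (_c("regularly_prompt", "is_true"),
                       _c("household_size_others", "ge", 1)),
                      data_requirement="survey_required"),
        ArchetypeRule("employed_youth_at_payday", "socio_behavioral",
                      (_c("age_at_visit", "ge", 18), _c("age_at_visit", "le", 29),
                       _c("employed", "is_true"),
                       _c("days_to_payday_next_appt", "lt", PAYDAY_WINDOW_DAYS)),
                      data_requirement="survey_required"),
        ArchetypeRule("prior_test_and_prompt", "socio_behavioral",
                      (_c("prior_hiv_test_history", "is_true"),
                       _c("regularly_prompt", "is_true"))),
        ArchetypeRule("lone_ranger", "socio_behavioral",
                      (_c("household_size_others", "le", 1),
                       _c("travel_time_min", "gt", NEARBY_TRAVEL_MIN)),
                      data_requirement="survey_required",
                      evaluation_time="at_initiation"),
        ArchetypeRule("unexpected_and_unsupported", "socio_behavioral",
                      (_c("planned_to_test_today", "is_false"),
                       _c("household_size_others", "le", 1)),
                      data_requirement="survey_required",
                      evaluation_time="at_initiation"),
        ArchetypeRule("disillusioned_disclosers", "socio_behavioral",
                      (_c("has_hiv_info", "is_true"),
                       _c("disclosed_status", "is_true"),
                       _c("household_size_others", "le", 1)),
                      data_requirement="survey_required",
                      evaluation_time="at_initiation"),
        ArchetypeRule("live_close_always_late", "socio_behavioral",
                      (_c("travel_time_min", "lt", NEARBY_TRAVEL_MIN),
                       _c("regularly_late", "is_true")),
                      data_requirement="survey_required"),
        ArchetypeRule("prepared_and_late", "socio_behavioral",
                      (_c("prepared_to_start_today", "is_true"),
                       _c("prior_hiv_test_history", "is_true"),
                       _c("regularly_late", "is_true")),
                      data_requirement="survey_required"),
    ]
    return demo + behav + socio


_CLIENT_FIELDS = [
    "sex", "household_size_others", "travel_time_min", "disclosed_status",
    "has_hiv_info", "planned_to_test_today", "prepared_to_start_today",
    "prior_hiv_test_history", "multi_facility", "phone_number_on_file",
    "payday_day_of_month",
]


def build_archetype_frame(labeled: pd.DataFrame, clients: pd.DataFrame) -> pd.DataFrame:
    """Per-visit evaluation frame for archetype rules.

    Combines client covariates with visit-history state: age at the visit,
    whether the current visit was on time, lateness of the previous two
    visits, counts of prior late/interrupted visits, and the day distance
    from the next appointment to the client's payday.
    """
    cl = clients.set_index("client_id")
    missing = set(labeled["client_id"]) - set(cl.index)
    if missing:
        raise KeyError(f"visits reference unknown client(s): {sorted(missing)[:3]}")
    v = labeled
    out = pd.DataFrame(index=v.index)
    out["client_id"] = v["client_id"]
    for f in _CLIENT_FIELDS:
        out[f] = v["client_id"].map(cl[f])
    out["employed"] = (v["client_id"].map(cl["employment"]) == "employed").astype(bool)

    # completed calendar years, so a 25th-birthday visit counts as adult
    birth = v["client_id"].map(cl["birth_date"])
    sched = v["scheduled_date"]
    before_birthday = (sched.dt.month < birth.dt.month) | (
        (sched.dt.month == birth.dt.month) & (sched.dt.day < birth.dt.day)
    )
    out["age_at_visit"] = sched.dt.year - birth.dt.year - before_birthday.astype(int)

    late = (v["days_late"].isna() | (v["days_late"] > 0)).astype(bool)
    late_gt3 = (v["days_late"].isna() | (v["days_late"] > ON_TIME_MAX_DAYS_LATE)).astype(bool)
    gt28 = (v["days_late"].isna() | (v["days_late"] > 28)).astype(bool)
    g = out["client_id"]
    out["current_on_time"] = v["days_late"].notna() & ~late_gt3
    prev1 = late.astype("boolean").groupby(g).shift(1).fillna(False)
    prev2 = late.astype("boolean").groupby(g).shift(2).fillna(False)
    out["prev_two_late"] = (prev1 & prev2).astype(bool)
    n_prior = late.groupby(g).cumcount()
    n_prior_gt3 = late_gt3.astype(int).groupby(g).cumsum() - late_gt3.astype(int)
    out["n_prior_visits"] = n_prior
    out["n_prior_gt3d_late"] = n_prior_gt3
    out["n_prior_gt28d_late"] = gt28.astype(int).groupby(g).cumsum() - gt28.astype(int)
    out["regularly_prompt"] = (n_prior >= PROMPT_MIN_PRIOR_VISITS) & (n_prior_gt3 == 0)
    out["regularly_late"] = n_prior_gt3 >= PROMPT_MIN_PRIOR_VISITS

    out["days_to_payday_next_appt"] = _days_to_payday(
        v["next_scheduled_date"], out["payday_day_of_month"]
    )
    return out


def _days_to_payday(next_sched: pd.Series, payday: pd.Series) -> pd.Series:
    """Absolute day distance from the next appointment to the nearest payday."""
    out = pd.Series(np.nan, index=next_sched.index)
    mask = (next_sched.notna() & payday.notna()).to_numpy()
    for i in np.flatnonzero(mask):
        d = next_sched.iloc[i]
        pday = int(payday.iloc[i])
        dists = []
        for moff in (-1, 0, 1):
            month_start = pd.Timestamp(d.year, d.month, 1) + pd.DateOffset(months=moff)
            day = min(pday, month_start.days_in_month)
            payday_date = pd.Timestamp(month_start.year, month_start.month, day)
            dists.append(abs((payday_date - d).days))
        out.iloc[i] = min(dists)
    return out


def assign_archetypes(
    labeled: pd.DataFrame,
    clients: pd.DataFrame,
    rules: list[ArchetypeRule] | None = None,
) -> pd.DataFrame:
    """Boolean visit x archetype membership matrix.

    Every visit with age >= 15 matches exactly one demographic archetype;
    behavioral and socio-behavioral archetypes may overlap freely. A rule
    whose required fields are absent for a client simply does not match
    (the skip is logged).
    """
    rules = builtin_rules() if rules is None else rules
    frame = build_archetype_frame(labeled, clients)
    out = pd.DataFrame(index=labeled.index)
    for rule in rules:
        needed = {c.field for c in rule.conditions}
        na_rows = frame[list(needed & set(frame.columns))].isna().any(axis=1)
        if na_rows.all() and len(frame):
            logger.warning("rule %r matches no visit: required fields all absent", rule.name)
        elif na_rows.any():
            logger.info("rule %r: skipped %d visits lacking required fields",
                        rule.name, int(na_rows.sum()))
        out[rule.name] = rule.match(frame)
    return out


def archetype_table(
    assignments: pd.DataFrame,
    labeled: pd.DataFrame,
    reference: str,
    archetypes: list[str] | None = None,
    cross_demographics: list[str] | None = None,
    restrict_months: int | None = None,
) -> pd.DataFrame:
    """IIT counts, rates and RR vs a reference archetype.

    Parameters
    ----------
    assignments : DataFrame
        Output of :func:`assign_archetypes`, index-aligned with ``labeled``.
    reference : str
        Archetype whose visits form the RR denominator group (must be
        non-empty); e.g. adult_female, prompt_and_loyal or super_green.
    archetypes : list of str, optional
        Rows to report (default: every assignment column).
    cross_demographics : list of str, optional
        When given, each reported archetype is crossed with each of these
        demographic archetypes (demographic x behavioral strata).
    restrict_months : int, optional
        Keep only visits within this many months on ART (needs a
        ``time_on_art_stratum``-bearing labeled frame with ``time_on_art``
        available via months_0_6 ... or a precomputed restriction).
    """
    df = labeled.loc[assignments.index]
    keep = df["iit_next_visit"].notna()
    if restrict_months is not None:
        if restrict_months != 6:
            raise ValueError("only the 6-month restriction is supported")
        keep &= df["time_on_art_stratum"] == "months_0_6"
    df = df.loc[keep]
    asg = assignments.loc[keep]
    y = df["iit_next_visit"].astype(bool)

    ref_mask = asg[reference]
    n_ref, e_ref = int(ref_mask.sum()), int(y[ref_mask].sum())
    if n_ref == 0:
        raise ValueError(f"reference archetype {reference!r} is empty")

    names = archetypes if archetypes is not None else list(asg.columns)
    combos: list[tuple[str, pd.Series]] = []
    for name in names:
        if cross_demographics:
            for demo in cross_demographics:
                combos.append((f"{demo}:{name}", asg[demo] & asg[name]))
        else:
            combos.append((name, asg[name]))

    rows = []
    for label, mask in combos:
        n, e = int(mask.sum()), int(y[mask].sum())
        row = {
            "archetype": label, "n_visits": n, "n_iit_next": e,
            "iit_rate": e / n if n else float("nan"),
            "rr_vs_reference": float("nan"), "ci_low": float("nan"),
            "ci_high": float("nan"), "reference": label == reference,
        }
        if label == reference:
            row["rr_vs_reference"] = 1.0
        elif n and e_ref:
            res = crude_rr(TwoByTwo(e, n, e_ref, n_ref))
            row.update(rr_vs_reference=res.rr, ci_low=res.ci_low, ci_high=res.ci_high)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiscoveredSegment:
    """A value configuration of key variables with its IIT rate."""

    defining_conditions: tuple[tuple[str, object], ...]
    n_visits: int
    n_iit: int
    iit_rate: float
    delta_vs_baseline: float


def discover_archetypes(
    frame: pd.DataFrame,
    iit_next_labels: pd.Series,
    key_variables: list[str],
    min_size: int = 50,
    order: int = 2,
) -> list[DiscoveredSegment]:
    """Exhaustively enumerate variable-tuple configurations by IIT rate.

    For every combination of ``order`` key variables (which must be binary or
    small categorical) and every configuration of their observed values, the
    segment's IIT rate is compared with the whole-population baseline rate.
    Configurations observed in no visit (including logically unsatisfiable
    ones) and segments smaller than ``min_size`` are dropped; the rest are
    returned sorted by absolute departure from baseline, largest first.
    """
    if not key_variables:
        raise ValueError("no key variables supplied")
    y = pd.Series(iit_next_labels).astype(bool)
    baseline = float(y.mean())
    levels = {}
    for var in key_variables:
        if var not in frame.columns:
            raise KeyError(f"unknown key variable {var!r}")
        vals = sorted(frame[var].dropna().unique().tolist())
        if len(vals) > 8:
            raise ValueError(f"variable {var!r} has {len(vals)} levels; discretize first")
        levels[var] = vals

    segments = []
    for combo in itertools.combinations(key_variables, order):
        for values in itertools.product(*(levels[v] for v in combo)):
            mask = pd.Series(True, index=frame.index)
            for var, val in zip(combo, values):
                mask &= frame[var] == val
            n = int(mask.sum())
            if n == 0 or n < min_size:
                continue
            e = int(y[mask].sum())
            rate = e / n
            segments.append(DiscoveredSegment(
                defining_conditions=tuple(zip(combo, values)),
                n_visits=n, n_iit=e, iit_rate=rate,
                delta_vs_baseline=rate - baseline,
            ))
    segments.sort(key=lambda s: (-abs(s.delta_vs_baseline), s.defining_conditions))
    return segments
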