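"""Visit labeling: lateness, the 28-day IIT outcome, and next-visit pairing.

A client is retained at a visit if it is attended before or within 28 days of
the scheduled date; otherwise the visit is an interruption in treatment (IIT).
The boundary is inclusive: 28 days late is retained, 29 is IIT, and early
attendance (up to 28 days before the scheduled date) counts as on time.

Because the outcome needs a month to accrue and captured data lag behind, a
visit only enters analysis if it was scheduled at least three months before
the database censor date (the ``eligible`` flag).

The prediction target attached to each visit is the IIT status of the client's
*next* scheduled visit (``iit_next_visit``); the last visit in a client's
record, or a visit whose successor is inside the censor window, has no target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .io import SchemaError, canonicalize_visits

__all__ = [
    "label_visits",
    "pair_next_visit",
    "time_on_art_stratum",
    "add_time_on_art",
    "STRATA",
]

IIT_GRACE_DAYS = 28
CENSOR_WINDOW_MONTHS = 3

STRATA = ("first_visit_after_initiation", "months_0_6", "months_7_12", "months_gt_12")


def _check_sorted(visits: pd.DataFrame) -> None:
    # duplicated (client_id, scheduled_date) pairs are already rejected by the
    # schema check, so any non-positive within-client diff means unsorted input
    diffs = visits.groupby("client_id", sort=False)["scheduled_date"].diff()
    bad = (diffs <= pd.Timedelta(0)).fillna(False)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"visits row {row}: not sorted by scheduled_date within client")


def label_visits(visits: pd.DataFrame, censor_date) -> pd.DataFrame:
    """Attach lateness and IIT labels to a visit table.

    Parameters
    ----------
    visits : DataFrame
        Schema-conformant visits, sorted by ``scheduled_date`` within client.
    censor_date : date-like
        The database censor date; must not precede any scheduled date.

    Returns
    -------
    DataFrame with added columns ``days_late`` (NA if never attended),
    ``attended_within_28``, ``iit_this_visit`` and ``eligible``.
    """
    visits = canonicalize_visits(visits)
    _check_sorted(visits)
    censor = pd.Timestamp(censor_date)
    if len(visits) and visits["scheduled_date"].max() > censor:
        raise ValueError("censor_date precedes some scheduled dates")

    out = visits.copy()
    days_late = (out["attended_date"] - out["scheduled_date"]).dt.days.astype("Int64")
    attended28 = (out["attended_date"].notna() & (days_late <= IIT_GRACE_DAYS)).astype(bool)
    out["days_late"] = days_late
    out["attended_within_28"] = attended28
    out["iit_this_visit"] = ~attended28
    cutoff = censor - relativedelta(months=CENSOR_WINDOW_MONTHS)
    out["eligible"] = (out["scheduled_date"] <= pd.Timestamp(cutoff)).astype(bool)
    return out


def pair_next_visit(labeled: pd.DataFrame) -> pd.DataFrame:
    """Attach each visit's next scheduled date and the next visit's IIT status.

    ``iit_next_visit`` is NA when the client has no following scheduled visit
    or when that visit is inside the censor window (not ``eligible``), since
    its outcome cannot be ascertained. Re-running on already-paired data is a
    no-op.
    """
    out = labeled.copy()
    g = out.groupby("client_id", sort=False)
    out["next_scheduled_date"] = g["scheduled_date"].shift(-1)
    nxt_iit = g["iit_this_visit"].shift(-1)
    nxt_eligible = g["eligible"].shift(-1)
    out["iit_next_visit"] = nxt_iit.where(nxt_eligible.astype("boolean").fillna(False)).astype(
        "boolean"
    )
    return out


def time_on_art_stratum(scheduled_date, art_start_date) -> str:
    """Calendar-month stratum of a visit relative to ART start.

    Boundaries: [0, 6] months -> ``months_0_6``; (6, 12] -> ``months_7_12``;
    beyond 12 -> ``months_gt_12``. Exactly six calendar months is still early
    ART; six months and a day is not. The first visit after initiation is
    flagged separately at cohort level (it also belongs to months_0_6).
    """
    scheduled = pd.Timestamp(scheduled_date)
    start = pd.Timestamp(art_start_date)
    if scheduled < start:
        raise ValueError("visit scheduled before ART start")
    rd = relativedelta(scheduled.to_pydatetime(), start.to_pydatetime())
    months = rd.years * 12 + rd.months
    exact = rd.days == 0 and rd.hours == 0
    if months < 6 or (months == 6 and exact):
        return "months_0_6"
    if months < 12 or (months == 12 and exact):
        return "months_7_12"
    return "months_gt_12"


def add_time_on_art(labeled: pd.DataFrame, clients: pd.DataFrame) -> pd.DataFrame:
    """Add ``time_on_art_stratum`` and ``first_visit_after_initiation`` columns."""
    start = clients.set_index("client_id")["art_start_date"]
    missing = set(labeled["client_id"]) - set(start.index)
    if missing:
        raise KeyError(f"visits reference unknown client(s): {sorted(missing)[:3]}")
    out = labeled.copy()
    starts = out["client_id"].map(start)
    out["time_on_art_stratum"] = [
        time_on_art_stratum(s, a) for s, a in zip(out["scheduled_date"], starts)
    ]
    out["first_visit_after_initiation"] = ~out.duplicated(subset="client_id", keep="first")
    return out
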