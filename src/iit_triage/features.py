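"""Per-visit predictor features.

Every feature is computed from information available at or before the visit it
describes: visit-history aggregates run over strictly prior visits plus the
current visit's own lateness, labs are the most recent result at or before the
visit, and the next appointment's calendar fields are known at the current
visit because that is when the appointment is issued. Nothing dated after the
current visit leaks in.

Lateness conventions match the outcome definitions: "late" for the percent-
late feature means more than 3 days after the scheduled date, and the
more-than-28-days counter uses the same strict boundary as the IIT rule. A
visit that was never attended counts as late under both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "SURVEY_ONLY_FEATURES",
    "build_features",
    "restrict_to_emr_features",
    "encode_for_model",
]

_DAYS_PER_MONTH = 30.4375

FEATURE_COLUMNS = [
    "pct_visits_gt3d_late",
    "n_times_gt28d_late",
    "n_visits_this_facility",
    "n_vl_tests",
    "months_since_first_visit",
    "months_since_last_visit",
    "current_age",
    "day_of_month_next_appt",
    "day_of_week_next_appt",
    "last_vl_value",
    "sex",
    "n_missed_months",
    "visits_on_regimen",
    "time_on_art",
    "appointment_month",
    "months_since_last_vl",
    "cd4_screening",
    "travel_time_min",
    "tb_symptom_count",
    "year_first_tested_positive",
    "household_size_others",
]

# collected only in the baseline survey, never in routine medical records
SURVEY_ONLY_FEATURES = [
    "travel_time_min",
    "household_size_others",
    "year_first_tested_positive",
]

ID_COLUMNS = ["client_id", "scheduled_date"]


def _month_index(ts: pd.Timestamp) -> int:
    return ts.year * 12 + ts.month


def _client_features(v: pd.DataFrame) -> pd.DataFrame:
    """Loop-computed history features for one client's visit block."""
    n = len(v)
    sched = v["scheduled_date"].to_list()
    attended = v["attended_date"].to_list()
    days_late = v["days_late"].to_list()
    regimen = v["regimen_code"].to_list()
    vl_dates = v["vl_date"].to_list()

    out = {
        "months_since_last_visit": [],
        "n_missed_months": [],
        "visits_on_regimen": [],
        "months_since_last_vl": [],
    }
    last_attended = None
    last_vl_date = None
    attended_months: set[int] = set()
    streak = 0
    for i in range(n):
        out["months_since_last_visit"].append(
            None if last_attended is None else (sched[i] - last_attended).days / _DAYS_PER_MONTH
        )
        streak = streak + 1 if (i > 0 and regimen[i] == regimen[i - 1]) else 1
        out["visits_on_regimen"].append(streak)

        if not pd.isna(attended[i]):
            attended_months.add(_month_index(attended[i]))
        span = range(_month_index(sched[0]), _month_index(sched[i]) + 1)
        out["n_missed_months"].append(sum(1 for m in span if m not in attended_months))

        if not pd.isna(vl_dates[i]) and vl_dates[i] <= sched[i]:
            last_vl_date = vl_dates[i]
        out["months_since_last_vl"].append(
            None if last_vl_date is None else (sched[i] - last_vl_date).days / _DAYS_PER_MONTH
        )
        if not pd.isna(attended[i]):
            last_attended = attended[i]
    return pd.DataFrame(out, index=v.index).astype(float)


def build_features(
    labeled: pd.DataFrame, clients: pd.DataFrame, eligible_only: bool = True
) -> pd.DataFrame:
    """Compute the per-visit feature table.

    Parameters
    ----------
    labeled : DataFrame
        Labeled, paired visits (from ``label_visits`` + ``pair_next_visit``).
    clients : DataFrame
        Client records; every visit's ``client_id`` must resolve.
    eligible_only : bool
        Restrict the output to censor-eligible visits (history is still
        accumulated over all visits). Row index alignment with ``labeled``
        is preserved.

    Returns a DataFrame with ``client_id``, ``scheduled_date``, the feature
    columns, and the ``iit_next_visit`` target when present in the input.
    """
    missing = set(labeled["client_id"]) - set(clients["client_id"])
    if missing:
        raise KeyError(
            f"visits reference client(s) absent from the client table: "
            f"{sorted(missing)[:3]}"
        )
    cl = clients.set_index("client_id")
    v = labeled
    late_gt3 = (v["days_late"].isna() | (v["days_late"] > 3)).astype(float)
    late_gt28 = (v["days_late"].isna() | (v["days_late"] > 28)).astype(float)
    g = v.groupby("client_id", sort=False)

    out = pd.DataFrame(index=v.index)
    out["client_id"] = v["client_id"]
    out["scheduled_date"] = v["scheduled_date"]
    seq = g.cumcount() + 1
    out["pct_visits_gt3d_late"] = late_gt3.groupby(v["client_id"]).cumsum() / seq
    out["n_times_gt28d_late"] = late_gt28.groupby(v["client_id"]).cumsum().astype(int)
    out["n_visits_this_facility"] = (
        v.groupby(["client_id", "facility_id"], sort=False).cumcount() + 1
    )
    out["n_vl_tests"] = (
        v["vl_value"].notna().astype(float).groupby(v["client_id"]).cumsum().astype(int)
    )
    first_sched = g["scheduled_date"].transform("first")
    out["months_since_first_visit"] = (
        (v["scheduled_date"] - first_sched).dt.days / _DAYS_PER_MONTH
    )
    birth = v["client_id"].map(cl["birth_date"])
    out["current_age"] = (v["scheduled_date"] - birth).dt.days / 365.25
    out["day_of_month_next_appt"] = v["next_scheduled_date"].dt.day.astype("Float64")
    out["day_of_week_next_appt"] = (v["next_scheduled_date"].dt.dayofweek + 1).astype(
        "Float64"
    )
    out["last_vl_value"] = v.groupby("client_id", sort=False)["vl_value"].ffill()
    out["sex"] = v["client_id"].map(cl["sex"])
    art_start = v["client_id"].map(cl["art_start_date"])
    out["time_on_art"] = (v["scheduled_date"] - art_start).dt.days / _DAYS_PER_MONTH
    out["appointment_month"] = v["scheduled_date"].dt.month
    out["cd4_screening"] = v["client_id"].map(cl["cd4_screening"])
    out["travel_time_min"] = v["client_id"].map(cl["travel_time_min"])
    out["tb_symptom_count"] = v["tb_symptom_count"]
    out["year_first_tested_positive"] = v["client_id"].map(
        cl["year_first_tested_positive"]
    ).astype("Float64")
    out["household_size_others"] = v["client_id"].map(cl["household_size_others"]).astype(
        "Float64"
    )

    loopy = pd.concat(
        [_client_features(block) for _, block in v.groupby("client_id", sort=False)]
    ).loc[v.index]
    for col in loopy.columns:
        out[col] = loopy[col]

    out = out[ID_COLUMNS + FEATURE_COLUMNS]
    if "iit_next_visit" in v.columns:
        out["iit_next_visit"] = v["iit_next_visit"]
    if eligible_only and "eligible" in v.columns:
        out = out.loc[v["eligible"].astype(bool)]
    return out


def restrict_to_emr_features(features: pd.DataFrame) -> pd.DataFrame:
    """Drop survey-only columns, keeping routinely captured EMR variables.

    Idempotent: columns already absent are ignored.
    """
    drop = [c for c in SURVEY_ONLY_FEATURES if c in features.columns]
    return features.drop(columns=drop)


def encode_for_model(
    features: pd.DataFrame, metadata: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Encode a feature table as a numeric design matrix.

    Categorical fields become one-hot indicator columns; a numeric field with
    absent values becomes a sentinel-imputed value column plus a missingness
    indicator. Column order is fixed by the metadata, so encoding the same
    input twice — or new data against a stored metadata — yields identically
    shaped matrices. An unseen categorical level at scoring time falls into an
    ``__other__`` bucket.
    """
    cols = [c for c in features.columns if c in FEATURE_COLUMNS]
    if metadata is None:
        metadata = {"sentinel": -1.0, "columns": cols, "categorical_levels": {}}
        for c in cols:
            if features[c].dtype == object:
                levels = sorted(x for x in features[c].dropna().unique())
                metadata["categorical_levels"][c] = levels
    else:
        missing = [c for c in metadata["columns"] if c not in features.columns]
        if missing:
            raise ValueError(f"feature column(s) missing at encode time: {missing}")

    sentinel = metadata["sentinel"]
    X = pd.DataFrame(index=features.index)
    for c in metadata["columns"]:
        if c in metadata["categorical_levels"]:
            s = features[c]
            known = set(metadata["categorical_levels"][c])
            for level in metadata["categorical_levels"][c]:
                X[f"{c}={level}"] = (s == level).astype(float)
            X[f"{c}=__other__"] = (s.notna() & ~s.isin(known)).astype(float)
        else:
            s = pd.to_numeric(features[c], errors="coerce").astype(float)
            X[c] = s.fillna(sentinel)
            X[f"{c}__missing"] = s.isna().astype(float)
    return X, metadata
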