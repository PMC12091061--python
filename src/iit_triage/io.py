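"""Reading and writing cohort files.

A cohort is a pair of CSV files, ``clients.csv`` and ``visits.csv``, with a
fixed column set, ISO-8601 dates, booleans as ``1``/``0`` and the empty string
as the absent-value marker. :func:`read_cohort` validates the schema and the
basic record invariants and raises :class:`SchemaError` naming the offending
column or row, so malformed inputs fail at the door rather than deep inside
the analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CLIENT_SCHEMA",
    "VISIT_SCHEMA",
    "write_cohort",
    "read_cohort",
    "canonicalize_clients",
    "canonicalize_visits",
]


class SchemaError(ValueError):
    """A cohort file violates the expected schema or a record invariant."""


# column -> kind, where kind in {"str", "date", "int", "float", "bool"}
CLIENT_SCHEMA: dict[str, str] = {
    "client_id": "str",
    "sex": "str",
    "birth_date": "date",
    "employment": "str",
    "payday_day_of_month": "int",
    "household_size_others": "int",
    "travel_time_min": "float",
    "disclosed_status": "bool",
    "has_hiv_info": "bool",
    "planned_to_test_today": "bool",
    "prepared_to_start_today": "bool",
    "prior_hiv_test_history": "bool",
    "year_first_tested_positive": "int",
    "cd4_screening": "float",
    "phone_number_on_file": "bool",
    "multi_facility": "bool",
    "art_start_date": "date",
}

VISIT_SCHEMA: dict[str, str] = {
    "client_id": "str",
    "facility_id": "str",
    "scheduled_date": "date",
    "attended_date": "date",
    "regimen_code": "str",
    "vl_value": "float",
    "vl_date": "date",
    "tb_symptom_count": "int",
}

_DTYPES = {
    "str": "object",
    "date": "datetime64[ns]",
    "int": "Int64",
    "float": "float64",
    "bool": "boolean",
}


def _canonicalize(df: pd.DataFrame, schema: dict[str, str], what: str) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise SchemaError(f"{what} has unknown column(s): {', '.join(unknown)}")
    out = pd.DataFrame(index=pd.RangeIndex(len(df)))
    for col, kind in schema.items():
        s = df[col].reset_index(drop=True)
        try:
            if kind == "date":
                if not pd.api.types.is_datetime64_any_dtype(s):
                    s = pd.to_datetime(s, format="ISO8601", errors="raise")
                out[col] = s.astype("datetime64[ns]")
            elif kind == "int":
                out[col] = pd.to_numeric(s, errors="raise").astype("Int64")
            elif kind == "float":
                out[col] = pd.to_numeric(s, errors="raise").astype("float64")
            elif kind == "bool":
                out[col] = s.map(_parse_bool).astype("boolean")
            else:
                out[col] = s.astype("object")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{what} column {col!r}: {exc}") from exc
    return out


_BOOL_VALUES = {True: True, False: False, "1": True, "0": False, 1: True, 0: False}


def _parse_bool(v):
    if pd.isna(v):
        return pd.NA
    try:
        return _BOOL_VALUES[v]
    except KeyError:
        raise ValueError(f"cannot interpret {v!r} as a boolean") from None


def canonicalize_clients(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a client table to canonical column order and dtypes."""
    return _canonicalize(df, CLIENT_SCHEMA, "clients")


def canonicalize_visits(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a visit table to canonical dtypes and validate record invariants."""
    out = _canonicalize(df, VISIT_SCHEMA, "visits")
    dup = out.duplicated(subset=["client_id", "scheduled_date"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"visits row {row}: duplicated (client_id, scheduled_date) "
            f"({out.at[row, 'client_id']}, {out.at[row, 'scheduled_date'].date()})"
        )
    # early attendance is allowed up to 28 days before the scheduled date
    delta = (out["attended_date"] - out["scheduled_date"]).dt.days
    bad = delta < -28
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"visits row {row}: attended_date more than 28 days before scheduled_date"
        )
    return out


def _serialize(df: pd.DataFrame, schema: dict[str, str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        s = df[col]
        if kind == "date":
            out[col] = s.dt.strftime("%Y-%m-%d")
        elif kind == "bool":
            out[col] = s.map({True: "1", False: "0"})
        elif kind == "int":
            out[col] = s.astype("object").map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif kind == "float":
            out[col] = s.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            out[col] = s
        out[col] = out[col].fillna("")
    return out


def write_cohort(clients: pd.DataFrame, visits: pd.DataFrame, path: str | Path) -> None:
    """Write ``clients.csv`` and ``visits.csv`` under directory ``path``.

    Records are validated (and canonicalized) before writing, so a cohort that
    violates the schema never reaches disk.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    clients = canonicalize_clients(clients)
    visits = canonicalize_visits(visits)
    _serialize(clients, CLIENT_SCHEMA).to_csv(path / "clients.csv", index=False)
    _serialize(visits, VISIT_SCHEMA).to_csv(path / "visits.csv", index=False)


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort directory; returns ``(clients, visits)``."""
    path = Path(path)
    clients_raw = pd.read_csv(path / "clients.csv", dtype="object", keep_default_na=False)
    visits_raw = pd.read_csv(path / "visits.csv", dtype="object", keep_default_na=False)
    clients = canonicalize_clients(clients_raw.replace({"": None}))
    visits = canonicalize_visits(visits_raw.replace({"": None}))
    return clients, visits
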