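"""Shared fixtures: small seeded synthetic cohorts and hand-built visit tables."""

from __future__ import annotations

import pandas as pd
import pytest

from iit_triage.io import CLIENT_SCHEMA, canonicalize_clients, canonicalize_visits
from iit_triage.labeling import add_time_on_art, label_visits, pair_next_visit
from iit_triage.synthetic import GeneratorConfig, generate_cohort


def make_client(client_id="C1", **overrides) -> dict:
    """A fully populated client row; override any field."""
    row = {
        "client_id": client_id,
        "sex": "F",
        "birth_date": "1985-06-15",
        "employment": "employed",
        "payday_day_of_month": 25,
        "household_size_others": 2,
        "travel_time_min": 15.0,
        "disclosed_status": True,
        "has_hiv_info": True,
        "planned_to_test_today": True,
        "prepared_to_start_today": True,
        "prior_hiv_test_history": True,
        "year_first_tested_positive": 2019,
        "cd4_screening": 350.0,
        "phone_number_on_file": True,
        "multi_facility": False,
        "art_start_date": "2020-01-01",
    }
    row.update(overrides)
    return row


def make_visits(client_id, scheduled_attended_pairs, facility="F001"):
    """Visit rows from (scheduled, attended-or-None) date pairs."""
    rows = []
    for sched, att in scheduled_attended_pairs:
        rows.append({
            "client_id": client_id,
            "facility_id": facility,
            "scheduled_date": sched,
            "attended_date": att,
            "regimen_code": "TLD",
            "vl_value": None,
            "vl_date": None,
            "tb_symptom_count": 0,
        })
    return rows


def clients_frame(rows):
    return canonicalize_clients(pd.DataFrame(rows, columns=list(CLIENT_SCHEMA)))


def visits_frame(rows):
    return canonicalize_visits(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """300-client default-condition cohort shared across tests."""
    cfg = GeneratorConfig(n_clients=300, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_labeled(small_cohort):
    clients, visits = small_cohort
    censor = visits["scheduled_date"].max()
    return clients, add_time_on_art(
        pair_next_visit(label_visits(visits, censor)), clients
    )
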