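"""Archetype rule definitions, assignment and combinatorial discovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from iit_triage.archetypes import (
    archetype_table,
    assign_archetypes,
    build_archetype_frame,
    builtin_rules,
    discover_archetypes,
)
from iit_triage.stats import TwoByTwo, crude_rr

from conftest import clients_frame, make_client, make_visits, visits_frame
from iit_triage.labeling import add_time_on_art, label_visits, pair_next_visit

CENSOR = "2021-06-30"
DEMOGRAPHIC = ("adult_female", "adult_male", "agyw", "abym")


def _label(clients, visits):
    return add_time_on_art(pair_next_visit(label_visits(visits, CENSOR)), clients)


def test_builtin_rule_inventory():
    rules = builtin_rules()
    assert len(rules) == 16
    by_cat = pd.Series([r.category for r in rules]).value_counts()
    assert by_cat["demographic"] == 4
    assert by_cat["behavioral"] == 4
    assert by_cat["socio_behavioral"] == 8
    assert len({r.name for r in rules}) == 16


def test_agyw_assignment():
    clients = clients_frame([make_client(sex="F", birth_date="1997-03-01")])  # 23 at visit
    visits = visits_frame(make_visits("C1", [("2020-02-01", "2020-02-01")]))
    asg = assign_archetypes(_label(clients, visits), clients)
    assert bool(asg.loc[0, "agyw"])
    assert not asg.loc[0, list(DEMOGRAPHIC)].drop("agyw").any()


def test_age_25_exactly_is_adult():
    clients = clients_frame([make_client(sex="M", birth_date="1995-02-01")])
    visits = visits_frame(make_visits("C1", [("2020-02-01", "2020-02-01")]))
    asg = assign_archetypes(_label(clients, visits), clients)
    assert bool(asg.loc[0, "adult_male"]) and not bool(asg.loc[0, "abym"])


def test_returning_but_not_late_twice():
    """Prior lateness (30, 0): returned after disengagement, but the previous
    two visits were not both late."""
    clients = clients_frame([make_client()])
    visits = visits_frame(make_visits("C1", [
        ("2020-02-01", "2020-03-02"),  # 30 days late
        ("2020-04-01", "2020-04-01"),  # on time
        ("2020-06-01", "2020-06-01"),  # current
    ]))
    asg = assign_archetypes(_label(clients, visits), clients)
    assert bool(asg.loc[2, "returning_after_disengagement"])
    assert not bool(asg.loc[2, "late_twice"])


def test_late_twice_requires_two_consecutive_late():
    clients = clients_frame([make_client()])
    visits = visits_frame(make_visits("C1", [
        ("2020-02-01", "2020-02-03"),
        ("2020-03-01", "2020-03-05"),
        ("2020-04-01", "2020-04-01"),
    ]))
    asg = assign_archetypes(_label(clients, visits), clients)
    assert bool(asg.loc[2, "late_twice"])


def test_super_green_needs_punctuality_and_company():
    clients = clients_frame([make_client(household_size_others=4)])
    visits = visits_frame(make_visits("C1", [
        ("2020-02-01", "2020-02-01"),
        ("2020-03-01", "2020-03-03"),  # 2 d late still "prompt" (<= 3 d)
        ("2020-04-01", "2020-04-01"),
    ]))
    asg = assign_archetypes(_label(clients, visits), clients)
    assert bool(asg.loc[2, "super_green"])  # >= 2 prior visits, all <= 3 d late
    assert not bool(asg.loc[1, "super_green"])  # only one prior visit


def test_employed_youth_at_payday_window():
    clients = clients_frame([
        make_client("C1", birth_date="1998-01-01", employment="employed",
                    payday_day_of_month=25),
        make_client("C2", birth_date="1998-01-01", employment="unemployed",
                    payday_day_of_month=None),
    ])
    rows = make_visits("C1", [("2020-02-01", "2020-02-01"), ("2020-03-23", None)]) + \
        make_visits("C2", [("2020-02-01", "2020-02-01"), ("2020-03-23", None)])
    asg = assign_archetypes(_label(clients, visits_frame(rows)), clients)
    # next appointment Mar 23 is 2 days from the 25th payday
    assert bool(asg.loc[0, "employed_youth_at_payday"])
    assert not bool(asg.loc[2, "employed_youth_at_payday"])  # not employed


def test_demographic_partition(small_labeled):
    clients, lab = small_labeled
    asg = assign_archetypes(lab, clients)
    frame = build_archetype_frame(lab, clients)
    adults = frame["age_at_visit"] >= 15
    assert (asg.loc[adults, list(DEMOGRAPHIC)].sum(axis=1) == 1).all()


def test_archetype_table_matches_manual_rr(small_labeled):
    clients, lab = small_labeled
    asg = assign_archetypes(lab, clients)
    table = archetype_table(asg, lab, reference="adult_female",
                            archetypes=["adult_female", "agyw"])
    keep = lab["iit_next_visit"].notna()
    y = lab.loc[keep, "iit_next_visit"].astype(bool)
    t = TwoByTwo(
        int(y[asg.loc[keep, "agyw"]].sum()), int(asg.loc[keep, "agyw"].sum()),
        int(y[asg.loc[keep, "adult_female"]].sum()), int(asg.loc[keep, "adult_female"].sum()),
    )
    expected = crude_rr(t)
    row = table.set_index("archetype").loc["agyw"]
    assert row["rr_vs_reference"] == pytest.approx(expected.rr)
    assert row["ci_low"] == pytest.approx(expected.ci_low)
    ref = table.set_index("archetype").loc["adult_female"]
    assert ref["reference"] and ref["rr_vs_reference"] == 1.0


def test_reference_identical_to_itself_is_unity(small_labeled):
    clients, lab = small_labeled
    asg = assign_archetypes(lab, clients)
    table = archetype_table(asg, lab, reference="prompt_and_loyal",
                            archetypes=["prompt_and_loyal"])
    assert table["rr_vs_reference"].iloc[0] == 1.0


def test_empty_reference_rejected(small_labeled):
    clients, lab = small_labeled
    asg = assign_archetypes(lab, clients)
    asg["never"] = False
    with pytest.raises(ValueError, match="empty"):
        archetype_table(asg, lab, reference="never")


def test_cross_strata_table(small_labeled):
    clients, lab = small_labeled
    asg = assign_archetypes(lab, clients)
    table = archetype_table(
        asg, lab, reference="adult_female",
        archetypes=["prompt_and_loyal", "returning_after_disengagement"],
        cross_demographics=["adult_female", "agyw"],
        restrict_months=6,
    )
    assert len(table) == 4
    assert "adult_female:prompt_and_loyal" in set(table["archetype"])


# --- discovery -------------------------------------------------------------


def _discovery_frame(n=4000, seed=1):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        f"v{i}": rng.integers(0, 2, n).astype(bool) for i in range(4)
    })
    base = 0.10
    planted = frame["v0"] & ~frame["v1"]
    p = np.where(planted, 2 * base, base)
    labels = pd.Series(rng.random(n) < p)
    return frame, labels


def test_two_binary_variables_give_at_most_four_configs():
    frame, labels = _discovery_frame()
    segs = discover_archetypes(frame, labels, ["v0", "v1"], min_size=1)
    assert len(segs) <= 4
    assert sum(s.n_visits for s in segs) == len(frame)


def test_unsatisfiable_configuration_removed():
    frame, labels = _discovery_frame()
    frame = frame.copy()
    frame["lives_alone"] = frame["v0"]
    frame["household_ge2"] = ~frame["v0"]  # logically exclusive with lives_alone
    segs = discover_archetypes(frame, labels, ["lives_alone", "household_ge2"], min_size=1)
    conds = [dict(s.defining_conditions) for s in segs]
    assert {"lives_alone": True, "household_ge2": True} not in conds


def test_planted_high_risk_pair_ranks_first():
    frame, labels = _discovery_frame(n=5000, seed=2)
    segs = discover_archetypes(frame, labels, [f"v{i}" for i in range(4)], min_size=50)
    top = dict(segs[0].defining_conditions)
    assert top == {"v0": True, "v1": False}
    assert segs[0].delta_vs_baseline > 0


def test_enumeration_count_matches_brute_force():
    """Segments evaluated before pruning equal the brute-force product count."""
    rng = np.random.default_rng(3)
    k = 5
    frame = pd.DataFrame({f"v{i}": rng.integers(0, 2, 600).astype(bool) for i in range(k)})
    labels = pd.Series(rng.random(600) < 0.15)
    segs = discover_archetypes(frame, labels, list(frame.columns), min_size=1)
    expected = sum(
        1
        for combo in itertools.combinations(frame.columns, 2)
        for vals in itertools.product([False, True], repeat=2)
        if ((frame[combo[0]] == vals[0]) & (frame[combo[1]] == vals[1])).any()
    )
    assert len(segs) == expected


def test_no_variables_is_an_error():
    frame, labels = _discovery_frame()
    with pytest.raises(ValueError, match="no key variables"):
        discover_archetypes(frame, labels, [], min_size=1)
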