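"""Percentile binning, doubling calibration and the triage table."""

import numpy as np
import pandas as pd
import pytest

from iit_triage.stats import TwoByTwo, crude_rr
from iit_triage.triage import (
    assign_bins,
    calibrate_doubling_cutoffs,
    doubling_objective,
    triage_table,
)


def test_hundred_distinct_scores_split_50_40_10():
    rng = np.random.default_rng(1)
    scores = rng.permutation(np.linspace(0.01, 0.99, 100))
    bins = assign_bins(scores)
    assert bins.value_counts().to_dict() == {"green": 50, "yellow": 40, "red": 10}


def test_scores_one_to_ten():
    bins = assign_bins(np.arange(1, 11), (0.5, 0.9))
    assert list(bins) == ["green"] * 5 + ["yellow"] * 4 + ["red"]


def test_identical_scores_all_green_with_warning():
    with pytest.warns(UserWarning, match="identical"):
        bins = assign_bins(np.full(30, 0.7))
    assert (bins == "green").all()


def test_ties_at_cutpoint_fall_to_lower_bin():
    # 60 copies of the median value straddle the 50% cut: all stay green
    scores = np.concatenate([np.zeros(20), np.full(60, 0.5), np.ones(20)])
    bins = assign_bins(scores)
    assert (bins[np.flatnonzero(scores == 0.5)] == "green").all()


def test_empty_scores_rejected():
    with pytest.raises(ValueError, match="no scores"):
        assign_bins([])


def _doubling_data(n=5000, seed=0, rates=(0.065, 0.13, 0.26)):
    """Scores uniform; true IIT rate steps x2 at the 50th and 90th centiles."""
    rng = np.random.default_rng(seed)
    scores = rng.random(n)
    p = np.where(scores < np.quantile(scores, 0.5), rates[0],
                 np.where(scores < np.quantile(scores, 0.9), rates[1], rates[2]))
    return scores, rng.random(n) < p


def test_calibration_recovers_constructed_doubling_cuts():
    scores, labels = _doubling_data(seed=3)
    p1, p2 = calibrate_doubling_cutoffs(scores, labels)
    assert abs(p1 - 0.50) <= 0.05
    assert abs(p2 - 0.90) <= 0.05


def test_calibration_result_approximately_doubles():
    """The returned cuts achieve (near-)doubling: their objective is within
    the plateau slack of the default cuts' objective."""
    scores, labels = _doubling_data(seed=4)
    cuts = calibrate_doubling_cutoffs(scores, labels)
    assert doubling_objective(scores, labels, cuts) <= doubling_objective(
        scores, labels, (0.5, 0.9)
    ) + 0.05


def test_objective_near_zero_for_rate_doubling_bins():
    """Bins with IIT rates 6% / 13% / 26% (ratios 2.17 and 2.00)."""
    n = 30000
    scores = np.concatenate([np.full(15000, 0.1), np.full(12000, 0.5), np.full(3000, 0.9)])
    labels = np.zeros(n, bool)
    labels[:900] = True                  # 6% of green
    labels[15000:15000 + 1560] = True    # 13% of yellow
    labels[27000:27000 + 780] = True     # 26% of red
    obj = doubling_objective(scores, labels, (0.5, 0.9))
    assert obj == pytest.approx((np.log(13 / 6) - np.log(2)) ** 2, abs=1e-6)
    assert obj < 0.01


def test_partition_property(small_labeled):
    rng = np.random.default_rng(7)
    _, lab = small_labeled
    scored = lab.loc[lab["iit_next_visit"].notna()]
    scores = pd.Series(rng.random(len(scored)), index=scored.index)
    bins = assign_bins(scores)
    table = triage_table(bins, lab, by_stratum=False)
    assert table["n_visits"].sum() == len(scored)


def test_triage_rr_matches_direct_stats(small_labeled):
    _, lab = small_labeled
    scored = lab.loc[lab["iit_next_visit"].notna()]
    rng = np.random.default_rng(2)
    # risk-linked scores so bins differ in rate
    y = scored["iit_next_visit"].astype(bool).to_numpy()
    scores = pd.Series(rng.random(len(scored)) + 0.4 * y, index=scored.index)
    table = triage_table(assign_bins(scores), lab, by_stratum=False)
    row = table.loc[table["bin"] == "red"].iloc[0]
    green = table.loc[table["bin"] == "green"].iloc[0]
    expected = crude_rr(TwoByTwo(
        int(row["n_iit_next"]), int(row["n_visits"]),
        int(green["n_iit_next"]), int(green["n_visits"]),
    ))
    assert row["rr_vs_green"] == pytest.approx(expected.rr)
    assert row["ci_low"] == pytest.approx(expected.ci_low)


def test_rr_invariant_under_monotone_score_rescaling(small_labeled):
    _, lab = small_labeled
    scored = lab.loc[lab["iit_next_visit"].notna()]
    rng = np.random.default_rng(9)
    scores = pd.Series(rng.random(len(scored)), index=scored.index)
    t1 = triage_table(assign_bins(scores), lab, by_stratum=False)
    t2 = triage_table(assign_bins(np.exp(5 * scores)), lab, by_stratum=False)
    assert t1["rr_vs_green"].fillna(-1).tolist() == t2["rr_vs_green"].fillna(-1).tolist()


def test_monotone_risk_across_bins_with_signal():
    """Risk-correlated scores give green <= yellow <= red IIT rates."""
    rng = np.random.default_rng(11)
    n = 5000
    propensity = rng.normal(size=n)
    y = rng.random(n) < 1 / (1 + np.exp(-(propensity - 2)))
    scores = propensity + rng.normal(scale=0.5, size=n)
    lab = pd.DataFrame({"iit_next_visit": y})
    table = triage_table(assign_bins(pd.Series(scores)), lab, by_stratum=False)
    rates = table.set_index("bin")["iit_rate"]
    assert rates["green"] <= rates["yellow"] <= rates["red"]
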