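"""Percentile triage of risk scores into green / yellow / red bins.

Scored visits are ranked against the scored analysis set itself: the lowest
50% of scores are low risk ("green"), the middle 40% moderate ("yellow") and
the top 10% high risk ("red"). Bin membership uses the strict-below percentile
rank, so ties at a cutpoint all fall into the lower-risk bin and a degenerate
all-equal score set is entirely green (with a warning).

The default (0.50, 0.90) cutpoints came from a doubling criterion — each bin's
IIT rate should be about twice the rate of the bin below — and
:func:`calibrate_doubling_cutoffs` recovers such cutpoints from data by a
deterministic grid search on the log-ratio objective

    sum over adjacent bin pairs of (log(rate_hi / rate_lo) - log 2)^2 .
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .labeling import STRATA
from .stats import TwoByTwo, crude_rr

__all__ = [
    "BIN_LABELS",
    "TriageBinning",
    "assign_bins",
    "doubling_objective",
    "calibrate_doubling_cutoffs",
    "triage_table",
]

BIN_LABELS = ("green", "yellow", "red")


class TriageBinning:
    """Realized binning: the percentile cuts and the score values they map to."""

    def __init__(self, cut_percentiles: tuple[float, float], scores: np.ndarray):
        p1, p2 = cut_percentiles
        if not 0.0 < p1 < p2 < 1.0:
            raise ValueError("cut percentiles must satisfy 0 < p1 < p2 < 1")
        self.cut_percentiles = (float(p1), float(p2))
        self.score_cutpoints = (
            float(np.quantile(scores, p1)),
            float(np.quantile(scores, p2)),
        )
        self.bin_labels = BIN_LABELS


def assign_bins(
    scores, cut_percentiles: tuple[float, float] = (0.50, 0.90)
) -> pd.Series:
    """Assign each score a green/yellow/red bin by empirical percentile rank.

    A score is green when the fraction of scores strictly below it is under
    the first cut, yellow under the second, red otherwise; with all-distinct
    scores and the default cuts this yields an exact 50/40/10 split.
    """
    s = pd.Series(scores).astype(float)
    if len(s) == 0:
        raise ValueError("no scores to bin")
    p1, p2 = cut_percentiles
    if not 0.0 < p1 < p2 < 1.0:
        raise ValueError("cut percentiles must satisfy 0 < p1 < p2 < 1")
    if s.nunique() == 1:
        warnings.warn("all scores identical; every visit assigned to the green bin")
    order = np.sort(s.to_numpy())
    frac_below = np.searchsorted(order, s.to_numpy(), side="left") / len(s)
    bins = np.where(frac_below < p1, "green", np.where(frac_below < p2, "yellow", "red"))
    return pd.Series(pd.Categorical(bins, categories=list(BIN_LABELS)), index=s.index)


def doubling_objective(scores, iit_next_labels, cut_percentiles) -> float:
    """Squared log-ratio departure from rate doubling across adjacent bins.

    Zero when the yellow bin's IIT rate is exactly twice green's and red's is
    exactly twice yellow's; infinite when a bin has no events.
    """
    bins = assign_bins(scores, cut_percentiles)
    y = pd.Series(iit_next_labels, index=bins.index).astype(bool)
    rates = []
    for b in BIN_LABELS:
        mask = bins == b
        if not mask.any() or not y[mask].any():
            return float("inf")
        rates.append(float(y[mask].mean()))
    log2 = np.log(2.0)
    return float(
        (np.log(rates[1] / rates[0]) - log2) ** 2
        + (np.log(rates[2] / rates[1]) - log2) ** 2
    )


def _binomial_segment_ll(e: float, m: float) -> float:
    if e <= 0 or e >= m:
        return 0.0
    r = e / m
    return e * math.log(r) + (m - e) * math.log(1.0 - r)


def calibrate_doubling_cutoffs(
    scores,
    iit_next_labels,
    p1_grid=None,
    p2_step: float = 0.01,
    p2_max: float = 0.98,
    min_gap: float = 0.05,
    slack: float = 0.05,
) -> tuple[float, float]:
    """Grid-search percentile cuts so each bin's IIT rate doubles the one below.

    The doubling objective alone has a flat near-minimal plateau: many cut
    pairs mix bin contents into approximately doubling rates, so its plain
    argmin wanders under sampling noise. The search therefore keeps every
    candidate whose objective is within ``slack`` of the minimum (log-ratio
    deviations of that order are indistinguishable at typical bin event
    counts) and, among those approximately-doubling candidates, returns the
    pair with the highest binomial log-likelihood of the implied three-
    plateau rate model — the cuts best supported by the data's own rate
    structure. When the risk curve really has three rate regimes this
    coincides with the regime boundaries; otherwise it degrades gracefully
    to the plain minimizer.

    Candidates with an event-free bin are skipped; if every candidate is
    skipped a ValueError is raised. Deterministic: ties resolve to the first
    candidate in grid order.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(iit_next_labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n = len(s)
    if n == 0:
        raise ValueError("no scored visits")
    if p1_grid is None:
        p1_grid = np.round(np.arange(0.20, 0.80 + 1e-9, 0.01), 2)

    order = np.argsort(s, kind="stable")
    # prefix counts over the sorted-by-score sequence
    events = np.concatenate([[0], np.cumsum(y[order])])
    log2 = np.log(2.0)
    sorted_s = s[order]
    cands: list[tuple[float, float, float, float]] = []
    for p1 in p1_grid:
        for p2 in np.round(np.arange(p1 + min_gap, p2_max + 1e-9, p2_step), 2):
            # bin boundary = count of scores whose strict-below rank is < p;
            # a tie block straddling the cut belongs wholly to the lower bin
            c1 = _tie_extend(sorted_s, int(np.ceil(n * p1 - 1e-9)))
            c2 = _tie_extend(sorted_s, int(np.ceil(n * p2 - 1e-9)))
            if not 0 < c1 < c2 < n:
                continue
            e_g, e_y, e_r = events[c1], events[c2] - events[c1], events[n] - events[c2]
            n_g, n_y, n_r = c1, c2 - c1, n - c2
            if min(e_g, e_y, e_r) == 0:
                continue
            r_g, r_y, r_r = e_g / n_g, e_y / n_y, e_r / n_r
            obj = (np.log(r_y / r_g) - log2) ** 2 + (np.log(r_r / r_y) - log2) ** 2
            ll = (
                _binomial_segment_ll(e_g, n_g)
                + _binomial_segment_ll(e_y, n_y)
                + _binomial_segment_ll(e_r, n_r)
            )
            cands.append((float(obj), float(ll), float(p1), float(p2)))
    if not cands:
        raise ValueError("no candidate cutpoints yield events in every bin")
    obj_min = min(c[0] for c in cands)
    near = [c for c in cands if c[0] <= obj_min + slack]
    best = max(near, key=lambda c: (c[1], -c[0]))
    return best[2], best[3]


def _tie_extend(sorted_s: np.ndarray, c: int) -> int:
    """Extend a cut index past any straddling tie block (ties stay lower-risk)."""
    if 0 < c < len(sorted_s) and sorted_s[c] == sorted_s[c - 1]:
        c = int(np.searchsorted(sorted_s, sorted_s[c - 1], side="right"))
    return c


def triage_table(
    bins: pd.Series,
    labeled: pd.DataFrame,
    by_stratum: bool = True,
) -> pd.DataFrame:
    """Counts, IIT rates and RR vs green per bin (optionally per ART stratum).

    ``bins`` must align by index with ``labeled`` rows carrying
    ``iit_next_visit``; visits without a next-visit outcome are excluded.
    Rows where the green reference is empty of visits or events carry NaN RR.
    """
    df = labeled.loc[bins.index].copy()
    df["bin"] = bins
    df = df.loc[df["iit_next_visit"].notna()]
    df["iit_next_visit"] = df["iit_next_visit"].astype(bool)

    strata: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if by_stratum and "time_on_art_stratum" in df.columns:
        strata.append(
            ("first_visit_after_initiation", df.loc[df["first_visit_after_initiation"]])
        )
        for s in ("months_0_6", "months_7_12", "months_gt_12"):
            block = df.loc[df["time_on_art_stratum"] == s]
            if len(block):
                strata.append((s, block))

    rows = []
    for stratum, block in strata:
        counts = {
            b: (
                int((block["bin"] == b).sum()),
                int(block.loc[block["bin"] == b, "iit_next_visit"].sum()),
            )
            for b in BIN_LABELS
        }
        n_ref, e_ref = counts["green"]
        for b in BIN_LABELS:
            n_b, e_b = counts[b]
            row = {
                "stratum": stratum,
                "bin": b,
                "n_visits": n_b,
                "n_iit_next": e_b,
                "iit_rate": e_b / n_b if n_b else float("nan"),
                "rr_vs_green": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "reference": b == "green",
            }
            if b != "green" and n_b and n_ref and e_ref:
                res = crude_rr(TwoByTwo(e_b, n_b, e_ref, n_ref))
                row.update(rr_vs_green=res.rr, ci_low=res.ci_low, ci_high=res.ci_high)
            rows.append(row)
    return pd.DataFrame(rows)
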