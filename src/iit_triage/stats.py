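"""Crude relative risk estimation and frequency tables.

All results tables in this package compare the proportion of visits followed
by an interruption in treatment (IIT) between an exposed group (a risk bin or
archetype) and a reference group. The effect measure is the crude relative
risk (RR) with a 95% confidence interval computed by the Katz log method:

    RR = (a / n1) / (c / n0)
    CI = exp( ln RR  +/-  z * sqrt(1/a - 1/n1 + 1/c - 1/n0) )

where ``a``/``n1`` are events/total in the exposed group and ``c``/``n0`` in
the reference group. No continuity correction is applied: a reference group
with zero events is an error, and an exposed group with zero events yields
RR = 0 with an undefined (NaN) interval.

Estimates are kept at full precision; rounding (half-up, two decimals) happens
only when rendering tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats as _sps

__all__ = ["TwoByTwo", "RRResult", "crude_rr", "proportion_table", "round_half_up"]


@dataclass(frozen=True)
class TwoByTwo:
    """Event counts for an exposed vs reference comparison.

    Attributes
    ----------
    exposed_events, exposed_total : int
        Events ``a`` and group size ``n1`` in the exposed group.
    reference_events, reference_total : int
        Events ``c`` and group size ``n0`` in the reference group.
    """

    exposed_events: int
    exposed_total: int
    reference_events: int
    reference_total: int

    def __post_init__(self) -> None:
        a, n1, c, n0 = (
            self.exposed_events,
            self.exposed_total,
            self.reference_events,
            self.reference_total,
        )
        if n1 <= 0 or n0 <= 0:
            raise ValueError("group totals must be positive")
        if not (0 <= a <= n1):
            raise ValueError(f"exposed events {a} outside [0, {n1}]")
        if not (0 <= c <= n0):
            raise ValueError(f"reference events {c} outside [0, {n0}]")

    def swapped(self) -> "TwoByTwo":
        """Exchange the exposed and reference groups."""
        return TwoByTwo(
            self.reference_events,
            self.reference_total,
            self.exposed_events,
            self.exposed_total,
        )


@dataclass(frozen=True)
class RRResult:
    """A relative risk point estimate with its confidence interval."""

    rr: float
    ci_low: float
    ci_high: float
    z: float

    def format(self, digits: int = 2, dash: str = "–") -> str:
        """Render as e.g. ``"2.17 (2.14–2.19)"`` with half-up rounding."""
        if math.isnan(self.ci_low):
            return f"{round_half_up(self.rr, digits)} (CI undefined)"
        return (
            f"{round_half_up(self.rr, digits)} "
            f"({round_half_up(self.ci_low, digits)}{dash}{round_half_up(self.ci_high, digits)})"
        )


def round_half_up(x: float, digits: int = 2) -> str:
    """Round half-up to ``digits`` decimals, returned as a string."""
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def crude_rr(t: TwoByTwo, confidence: float = 0.95) -> RRResult:
    """Crude relative risk with a Katz log-method confidence interval.

    Parameters
    ----------
    t : TwoByTwo
        The exposed/reference event counts.
    confidence : float
        Two-sided confidence level (default 0.95, z = 1.96).

    Raises
    ------
    ValueError
        If the reference group has zero events, making the RR undefined.
    """
    a, n1 = t.exposed_events, t.exposed_total
    c, n0 = t.reference_events, t.reference_total
    if c == 0:
        raise ValueError("reference group has zero events; RR undefined")
    z = float(_sps.norm.ppf(0.5 + confidence / 2.0))
    rr = (a / n1) / (c / n0)
    if a == 0:
        return RRResult(rr=0.0, ci_low=float("nan"), ci_high=float("nan"), z=z)
    se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    log_rr = math.log(rr)
    return RRResult(
        rr=rr,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        z=z,
    )


def proportion_table(groups: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Frequencies and proportions for named (events, total) count pairs.

    Returns a DataFrame indexed by group name with columns ``n``, ``events``
    and ``percent`` (full precision; NaN for a zero denominator).
    """
    rows = {}
    for name, (events, total) in groups.items():
        if total < 0 or events < 0 or (total > 0 and events > total):
            raise ValueError(f"invalid counts for group {name!r}: {events}/{total}")
        pct = float("nan") if total == 0 else 100.0 * events / total
        rows[name] = {"n": total, "events": events, "percent": pct}
    return pd.DataFrame.from_dict(rows, orient="index")
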