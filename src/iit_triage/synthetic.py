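"""Synthetic EMR/survey cohort generator.

Emulates longitudinal HIV clinic visit records with the statistical structure
the triaging analysis assumes: clients carry demographic and survey covariates
linked to a latent disengagement propensity, scheduled visits are attended
with configurable lateness, a visit drawn "more than 28 days late" may be
attended late or never, and a missed visit is followed by a re-engagement
visit with configurable probability (otherwise the client drops out of the
observed record).

The generator is marginally calibrated: a global intercept is solved (on a
fixed internal population sample, independent of ``n_clients``) so that with
the configured covariate effects at zero the population-level probability of a
visit being more than 28 days late equals ``base_iit_rate``.  Covariate
effects and archetype multipliers act on the log-odds of that event, so
switching them on raises risk in the carrier subgroup above the base rate.

Randomness fans out from a single integer seed into independent per-client
substreams, so enlarging ``n_clients`` reproduces the smaller cohort as a
prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import CLIENT_SCHEMA, VISIT_SCHEMA, canonicalize_clients, canonicalize_visits

__all__ = ["GeneratorConfig", "generate_cohort", "COVARIATE_PREDICATES"]

_DAYS_PER_MONTH = 30.4375

# named covariate -> indicator on a generated client; covariate_effects maps
# these names to additive log-odds shifts of the per-visit disengagement event
COVARIATE_PREDICATES = {
    "male": lambda c: c["sex"] == "M",
    "age_lt_25": lambda c: c["age_at_start"] < 25,
    "lives_alone": lambda c: c["household_size_others"] == 0,
    "unemployed": lambda c: c["employment"] == "unemployed",
    "undisclosed": lambda c: not c["disclosed_status"],
    "multi_facility": lambda c: c["multi_facility"],
    "long_travel": lambda c: c["travel_time_min"] > 30,
    "no_prior_test": lambda c: not c["prior_hiv_test_history"],
    "not_prepared": lambda c: not c["prepared_to_start_today"],
    "low_cd4": lambda c: c["cd4_screening"] is not None and c["cd4_screening"] < 200,
}

# dynamic visit-history states that archetype_multipliers may act on
_DYNAMIC_STATES = ("returning_after_disengagement", "late_twice")


def _default_effects() -> dict[str, float]:
    # moderate, realistic covariate signal: young age and thin social support
    # carry the largest risk, consistent with observed archetype risk ratios
    return {
        "male": 0.20,
        "age_lt_25": 0.50,
        "lives_alone": 0.35,
        "unemployed": 0.15,
        "undisclosed": 0.20,
        "multi_facility": 0.25,
        "long_travel": 0.25,
        "no_prior_test": 0.15,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Attributes
    ----------
    n_clients : int
        Number of clients to simulate.
    max_followup : int
        Maximum follow-up in months after ART start (default 14, a short
        post-initiation cohort).
    base_iit_rate : float
        Target marginal probability that a scheduled visit is missed by more
        than 28 days (the interruption-in-treatment event), default 0.12.
    visit_interval_early, visit_interval_late : int
        Scheduling gap in days: monthly (28 d) for the first
        ``n_monthly_visits`` visits, then two-monthly (56 d).
    covariate_effects : dict
        Named covariate -> log-odds shift on the disengagement event; names
        must be keys of ``COVARIATE_PREDICATES``.
    lateness_mixture : tuple of 4 floats
        Population probabilities for attendance delay categories
        {on time or early, 1-3 d late, 4-28 d late, >28 d late}; the first
        three set the conditional split among retained visits, the fourth is
        the nominal mass of the >28 d event (superseded per client by the
        calibrated propensity; with null effects they coincide when equal to
        ``base_iit_rate``).
    archetype_multipliers : dict
        Risk multiplier (on the odds scale) applied when a visit is in a
        dynamic history state: ``returning_after_disengagement`` (some prior
        visit >28 d late) or ``late_twice`` (previous two visits late).
    p_reengage : float
        Probability that a never-attended visit is followed by a
        re-engagement visit rather than drop-out.
    p_attend_late_given_gt28 : float
        Probability that a ">28 d late" visit is eventually attended
        (29-84 d late) rather than never attended.
    client_noise_sd : float
        SD of the client-level normal noise on the log-odds scale; creates
        the persistent between-client heterogeneity that visit-history
        features can learn.
    lab_present_prob : float
        Probability a viral-load result is captured at an attended visit.
    seed : int
        Master seed; all draws derive from it.
    """

    n_clients: int = 1000
    max_followup: int = 14
    base_iit_rate: float = 0.12
    visit_interval_early: int = 28
    visit_interval_late: int = 56
    n_monthly_visits: int = 3
    covariate_effects: dict[str, float] = field(default_factory=_default_effects)
    lateness_mixture: tuple[float, float, float, float] = (0.55, 0.18, 0.15, 0.12)
    archetype_multipliers: dict[str, float] = field(default_factory=dict)
    p_reengage: float = 0.7
    p_attend_late_given_gt28: float = 0.5
    client_noise_sd: float = 0.6
    lab_present_prob: float = 0.7
    p_female: float = 0.68
    cohort_start: str = "2017-01-01"
    enrollment_months: int = 24
    seed: int = 0

    def validate(self) -> None:
        if self.n_clients < 0:
            raise ValueError("n_clients must be >= 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        if not 0.0 <= self.base_iit_rate <= 1.0:
            raise ValueError("base_iit_rate must be a probability")
        mix = np.asarray(self.lateness_mixture, dtype=float)
        if mix.shape != (4,) or (mix < 0).any() or (mix > 1).any():
            raise ValueError("lateness_mixture must be 4 probabilities")
        if not math.isclose(float(mix.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"lateness_mixture sums to {mix.sum():.6f}, not 1")
        for name in self.covariate_effects:
            if name not in COVARIATE_PREDICATES:
                raise ValueError(f"unknown covariate effect {name!r}")
        for name in self.archetype_multipliers:
            if name not in _DYNAMIC_STATES:
                raise ValueError(f"unknown archetype multiplier {name!r}")
        for p in (self.p_reengage, self.p_attend_late_given_gt28, self.p_female,
                  self.lab_present_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _client_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, i)))


def _draw_client(rng: np.random.Generator, cfg: GeneratorConfig, i: int) -> dict:
    sex = "F" if rng.random() < cfg.p_female else "M"
    # age at ART start: lognormal, median ~35 y, truncated to [16, 85]
    age = float(np.clip(rng.lognormal(mean=math.log(35.0), sigma=0.33), 16.0, 85.0))
    employment = rng.choice(["employed", "unemployed", "unknown"], p=[0.45, 0.45, 0.10])
    payday = int(rng.integers(25, 32)) if employment == "employed" else None
    household = int(rng.poisson(1.8))
    travel = float(np.round(rng.gamma(2.0, 15.0), 1))
    start_offset = int(rng.integers(0, cfg.enrollment_months * 30))
    art_start = pd.Timestamp(cfg.cohort_start) + pd.Timedelta(days=start_offset)
    cd4 = float(np.round(rng.gamma(2.0, 175.0), 0)) if rng.random() < cfg.lab_present_prob else None
    prior_test = bool(rng.random() < 0.6)
    years_back = int(rng.geometric(0.6) - 1) if prior_test else 0
    return {
        "client_id": f"C{i:06d}",
        "sex": sex,
        "age_at_start": age,
        "birth_date": art_start - pd.Timedelta(days=round(age * 365.25)),
        "employment": str(employment),
        "payday_day_of_month": payday,
        "household_size_others": household,
        "travel_time_min": travel,
        "disclosed_status": bool(rng.random() < 0.7),
        "has_hiv_info": bool(rng.random() < 0.8),
        "planned_to_test_today": bool(rng.random() < 0.5),
        "prepared_to_start_today": bool(rng.random() < 0.8),
        "prior_hiv_test_history": prior_test,
        "year_first_tested_positive": int(art_start.year - years_back),
        "cd4_screening": cd4,
        "phone_number_on_file": bool(rng.random() < 0.85),
        "multi_facility": bool(rng.random() < 0.10),
        "art_start_date": art_start,
    }


def _linear_predictor(client: dict, cfg: GeneratorConfig, noise: float) -> float:
    eta = noise
    for name, coef in cfg.covariate_effects.items():
        if COVARIATE_PREDICATES[name](client):
            eta += coef
    return eta


def _planned_slots(cfg: GeneratorConfig) -> tuple[int, float]:
    """Visit count and span (days) for a perfectly punctual client."""
    horizon = cfg.max_followup * _DAYS_PER_MONTH
    days, k, span = 0.0, 0, 0.0
    while True:
        gap = cfg.visit_interval_early if k < cfg.n_monthly_visits else cfg.visit_interval_late
        days += gap
        if days > horizon:
            return k, span
        k += 1
        span = days


def _calibrate_intercept(cfg: GeneratorConfig, n_pop: int = 8192) -> float:
    """Solve the global intercept so the marginal >28 d rate hits base_iit_rate.

    Uses a fixed internal population sample (its own substream, independent of
    ``n_clients``) and weights each sampled client by their expected number of
    realized visits, since clients who drop out early contribute fewer visits.
    """
    if cfg.base_iit_rate <= 0.0:
        return -math.inf
    if cfg.base_iit_rate >= 1.0:
        return math.inf
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    etas = np.empty(n_pop)
    for j in range(n_pop):
        client = _draw_client(rng, cfg, j)
        noise = rng.normal(0.0, cfg.client_noise_sd)
        etas[j] = _linear_predictor(client, cfg, noise)
    k_max, span = _planned_slots(cfg)
    k_max = max(k_max, 1)
    horizon = cfg.max_followup * _DAYS_PER_MONTH
    gbar = max(span / k_max, 1.0)
    drop = (1.0 - cfg.p_attend_late_given_gt28) * (1.0 - cfg.p_reengage)
    mix = np.asarray(cfg.lateness_mixture[:3], dtype=float)
    mix = mix / mix.sum() if mix.sum() > 0 else np.array([1.0, 0.0, 0.0])
    # mean attendance delay per category: early/on-time, 1-3 d, 4-28 d, 29-84 d
    mean_delay_attended = float(mix @ np.array([-1.5, 2.0, 16.0]))
    mean_delay_late = (29 + 84) / 2.0

    def gap(alpha: float) -> float:
        p = expit(alpha + etas)
        # the schedule anchors on attended dates, so late-prone clients fit
        # fewer visits into follow-up; fold the mean shift into the horizon
        shift = (1.0 - p) * mean_delay_attended + p * cfg.p_attend_late_given_gt28 * mean_delay_late
        k_eff = np.minimum(float(k_max), horizon / (gbar + np.maximum(shift, 0.0)))
        q = np.clip(p * drop, 1e-12, 1.0)
        w = (1.0 - (1.0 - q) ** k_eff) / q  # expected realized visits
        return float(np.average(p, weights=w)) - cfg.base_iit_rate

    return float(brentq(gap, -20.0, 20.0, xtol=1e-10))


def _empty_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    clients = canonicalize_clients(pd.DataFrame({c: [] for c in CLIENT_SCHEMA}))
    visits = canonicalize_visits(pd.DataFrame({c: [] for c in VISIT_SCHEMA}))
    return clients, visits


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns canonical ``(clients, visits)`` DataFrames.

    Deterministic given the config (including its seed): identical configs
    yield byte-identical CSV output through :func:`iit_triage.io.write_cohort`.
    """
    config.validate()
    if config.n_clients == 0:
        return _empty_cohort()

    alpha = _calibrate_intercept(config)
    mix_attended = np.asarray(config.lateness_mixture[:3], dtype=float)
    if mix_attended.sum() <= 0:
        mix_attended = np.array([1.0, 0.0, 0.0])
    mix_attended = mix_attended / mix_attended.sum()
    horizon_days = config.max_followup * _DAYS_PER_MONTH
    log_mult = {k: math.log(v) for k, v in config.archetype_multipliers.items() if v > 0}

    client_rows: list[dict] = []
    visit_rows: list[dict] = []
    for i in range(config.n_clients):
        rng = _client_rng(config.seed, i)
        client = _draw_client(rng, config, i)
        noise = rng.normal(0.0, config.client_noise_sd)
        eta = _linear_predictor(client, config, noise)
        client_rows.append({k: v for k, v in client.items() if k != "age_at_start"})

        regimen = "TLD" if rng.random() < 0.9 else "TEE"
        anchor = client["art_start_date"]
        prior_gt28 = False
        recent_late: list[bool] = []
        k = 0
        while True:
            gap = (config.visit_interval_early if k < config.n_monthly_visits
                   else config.visit_interval_late)
            scheduled = anchor + pd.Timedelta(days=gap)
            if (scheduled - client["art_start_date"]).days > horizon_days:
                break
            k += 1

            eta_visit = (-math.inf if alpha == -math.inf else alpha + eta)
            if prior_gt28 and "returning_after_disengagement" in log_mult:
                eta_visit += log_mult["returning_after_disengagement"]
            if len(recent_late) >= 2 and all(recent_late[-2:]) and "late_twice" in log_mult:
                eta_visit += log_mult["late_twice"]
            p28 = expit(eta_visit) if math.isfinite(eta_visit) else (
                0.0 if eta_visit < 0 else 1.0)

            if rng.random() < p28:  # >28 d late: attended very late or never
                if rng.random() < config.p_attend_late_given_gt28:
                    delay = int(rng.integers(29, 85))
                else:
                    delay = None
            else:
                cat = rng.choice(3, p=mix_attended)
                if cat == 0:
                    delay = int(rng.integers(-3, 1))
                elif cat == 1:
                    delay = int(rng.integers(1, 4))
                else:
                    delay = int(rng.integers(4, 29))
            attended = None if delay is None else scheduled + pd.Timedelta(days=delay)

            if attended is not None and rng.random() < 0.03:
                regimen = "TEE" if regimen == "TLD" else "TLD"
            vl_value = vl_date = None
            if attended is not None and rng.random() < config.lab_present_prob:
                if rng.random() < 0.75:
                    vl_value = float(np.round(10 ** rng.uniform(1.0, 1.69), 0))
                else:
                    vl_value = float(np.round(10 ** rng.uniform(1.7, 5.5), 0))
                vl_date = attended
            visit_rows.append({
                "client_id": client["client_id"],
                "facility_id": "F001",
                "scheduled_date": scheduled,
                "attended_date": attended,
                "regimen_code": regimen,
                "vl_value": vl_value,
                "vl_date": vl_date,
                "tb_symptom_count": int(rng.binomial(4, 0.05)),
            })

            late = delay is None or delay > 0
            gt28 = delay is None or delay > 28
            recent_late.append(late)
            prior_gt28 = prior_gt28 or gt28
            if attended is None:
                if rng.random() >= config.p_reengage:
                    break  # drop-out: no further visits observed
                anchor = scheduled
            else:
                anchor = attended

    clients = canonicalize_clients(pd.DataFrame(client_rows, columns=list(CLIENT_SCHEMA)))
    visits = canonicalize_visits(pd.DataFrame(visit_rows, columns=list(VISIT_SCHEMA)))
    return clients, visits
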