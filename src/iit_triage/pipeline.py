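"""End-to-end pipeline: simulate/ingest -> label -> featurize -> train ->
score -> triage -> archetypes, from a single config.

Every stage draws its randomness from a named substream of one master seed,
so e.g. changing the model seed leaves the simulated cohort untouched. All
artifacts are plain CSV/JSON; the run log records the config hash, the seed
and every operative convention (boundaries, tie rules, reference groups) so a
run can be audited and reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import archetypes as arch
from . import triage as thr
from .features import build_features, restrict_to_emr_features
from .io import read_cohort, write_cohort
from .labeling import add_time_on_art, label_visits, pair_next_visit
from .model import (
    ModelConfig,
    evaluate,
    rebalance,
    score_visits,
    split_train_test,
    train_classifier,
)
from .stats import round_half_up
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_triage_table", "render_archetype_table"]

_STAGES = {"simulate": 0, "model": 1, "rebalance": 2}

ARCHETYPE_REFERENCES = {
    "demographic": "adult_female",
    "behavioral": "prompt_and_loyal",
    "socio_behavioral": "super_green",
}


def stage_seed(seed: int, stage: str) -> int:
    """A stable per-stage substream seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(100, _STAGES[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the CLI ``run-all`` command."""

    seed: int = 0
    input_dir: str | None = None  # read an existing cohort instead of simulating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    censor_date: str | None = None  # default: the last scheduled date in the data
    model: ModelConfig = field(default_factory=ModelConfig)
    emr_only: bool = False
    cut_percentiles: tuple[float, float] = (0.50, 0.90)
    calibrate_doubling: bool = False
    archetype_min_size: int = 50
    demographics_restrict_months: int | None = 6
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        gen.lateness_mixture = tuple(gen.lateness_mixture)
        model = ModelConfig(**raw.pop("model", {}))
        cfg = cls(generator=gen, model=model, **raw)
        cfg.cut_percentiles = tuple(cfg.cut_percentiles)
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the output location is not part of the analysis
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns a dict with the in-memory results (labeled frame, features,
    metrics, tables) for programmatic use.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- simulate or ingest -------------------------------------------------
    if config.input_dir is not None:
        clients, visits = read_cohort(config.input_dir)
    else:
        gen = replace(config.generator, seed=stage_seed(config.seed, "simulate"))
        clients, visits = generate_cohort(gen)
        write_cohort(clients, visits, out_dir / "cohort")

    # --- label --------------------------------------------------------------
    censor = config.censor_date or visits["scheduled_date"].max()
    labeled = add_time_on_art(pair_next_visit(label_visits(visits, censor)), clients)
    labeled.to_csv(out_dir / "labeled.csv", index=False)

    # --- featurize ----------------------------------------------------------
    features = build_features(labeled, clients)
    if config.emr_only:
        features_model = restrict_to_emr_features(features)
    else:
        features_model = features
    features.to_csv(out_dir / "features.csv", index=False)

    # --- train & evaluate ---------------------------------------------------
    model_cfg = replace(config.model, seed=stage_seed(config.seed, "model"))
    train, test = split_train_test(features_model, model_cfg)
    train_bal = rebalance(train, model_cfg.rebalance, seed=stage_seed(config.seed, "rebalance"))
    scorer = train_classifier(train_bal, model_cfg)
    metrics = {"model": evaluate(scorer, test).to_dict()}
    if config.emr_only:
        # report the survey-free restriction next to the full model
        full_train, full_test = split_train_test(features, model_cfg)
        full_bal = rebalance(full_train, model_cfg.rebalance,
                             seed=stage_seed(config.seed, "rebalance"))
        metrics = {
            "model": evaluate(train_classifier(full_bal, model_cfg), full_test).to_dict(),
            "emr_restricted": metrics["model"],
        }
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    # --- score & triage -----------------------------------------------------
    scored = features_model.loc[features_model["iit_next_visit"].notna()].copy()
    scored["risk_score"] = score_visits(scorer, scored)
    cuts = config.cut_percentiles
    if config.calibrate_doubling:
        cuts = thr.calibrate_doubling_cutoffs(
            scored["risk_score"], scored["iit_next_visit"].astype(bool)
        )
    bins = thr.assign_bins(scored["risk_score"], cuts)
    triage_tab = thr.triage_table(bins, labeled)
    triage_tab.to_csv(out_dir / "triage_table.csv", index=False)

    # --- archetypes ---------------------------------------------------------
    rules = arch.builtin_rules()
    assignments = arch.assign_archetypes(labeled, clients, rules)
    blocks = []
    for category, reference in ARCHETYPE_REFERENCES.items():
        names = [r.name for r in rules if r.category == category]
        block = arch.archetype_table(assignments, labeled, reference, archetypes=names)
        block.insert(0, "category", category)
        blocks.append(block)
    arch_tab = pd.concat(blocks, ignore_index=True)
    arch_tab.to_csv(out_dir / "archetype_table.csv", index=False)

    behavioral = [r.name for r in rules if r.category == "behavioral"]
    demographic = [r.name for r in rules if r.category == "demographic"]
    arch_demo = arch.archetype_table(
        assignments, labeled, "adult_female",
        archetypes=behavioral, cross_demographics=demographic,
        restrict_months=config.demographics_restrict_months,
    )
    arch_demo.to_csv(out_dir / "archetype_demographics.csv", index=False)

    run_log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "censor_date": str(pd.Timestamp(censor).date()),
        "conventions": {
            "iit_grace_days": 28,
            "boundary": "28 days late retained, 29 late is IIT; early attendance on time",
            "censor_window_months": 3,
            "cut_percentiles": list(cuts),
            "tie_rule": "ties at a cutpoint fall to the lower-risk bin",
            "late_threshold_days": 3,
            "adult_age": arch.ADULT_AGE,
            "archetype_references": ARCHETYPE_REFERENCES,
            "archetype_min_size": config.archetype_min_size,
            "demographics_restrict_months": config.demographics_restrict_months,
            "classification_threshold": 0.5,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))

    return {
        "clients": clients, "visits": visits, "labeled": labeled,
        "features": features, "scorer": scorer, "metrics": metrics,
        "scores": scored, "bins": bins, "cut_percentiles": cuts,
        "triage_table": triage_tab, "archetype_table": arch_tab,
        "archetype_demographics": arch_demo, "run_log": run_log,
    }


def _fmt_rr(rr: float, lo: float, hi: float, reference: bool) -> str:
    if reference:
        return "Ref"
    if pd.isna(rr):
        return "N/A"
    if pd.isna(lo):
        return round_half_up(rr, 2)
    return f"{round_half_up(rr, 2)} ({round_half_up(lo, 2)}–{round_half_up(hi, 2)})"


def render_triage_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable threshold-approach table (counts, percent, RR text)."""
    out = pd.DataFrame()
    out["Stratum"] = table["stratum"]
    out["Risk group"] = table["bin"].astype(str).str.upper()
    out["Visits"] = table["n_visits"]
    out["IIT at next visit (n, %)"] = [
        f"{e} ({round_half_up(100 * r, 0)}%)" if n else "N/A"
        for e, r, n in zip(table["n_iit_next"], table["iit_rate"].fillna(0),
                           table["n_visits"])
    ]
    out["RR (95% CI)"] = [
        _fmt_rr(rr, lo, hi, ref)
        for rr, lo, hi, ref in zip(table["rr_vs_green"], table["ci_low"],
                                   table["ci_high"], table["reference"])
    ]
    return out


def render_archetype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable archetype table."""
    out = pd.DataFrame()
    if "category" in table.columns:
        out["Category"] = table["category"]
    out["Archetype"] = table["archetype"]
    out["Visits"] = table["n_visits"]
    out["IIT (n, %)"] = [
        f"{e} ({round_half_up(100 * r, 0)}%)" if n else "N/A"
        for e, r, n in zip(table["n_iit_next"], table["iit_rate"].fillna(0),
                           table["n_visits"])
    ]
    out["RR (95% CI)"] = [
        _fmt_rr(rr, lo, hi, ref)
        for rr, lo, hi, ref in zip(table["rr_vs_reference"], table["ci_low"],
                                   table["ci_high"], table["reference"])
    ]
    return out
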