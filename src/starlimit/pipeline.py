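"""End-to-end orchestration: validate -> score -> fit -> compare -> test.

A run is driven by one structured config (YAML or dict) and one seed, and
every number in the resulting report is reproducible from those plus the
input files.  Stages execute in the order the analysis is reported:
score validation, learning-curve fitting and model comparison,
noninferiority of plateau and rate (overall and per starting-device
subgroup), crossover analysis, then workload.  Each stage logs its wall
time and writes its tables under the run directory; failures abort with the
stage named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import curve_menu, get_curve
from .inference import crossover_lmm, noninferiority_from_fit
from .nlme import compare_models, fit_nlme
from .scoring import (
    DEFAULT_CANDIDATES,
    build_features,
    composite_score,
    derive_expert_threshold,
    flag_outliers,
    select_score_model,
    subject_median_times,
    validation_subset,
)
from .synthetic_study import SimConfig, DeviceTruth, simulate_study
from .trial_data import read_trials, trials_to_frame, write_trials
from .workload import rm_anova_all, tlx_frame

__all__ = ["RunReport", "run_pipeline", "load_config", "scored_frame"]

logger = logging.getLogger("starlimit")

_VALID_KEYS = {
    "seed",
    "simulate",
    "inputs",
    "curve",
    "curves",
    "shared",
    "n_starts",
    "margin_frac",
    "alpha",
    "column_map",
}


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    parse: Dict[str, int]
    outliers: List[str]
    score_model_table: pd.DataFrame
    expert_threshold: dict
    curve_comparison: pd.DataFrame
    selected_curve: str
    fixed_effects: pd.DataFrame
    noninferiority: pd.DataFrame
    crossover: pd.DataFrame
    workload: pd.DataFrame
    notes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "parse": self.parse,
            "outliers": self.outliers,
            "score_model_table": self.score_model_table.to_dict(orient="records"),
            "expert_threshold": self.expert_threshold,
            "curve_comparison": self.curve_comparison.to_dict(orient="records"),
            "selected_curve": self.selected_curve,
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
            "noninferiority": self.noninferiority.to_dict(orient="records"),
            "crossover": self.crossover.to_dict(orient="records"),
            "workload": self.workload.to_dict(orient="records"),
            "notes": self.notes,
        }
        return out


def load_config(source) -> dict:
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text()) or {}
    problems = []
    unknown = set(cfg) - _VALID_KEYS
    if unknown:
        problems.append(f"unknown config key(s): {sorted(unknown)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        problems.append("config must name either 'simulate' or 'inputs'")
    valid_names = sorted(s.name for s in curve_menu())
    for key in ("curve",):
        if key in cfg and cfg[key] not in valid_names:
            problems.append(f"unknown curve {cfg[key]!r}; valid names: {valid_names}")
    for name in cfg.get("curves", []) or []:
        if name not in valid_names:
            problems.append(f"unknown curve {name!r}; valid names: {valid_names}")
    if problems:
        raise ValueError("config invalid: " + "; ".join(problems))
    cfg.setdefault("seed", 0)
    cfg.setdefault("curve", "modified_weibull")
    cfg.setdefault("curves", valid_names)
    cfg.setdefault("shared", ["P0", "c"])
    cfg.setdefault("n_starts", 2)
    cfg.setdefault("margin_frac", 0.2)
    cfg.setdefault("alpha", 0.05)
    return cfg


def scored_frame(trials) -> pd.DataFrame:
    """Trial records -> DataFrame with the composite score attached."""
    frame = trials_to_frame(trials) if not isinstance(trials, pd.DataFrame) else trials.copy()
    frame["score"] = composite_score(
        frame["time_s"].to_numpy(), frame["edge"].to_numpy()
    )
    return frame


def _sim_config_from(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate") or {})
    sim.pop("preset", None)
    truth = sim.pop("truth", None)
    kwargs = {k: v for k, v in sim.items() if k in {f.name for f in dataclasses.fields(SimConfig)}}
    kwargs["seed"] = seed
    config = SimConfig(**kwargs)
    if truth:
        config.truth = {
            dev: DeviceTruth(**vals) for dev, vals in truth.items()
        }
    return config


def run_pipeline(config, out_dir="runs/latest") -> RunReport:
    """Execute the full analysis; returns the consolidated report."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    notes: List[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(summary=""):
            logger.info("stage=%s wall_s=%.2f %s", name, time.perf_counter() - t0, summary)

        return done

    try:
        # -- data ------------------------------------------------------------
        done = stage("data")
        if "simulate" in cfg:
            sim = simulate_study(_sim_config_from(cfg, seed))
            trials, tlx_records = sim.trials, sim.tlx
            write_trials(trials, out / "trials.csv")
            tlx_tbl = tlx_frame(tlx_records)
            tlx_tbl.to_csv(out / "tlx.csv", index=False)
            sim.truth.to_csv(out / "truth_ledger.csv", index=False)
            parse = {"n_rows": len(trials), "n_rejected": 0}
        else:
            trials, report = read_trials(
                cfg["inputs"]["trials"], dialect=cfg.get("column_map")
            )
            parse = {"n_rows": report.n_rows, "n_rejected": report.n_rejected}
            notes.extend(report.errors)
            tlx_tbl = pd.read_csv(cfg["inputs"]["tlx"]) if "tlx" in cfg["inputs"] else None
        frame = scored_frame(trials)
        done(f"n_trials={len(frame)}")

        # -- score validation --------------------------------------------------
        done = stage("score_validation")
        val = validation_subset(frame)
        med = subject_median_times(val)
        outliers = flag_outliers(med)
        val_kept = val[~val["subject_id"].isin(outliers)]
        features = build_features(val_kept)
        score_tbl = select_score_model(
            DEFAULT_CANDIDATES, features, val_kept["cohort"].to_numpy()
        )
        thr = derive_expert_threshold(
            val_kept.loc[val_kept["cohort"] == "novice", "score"],
            val_kept.loc[val_kept["cohort"] == "expert", "score"],
        )
        score_tbl.to_csv(out / "score_models.csv")
        done(f"threshold={thr.threshold:.1f}")

        # -- curve fitting and comparison -------------------------------------
        done = stage("curve_fitting")
        novices = frame[frame["cohort"] == "novice"]
        fits = {}
        for name in cfg["curves"]:
            fits[name] = fit_nlme(
                novices,
                name,
                shared=tuple(cfg["shared"]),
                n_starts=int(cfg["n_starts"]),
                seed=seed,
            )
        comparison = compare_models(list(fits.values()))
        comparison.to_csv(out / "curve_comparison.csv")
        selected = cfg["curve"] if cfg["curve"] in fits else comparison.iloc[0]["curve"]
        primary = fits[selected]
        primary.fixed.to_csv(out / "fixed_effects.csv", index=False)
        done(f"selected={selected} aic={primary.aic:.2f}")

        # -- noninferiority ----------------------------------------------------
        done = stage("noninferiority")
        ni_rows = []
        for coefficient in ("plateau", "rate"):
            res = noninferiority_from_fit(
                primary,
                coefficient=coefficient,
                margin_frac=float(cfg["margin_frac"]),
                alpha=float(cfg["alpha"]),
            )
            ni_rows.append({"analysis": "overall", **dataclasses.asdict(res)})
        for order_dev in primary.devices:
            started = (
                novices[novices["phase"] == 1]
                .groupby("subject_id")["device"]
                .first()
            )
            subjects = started[started == order_dev].index
            sub = novices[novices["subject_id"].isin(subjects)]
            if sub["subject_id"].nunique() >= 3:
                subgroup_fit = fit_nlme(
                    sub,
                    selected,
                    shared=tuple(cfg["shared"]),
                    n_starts=int(cfg["n_starts"]),
                    seed=seed,
                )
                res = noninferiority_from_fit(
                    subgroup_fit,
                    coefficient="plateau",
                    margin_frac=float(cfg["margin_frac"]),
                    alpha=float(cfg["alpha"]),
                )
                ni_rows.append(
                    {"analysis": f"started_{order_dev}", **dataclasses.asdict(res)}
                )
        ni_tbl = pd.DataFrame(ni_rows).drop(columns=["notes"])
        ni_tbl.to_csv(out / "noninferiority.csv", index=False)
        done()

        # -- crossover ---------------------------------------------------------
        done = stage("crossover")
        cross = crossover_lmm(novices)
        cross.to_csv(out / "crossover.csv", index=False)
        done()

        # -- workload ----------------------------------------------------------
        done = stage("workload")
        if tlx_tbl is not None:
            started = (
                novices[novices["phase"] == 1].groupby("subject_id")["device"].first()
            )
            tlx_tbl = tlx_tbl.merge(
                started.rename("group"), left_on="subject_id", right_index=True
            )
            workload_tbl = rm_anova_all(tlx_tbl)
            workload_tbl.to_csv(out / "workload.csv", index=False)
        else:
            workload_tbl = pd.DataFrame()
            notes.append("no TLX input; workload stage skipped")
        done()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    report = RunReport(
        config={k: v for k, v in cfg.items()},
        seed=seed,
        version=__version__,
        parse=parse,
        outliers=list(outliers),
        score_model_table=score_tbl.reset_index(),
        expert_threshold={
            "threshold": thr.threshold,
            "threshold_rounded": thr.threshold_rounded,
            "youden_j": thr.youden_j,
            "low_separability": thr.low_separability,
        },
        curve_comparison=comparison.reset_index(),
        selected_curve=str(selected),
        fixed_effects=primary.fixed,
        noninferiority=ni_tbl,
        crossover=cross,
        workload=workload_tbl,
        notes=notes,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
    return report
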