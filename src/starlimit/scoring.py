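"""Composite performance score and its validation analytics.

The composite score for one repetition is

    score = 90 - 0.3 * time_s + 0.5 * edge

which maps the rubric-feasible domain (time 0..300 s, edge 0..20) exactly
onto [0, 100]: faster completion and more accurate edges both raise the
score.  Perforations and the flesh score never enter the final composite;
they only appear inside candidate "accuracy" features when ranking score
models.

Validation mirrors how a bench-task score is credentialed: logistic
discrimination between absolute novices (first five attempts) and absolute
experts (final five attempts), AIC-ranked over a menu of feature sets,
within-cohort outlier screening on median completion time, and a
Youden-optimal expert threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScoreModelSpec",
    "DiscriminantFit",
    "ThresholdResult",
    "composite_score",
    "DEFAULT_CANDIDATES",
    "build_features",
    "validation_subset",
    "fit_discriminant",
    "select_score_model",
    "flag_outliers",
    "subject_median_times",
    "derive_expert_threshold",
]

FEATURE_NAMES = ("time_term", "edge", "accuracy", "clean_star", "perforations")


def composite_score(time_s, edge):
    """Composite performance score: ``90 - 0.3*time_s + 0.5*edge``.

    Accepts scalars or arrays; inputs must lie within the rubric bounds
    (time 0..300 s, edge 0..20), which guarantees a result in [0, 100].
    """
    time_s = np.asarray(time_s, dtype=float)
    edge = np.asarray(edge, dtype=float)
    if np.any(time_s < 0) or np.any(time_s > 300):
        raise ValueError("time_s out of bounds [0, 300] s")
    if np.any(edge < 0) or np.any(edge > 20):
        raise ValueError("edge out of bounds [0, 20]")
    out = 90.0 - 0.3 * time_s + 0.5 * edge
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScoreModelSpec:
    """A candidate feature set for novice/expert discrimination.

    The time term ``1 - time_s/300`` is always included — every candidate
    builds on completion speed.
    """

    name: str
    feature_set: Tuple[str, ...]

    def __post_init__(self):
        if "time_term" not in self.feature_set:
            raise ValueError("every score model includes 'time_term'")
        unknown = set(self.feature_set) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")


DEFAULT_CANDIDATES = [
    ScoreModelSpec("time", ("time_term",)),
    ScoreModelSpec("time+edge", ("time_term", "edge")),
    ScoreModelSpec("time+accuracy", ("time_term", "accuracy")),
    ScoreModelSpec("time+clean_star", ("time_term", "clean_star")),
    ScoreModelSpec("time+clean_star+edge", ("time_term", "clean_star", "edge")),
    ScoreModelSpec("time+edge+perforations", ("time_term", "edge", "perforations")),
]


@dataclass
class DiscriminantFit:
    model: ScoreModelSpec
    coefficients: np.ndarray  # intercept first
    loglik: float
    aic: float
    converged: bool


@dataclass
class ThresholdResult:
    threshold: float
    threshold_rounded: float
    youden_j: float
    low_separability: bool
    notes: List[str] = field(default_factory=list)


def build_features(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the candidate features from rubric items.

    ``accuracy`` is a monotone composite of the accuracy-related items,
    ``edge + flesh - perforations``, min-max rescaled to [0, 1] over the
    data at hand (logistic discrimination is invariant to the affine
    rescale).  ``clean_star`` is the flesh score.
    """
    out = pd.DataFrame(index=frame.index)
    out["time_term"] = 1.0 - frame["time_s"] / 300.0
    out["edge"] = frame["edge"].astype(float)
    raw_acc = (frame["edge"] + frame["flesh"] - frame["perforations"]).astype(float)
    span = raw_acc.max() - raw_acc.min()
    out["accuracy"] = (raw_acc - raw_acc.min()) / span if span > 0 else 0.0
    out["clean_star"] = frame["flesh"].astype(float)
    out["perforations"] = frame["perforations"].astype(float)
    return out


def validation_subset(frame: pd.DataFrame) -> pd.DataFrame:
    """Absolute-novice vs absolute-expert observations.

    Novices contribute their first five attempts (phase 1, trials 1-5);
    experts contribute their final five attempts (trials 16-20).
    """
    nov = frame[(frame["cohort"] == "novice") & (frame["phase"] == 1) & (frame["trial"] <= 5)]
    exp = frame[(frame["cohort"] == "expert") & (frame["trial"] >= 16)]
    return pd.concat([nov, exp], ignore_index=True)


def fit_discriminant(
    features: pd.DataFrame, labels: Sequence[str], model: Optional[ScoreModelSpec] = None
) -> DiscriminantFit:
    """Maximum-likelihood logistic discrimination of expert vs novice.

    Separation does not abort the fit: iterations are capped, the
    convergence flag is lowered, and the AIC of the capped fit is still
    reported.
    """
    labels = np.asarray(labels)
    classes = set(labels)
    if classes - {"novice", "expert"}:
        raise ValueError(f"labels must be 'novice'/'expert', got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both cohorts must be present")
    y = (labels == "expert").astype(float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 observations per cohort")
    if model is not None:
        features = features[list(model.feature_set)]
    X = sm.add_constant(np.asarray(features, dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            llf = float(res.llf)
        except Exception:
            # singular design or total separation beyond the optimizer:
            # cap at the no-information fit so an AIC is still reported
            params = np.zeros(X.shape[1])
            p = y.mean()
            llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
            converged = False
    k = X.shape[1]
    aic = 2.0 * k - 2.0 * llf
    spec = model if model is not None else ScoreModelSpec(
        "custom", tuple(features.columns) if hasattr(features, "columns") else ("time_term",)
    )
    return DiscriminantFit(spec, params, llf, aic, converged)


def select_score_model(
    candidates: Sequence[ScoreModelSpec], features: pd.DataFrame, labels: Sequence[str]
) -> pd.DataFrame:
    """Rank candidate score models by AIC for novice/expert discrimination.

    Best (lowest AIC) first; ties broken by fewer features, then name.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    for spec in candidates:
        fit = fit_discriminant(features[list(spec.feature_set)], labels, model=spec)
        rows.append(
            {
                "name": spec.name,
                "n_features": len(spec.feature_set),
                "aic": fit.aic,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    tbl = pd.DataFrame(rows).sort_values(
        ["aic", "n_features", "name"], kind="mergesort"
    )
    tbl = tbl.reset_index(drop=True)
    tbl.index = tbl.index + 1
    tbl.index.name = "rank"
    return tbl


def subject_median_times(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-subject median completion time with cohort, for outlier screening."""
    g = frame.groupby("subject_id", sort=False)
    return pd.DataFrame(
        {
            "subject_id": [sid for sid, _ in g],
            "cohort": g["cohort"].first().to_numpy(),
            "median_time_s": g["time_s"].median().to_numpy(),
        }
    )


def flag_outliers(summary: pd.DataFrame) -> List[str]:
    """Subjects whose median time lies beyond 1.5*IQR fences within cohort.

    ``summary`` has columns subject_id, cohort, median_time_s (see
    :func:`subject_median_times`).  Requires >= 4 subjects per cohort.
    """
    flagged: List[str] = []
    for cohort, grp in summary.groupby("cohort"):
        if len(grp) < 4:
            raise ValueError(f"cohort {cohort!r} has fewer than 4 subjects")
        q1, q3 = np.percentile(grp["median_time_s"], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        bad = grp[(grp["median_time_s"] < lo) | (grp["median_time_s"] > hi)]
        flagged.extend(bad["subject_id"].tolist())
    return flagged


def derive_expert_threshold(
    novice_scores: Sequence[float], expert_scores: Sequence[float]
) -> ThresholdResult:
    """Youden-optimal expert/novice cutpoint on the composite score.

    Candidate cutpoints are midpoints between adjacent distinct observed
    scores; a score at or above the cut classifies as expert.  When several
    cutpoints tie on Youden's J, the midpoint of the tied interval is
    returned.  Complete distributional overlap yields a low-separability
    warning rather than a failure.
    """
    nov = np.asarray(novice_scores, dtype=float)
    exp = np.asarray(expert_scores, dtype=float)
    if nov.size == 0 or exp.size == 0:
        raise ValueError("both score groups must be non-empty")
    values = np.unique(np.concatenate([nov, exp]))
    if values.size == 1:
        return ThresholdResult(
            float(values[0]), float(5 * round(values[0] / 5)), 0.0, True,
            ["all scores identical; threshold is arbitrary"],
        )
    cuts = (values[:-1] + values[1:]) / 2.0
    j = np.array(
        [np.mean(exp >= c) + np.mean(nov < c) - 1.0 for c in cuts]
    )
    jmax = j.max()
    best = cuts[np.isclose(j, jmax)]
    threshold = float((best.min() + best.max()) / 2.0)
    low_sep = bool(jmax <= 1e-12)
    notes = ["distributions overlap completely; cutpoint is uninformative"] if low_sep else []
    return ThresholdResult(threshold, float(5 * round(threshold / 5)), float(jmax), low_sep, notes)
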