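"""Noninferiority testing, crossover analysis, and multiplicity adjustment.

The noninferiority question: is the new device's learning-curve coefficient
(plateau or rate) at most 20% worse than the reference device's?  With the
margin ``m = margin_frac * |est_ref|`` the one-tailed t statistic is

    t = (est_new - est_ref + m) / sqrt(se_ref**2 + se_new**2)

tested against the upper tail of Student's t at the coefficient degrees of
freedom; p < alpha declares noninferiority.  "Worse" means lower for both
coefficients — a lower plateau is poorer settled performance and a lower
rate is slower learning under the curve parameterization used here.

The crossover analysis asks whether the starting device mattered: a linear
mixed model (random intercept per subject) on the settled trials of each
phase with phase, device-order group, and their interaction as fixed
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NoninferiorityResult",
    "noninferiority_test",
    "noninferiority_from_fit",
    "crossover_lmm",
    "bh_adjust",
]


@dataclass
class NoninferiorityResult:
    coefficient: str
    est_ref: float
    est_new: float
    margin: float
    se_diff: float
    df: float
    t_stat: float
    p_one_tailed: float
    noninferior: bool
    alpha: float = 0.05
    notes: List[str] = field(default_factory=list)


def noninferiority_test(
    est_ref: float,
    se_ref: float,
    est_new: float,
    se_new: float,
    df: float,
    margin_frac: float = 0.2,
    coefficient: str = "plateau",
    alpha: float = 0.05,
) -> NoninferiorityResult:
    """One-tailed t test of the new device against the inferiority margin.

    The two coefficient estimates are treated as independent, so
    ``se_diff = sqrt(se_ref**2 + se_new**2)`` — the test is built from the
    reported (estimate, SE, df) outputs of separate device curves.  A zero
    ``margin_frac`` degenerates to a one-tailed superiority test and is
    flagged as such.
    """
    if se_ref <= 0 or se_new <= 0:
        raise ValueError("standard errors must be positive")
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    margin = margin_frac * abs(est_ref)
    se_diff = float(np.hypot(se_ref, se_new))
    t_stat = (est_new - est_ref + margin) / se_diff
    p = float(stats.t.sf(t_stat, df))
    notes = []
    if margin_frac == 0:
        notes.append("margin_frac = 0: this is a one-tailed superiority test")
    return NoninferiorityResult(
        coefficient=coefficient,
        est_ref=float(est_ref),
        est_new=float(est_new),
        margin=float(margin),
        se_diff=se_diff,
        df=float(df),
        t_stat=float(t_stat),
        p_one_tailed=p,
        noninferior=bool(p < alpha),
        alpha=alpha,
        notes=notes,
    )


def noninferiority_from_fit(
    fit,
    coefficient: str = "plateau",
    ref_device: str = "microscope",
    new_device: str = "exoscope",
    margin_frac: float = 0.2,
    alpha: float = 0.05,
) -> NoninferiorityResult:
    """Noninferiority test read off a fitted mixed-effects curve."""
    param = {"plateau": "A", "rate": "r"}[coefficient]
    est_ref, se_ref, df = fit.fixed_effect(param, ref_device)
    est_new, se_new, _ = fit.fixed_effect(param, new_device)
    return noninferiority_test(
        est_ref, se_ref, est_new, se_new, df,
        margin_frac=margin_frac, coefficient=coefficient, alpha=alpha,
    )


def crossover_lmm(
    frame: pd.DataFrame,
    last_k: int = 5,
    settled_phase2: bool = True,
    score_col: str = "score",
) -> pd.DataFrame:
    """Linear mixed model on the trials around the crossover.

    Takes the final ``last_k`` trials of phase 1 and, by default, the final
    ``last_k`` trials of phase 2 (settled performance in each phase; pass
    ``settled_phase2=False`` to use the first ``last_k`` trials after the
    switch instead).  Fixed effects: phase (post vs pre crossover), device
    order group, and their interaction; random intercept per subject;
    maximum likelihood.  Returns an effect table with Wald F statistics and
    containment degrees of freedom.
    """
    df_in = frame.rename(columns={score_col: "score"}).copy()
    tmax = int(df_in["trial"].max())
    pre = df_in[(df_in["phase"] == 1) & (df_in["trial"] > tmax - last_k)]
    if settled_phase2:
        post = df_in[(df_in["phase"] == 2) & (df_in["trial"] > tmax - last_k)]
    else:
        post = df_in[(df_in["phase"] == 2) & (df_in["trial"] <= last_k)]
    data = pd.concat([pre, post], ignore_index=True)

    has_both = data.groupby("subject_id")["phase"].nunique()
    incomplete = has_both[has_both < 2].index.tolist()
    if incomplete:
        warnings.warn(
            f"subjects missing a crossover phase excluded: {incomplete}",
            UserWarning,
            stacklevel=2,
        )
        data = data[~data["subject_id"].isin(incomplete)]
    if data.empty:
        raise ValueError("no subjects with both phases")

    # order group: which device the subject started on
    first_dev = (
        data[data["phase"] == 1].groupby("subject_id")["device"].first().rename("order_group")
    )
    data = data.merge(first_dev, on="subject_id")
    data["post"] = (data["phase"] == 2).astype(float)
    data["grp"] = (data["order_group"] == "microscope").astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ post * grp", data, groups=data["subject_id"]
        ).fit(reml=False)

    n_sub = data["subject_id"].nunique()
    n_obs = len(data)
    rows = []
    name_map = {"post": "phase", "grp": "order_group", "post:grp": "interaction"}
    for term, label in name_map.items():
        est = float(model.params[term])
        se = float(model.bse[term])
        f_stat = (est / se) ** 2 if se > 0 else np.inf
        # containment: between-subject terms against subjects, within against obs
        df_den = n_sub - 2 if label == "order_group" else n_obs - n_sub - 2
        df_den = max(df_den, 1)
        p = float(stats.f.sf(f_stat, 1, df_den))
        rows.append(
            {
                "effect": label,
                "estimate": est,
                "se": se,
                "F": float(f_stat),
                "df_num": 1,
                "df_den": df_den,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
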