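"""NASA Raw TLX workload scoring and analysis.

The Raw (unweighted) Task Load Index rates six domains — mental, physical,
and temporal demand, performance, effort, frustration — on a 20-point
scale; the total is their plain sum (range 6..120, or down to 0 if a rater
used 0).  Ratings of 0 are accepted at parse time but flagged, since "a
20-point scale" leaves the lower anchor ambiguous.

The device comparison is a mixed-design (repeated-measures two-way) ANOVA:
device is the within-subject factor, starting-device group the
between-subject factor.  Degenerate tables (zero residual variance) are
resolved to F = 0 when the effect sum of squares is zero and F = inf when
it is not, rather than left as 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .inference import bh_adjust

__all__ = [
    "TLX_DOMAINS",
    "TLXRecord",
    "tlx_total",
    "tlx_frame",
    "rm_anova",
    "rm_anova_all",
    "likert_summary",
]

TLX_DOMAINS = ("mental", "physical", "temporal", "performance", "effort", "frustration")


@dataclass
class TLXRecord:
    """Six workload-domain ratings for one subject on one device."""

    subject_id: str
    device: str
    mental: int
    physical: int
    temporal: int
    performance: int
    effort: int
    frustration: int
    notes: List[str] = field(default_factory=list)

    def __post_init__(self):
        for d in TLX_DOMAINS:
            v = getattr(self, d)
            if not 0 <= v <= 20:
                raise ValueError(f"{d} rating {v} outside the 20-point scale (0..20)")
            if v == 0:
                self.notes.append(f"{d} rated 0 on a 20-point scale")

    @property
    def total(self) -> int:
        return int(sum(getattr(self, d) for d in TLX_DOMAINS))


def tlx_total(record) -> int:
    """Total workload: the plain sum of the six domain ratings."""
    if isinstance(record, TLXRecord):
        return record.total
    vals = [int(record[d]) for d in TLX_DOMAINS]
    for d, v in zip(TLX_DOMAINS, vals):
        if not 0 <= v <= 20:
            raise ValueError(f"{d} rating {v} outside the 20-point scale (0..20)")
    return int(sum(vals))


def tlx_frame(records: Sequence[TLXRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "device": r.device}
        row.update({d: getattr(r, d) for d in TLX_DOMAINS})
        row["total"] = r.total
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "device", *TLX_DOMAINS, "total"])


def rm_anova(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Mixed-design ANOVA of one TLX response: device within, group between.

    ``table`` is long format with columns subject_id, device, group and the
    response.  Subjects lacking both device rows are excluded with a
    warning.  Returns effects ``device``, ``group``, ``interaction`` with
    sums of squares, F and p.
    """
    data = table.copy()
    counts = data.groupby("subject_id")["device"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        warnings.warn(
            f"subjects without both device rows excluded: {incomplete}",
            UserWarning,
            stacklevel=2,
        )
        data = data[~data["subject_id"].isin(incomplete)]
    if data.empty:
        raise ValueError("no complete subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = pg.mixed_anova(
                data=data,
                dv=response,
                within="device",
                between="group",
                subject="subject_id",
            )
    name_map = {"group": "group", "device": "device", "Interaction": "interaction"}
    rows = []
    for _, r in aov.iterrows():
        label = name_map.get(str(r["Source"]), str(r["Source"]))
        ss = float(r["SS"])
        # degenerate (zero-variance) tables come back without F/p columns
        f_stat = float(r["F"]) if "F" in r.index else np.nan
        p_key = "p_unc" if "p_unc" in r.index else "p-unc"
        p = float(r[p_key]) if p_key in r.index else np.nan
        if not np.isfinite(f_stat):
            # zero residual variance: resolve the 0/0 and x/0 cases
            if np.isclose(ss, 0.0):
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = np.inf, 0.0
        rows.append(
            {
                "effect": label,
                "SS": ss,
                "df_num": int(r["DF1"]),
                "df_den": int(r["DF2"]),
                "F": f_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def rm_anova_all(
    table: pd.DataFrame, responses: Sequence[str] = (*TLX_DOMAINS, "total")
) -> pd.DataFrame:
    """ANOVA across all TLX responses with BH adjustment within each effect."""
    parts = []
    for resp in responses:
        tbl = rm_anova(table, resp)
        tbl.insert(0, "response", resp)
        parts.append(tbl)
    out = pd.concat(parts, ignore_index=True)
    out["p_adj"] = np.nan
    for effect in out["effect"].unique():
        sel = out["effect"] == effect
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out


def likert_summary(
    responses: pd.DataFrame,
    device_low: str = "microscope",
    device_high: str = "exoscope",
) -> pd.DataFrame:
    """Per-question preference counts on a 5-level Likert scale.

    Ratings 1-2 mean (strongly) prefer ``device_low``, 3 neutral, 4-5
    (strongly) prefer ``device_high``.  Exact fractions are reported next
    to percentages because rounded percentages alone are ambiguous.
    """
    rows = []
    for q in responses.columns:
        vals = responses[q].dropna().astype(int)
        if ((vals < 1) | (vals > 5)).any():
            raise ValueError(f"question {q!r}: ratings must be on the 5-level scale 1..5")
        n = len(vals)
        n_low = int((vals <= 2).sum())
        n_neutral = int((vals == 3).sum())
        n_high = int((vals >= 4).sum())
        rows.append(
            {
                "question": q,
                "n": n,
                f"prefer_{device_low}": n_low,
                "neutral": n_neutral,
                f"prefer_{device_high}": n_high,
                f"pct_{device_low}": 100.0 * n_low / n if n else np.nan,
                f"pct_{device_high}": 100.0 * n_high / n if n else np.nan,
                f"frac_{device_low}": f"{n_low}/{n}",
                f"frac_{device_high}": f"{n_high}/{n}",
            }
        )
    return pd.DataFrame(rows)
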