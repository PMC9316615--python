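"""Noninferiority of the exoscope's learning plateau and rate.

Reads the fitted fixed effects (estimate, SE, df) written by 03_fit_curves
and runs the one-tailed t test against the a-priori 20% margin, overall and
within each starting-device subgroup (the subgroup curves are refitted on
the subgroup's trials).
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from starlimit.inference import noninferiority_from_fit, noninferiority_test
from starlimit.nlme import fit_nlme
from starlimit.pipeline import scored_frame
from starlimit.trial_data import read_trials

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    fixed = pd.read_csv(ROOT / "fixed_effects.csv")
    rows = []
    for coefficient, param in (("plateau", "A"), ("rate", "r")):
        sub = fixed[fixed["param"] == param].set_index("device")
        res = noninferiority_test(
            est_ref=sub.loc["microscope", "estimate"],
            se_ref=sub.loc["microscope", "se"],
            est_new=sub.loc["exoscope", "estimate"],
            se_new=sub.loc["exoscope", "se"],
            df=sub.loc["microscope", "df"],
            coefficient=coefficient,
        )
        rows.append({"analysis": "overall", **dataclasses.asdict(res)})
        verdict = "noninferior" if res.noninferior else "NOT noninferior"
        print(
            f"{coefficient:8s} exoscope {res.est_new:8.3f} vs microscope "
            f"{res.est_ref:8.3f} margin {res.margin:6.3f} -> one-tailed "
            f"p = {res.p_one_tailed:.4f} ({verdict})"
        )

    records, _ = read_trials(ROOT / "data" / "trials.csv")
    frame = scored_frame(records)
    novices = frame[frame["cohort"] == "novice"]
    started = novices[novices["phase"] == 1].groupby("subject_id")["device"].first()
    for dev in ("microscope", "exoscope"):
        subjects = started[started == dev].index
        sub = novices[novices["subject_id"].isin(subjects)]
        fit = fit_nlme(sub, "modified_weibull", n_starts=2, seed=args.seed)
        res = noninferiority_from_fit(fit, coefficient="plateau")
        rows.append({"analysis": f"started_{dev}", **dataclasses.asdict(res)})
        print(
            f"plateau, subgroup that started on the {dev}: "
            f"p = {res.p_one_tailed:.4f} "
            f"({'noninferior' if res.noninferior else 'NOT noninferior'})"
        )

    pd.DataFrame(rows).drop(columns=["notes"]).to_csv(
        ROOT / "noninferiority.csv", index=False
    )


if __name__ == "__main__":
    main()
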