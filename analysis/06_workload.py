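"""NASA Raw TLX workload comparison between the devices.

Repeated-measures two-way ANOVA (device within subject, starting-device
group between) for each of the six domains and the total, with
Benjamini-Hochberg adjustment across responses within each effect.
"""

import argparse
from pathlib import Path

import pandas as pd

from starlimit.pipeline import scored_frame
from starlimit.trial_data import read_trials
from starlimit.workload import rm_anova_all

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    tlx = pd.read_csv(ROOT / "data" / "tlx.csv")
    records, _ = read_trials(ROOT / "data" / "trials.csv")
    frame = scored_frame(records)
    novices = frame[frame["cohort"] == "novice"]
    started = novices[novices["phase"] == 1].groupby("subject_id")["device"].first()
    tlx = tlx.merge(started.rename("group"), left_on="subject_id", right_index=True)

    med = tlx.groupby("device")["total"].median()
    print("median total workload by device:")
    print(med.to_string())

    tbl = rm_anova_all(tlx)
    tbl.to_csv(ROOT / "workload.csv", index=False)
    print("\nmixed-design ANOVA across domains (BH-adjusted p within effect):")
    print(tbl.to_string(index=False))
    sig = tbl[(tbl["p_adj"] < 0.05)]
    if sig.empty:
        print("\nno effect survives the false-discovery-rate adjustment")
    else:
        print("\neffects surviving FDR adjustment:")
        print(sig.to_string(index=False))


if __name__ == "__main__":
    main()
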