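"""Validate the composite performance score as a novice/expert discriminator.

Compares absolute novices (first five attempts) with absolute experts (final
five attempts): screens outlying subjects on median completion time, ranks
candidate score models by AIC, and derives the expert threshold from the
Youden-optimal cutpoint.
"""

import argparse
from pathlib import Path

from starlimit.pipeline import scored_frame
from starlimit.scoring import (
    DEFAULT_CANDIDATES,
    build_features,
    derive_expert_threshold,
    flag_outliers,
    select_score_model,
    subject_median_times,
    validation_subset,
)
from starlimit.trial_data import read_trials

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    records, report = read_trials(ROOT / "data" / "trials.csv")
    print(f"loaded {report.n_rows} rows, {report.n_rejected} rejected")

    frame = scored_frame(records)
    val = validation_subset(frame)
    outliers = flag_outliers(subject_median_times(val))
    print(f"outlying subjects excluded from validation: {outliers or 'none'}")
    kept = val[~val["subject_id"].isin(outliers)]

    tbl = select_score_model(
        DEFAULT_CANDIDATES, build_features(kept), kept["cohort"].to_numpy()
    )
    tbl.to_csv(ROOT / "score_models.csv")
    print("\nAIC ranking of candidate score models (best first):")
    print(tbl.to_string())

    thr = derive_expert_threshold(
        kept.loc[kept["cohort"] == "novice", "score"],
        kept.loc[kept["cohort"] == "expert", "score"],
    )
    print(
        f"\nexpert threshold: {thr.threshold:.2f} raw, {thr.threshold_rounded:g} "
        f"rounded to the nearest 5 (Youden J = {thr.youden_j:.3f})"
    )
    if thr.low_separability:
        print("warning: novice and expert scores overlap almost completely")


if __name__ == "__main__":
    main()
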