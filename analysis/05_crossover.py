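"""Did the starting device matter?  Crossover analysis of settled trials.

Linear mixed model (random intercept per subject) on the final five trials
of each phase: phase effect (performance change after crossover), starting-
device group effect, and their interaction.
"""

import argparse
from pathlib import Path

from starlimit.inference import crossover_lmm
from starlimit.pipeline import scored_frame
from starlimit.trial_data import read_trials

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    records, _ = read_trials(ROOT / "data" / "trials.csv")
    frame = scored_frame(records)
    novices = frame[frame["cohort"] == "novice"]

    tbl = crossover_lmm(novices)
    tbl.to_csv(ROOT / "crossover.csv", index=False)
    print("crossover linear mixed model (final five trials of each phase):")
    print(tbl.to_string(index=False))
    phase = tbl[tbl["effect"] == "phase"].iloc[0]
    direction = "improved" if phase["estimate"] > 0 else "declined"
    print(
        f"\nperformance {direction} by {abs(phase['estimate']):.2f} points after "
        f"crossover (F = {phase['F']:.2f}, p = {phase['p']:.4f})"
    )


if __name__ == "__main__":
    main()
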