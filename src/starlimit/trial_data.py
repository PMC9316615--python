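"""Trial records, delimited-text I/O, and permuted-block randomization.

One :class:`TrialRecord` is one scored repetition of the grape-dissection
task: who performed it (subject, cohort), on which optical device, where it
sits in the crossover (phase 1 or 2, trial 1..20 within phase), and the five
rubric items — completion time (capped at 300 s), completeness of the
dissected star, flesh score 0-2, edge score (up to 20 with a star, up to 10
without), and perforation count.

Files are plain CSV with canonical snake-case headers; a caller-supplied
rename map adapts foreign dialects.  Invalid rows are rejected with the rule
named, never silently dropped: :func:`read_trials` returns a parse report so
the bookkeeping of every grape stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ParseReport",
    "RandomizationList",
    "TIME_CAP_S",
    "validate_record",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "permuted_block_sequence",
]

TIME_CAP_S = 300.0

COHORTS = ("novice", "expert")
DEVICES = ("exoscope", "microscope")

COLUMNS = (
    "subject_id",
    "cohort",
    "device",
    "phase",
    "trial",
    "time_s",
    "complete",
    "flesh",
    "edge",
    "perforations",
    "capped",
)


@dataclass
class TrialRecord:
    """One scored repetition of the microsurgical task."""

    subject_id: str
    cohort: str
    device: str
    phase: int
    trial: int
    time_s: float
    complete: int
    flesh: int
    edge: int
    perforations: int
    capped: bool = False  # repetition stopped at the 5-minute cap


@dataclass
class ParseReport:
    n_rows: int
    n_rejected: int
    errors: List[str] = field(default_factory=list)


@dataclass
class RandomizationList:
    """Device-order allocations from permuted blocked randomization."""

    assignments: List[str]  # each "exoscope-first" or "microscope-first"
    block_sizes: Tuple[int, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.assignments)


def validate_record(rec: TrialRecord) -> List[str]:
    """Return the list of violated invariant rules (empty when valid)."""
    problems = []
    if rec.cohort not in COHORTS:
        problems.append(f"cohort must be one of {COHORTS}, got {rec.cohort!r}")
    if rec.device not in DEVICES:
        problems.append(f"device must be one of {DEVICES}, got {rec.device!r}")
    if rec.phase not in (1, 2):
        problems.append(f"phase must be 1 or 2, got {rec.phase}")
    if rec.cohort == "expert" and rec.phase != 1:
        problems.append("experts perform a single phase (phase must be 1)")
    if not 1 <= rec.trial <= 20:
        problems.append(f"trial must be in 1..20, got {rec.trial}")
    if not 0.0 <= rec.time_s <= TIME_CAP_S:
        problems.append(
            f"time cap: time_s must be in [0, {TIME_CAP_S:g}] s, got {rec.time_s}"
        )
    if rec.complete not in (0, 1):
        problems.append(f"complete must be 0 or 1, got {rec.complete}")
    if rec.flesh not in (0, 1, 2):
        problems.append(f"flesh must be 0, 1 or 2, got {rec.flesh}")
    edge_cap = 20 if rec.complete == 1 else 10
    if not 0 <= rec.edge <= edge_cap:
        problems.append(
            f"edge cap: edge must be in 0..{edge_cap} when complete={rec.complete}, "
            f"got {rec.edge}"
        )
    if rec.perforations < 0:
        problems.append(f"perforations must be >= 0, got {rec.perforations}")
    return problems


def _records_from_frame(df: pd.DataFrame) -> Tuple[List[TrialRecord], ParseReport]:
    records: List[TrialRecord] = []
    errors: List[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                cohort=str(row.cohort),
                device=str(row.device),
                phase=int(row.phase),
                trial=int(row.trial),
                time_s=float(row.time_s),
                complete=int(row.complete),
                flesh=int(row.flesh),
                edge=int(row.edge),
                perforations=int(row.perforations),
                capped=bool(getattr(row, "capped", False)),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {idx}: unparseable value ({exc})")
            continue
        problems = validate_record(rec)
        if problems:
            errors.extend(f"row {idx}: {p}" for p in problems)
        else:
            records.append(rec)
    # trial indices must be consecutive from 1 within each subject x device
    frame = trials_to_frame(records)
    bad_keys = set()
    if len(frame):
        for (sid, dev), grp in frame.groupby(["subject_id", "device"], sort=False):
            trials = sorted(grp["trial"])
            if trials != list(range(1, len(trials) + 1)):
                bad_keys.add((sid, dev))
                errors.append(
                    f"subject {sid!r} device {dev!r}: trial indices {trials} are not "
                    "consecutive starting at 1"
                )
    if bad_keys:
        records = [r for r in records if (r.subject_id, r.device) not in bad_keys]
    report = ParseReport(n_rows=len(df), n_rejected=len(df) - len(records), errors=errors)
    return records, report


def read_trials(
    path, dialect: Optional[Dict[str, str]] = None
) -> Tuple[List[TrialRecord], ParseReport]:
    """Read trial records from CSV.

    ``dialect`` maps file column names to canonical ones, e.g.
    ``{"Time (s)": "time_s"}``.  Missing mandatory columns raise; invalid
    rows are rejected and reported row-by-row with the failed rule named.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    mandatory = [c for c in COLUMNS if c != "capped"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if "capped" not in df.columns:
        df["capped"] = False
    return _records_from_frame(df[list(COLUMNS)])


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(COLUMNS))
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_trials(records: Sequence[TrialRecord], path) -> None:
    """Write records as CSV; re-reading reproduces them field-for-field."""
    for i, rec in enumerate(records, start=1):
        problems = validate_record(rec)
        if problems:
            raise ValueError(f"record {i} invalid: {problems[0]}")
    frame = trials_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.4f")


def permuted_block_sequence(
    n: int, block_sizes: Iterable[int] = (2, 4), seed: int = 0
) -> RandomizationList:
    """Computer-generated permuted blocked randomization of device order.

    Blocks are drawn uniformly from ``block_sizes`` (each size must be even
    so the two arms balance within a block); within each block, half the
    slots are exoscope-first and half microscope-first, in random order.
    Deterministic for a fixed seed.
    """
    sizes = tuple(sorted(set(int(b) for b in block_sizes)))
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sizes:
        raise ValueError("need at least one block size")
    for b in sizes:
        if b <= 0 or b % 2 != 0:
            raise ValueError(f"block size must be an even positive integer, got {b}")
    rng = np.random.default_rng(seed)
    assignments: List[str] = []
    while len(assignments) < n:
        remaining = n - len(assignments)
        # prefer block sizes that still fit, so a list length divisible by
        # every block size closes on a completed (balanced) block
        feasible = [b for b in sizes if b <= remaining]
        b = int(rng.choice(feasible if feasible else [min(sizes)]))
        block = ["exoscope-first"] * (b // 2) + ["microscope-first"] * (b // 2)
        rng.shuffle(block)
        assignments.extend(block)
    return RandomizationList(assignments[:n], sizes, int(seed))
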