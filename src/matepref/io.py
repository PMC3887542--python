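"""Reading and writing the long-format trial-table interchange CSV.

One row per no-choice trial; seconds are the only time unit.  Readers
validate rather than coerce: structural problems (missing columns) and
row-level invariant violations (a mated pair without a copulation
duration, a latency beyond the censor time) are reported with CSV line
numbers and reject the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_trials import TRIAL_COLUMNS, DesignConfig

__all__ = ["read_trials", "write_trials", "read_design", "write_design",
           "TrialValidationError"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [c for c in TRIAL_COLUMNS if c not in ("array_id", "chamber")]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


class TrialValidationError(ValueError):
    """Raised when a trial CSV violates the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"invalid trial table ({len(problems)} problem(s)):\n  {shown}{more}")


def _parse_bool(value, line: int, col: str, problems: list[str]) -> bool | None:
    s = str(value).strip().lower()
    if s in _BOOL:
        return _BOOL[s]
    problems.append(f"line {line}: column {col!r} has non-boolean value {value!r}")
    return None


def read_trials(path: str | Path, censor_time: float = 3600.0) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Enforces the record invariants: latencies positive; copulation
    latency defined iff courted and never above ``censor_time``, equal
    to it exactly when the pair courted but did not mate; mating implies
    courtship; copulation duration defined iff mated.
    """
    df = pd.read_csv(path, dtype={"male_line": str, "female_line": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing required column(s): {missing}"])

    problems: list[str] = []
    courted = np.empty(len(df), dtype=object)
    mated = np.empty(len(df), dtype=object)
    for k, (idx, row) in enumerate(df.iterrows()):
        line = k + 2  # header is line 1
        c = _parse_bool(row["courted"], line, "courted", problems)
        m = _parse_bool(row["mated"], line, "mated", problems)
        courted[k], mated[k] = c, m
        if c is None or m is None:
            continue
        cl = row["courtship_latency"]
        pl = row["copulation_latency"]
        dur = row["copulation_duration"]
        if m and not c:
            problems.append(f"line {line}: mated=true but courted=false")
        if c:
            if pd.isna(cl) or cl <= 0:
                problems.append(f"line {line}: courted=true requires courtship_latency > 0")
        else:
            if not pd.isna(cl):
                problems.append(f"line {line}: courted=false but courtship_latency present")
            if not pd.isna(pl):
                problems.append(f"line {line}: courted=false but copulation_latency present")
        if c and pd.isna(pl):
            problems.append(f"line {line}: courted=true requires a copulation_latency "
                            "(censor time when unmated)")
        if not pd.isna(pl):
            if pl <= 0 or pl > censor_time:
                problems.append(f"line {line}: copulation_latency {pl} outside (0, {censor_time}]")
            if c and not m and pl != censor_time:
                problems.append(f"line {line}: unmated pair must be censored at "
                                f"{censor_time}, got {pl}")
        if m and pd.isna(dur):
            problems.append(f"line {line}: mated=true but copulation_duration empty")
        if not m and not pd.isna(dur):
            problems.append(f"line {line}: mated=false but copulation_duration present")
        if not pd.isna(dur) and dur <= 0:
            problems.append(f"line {line}: copulation_duration must be positive")
    if problems:
        raise TrialValidationError(problems)

    df["courted"] = courted.astype(bool)
    df["mated"] = mated.astype(bool)
    for col in ("courtship_latency", "copulation_latency", "copulation_duration"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    logger.info("read %d trial(s) from %s (%d courted, %d mated)",
                len(df), path, int(df['courted'].sum()), int(df['mated'].sum()))
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table with the canonical column order; NaN as empty."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def write_design(design: DesignConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(design), indent=2) + "\n")


def read_design(path: str | Path) -> DesignConfig:
    return DesignConfig(**json.loads(Path(path).read_text()))
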