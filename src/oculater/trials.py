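"""Trial-level data model for the saccade-reward experiments.

A trial table is a :class:`pandas.DataFrame` with one row per trial and a
fixed column schema (:data:`COLUMNS`).  Each row records which block and
condition the trial belonged to, the reward assigned to each hemifield,
what the participant did (response side, saccade latency relative to
target onset) and how the trial was scored (hit, too early, too late,
wrong target, no response, or recording error).

Latencies are stored in milliseconds relative to target onset; the 600 ms
foreperiod between the fixation-cross cue and target onset is not part of
the latency.  Missing values (latency on no-response trials, contrasts in
experiments that never manipulated contrast) are encoded as empty CSV
fields and surface as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical column order of a trial-table CSV.
COLUMNS = [
    "participant_id",
    "experiment",
    "block_id",
    "trial_index",
    "choice_proportion",
    "reward_low",
    "reward_high",
    "congruency",
    "difficulty",
    "cued",
    "trial_type",
    "target_side",
    "high_reward_side",
    "contrast_left",
    "contrast_right",
    "response_side",
    "latency_ms",
    "outcome",
]

CHOICE_PROPORTIONS = {0.0, 0.25, 0.5, 0.75}
REWARD_LOW_VALUES = {1, 4}
REWARD_HIGH_VALUES = {6, 9}
CONGRUENCY_VALUES = {"congruent", "incongruent", "none"}
DIFFICULTY_VALUES = {"easy", "medium", "difficult", "none"}
TRIAL_TYPES = {"single", "choice"}
TARGET_SIDES = {"left", "right", "both"}
SIDES = {"left", "right"}
RESPONSE_SIDES = {"left", "right", "none"}
CONTRASTS = {0.08, 0.2, 0.5}
OUTCOMES = {
    "hit",
    "too_early",
    "too_late",
    "wrong_target",
    "no_response",
    "recording_error",
}

#: Columns that must be constant within one block of one participant.
_BLOCK_CONSTANT = ["choice_proportion", "congruency", "difficulty", "cued"]

_DTYPES = {
    "participant_id": str,
    "experiment": int,
    "block_id": str,
    "trial_index": int,
    "choice_proportion": float,
    "reward_low": int,
    "reward_high": int,
    "congruency": str,
    "difficulty": str,
    "cued": bool,
    "trial_type": str,
    "target_side": str,
    "high_reward_side": str,
    "contrast_left": float,
    "contrast_right": float,
    "response_side": str,
    "latency_ms": float,
    "outcome": str,
}


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema or its invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


@dataclass
class Violation:
    """One invariant violation, located by row index (or None for table-level)."""

    row: int | None
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        where = "table" if self.row is None else f"row {self.row}"
        return f"{where} [{self.field}]: {self.message}"


@dataclass
class ValidationReport:
    """Collected invariant violations; empty report <=> valid table."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, row: int | None, column: str, message: str) -> None:
        self.violations.append(Violation(row, column, message))

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "valid trial table"
        head = "\n".join(str(v) for v in self.violations[:20])
        extra = len(self.violations) - 20
        return head + (f"\n... and {extra} more" if extra > 0 else "")


def _check_enum(df, report, column, allowed, allow_na=False):
    col = df[column]
    bad = ~col.isin(allowed)
    if allow_na:
        bad &= col.notna()
    for row in df.index[bad]:
        report.add(row, column, f"value {col.loc[row]!r} not in {sorted(map(str, allowed))}")


def validate_trials(df: pd.DataFrame) -> ValidationReport:
    """Check a trial table against the schema invariants.

    Returns a :class:`ValidationReport` listing every violated invariant
    with the offending row index; never raises.
    """
    report = ValidationReport()
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        report.add(None, ",".join(missing), "missing required columns")
        return report

    _check_enum(df, report, "congruency", CONGRUENCY_VALUES)
    _check_enum(df, report, "difficulty", DIFFICULTY_VALUES)
    _check_enum(df, report, "trial_type", TRIAL_TYPES)
    _check_enum(df, report, "target_side", TARGET_SIDES)
    _check_enum(df, report, "high_reward_side", SIDES)
    _check_enum(df, report, "response_side", RESPONSE_SIDES)
    _check_enum(df, report, "outcome", OUTCOMES)
    _check_enum(df, report, "choice_proportion", CHOICE_PROPORTIONS)
    _check_enum(df, report, "reward_low", REWARD_LOW_VALUES)
    _check_enum(df, report, "reward_high", REWARD_HIGH_VALUES)
    _check_enum(df, report, "contrast_left", CONTRASTS, allow_na=True)
    _check_enum(df, report, "contrast_right", CONTRASTS, allow_na=True)

    bad = ~df["experiment"].isin(range(1, 7))
    for row in df.index[bad]:
        report.add(row, "experiment", "experiment must be an integer in 1..6")
    bad = df["trial_index"] < 1
    for row in df.index[bad]:
        report.add(row, "trial_index", "trial_index must be >= 1")

    # choice trials show both targets; single trials exactly one
    is_choice = df["trial_type"] == "choice"
    is_both = df["target_side"] == "both"
    for row in df.index[is_choice ^ is_both]:
        report.add(row, "target_side",
                   "trial_type == 'choice' if and only if target_side == 'both'")

    # rewards are complementary score points
    bad = (df["reward_low"] + df["reward_high"]) != 10
    for row in df.index[bad]:
        report.add(row, "reward_low", "rewards must sum to 10 score points")

    # absent latency only on no-response / recording-error trials
    no_lat = df["latency_ms"].isna()
    allowed = df["outcome"].isin({"no_response", "recording_error"})
    for row in df.index[no_lat & ~allowed]:
        report.add(row, "latency_ms",
                   "latency may be absent only for no_response/recording_error")
    bad = df["latency_ms"] <= 0
    for row in df.index[bad.fillna(False)]:
        report.add(row, "latency_ms", "latency must be positive")

    # block-level condition labels are constant within a block
    for (pid, block), grp in df.groupby(["participant_id", "block_id"], sort=False):
        for col in _BLOCK_CONSTANT:
            if grp[col].nunique(dropna=False) > 1:
                report.add(int(grp.index[0]), col,
                           f"{col} varies within block {block!r} of {pid!r}")
    return report


def read_trials(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a trial-table CSV, coerce dtypes and (by default) validate.

    Raises :class:`TrialValidationError` naming row and field on the first
    read if the table violates any invariant, and ``ValueError`` if the
    header does not match the documented schema.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "block_id": str})
    if list(df.columns) != COLUMNS:
        raise ValueError(
            f"{path}: header mismatch; expected columns {COLUMNS}, got {list(df.columns)}"
        )
    for col, dtype in _DTYPES.items():
        if dtype is bool:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1"})
        elif dtype is int:
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise TrialValidationError(_coerce_report(col, exc)) from exc
        elif dtype is float:
            df[col] = pd.to_numeric(df[col], errors="coerce") if df[col].dtype == object \
                else df[col].astype(float)
        else:
            df[col] = df[col].fillna("none").astype(str)
    if validate:
        report = validate_trials(df)
        if not report.ok:
            raise TrialValidationError(report)
    return df


def _coerce_report(col, exc):
    rep = ValidationReport()
    rep.add(None, col, f"could not coerce column: {exc}")
    return rep


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV with the fixed column order.

    Absent values become empty fields; booleans are written as
    ``True``/``False``.  ``read_trials(write_trials(df))`` round-trips
    exactly.
    """
    out = df.loc[:, COLUMNS].copy()
    out.to_csv(path, index=False)


def empty_trials() -> pd.DataFrame:
    """Return an empty trial table with the correct columns and dtypes."""
    return pd.DataFrame({c: pd.Series(dtype=(_DTYPES[c] if _DTYPES[c] is not str else object))
                         for c in COLUMNS})
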