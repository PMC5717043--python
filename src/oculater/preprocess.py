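"""Trial filtering and derived labels applied before any analysis.

Latencies outside the 100-450 ms analysis window are excluded (bounds
inclusive: the exclusion rule targets saccades strictly earlier than
100 ms or later than 450 ms).  Recording-error trials are counted
separately and never analyzed.  Sequential (N-1) labels attach, to every
trial, the type and direction of the immediately preceding trial within
the same block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the latency-window filter."""

    n_total: int
    n_kept: int
    n_window_excluded: int
    n_recording_error: int

    @property
    def fraction_window_excluded(self) -> float:
        return self.n_window_excluded / self.n_total if self.n_total else 0.0

    @property
    def fraction_recording_error(self) -> float:
        return self.n_recording_error / self.n_total if self.n_total else 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["fraction_window_excluded"] = self.fraction_window_excluded
        d["fraction_recording_error"] = self.fraction_recording_error
        return json.dumps(d, indent=2)


def apply_latency_window(df: pd.DataFrame, lo_ms: float = 100.0,
                         hi_ms: float = 450.0):
    """Keep trials with a measured latency in ``[lo_ms, hi_ms]``.

    Recording-error trials are always dropped and counted in their own
    bucket; every other dropped trial (absent latency or latency outside
    the window) counts as window-excluded.  Returns
    ``(kept DataFrame, ExclusionReport)``.
    """
    if lo_ms >= hi_ms:
        raise ValueError(f"need lo_ms < hi_ms, got {lo_ms} >= {hi_ms}")
    rec_err = df["outcome"] == "recording_error"
    in_window = df["latency_ms"].between(lo_ms, hi_ms) & ~rec_err
    kept = df.loc[in_window].copy()
    report = ExclusionReport(
        n_total=len(df),
        n_kept=int(in_window.sum()),
        n_window_excluded=int((~in_window & ~rec_err).sum()),
        n_recording_error=int(rec_err.sum()),
    )
    return kept, report


def label_previous_trial(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ``prev_type`` and ``prev_direction`` columns.

    ``prev_type`` is the previous trial's type within the same block
    ('none' for block-initial trials).  ``prev_direction`` compares the
    previous trial's saccade direction (for choice-trials: the chosen
    side) with the current trial's target side ('same' / 'opposite';
    'none' when either side is undefined).  Must be called on the full,
    unfiltered table so that labels reflect the true trial sequence.
    """
    key = ["participant_id", "block_id"]
    idx = df.groupby(key, sort=False)["trial_index"].diff()
    if ((idx.dropna() <= 0).any()):
        raise ValueError("records are not ordered by trial_index within blocks")
    out = df.copy()
    grp = out.groupby(key, sort=False)
    out["prev_type"] = grp["trial_type"].shift(1).fillna("none")
    prev_resp = grp["response_side"].shift(1).fillna("none")
    cur = out["target_side"]
    comparable = (prev_resp.isin(["left", "right"])) & (cur.isin(["left", "right"]))
    out["prev_direction"] = np.where(
        comparable, np.where(prev_resp == cur, "same", "opposite"), "none")
    return out


def later_conditions(df: pd.DataFrame) -> dict:
    """Group hit single-trial latencies into the four LATER conditions.

    Keys combine the block context (choice-trials present or not) with the
    target's reward level: ``no_choice_high``, ``no_choice_low``,
    ``with_choice_high``, ``with_choice_low``.  Choice-trial latencies are
    never included.  Apply the latency window first.
    """
    singles = df[(df["trial_type"] == "single") & (df["outcome"] == "hit")]
    ctx = np.where(singles["choice_proportion"] > 0, "with_choice", "no_choice")
    level = np.where(singles["target_side"] == singles["high_reward_side"],
                     "high", "low")
    out = {}
    for key in ("no_choice_high", "no_choice_low",
                "with_choice_high", "with_choice_low"):
        c, lv = key.rsplit("_", 1)
        mask = (ctx == c) & (level == lv)
        lat = singles.loc[mask, "latency_ms"].to_numpy(dtype=float)
        if lat.size:
            out[key] = lat
    return out


@dataclass(frozen=True)
class MissSummary:
    """Breakdown of missed single-trials.

    Proportions cover the three saccadic miss categories and sum to 1;
    no-response trials are a separate bucket.  ``defined`` is False when
    there are no saccadic misses at all.
    """

    defined: bool
    p_too_early: float | None
    p_too_late: float | None
    p_wrong_target: float | None
    n_misses: int
    n_no_response: int
    miss_rate_by_condition: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


_MISS_CATS = ["too_early", "too_late", "wrong_target"]


def classify_misses(df: pd.DataFrame, condition: str = "difficulty") -> MissSummary:
    """Categorize non-hit single-trials and their per-condition rates.

    The per-condition miss probability counts every non-hit outcome
    (including no-response, excluding recording errors) among single-trials
    toward the less rewarded side, mirroring an analysis in which missing
    the target is the dependent variable.
    """
    singles = df[(df["trial_type"] == "single")
                 & (df["outcome"] != "recording_error")]
    misses = singles[singles["outcome"].isin(_MISS_CATS)]
    n_no_response = int((singles["outcome"] == "no_response").sum())
    n_misses = len(misses)
    if n_misses == 0:
        props = dict.fromkeys(_MISS_CATS, None)
        defined = False
    else:
        counts = misses["outcome"].value_counts()
        props = {c: float(counts.get(c, 0)) / n_misses for c in _MISS_CATS}
        defined = True

    low = singles[singles["target_side"] != singles["high_reward_side"]]
    rates = {}
    for cond, grp in low.groupby(condition, sort=False):
        rates[str(cond)] = float((grp["outcome"] != "hit").mean())
    return MissSummary(
        defined=defined,
        p_too_early=props["too_early"],
        p_too_late=props["too_late"],
        p_wrong_target=props["wrong_target"],
        n_misses=n_misses,
        n_no_response=n_no_response,
        miss_rate_by_condition=rates,
    )
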