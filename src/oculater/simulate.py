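"""Generative model for synthetic saccade-reward trial tables.

Single-trial latencies are drawn from the recinormal (LATER) distribution
of the trial's condition.  The condition determines the baseline level
``theta0`` of the accumulator; the rate parameters ``mu`` and ``sigma``
and the threshold ``theta_t`` are shared.  Four baseline cells encode the
block context:

* ``no_choice_high`` / ``no_choice_low`` — single-trials in blocks without
  choice-trials, toward the highly / less rewarded hemifield.
* ``with_choice_chosen`` / ``with_choice_nonchosen`` — single-trials in
  blocks with interleaved choice-trials, toward the hemifield that is
  (almost always) chosen in choice-trials versus the non-chosen one.  In
  congruent blocks the chosen side is the highly rewarded single-trial
  side; in incongruent blocks it is the opposite side, so the latency
  pattern follows the choice-trial rewards rather than the single-trial
  rewards.

On top of the block-level cells, three trial-level rules modulate the
effective baseline:

* inter-trial inhibition — a single-trial whose target is opposite to the
  side chosen in the immediately preceding choice-trial starts from a
  baseline lowered by ``delta_theta0_inhibit``;
* cueing — a cue announcing "next trial is a single-trial" restores a
  fraction ``cue_relief`` of the gap between the trial's effective
  baseline and its no-choice reference cell;
* difficulty — the contrast manipulation of choice-trials scales the
  non-chosen cell's baseline deficit by ``difficulty_deficit_scale`` and
  raises the wrong-target rate.

Choice-trials are resolved by a Bernoulli draw (``p_choose_high``) and
their latencies are drawn from the chosen cell's parameters; they are
summarized but never entered into LATER fits.  Misses are generated as
anticipations (uniform 50-99 ms), deadline overruns (latency beyond
``deadline_ms``), wrong-target saccades, and configurable no-response and
recording-error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import BlockDesign, ExperimentDesign
from .trials import COLUMNS

THETA0_CELLS = ("no_choice_high", "no_choice_low",
                "with_choice_chosen", "with_choice_nonchosen")


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic-trial generative model.

    Rates are in threshold units per ms; probabilities are per trial.
    """

    theta0_by_condition: dict
    theta_t: float = 1.0
    mu: float = 0.004347
    sigma: float = 0.000696
    p_choose_high: float = 0.95
    delta_theta0_inhibit: float = 0.076
    cue_relief: float = 0.5
    contrast_mu_scale: dict = field(
        default_factory=lambda: {0.08: 0.873, 0.2: 1.0, 0.5: 1.02})
    difficulty_deficit_scale: dict = field(
        default_factory=lambda: {"none": 1.0, "easy": 0.7, "medium": 1.0,
                                 "difficult": 1.4})
    wrong_target_rate: dict = field(
        default_factory=lambda: {"none": 0.005, "easy": 0.01, "medium": 0.03,
                                 "difficult": 0.10})
    p_too_early: float = 0.01
    p_no_response: float = 0.0
    p_recording_error: float = 0.03
    deadline_ms: float = 500.0

    def validate(self) -> "GenerativeParams":
        missing = [c for c in THETA0_CELLS if c not in self.theta0_by_condition]
        if missing:
            raise ValueError(f"theta0_by_condition missing cells {missing}")
        for cell, v in self.theta0_by_condition.items():
            if not 0.0 <= v < self.theta_t:
                raise ValueError(f"theta0[{cell}] = {v} outside [0, theta_t)")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")
        for name in ("p_choose_high", "cue_relief", "p_too_early",
                     "p_no_response", "p_recording_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.delta_theta0_inhibit < 0:
            raise ValueError("delta_theta0_inhibit must be >= 0")
        if self.deadline_ms <= 0:
            raise ValueError("deadline_ms must be positive")
        return self


def default_study_params() -> GenerativeParams:
    """Defaults sized to the study's reported latency means.

    Solved from the recinormal mean E[T] ~= (theta/mu)(1 + (sigma/mu)^2)
    so that no-choice single-trials average ~187 ms (highly rewarded) and
    ~192 ms (less rewarded), with-choice chosen-side trials ~192 ms, and
    with-choice non-chosen trials ~228 ms as a mixture of the after-single
    (~218 ms) and after-choice (~236 ms) states at 50% choice-trials.
    """
    return GenerativeParams(
        theta0_by_condition={
            "no_choice_high": 0.2074,
            "no_choice_low": 0.1861,
            "with_choice_chosen": 0.1861,
            "with_choice_nonchosen": 0.076,
        },
    )


def _sample_positive_normal(rng, mu, sigma):
    """Elementwise Normal(mu, sigma) with non-positive draws rejected."""
    r = rng.normal(mu, sigma)
    bad = r <= 0
    while np.any(bad):
        r = np.where(bad, rng.normal(mu, sigma), r)
        bad = r <= 0
    return r


def _opposite(sides: np.ndarray) -> np.ndarray:
    return np.where(sides == "left", "right", "left")


def _simulate_block(block: BlockDesign, params: GenerativeParams,
                    experiment: int, participant_id: str,
                    rng: np.random.Generator) -> pd.DataFrame:
    low_side = "left" if block.high_reward_side == "right" else "right"
    chosen_side = (block.high_reward_side if block.congruency != "incongruent"
                   else low_side)
    nonchosen_side = "left" if chosen_side == "right" else "right"

    # trial layout, then a seeded shuffle
    trial_type = np.array(["choice"] * block.n_choice
                          + ["single"] * (block.n_single_high + block.n_single_low))
    target = np.array(["both"] * block.n_choice
                      + [block.high_reward_side] * block.n_single_high
                      + [low_side] * block.n_single_low)
    contrast = np.full(trial_type.size, np.nan)
    if block.single_contrasts is not None:
        n_single = block.n_single_high + block.n_single_low
        cyc = np.resize(np.asarray(block.single_contrasts, dtype=float), n_single)
        contrast[block.n_choice:] = cyc
    order = rng.permutation(trial_type.size)
    trial_type, target, contrast = trial_type[order], target[order], contrast[order]
    n = trial_type.size
    is_choice = trial_type == "choice"
    is_single = ~is_choice

    # resolve choice-trials
    choose_high = rng.random(n) < params.p_choose_high
    response = np.where(is_choice,
                        np.where(choose_high, chosen_side, nonchosen_side),
                        target).astype(object)

    # effective baseline per trial
    t0 = params.theta0_by_condition
    scale = params.difficulty_deficit_scale.get(block.difficulty, 1.0)
    if block.n_choice > 0:
        nonchosen_theta0 = t0["with_choice_chosen"] - scale * (
            t0["with_choice_chosen"] - t0["with_choice_nonchosen"])
        theta0 = np.where(target == chosen_side, t0["with_choice_chosen"],
                          np.where(target == nonchosen_side, nonchosen_theta0,
                                   t0["with_choice_chosen"]))  # choice-trials
        ref = np.where(target == block.high_reward_side, t0["no_choice_high"],
                       t0["no_choice_low"])
    else:
        theta0 = np.where(target == block.high_reward_side, t0["no_choice_high"],
                          t0["no_choice_low"])
        ref = theta0
    theta0 = theta0.astype(float).copy()

    # inter-trial inhibition: single-trial opposite to the previously chosen side
    prev_choice = np.zeros(n, dtype=bool)
    prev_choice[1:] = is_choice[:-1]
    prev_resp = np.roll(response, 1)
    inhibited = is_single & prev_choice & (target != prev_resp)
    theta0[inhibited] -= params.delta_theta0_inhibit

    # cueing restores part of the gap to the no-choice reference
    if block.cued and block.n_choice > 0:
        relief = params.cue_relief * (ref - theta0)
        theta0[is_single] += relief[is_single]
    theta0 = np.clip(theta0, 0.0, 0.999 * params.theta_t)

    # rate of rise, scaled by single-target contrast where manipulated
    mu = np.full(n, params.mu)
    has_contrast = np.isfinite(contrast)
    if np.any(has_contrast):
        factors = np.array([params.contrast_mu_scale.get(c, 1.0)
                            for c in contrast[has_contrast]])
        mu[has_contrast] *= factors
    rate = _sample_positive_normal(rng, mu, params.sigma)
    latency = (params.theta_t - theta0) / rate

    outcome = np.where(latency > params.deadline_ms, "too_late", "hit").astype(object)

    # anticipations: uniform 50-99 ms, random direction
    early = is_single & (rng.random(n) < params.p_too_early)
    latency[early] = rng.uniform(50.0, 99.0, size=int(early.sum()))
    outcome[early] = "too_early"
    response[early] = np.where(rng.random(int(early.sum())) < 0.5, "left", "right")

    # wrong-target saccades toward the other hemifield (non-chosen-side
    # single-trials only; chosen-side misses are vanishingly rare)
    if block.n_choice > 0:
        p_wrong = params.wrong_target_rate.get(block.difficulty, 0.0)
        wrong = (is_single & (target == nonchosen_side) & ~early
                 & (rng.random(n) < p_wrong) & (outcome == "hit"))
        outcome[wrong] = "wrong_target"
        response[wrong] = _opposite(target[wrong])

    # no-response and recording-error trials have no measurable latency
    u = rng.random(n)
    noresp = u < params.p_no_response
    recerr = (u >= params.p_no_response) & (
        u < params.p_no_response + params.p_recording_error)
    outcome[noresp] = "no_response"
    outcome[recerr] = "recording_error"
    latency[noresp | recerr] = np.nan
    response[noresp | recerr] = "none"

    df = pd.DataFrame({
        "participant_id": participant_id,
        "experiment": experiment,
        "block_id": block.block_id,
        "trial_index": np.arange(1, n + 1),
        "choice_proportion": block.choice_proportion,
        "reward_low": block.reward_low,
        "reward_high": block.reward_high,
        "congruency": block.congruency,
        "difficulty": block.difficulty,
        "cued": block.cued,
        "trial_type": trial_type,
        "target_side": target,
        "high_reward_side": block.high_reward_side,
        "contrast_left": np.where(target != "right", contrast, np.nan),
        "contrast_right": np.where(target != "left", contrast, np.nan),
        "response_side": response,
        "latency_ms": latency,
        "outcome": outcome,
    })
    if block.choice_contrasts is not None:
        hi_c, lo_c = block.choice_contrasts
        left_is_high = block.high_reward_side == "left"
        df.loc[is_choice, "contrast_left"] = hi_c if left_is_high else lo_c
        df.loc[is_choice, "contrast_right"] = lo_c if left_is_high else hi_c
    return df


def simulate_experiment(design: ExperimentDesign, params: GenerativeParams,
                        n_participants: int, seed: int) -> pd.DataFrame:
    """Simulate ``n_participants`` runs of one experimental design.

    Trial counts per block match the design exactly; trial order, choice
    resolutions, latencies and misses are drawn from ``seed`` and identical
    seeds give identical tables.
    """
    design.validate()
    params.validate()
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_participants):
        pid = f"p{i + 1:02d}"
        for block in design.blocks:
            frames.append(_simulate_block(block, params, design.experiment,
                                          pid, rng))
    return pd.concat(frames, ignore_index=True).loc[:, COLUMNS]


def with_theta0(params: GenerativeParams, **cells: float) -> GenerativeParams:
    """Return a copy of ``params`` with some baseline cells replaced."""
    new = dict(params.theta0_by_condition, **cells)
    return replace(params, theta0_by_condition=new)
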