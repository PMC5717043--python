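"""Block compositions of the six saccade-reward experiments.

Each experiment is a list of blocks; a block fixes the choice-trial
proportion, the reward pair assigned to the two hemifields, and (where
manipulated) congruency, difficulty, cueing and target contrasts.  Trial
counts per cell are exact, not expected values: the simulator lays out
exactly the listed numbers of choice- and single-trials and shuffles
their order within the block.

Design summary (per participant):

* exp1 — 2 reward differences x 3 choice proportions (0/25/75%), blocks of
  80 trials, single-trials split equally between hemifields.
* exp2 — 2 blocks of 120: 30 choice-trials, 30 single-trials to the highly
  and 60 to the less rewarded side (saccade frequency equated).
* exp3 — 3 blocks of 120 (large reward difference): congruent and
  incongruent blocks with 75% choice-trials, plus a single-trial-only block.
* exp4 — easy/medium/difficult blocks of 120 in which the choice-trial
  target contrasts favor or oppose the high reward, plus an unrewarded-style
  latency-control block of single-trials at three contrasts (rewards carry
  the nominal small pair so the table stays schema-valid).
* exp5 — 280 trials with 50% choice-trials; half of the single-trials are
  cued, encoded as a cued and an uncued block of 140.
* exp6 — 10 blocks of 100 single-trials only and 20 blocks of 100 with 50%
  choice-trials (3000 trials), the design used for LATER fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SMALL_REWARDS = (4, 6)
LARGE_REWARDS = (1, 9)


@dataclass(frozen=True)
class BlockDesign:
    """Exact trial composition of one block."""

    block_id: str
    choice_proportion: float
    reward_low: int
    reward_high: int
    n_choice: int
    n_single_high: int  # single-trials to the highly rewarded side
    n_single_low: int   # single-trials to the less rewarded side
    high_reward_side: str = "right"
    congruency: str = "none"
    difficulty: str = "none"
    cued: bool = False
    #: (contrast of the high-reward target, of the low-reward target) in
    #: choice-trials; None where contrast was not manipulated.
    choice_contrasts: tuple[float, float] | None = None
    #: contrast levels cycled over single-trials; None -> not manipulated.
    single_contrasts: tuple[float, ...] | None = None

    @property
    def n_trials(self) -> int:
        return self.n_choice + self.n_single_high + self.n_single_low

    def validate(self) -> None:
        if min(self.n_choice, self.n_single_high, self.n_single_low) < 0:
            raise ValueError(f"{self.block_id}: negative trial count")
        if self.n_trials == 0:
            raise ValueError(f"{self.block_id}: empty block")
        if self.reward_low + self.reward_high != 10:
            raise ValueError(f"{self.block_id}: rewards must sum to 10")
        got = self.n_choice / self.n_trials
        if abs(got - self.choice_proportion) > 0.5 / self.n_trials + 1e-9:
            raise ValueError(
                f"{self.block_id}: choice proportion {got:.3f} does not match "
                f"label {self.choice_proportion}")
        if self.high_reward_side not in {"left", "right"}:
            raise ValueError(f"{self.block_id}: bad high_reward_side")


@dataclass(frozen=True)
class ExperimentDesign:
    """One experiment: an ordered list of blocks."""

    experiment: int
    blocks: tuple[BlockDesign, ...] = field(default_factory=tuple)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def validate(self) -> None:
        if not 1 <= self.experiment <= 6:
            raise ValueError("experiment must be 1..6")
        if not self.blocks:
            raise ValueError("design has no blocks")
        seen = set()
        for b in self.blocks:
            b.validate()
            if b.block_id in seen:
                raise ValueError(f"duplicate block_id {b.block_id!r}")
            seen.add(b.block_id)


def _side(i: int) -> str:
    # counterbalance the highly rewarded hemifield across blocks
    return "right" if i % 2 == 0 else "left"


def exp1() -> ExperimentDesign:
    blocks = []
    i = 0
    for label, (lo, hi) in [("small", SMALL_REWARDS), ("large", LARGE_REWARDS)]:
        for prop in (0.0, 0.25, 0.75):
            n_choice = round(80 * prop)
            n_single = 80 - n_choice
            blocks.append(BlockDesign(
                block_id=f"{label}_p{int(prop * 100):02d}",
                choice_proportion=prop, reward_low=lo, reward_high=hi,
                n_choice=n_choice, n_single_high=n_single // 2,
                n_single_low=n_single // 2, high_reward_side=_side(i)))
            i += 1
    return ExperimentDesign(1, tuple(blocks))


def exp2() -> ExperimentDesign:
    blocks = [
        BlockDesign(block_id=label, choice_proportion=0.25,
                    reward_low=lo, reward_high=hi, n_choice=30,
                    n_single_high=30, n_single_low=60, high_reward_side=_side(i))
        for i, (label, (lo, hi)) in enumerate(
            [("small", SMALL_REWARDS), ("large", LARGE_REWARDS)])
    ]
    return ExperimentDesign(2, tuple(blocks))


def exp3() -> ExperimentDesign:
    lo, hi = LARGE_REWARDS
    blocks = (
        BlockDesign("congruent", 0.75, lo, hi, n_choice=90, n_single_high=15,
                    n_single_low=15, congruency="congruent", high_reward_side="right"),
        BlockDesign("incongruent", 0.75, lo, hi, n_choice=90, n_single_high=15,
                    n_single_low=15, congruency="incongruent", high_reward_side="left"),
        BlockDesign("single_only", 0.0, lo, hi, n_choice=0, n_single_high=60,
                    n_single_low=60, high_reward_side="right"),
    )
    return ExperimentDesign(3, blocks)


def exp4() -> ExperimentDesign:
    lo, hi = SMALL_REWARDS
    contrasts = {"easy": (0.5, 0.08), "medium": (0.2, 0.2), "difficult": (0.08, 0.5)}
    blocks = [
        BlockDesign(diff, 0.5, lo, hi, n_choice=60, n_single_high=30,
                    n_single_low=30, difficulty=diff,
                    choice_contrasts=contrasts[diff], single_contrasts=(0.2,),
                    high_reward_side=_side(i))
        for i, diff in enumerate(["easy", "medium", "difficult"])
    ]
    blocks.append(BlockDesign(
        "latency_control", 0.0, lo, hi, n_choice=0, n_single_high=60,
        n_single_low=60, single_contrasts=(0.08, 0.2, 0.5)))
    return ExperimentDesign(4, tuple(blocks))


def exp5() -> ExperimentDesign:
    lo, hi = LARGE_REWARDS
    blocks = (
        BlockDesign("uncued", 0.5, lo, hi, n_choice=70, n_single_high=35,
                    n_single_low=35, cued=False, high_reward_side="right"),
        BlockDesign("cued", 0.5, lo, hi, n_choice=70, n_single_high=35,
                    n_single_low=35, cued=True, high_reward_side="right"),
    )
    return ExperimentDesign(5, blocks)


def exp6() -> ExperimentDesign:
    lo, hi = LARGE_REWARDS
    blocks = []
    for i in range(10):
        blocks.append(BlockDesign(
            f"nc{i + 1:02d}", 0.0, lo, hi, n_choice=0, n_single_high=50,
            n_single_low=50, high_reward_side=_side(i)))
    for i in range(20):
        blocks.append(BlockDesign(
            f"wc{i + 1:02d}", 0.5, lo, hi, n_choice=50, n_single_high=25,
            n_single_low=25, high_reward_side=_side(i)))
    return ExperimentDesign(6, tuple(blocks))


_FACTORIES = {1: exp1, 2: exp2, 3: exp3, 4: exp4, 5: exp5, 6: exp6}


def get_design(experiment: int | str) -> ExperimentDesign:
    """Return the design for ``experiment`` (1..6 or 'exp1'..'exp6')."""
    if isinstance(experiment, str):
        experiment = int(experiment.removeprefix("exp"))
    try:
        design = _FACTORIES[experiment]()
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}; expected 1..6") from None
    design.validate()
    return design
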