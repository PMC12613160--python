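"""Difficulty grid and trial schedule of the motor-cognitive stress test.

The test is a series of 16 treadmill walking trials.  Each trial sits in a
cell of a motor x cognitive difficulty grid: the motor axis raises treadmill
speed (percent of the subject's preferred walking speed) and adds virtual
obstacles, the cognitive axis shows arithmetic expressions with more digits
and shorter display times.  The subject answers whether the expression sums
to at most :data:`ARITHMETIC_SUM_THRESHOLD` or more.

The default grid is 4 x 4 (ordinals 0-3 on each axis).  Level 0 on both axes
is the "no challenge" cell, scored from the plain baseline walk rather than
from a dedicated trial.  The hardest cell combines 140% treadmill speed with
three-digit expressions displayed for 3 s; the moderate mid-grid cell pairs
120% speed with two digits for 5 s.  Only those anchor cells are fixed by the
test definition; the level-1 descriptors are package defaults and the whole
grid is configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import DomainError

#: Arithmetic task threshold: the subject reports whether the displayed
#: expression sums to <= 4 or > 4.
ARITHMETIC_SUM_THRESHOLD = 4

#: Allowed per-trial duration range in minutes.
DURATION_RANGE_MIN = (0.45, 2.0)

#: Number of walking trials in a complete test.
N_TRIALS = 16

#: Fixed cells of the three lead-in trials (same learning experience for
#: everyone): motor-focused, cognitive-focused, then a combined trial.
LEAD_BLOCK = ((1, 0), (0, 1), (1, 1))

TRIAL_TYPES = ("baseline", "motor-focused", "cognitive-focused", "combined")


def expression_answer(digits) -> bool:
    """True answer of one arithmetic stimulus: does it sum to <= threshold?"""
    return int(np.sum(digits)) <= ARITHMETIC_SUM_THRESHOLD


@dataclass(frozen=True)
class MotorLevel:
    """One rung of the motor-difficulty ladder.

    ``speed_pct`` is treadmill speed as a percentage of the preferred walking
    speed; ``obstacles`` says whether virtual obstacles are shown.
    """

    ordinal: int
    speed_pct: float
    obstacles: bool

    def __post_init__(self):
        if self.ordinal < 0:
            raise DomainError(f"motor ordinal must be >= 0, got {self.ordinal}")
        if (self.ordinal == 0) != (not self.obstacles):
            raise DomainError("motor level 0 and only level 0 has no obstacles")
        if self.speed_pct <= 0:
            raise DomainError("speed_pct must be positive")


@dataclass(frozen=True)
class CognitiveLevel:
    """One rung of the cognitive-difficulty ladder.

    ``digits`` is the number of digits in the arithmetic expression and
    ``display_time_s`` how long it stays on screen (infinite when there is
    no cognitive task).
    """

    ordinal: int
    digits: int
    display_time_s: float

    def __post_init__(self):
        if self.ordinal < 0:
            raise DomainError(f"cognitive ordinal must be >= 0, got {self.ordinal}")
        if (self.ordinal == 0) != (self.digits == 0):
            raise DomainError("cognitive level 0 and only level 0 has no digits")
        if self.display_time_s <= 0:
            raise DomainError("display_time_s must be positive")


DEFAULT_MOTOR_LEVELS = (
    MotorLevel(0, 100.0, False),
    MotorLevel(1, 100.0, True),
    MotorLevel(2, 120.0, True),
    MotorLevel(3, 140.0, True),
)

DEFAULT_COGNITIVE_LEVELS = (
    CognitiveLevel(0, 0, math.inf),
    CognitiveLevel(1, 1, 8.0),
    CognitiveLevel(2, 2, 5.0),
    CognitiveLevel(3, 3, 3.0),
)


@dataclass(frozen=True)
class DifficultyGrid:
    """Ordered motor and cognitive levels spanning the difficulty grid."""

    motor_levels: tuple = DEFAULT_MOTOR_LEVELS
    cognitive_levels: tuple = DEFAULT_COGNITIVE_LEVELS

    def __post_init__(self):
        for levels, name in ((self.motor_levels, "motor"), (self.cognitive_levels, "cognitive")):
            if not levels:
                raise DomainError(f"{name}_levels is empty")
            ordinals = [lv.ordinal for lv in levels]
            if ordinals != list(range(len(levels))):
                raise DomainError(f"{name} ordinals must be 0..{len(levels) - 1} in order")
        speeds = [lv.speed_pct for lv in self.motor_levels]
        if any(b < a for a, b in zip(speeds, speeds[1:])):
            raise DomainError("speed_pct must be non-decreasing in motor ordinal")
        digits = [lv.digits for lv in self.cognitive_levels]
        times = [lv.display_time_s for lv in self.cognitive_levels]
        if any(b < a for a, b in zip(digits, digits[1:])):
            raise DomainError("digits must be non-decreasing in cognitive ordinal")
        if any(b > a for a, b in zip(times, times[1:])):
            raise DomainError("display_time_s must be non-increasing in cognitive ordinal")

    @property
    def shape(self) -> tuple:
        return (len(self.motor_levels), len(self.cognitive_levels))

    def cells(self) -> Iterator[tuple]:
        for m in range(len(self.motor_levels)):
            for c in range(len(self.cognitive_levels)):
                yield (m, c)

    def non_baseline_cells(self) -> list:
        return [cell for cell in self.cells() if cell != (0, 0)]


def build_default_grid() -> DifficultyGrid:
    """The default 4 x 4 grid (16 cells, including the no-challenge cell)."""
    return DifficultyGrid()


def classify_trial_type(motor_ordinal: int, cognitive_ordinal: int,
                        grid: DifficultyGrid | None = None) -> str:
    """Classify a grid cell as baseline / motor-focused / cognitive-focused / combined."""
    grid = grid or build_default_grid()
    n_m, n_c = grid.shape
    if not (0 <= motor_ordinal < n_m) or not (0 <= cognitive_ordinal < n_c):
        raise DomainError(
            f"cell ({motor_ordinal}, {cognitive_ordinal}) outside grid of shape {grid.shape}"
        )
    if motor_ordinal == 0 and cognitive_ordinal == 0:
        return "baseline"
    if cognitive_ordinal == 0:
        return "motor-focused"
    if motor_ordinal == 0:
        return "cognitive-focused"
    return "combined"


@dataclass(frozen=True)
class Trial:
    index: int
    trial_type: str
    motor: int
    cognitive: int
    duration_min: float

    def __post_init__(self):
        if not (1 <= self.index <= N_TRIALS):
            raise DomainError(f"trial index must be in 1..{N_TRIALS}")
        lo, hi = DURATION_RANGE_MIN
        if not (lo <= self.duration_min <= hi):
            raise DomainError(f"duration {self.duration_min} outside [{lo}, {hi}] min")
        expected = classify_trial_type(self.motor, self.cognitive)
        if self.trial_type != expected:
            raise DomainError(
                f"trial_type {self.trial_type!r} inconsistent with cell "
                f"({self.motor}, {self.cognitive}) -> {expected!r}"
            )


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered, seeded realisation of the 16-trial test."""

    trials: tuple
    seed: int

    def __post_init__(self):
        if len(self.trials) != N_TRIALS:
            raise DomainError(f"schedule must have {N_TRIALS} trials")
        lead = tuple((t.motor, t.cognitive) for t in self.trials[:3])
        if lead != LEAD_BLOCK:
            raise DomainError(f"first three trials must be cells {LEAD_BLOCK}")

    def cells(self) -> list:
        return [(t.motor, t.cognitive) for t in self.trials]

    def to_frame(self, grid: DifficultyGrid | None = None) -> pd.DataFrame:
        grid = grid or build_default_grid()
        rows = []
        for t in self.trials:
            ml = grid.motor_levels[t.motor]
            cl = grid.cognitive_levels[t.cognitive]
            rows.append({
                "trial_index": t.index,
                "trial_type": t.trial_type,
                "motor_level": t.motor,
                "cognitive_level": t.cognitive,
                "speed_pct": ml.speed_pct,
                "digits": cl.digits,
                "display_time_s": cl.display_time_s,
                "duration_min": t.duration_min,
            })
        return pd.DataFrame(rows)

    def to_json(self, grid: DifficultyGrid | None = None) -> str:
        frame = self.to_frame(grid)
        payload = {"seed": self.seed, "trials": frame.to_dict(orient="records")}
        return json.dumps(payload, indent=2, default=str)


def build_schedule(grid: DifficultyGrid | None = None, seed: int = 0) -> TrialSchedule:
    """Build one seeded 16-trial schedule.

    Trials 1-3 are the fixed lead block.  Trials 4-16 contain the remaining
    12 non-baseline cells plus one repeated cell (chosen at random among all
    non-baseline cells) in seeded-random order, so every non-baseline cell is
    visited at least once and exactly one cell twice.  The no-challenge cell
    is scored from the baseline walk, not from a trial.
    """
    grid = grid or build_default_grid()
    rng = np.random.default_rng(seed)
    non_baseline = grid.non_baseline_cells()
    remaining = [cell for cell in non_baseline if cell not in LEAD_BLOCK]
    repeat = non_baseline[int(rng.integers(len(non_baseline)))]
    tail = remaining + [repeat]
    order = rng.permutation(len(tail))
    tail = [tail[i] for i in order]
    cells = list(LEAD_BLOCK) + tail
    lo, hi = DURATION_RANGE_MIN
    durations = rng.uniform(lo, hi, size=len(cells))
    trials = tuple(
        Trial(
            index=i + 1,
            trial_type=classify_trial_type(m, c, grid),
            motor=m,
            cognitive=c,
            duration_min=float(d),
        )
        for i, ((m, c), d) in enumerate(zip(cells, durations))
    )
    return TrialSchedule(trials=trials, seed=int(seed))
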