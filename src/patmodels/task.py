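"""Passive-active Approach-avoidance Task (PAT) structure.

The PAT crosses money on offer (1-5 euros), threat magnitude (1-5 electric
shocks) and action context (whether approaching requires a button press or
withholding one).  Each run contains one repetition of the full 5 x 5 x 2
factorial with long anticipation-to-movement intervals (AMI, 6-7 s; the
trials that enter cardiac analyses) plus 12 filler trials with short AMIs
(0.5-5.5 s) that keep participants engaged, for 62 trials per run.
Approaching yields money with probability .40, shocks with .40 and nothing
with .20; avoiding yields nothing with .80 and money/shocks with .10 each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

ACTION_CONTEXTS = ("active", "passive")


@dataclass
class TaskConfig:
    """Task constants. Defaults reproduce the standard PAT session."""

    money_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    shock_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_runs: int = 3
    long_ami_range: tuple[float, float] = (6.0, 7.0)
    short_ami_range: tuple[float, float] = (0.5, 5.5)
    n_short_per_run: int = 12
    iti_range: tuple[float, float] = (9.0, 11.0)
    movement_window: float = 0.7
    outcome_screen: float = 1.5
    #: P(money, shocks, nothing) after an approach choice.
    p_outcome_approach: tuple[float, float, float] = (0.40, 0.40, 0.20)
    #: P(money, shocks, nothing) after an avoid choice.
    p_outcome_avoid: tuple[float, float, float] = (0.10, 0.10, 0.80)
    tr: float = 1.5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("money_levels", "shock_levels"):
            levels = getattr(self, name)
            if len(levels) != 5 or len(set(levels)) != 5:
                raise ConfigurationError(f"{name} must hold 5 distinct levels")
        for name in ("p_outcome_approach", "p_outcome_avoid"):
            triple = getattr(self, name)
            if len(triple) != 3 or any(p < 0 for p in triple):
                raise ConfigurationError(f"{name} must be 3 nonnegative probabilities")
            if abs(sum(triple) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {sum(triple)})")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        lo_s, hi_s = self.short_ami_range
        lo_l, hi_l = self.long_ami_range
        if not (lo_s < hi_s and lo_l < hi_l):
            raise ConfigurationError("AMI ranges must be increasing")
        if hi_s >= lo_l:
            raise ConfigurationError("short and long AMI ranges must be disjoint")

    @property
    def n_long_per_run(self) -> int:
        return len(self.money_levels) * len(self.shock_levels) * len(ACTION_CONTEXTS)

    @property
    def n_trials_per_run(self) -> int:
        return self.n_long_per_run + self.n_short_per_run


def factorial_cells(config: TaskConfig) -> list[tuple[int, int, str]]:
    """All (money, shocks, action_context) cells of the design."""
    return [
        (m, s, ac)
        for m in config.money_levels
        for s in config.shock_levels
        for ac in ACTION_CONTEXTS
    ]


def build_schedule(
    config: TaskConfig, n_subjects: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Generate per-subject trial schedules.

    Per run: the full factorial once with long AMIs, plus ``n_short_per_run``
    short-AMI trials whose conditions are drawn without replacement from the
    factorial cells (preserving marginal balance), shuffled together.  Trial
    onsets accumulate ITI + AMI + movement window + outcome screen.

    Returns a table with one row per trial: ``subject, run, trial, money,
    shocks, action_context, ami, onset, is_long``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cells = factorial_cells(config)
    if config.n_short_per_run > len(cells):
        raise ConfigurationError("n_short_per_run exceeds number of factorial cells")

    rows = []
    for subject in range(n_subjects):
        for run in range(config.n_runs):
            long_part = [(m, s, ac, True) for (m, s, ac) in cells]
            short_cells = [
                cells[i]
                for i in rng.choice(len(cells), size=config.n_short_per_run, replace=False)
            ]
            short_part = [(m, s, ac, False) for (m, s, ac) in short_cells]
            trials = long_part + short_part
            order = rng.permutation(len(trials))
            t = 0.0
            for idx, j in enumerate(order):
                m, s, ac, is_long = trials[j]
                iti = rng.uniform(*config.iti_range)
                lo, hi = config.long_ami_range if is_long else config.short_ami_range
                ami = rng.uniform(lo, hi)
                onset = t + iti  # anticipation-screen onset
                t = onset + ami + config.movement_window + config.outcome_screen
                rows.append(
                    (subject, run, idx, m, s, ac, ami, onset, is_long)
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject", "run", "trial", "money", "shocks", "action_context",
            "ami", "onset", "is_long",
        ],
    )
    return frame


def shock_workup(ratings) -> tuple[int, list[int]]:
    """Adaptive shock-intensity staircase.

    Five shocks are delivered, starting at intensity level 2 (of 10).  After
    each subjective pain rating (1-5) the level for the next shock is raised
    by one if the rating was <= 3, lowered by one if it was 5, and held if it
    was 4, clipped to [1, 10].  Returns the level at which the fifth shock
    was delivered and the full level trajectory.
    """
    ratings = list(ratings)
    if len(ratings) != 5:
        raise DataError(f"shock workup needs exactly 5 ratings, got {len(ratings)}")
    if any((not float(r).is_integer()) or not (1 <= r <= 5) for r in ratings):
        raise DataError("ratings must be integers in 1..5")
    level = 2
    trajectory = [level]
    for rating in ratings[:-1]:  # level only updates before the next shock
        if rating <= 3:
            level += 1
        elif rating == 5:
            level -= 1
        level = min(10, max(1, level))
        trajectory.append(level)
    return trajectory[-1], trajectory
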