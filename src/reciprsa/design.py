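"""Task structure and payoff arithmetic for the reciprocal partner-choice task.

The task crosses three reciprocal-efficiency conditions with nine benefactor
cost levels (27 cells per run).  On every trial the participant picks one of
two benefactors (altruistic vs. strategic) and allocates part of a fixed
endowment to the chosen one; the benefactor receives the allocation scaled by
that benefactor's efficiency multiplier.  Everything downstream (simulation,
behavioral statistics, RSA condition grids) references the constants and
types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "COSTS",
    "ENDOWMENT",
    "PAIN_CONVERSION_RATE",
    "PAIN_REDUCTION_CAP_S",
    "CHOICE_ALTRUISTIC",
    "CHOICE_STRATEGIC",
    "EfficiencyCondition",
    "CONDITION_ORDER",
    "Trial",
    "Design",
    "build_design",
    "pain_reduction",
    "benefactor_receipt",
    "relative_self_payoff",
]

#: Benefactor cost levels (yuan); unknown levels are rejected, never binned.
COSTS: tuple[int, ...] = (4, 6, 8, 10, 12, 14, 16, 18, 20)

#: Participant endowment available for allocation (yuan).
ENDOWMENT: int = 25

#: Seconds of pain reduction per yuan the benefactor spends.
PAIN_CONVERSION_RATE: float = 0.8

#: Upper bound on pain reduction (s), reached at the maximum cost.
PAIN_REDUCTION_CAP_S: float = 16.0

CHOICE_ALTRUISTIC = "altruistic"
CHOICE_STRATEGIC = "strategic"
_VALID_CHOICES = (CHOICE_ALTRUISTIC, CHOICE_STRATEGIC)


class EfficiencyCondition(str, Enum):
    """One of the three efficiency conditions.

    The label encodes the (altruistic, strategic) efficiency multipliers:
    ``A1S3`` -> (1, 3), ``A1S1`` -> (1, 1), ``A3S1`` -> (3, 1).
    """

    A1S3 = "A1S3"
    A1S1 = "A1S1"
    A3S1 = "A3S1"

    @property
    def eff_altruistic(self) -> int:
        return int(self.value[1])

    @property
    def eff_strategic(self) -> int:
        return int(self.value[3])

    def efficiency_of(self, benefactor_type: str) -> int:
        """Multiplier applying to an allocation to ``benefactor_type``."""
        if benefactor_type == CHOICE_ALTRUISTIC:
            return self.eff_altruistic
        if benefactor_type == CHOICE_STRATEGIC:
            return self.eff_strategic
        raise ValueError(f"unknown benefactor type: {benefactor_type!r}")


#: Canonical condition order used for trends, contrasts, and RDM grids.
CONDITION_ORDER: tuple[EfficiencyCondition, ...] = (
    EfficiencyCondition.A1S3,
    EfficiencyCondition.A1S1,
    EfficiencyCondition.A3S1,
)


@dataclass
class Trial:
    """One interaction round.

    ``choice`` and ``allocation`` are ``None`` for design skeletons and for
    missed responses; missing responses are excluded from all statistics.
    """

    participant_id: str
    run: int
    condition: EfficiencyCondition
    cost: int
    choice: str | None = None
    allocation: int | None = None

    def __post_init__(self) -> None:
        if self.cost not in COSTS:
            raise ValueError(f"cost {self.cost} not in allowed levels {COSTS}")
        if self.choice is not None and self.choice not in _VALID_CHOICES:
            raise ValueError(f"invalid choice {self.choice!r}")
        if self.allocation is not None:
            if self.choice is None:
                raise ValueError("allocation present without a choice")
            if not 0 <= self.allocation <= ENDOWMENT:
                raise ValueError(
                    f"allocation {self.allocation} outside [0, {ENDOWMENT}]"
                )


@dataclass
class Design:
    """Ordered trial skeletons: each run holds one trial per design cell."""

    trials: list[Trial] = field(default_factory=list)
    n_runs: int = 3
    trials_per_run: int = len(COSTS) * len(CONDITION_ORDER)


def build_design(
    n_runs: int, seed: int, participant_id: str = "sim"
) -> Design:
    """Build the within-subject design: ``n_runs`` x 27 trial skeletons.

    Each run contains every (condition, cost) cell exactly once, in an order
    shuffled by ``seed`` (one independent shuffle per run).

    Raises
    ------
    ValueError
        If ``n_runs < 1``.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed)
    cells = [(cond, cost) for cond in CONDITION_ORDER for cost in COSTS]
    trials: list[Trial] = []
    for run in range(1, n_runs + 1):
        order = rng.permutation(len(cells))
        for idx in order:
            cond, cost = cells[idx]
            trials.append(
                Trial(
                    participant_id=participant_id,
                    run=run,
                    condition=cond,
                    cost=cost,
                )
            )
    return Design(trials=trials, n_runs=n_runs, trials_per_run=len(cells))


def pain_reduction(cost: float) -> float:
    """Seconds of pain reduction bought by a benefactor cost (yuan).

    Linear at ``PAIN_CONVERSION_RATE`` s/yuan, capped at
    ``PAIN_REDUCTION_CAP_S``.
    """
    if not 0 <= cost <= 20:
        raise ValueError(f"cost {cost} outside [0, 20]")
    return min(PAIN_CONVERSION_RATE * cost, PAIN_REDUCTION_CAP_S)


def benefactor_receipt(allocation: float, efficiency: int) -> float:
    """Yuan received by the benefactor: allocation scaled by efficiency."""
    if not 0 <= allocation <= ENDOWMENT:
        raise ValueError(f"allocation {allocation} outside [0, {ENDOWMENT}]")
    if efficiency not in (1, 3):
        raise ValueError(f"efficiency must be 1 or 3, got {efficiency}")
    return efficiency * allocation


def relative_self_payoff(
    allocation: float, efficiency: int, endowment: float = ENDOWMENT
) -> float:
    """Self-interest index in [0, 1].

    ``kept / (kept + efficiency * allocation)`` with
    ``kept = endowment - allocation``; 1.0 when nothing is given, 0.0 when
    everything is given.
    """
    if endowment <= 0:
        raise ValueError("endowment must be positive")
    if not 0 <= allocation <= endowment:
        raise ValueError(
            f"allocation {allocation} outside [0, {endowment}]"
        )
    kept = endowment - allocation
    return kept / (kept + efficiency * allocation)
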