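"""LC-CUSUM chart construction and execution.

The learning-curve CUSUM (LC-CUSUM) is a sequential test for competency
acquisition.  Unlike a classical CUSUM, which assumes a process in control
and signals deterioration, the LC-CUSUM assumes the learner is *not yet*
competent (null hypothesis: per-procedure failure rate at an unacceptable
level ``p0``) and signals competency once the accumulated log-likelihood
ratio in favour of an adequate failure rate ``p1 < p0`` crosses an
in-control limit ``h``.

The chart score :math:`S_t` evolves per procedure as

.. math:: S_t = \\max(0,\\; S_{t-1} + W_t), \\qquad
          W_t = \\begin{cases}
              \\ln\\frac{1-p_1}{1-p_0} & \\text{success} \\\\
              \\ln\\frac{p_1}{p_0}     & \\text{failure}
          \\end{cases}

with a holding barrier at 0 and a signal when :math:`S_t \\ge h`.

Two parameterizations are provided:

* :class:`MonitoringDesign` — the continuous-score chart with likelihood
  ratio increments derived from ``(p1, delta)``.  With the default
  clinical parameters (adequate failure rate 10%, equivalence zone 5%,
  h = 0.74) the increments are +0.057 per success and −0.405 per failure
  and 13 consecutive successes are required to signal.
* :class:`IntegerProgramDesign` — a didactically simplified integer
  variant (+1 per success, −7 per failure, limit 13) used to score a
  three-level mastery-learning program.  Each competency level occupies a
  band of 13 score units (0–13, 13–26, 26–39), the score is clamped at
  the current level's floor, and passing the program means signalling
  all three levels within a per-level cap of 50 procedures — so the
  fastest possible pass takes exactly 39 procedures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "MonitoringDesign",
    "IntegerProgramDesign",
    "ChartState",
    "ProgramResult",
    "LevelChart",
    "build_design",
    "default_integer_design",
    "update_chart",
    "run_chart",
    "run_level",
    "run_integer_program",
    "consecutive_successes_to_signal",
]

#: Absolute tolerance used when comparing a floating chart score against
#: the signal limit; guards exact-hit cases such as 13 unit steps vs h=13.
SIGNAL_TOL = 1e-12


class DesignError(ValueError):
    """Invalid monitoring-design parameter."""


class AbsorbingStateError(RuntimeError):
    """An already-signalled chart state was updated."""


@dataclass(frozen=True)
class MonitoringDesign:
    """Continuous LC-CUSUM design.

    Parameters are the clinical quantities; the score increments are the
    Bernoulli log-likelihood ratios and are stored at full floating
    precision (printed 3-dp values are a presentation rounding).
    """

    acceptable_failure_rate: float
    equivalence_delta: float
    signal_limit: float
    horizon: int
    unacceptable_failure_rate: float
    success_increment: float
    failure_increment: float

    def __post_init__(self) -> None:
        p1, d = self.acceptable_failure_rate, self.equivalence_delta
        if not (0.0 < p1 < 1.0):
            raise DesignError(
                f"acceptable_failure_rate must be in (0,1), got {p1}"
            )
        if d <= 0.0:
            raise DesignError(
                f"equivalence_delta must be > 0 (a zero-width equivalence "
                f"zone makes both increments 0), got {d}"
            )
        if p1 + d >= 1.0:
            raise DesignError(
                "unacceptable_failure_rate = acceptable_failure_rate + "
                f"equivalence_delta must be < 1, got {p1 + d}"
            )
        if self.signal_limit <= 0.0:
            raise DesignError(f"signal_limit must be > 0, got {self.signal_limit}")
        if self.horizon < 1:
            raise DesignError(f"horizon must be >= 1, got {self.horizon}")
        if not self.success_increment > 0.0:
            raise DesignError(
                f"success_increment must be > 0, got {self.success_increment}"
            )
        if not self.failure_increment < 0.0:
            raise DesignError(
                f"failure_increment must be < 0, got {self.failure_increment}"
            )
        if self.signal_limit / self.success_increment > self.horizon + SIGNAL_TOL:
            raise DesignError(
                "signal_limit unreachable within horizon: "
                f"{self.signal_limit}/{self.success_increment} > {self.horizon}"
            )


def build_design(
    acceptable_failure_rate: float,
    equivalence_delta: float,
    signal_limit: float = 0.74,
    horizon: int = 50,
) -> MonitoringDesign:
    """Construct a continuous LC-CUSUM design from clinical parameters.

    The increments are the Bernoulli log-likelihood-ratio scores

    ``success_increment = ln((1 - p1) / (1 - p0))`` and
    ``failure_increment = ln(p1 / p0)`` with ``p0 = p1 + delta``.

    With ``(0.10, 0.05)`` this yields +0.0572 / −0.4055, i.e. +0.057 and
    −0.405 at three decimals.

    Raises
    ------
    DesignError
        If any rate is out of range, the equivalence zone is degenerate,
        or the limit cannot be reached within the horizon.
    """
    p1 = acceptable_failure_rate
    d = equivalence_delta
    if not (0.0 < p1 < 1.0):
        raise DesignError(f"acceptable_failure_rate must be in (0,1), got {p1}")
    if d <= 0.0:
        raise DesignError(f"equivalence_delta must be > 0, got {d}")
    p0 = p1 + d
    if p0 >= 1.0:
        raise DesignError(
            f"acceptable_failure_rate + equivalence_delta must be < 1, got {p0}"
        )
    return MonitoringDesign(
        acceptable_failure_rate=p1,
        equivalence_delta=d,
        signal_limit=signal_limit,
        horizon=horizon,
        unacceptable_failure_rate=p0,
        success_increment=math.log((1.0 - p1) / (1.0 - p0)),
        failure_increment=math.log(p1 / p0),
    )


@dataclass(frozen=True)
class IntegerProgramDesign:
    """Integer-scored multi-level mastery program design.

    Defaults are the simplified scheme: +1 per success, −7 per failure,
    13 score units per competency level, 3 levels, at most 50 procedures
    per level.  ``program_target`` (= n_levels × level_width = 39) is the
    score that completes the program and the minimum number of
    procedures with which it can be passed.
    """

    success_step: int = 1
    failure_step: int = -7
    level_width: int = 13
    n_levels: int = 3
    per_level_cap: int = 50

    def __post_init__(self) -> None:
        if not self.success_step > 0:
            raise DesignError(f"success_step must be > 0, got {self.success_step}")
        if not self.failure_step < 0:
            raise DesignError(f"failure_step must be < 0, got {self.failure_step}")
        if self.level_width <= 0:
            raise DesignError(f"level_width must be > 0, got {self.level_width}")
        if self.n_levels <= 0:
            raise DesignError(f"n_levels must be > 0, got {self.n_levels}")
        if self.per_level_cap < self.level_width / self.success_step:
            raise DesignError(
                f"per_level_cap {self.per_level_cap} cannot accommodate a "
                f"signal (needs >= {self.level_width / self.success_step})"
            )

    @property
    def program_target(self) -> int:
        return self.n_levels * self.level_width


def default_integer_design() -> IntegerProgramDesign:
    """The operational integer design: +1/−7, width 13, 3 levels, cap 50."""
    return IntegerProgramDesign()


@dataclass(frozen=True)
class ChartState:
    """Evolving state of a single chart; absorbing once signalled."""

    score: float = 0.0
    procedures_observed: int = 0
    signalled: bool = False
    signal_index: Optional[int] = None
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.score < self.floor - SIGNAL_TOL:
            raise ValueError(f"score {self.score} below floor {self.floor}")
        if self.signalled != (self.signal_index is not None):
            raise ValueError("signal_index must be set iff signalled")


def update_chart(
    state: ChartState, passed: bool, design: MonitoringDesign
) -> ChartState:
    """Advance a continuous chart by one procedure outcome.

    The new score is ``max(floor, score + increment)``; the chart signals
    when the score reaches ``signal_limit``.  Updating an
    already-signalled state raises :class:`AbsorbingStateError`.
    """
    if state.signalled:
        raise AbsorbingStateError("chart already signalled; state is absorbing")
    inc = design.success_increment if passed else design.failure_increment
    score = max(state.floor, state.score + inc)
    n = state.procedures_observed + 1
    signalled = score >= design.signal_limit - SIGNAL_TOL
    return replace(
        state,
        score=score,
        procedures_observed=n,
        signalled=signalled,
        signal_index=n if signalled else None,
    )


def run_chart(
    outcomes: Iterable[bool], design: MonitoringDesign
) -> tuple[list[float], Optional[int]]:
    """Fold a pass/fail sequence through a fresh continuous chart.

    Returns the score trajectory (one entry per consumed outcome) and the
    1-based procedure index of the first signal, or ``None``.  Updating
    stops at the signal.  Sequences longer than the design horizon are
    truncated with a warning.
    """
    outcomes = list(outcomes)
    if len(outcomes) > design.horizon:
        warnings.warn(
            f"outcome sequence of length {len(outcomes)} truncated to "
            f"horizon {design.horizon}",
            stacklevel=2,
        )
        outcomes = outcomes[: design.horizon]
    state = ChartState()
    trajectory: list[float] = []
    for passed in outcomes:
        state = update_chart(state, bool(passed), design)
        trajectory.append(state.score)
        if state.signalled:
            break
    return trajectory, state.signal_index


def consecutive_successes_to_signal(
    design: MonitoringDesign | IntegerProgramDesign,
) -> int:
    """Number of consecutive successes needed to signal from the floor."""
    if isinstance(design, IntegerProgramDesign):
        return math.ceil(design.level_width / design.success_step)
    return math.ceil((design.signal_limit - SIGNAL_TOL) / design.success_increment)


class LevelChart:
    """Stateful integer chart for one competency level.

    Scores live in the band ``[floor, floor + level_width]`` where
    ``floor = level * level_width``; a failure can never push the score
    below the floor, and the level signals when the score reaches the
    band's ceiling.
    """

    def __init__(self, design: IntegerProgramDesign, level: int) -> None:
        if not 0 <= level < design.n_levels:
            raise DesignError(
                f"level must be in [0, {design.n_levels}), got {level}"
            )
        self.design = design
        self.level = level
        self.floor = level * design.level_width
        self.ceiling = self.floor + design.level_width
        self.score: int = self.floor
        self.procedures_observed = 0
        self.signal_index: Optional[int] = None

    @property
    def signalled(self) -> bool:
        return self.signal_index is not None

    def update(self, passed: bool) -> int:
        if self.signalled:
            raise AbsorbingStateError("level already signalled")
        step = self.design.success_step if passed else self.design.failure_step
        self.score = max(self.floor, self.score + step)
        self.procedures_observed += 1
        if self.score >= self.ceiling:
            self.signal_index = self.procedures_observed
        return self.score


def run_level(
    outcomes: Iterable[bool],
    design: IntegerProgramDesign,
    level: int = 0,
    allow_overrun: bool = False,
) -> tuple[list[int], Optional[int]]:
    """Run one integer level over a pass/fail sequence.

    Consumes at most ``per_level_cap`` outcomes unless ``allow_overrun``;
    stops at the signal.  Returns (trajectory, 1-based signal index).
    """
    chart = LevelChart(design, level)
    trajectory: list[int] = []
    for passed in outcomes:
        if not allow_overrun and chart.procedures_observed >= design.per_level_cap:
            break
        trajectory.append(chart.update(bool(passed)))
        if chart.signalled:
            break
    return trajectory, chart.signal_index


@dataclass(frozen=True)
class ProgramResult:
    """Outcome of running the full multi-level integer program."""

    per_level_traces: tuple[tuple[int, ...], ...]
    per_level_signalled: tuple[bool, ...]
    per_level_signal_indices: tuple[Optional[int], ...]
    per_level_procedure_counts: tuple[int, ...]
    total_procedures: int
    program_passed: bool

    def __post_init__(self) -> None:
        if self.total_procedures != sum(self.per_level_procedure_counts):
            raise ValueError("total_procedures must equal sum of level counts")


def run_integer_program(
    outcomes_by_level: Sequence[Sequence[bool]],
    design: IntegerProgramDesign | None = None,
    allow_overrun: bool = False,
) -> ProgramResult:
    """Run the multi-level integer program over per-level outcome streams.

    Within level ``k`` the score starts at the floor ``k * level_width``
    and signals at the band ceiling.  Passing the program requires every
    level to signal within ``per_level_cap`` procedures.  By default
    evaluation stops at the first failed level; with ``allow_overrun``
    all levels are evaluated in full and a level may keep accumulating
    outcomes past the cap (the recorded trace extends, but the pass/fail
    verdict still applies the cap).
    """
    if design is None:
        design = default_integer_design()
    if len(outcomes_by_level) != design.n_levels:
        raise DesignError(
            f"expected {design.n_levels} outcome sequences, "
            f"got {len(outcomes_by_level)}"
        )
    traces: list[tuple[int, ...]] = []
    signalled_within_cap: list[bool] = []
    signal_indices: list[Optional[int]] = []
    counts: list[int] = []
    for level, outcomes in enumerate(outcomes_by_level):
        trace, sig = run_level(outcomes, design, level, allow_overrun=allow_overrun)
        traces.append(tuple(trace))
        signal_indices.append(sig)
        counts.append(len(trace))
        within = sig is not None and sig <= design.per_level_cap
        signalled_within_cap.append(within)
        if not within and not allow_overrun:
            # remaining levels are not attempted
            for _ in range(level + 1, design.n_levels):
                traces.append(())
                signal_indices.append(None)
                counts.append(0)
                signalled_within_cap.append(False)
            break
    return ProgramResult(
        per_level_traces=tuple(traces),
        per_level_signalled=tuple(signalled_within_cap),
        per_level_signal_indices=tuple(signal_indices),
        per_level_procedure_counts=tuple(counts),
        total_procedures=sum(counts),
        program_passed=all(signalled_within_cap),
    )
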