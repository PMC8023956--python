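"""Operating characteristics of LC-CUSUM designs.

Answers the design question behind a competency chart: if a learner's
true per-procedure failure rate is r, what is the probability that the
chart signals competency within the monitoring horizon, and when?

Two routes are provided and kept deliberately independent of each other:

* :func:`signal_probability_exact` — a forward dynamic program over the
  exact set of reachable clamped scores.  Because the success and
  failure increments are incommensurable reals, a rounded score grid
  would introduce discretization error; instead each reachable state is
  keyed by the lattice coordinates (number of successes, number of
  failures) accumulated since the chart last touched the floor, which
  identifies the score exactly.  Mass is absorbed when a success step
  crosses the limit.
* :func:`signal_probability_mc` — a vectorized Monte Carlo simulation
  with an explicit seed and a binomial standard error, used as the
  stochastic oracle for the DP (and vice versa).

:func:`calibrate_limit` inverts the exact OC: it finds the largest limit
on a user grid whose signal probability at a reference failure rate
still meets a power target.  The OC is a step function of h (it only
changes when h crosses a reachable score), which is why a grid search,
not bisection on a continuum, is the right tool.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .charts import (
    SIGNAL_TOL,
    DesignError,
    IntegerProgramDesign,
    MonitoringDesign,
    build_design,
)

__all__ = [
    "OCQuery",
    "OCResult",
    "CalibrationResult",
    "UnattainableError",
    "signal_probability_exact",
    "signal_probability_mc",
    "program_pass_probability",
    "calibrate_limit",
]

Design = Union[MonitoringDesign, IntegerProgramDesign]


@dataclass(frozen=True)
class OCQuery:
    """A single operating-characteristic question.

    ``horizon`` defaults to the design's own horizon (continuous) or the
    per-level cap (integer variant).
    """

    design: Design
    true_failure_rate: float
    horizon: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_failure_rate <= 1.0:
            raise DesignError(
                f"true_failure_rate must be in [0,1], got {self.true_failure_rate}"
            )
        if self.horizon is not None and self.horizon < 1:
            raise DesignError(f"horizon must be >= 1, got {self.horizon}")

    @property
    def effective_horizon(self) -> int:
        if self.horizon is not None:
            return self.horizon
        if isinstance(self.design, IntegerProgramDesign):
            return self.design.per_level_cap
        return self.design.horizon

    @property
    def steps(self) -> tuple[float, float, float]:
        """(success step, failure step, signal limit) relative to floor 0."""
        d = self.design
        if isinstance(d, IntegerProgramDesign):
            return float(d.success_step), float(d.failure_step), float(d.level_width)
        return d.success_increment, d.failure_increment, d.signal_limit


@dataclass(frozen=True)
class OCResult:
    """Signal probability and run-length distribution over a horizon."""

    signal_probability: float
    run_length_pmf: Mapping[int, float]
    no_signal_probability: float
    standard_error: Optional[float] = None

    def expected_run_length(self) -> float:
        """Mean signal time conditional on signalling (nan if never)."""
        if self.signal_probability == 0.0:
            return float("nan")
        num = sum(t * p for t, p in self.run_length_pmf.items())
        return num / self.signal_probability


def signal_probability_exact(query: OCQuery) -> OCResult:
    """Exact first-signal distribution by forward dynamic programming.

    States are keyed by (successes, failures) since the last floor
    contact; the chart score is ``up*i + down*j`` which is exact for
    every reachable state.  Deterministic, O(horizon x reachable states).
    """
    up, down, limit = query.steps
    r = query.true_failure_rate
    horizon = query.effective_horizon
    q = 1.0 - r
    states: dict[tuple[int, int], float] = {(0, 0): 1.0}
    pmf: dict[int, float] = {}
    for t in range(1, horizon + 1):
        new: dict[tuple[int, int], float] = defaultdict(float)
        absorbed = 0.0
        for (i, j), mass in states.items():
            score = up * i + down * j
            if q > 0.0:
                if score + up >= limit - SIGNAL_TOL:
                    absorbed += mass * q
                else:
                    new[(i + 1, j)] += mass * q
            if r > 0.0:
                if score + down <= SIGNAL_TOL:
                    new[(0, 0)] += mass * r
                else:
                    new[(i, j + 1)] += mass * r
        if absorbed > 0.0:
            pmf[t] = absorbed
        states = dict(new)
    return OCResult(
        signal_probability=sum(pmf.values()),
        run_length_pmf=pmf,
        no_signal_probability=sum(states.values()),
    )


def signal_probability_mc(
    query: OCQuery, replicates: int, seed: int
) -> OCResult:
    """Monte Carlo estimate of the first-signal distribution.

    Unbiased, with a binomial standard error on the signal probability;
    fully reproducible under a fixed seed.
    """
    if replicates < 1:
        raise DesignError(f"replicates must be >= 1, got {replicates}")
    up, down, limit = query.steps
    r = query.true_failure_rate
    horizon = query.effective_horizon
    rng = np.random.default_rng(seed)
    scores = np.zeros(replicates)
    active = np.ones(replicates, dtype=bool)
    signal_time = np.zeros(replicates, dtype=np.int64)
    for t in range(1, horizon + 1):
        if not active.any():
            break
        fails = rng.random(replicates) < r
        step = np.where(fails, down, up)
        scores = np.where(active, np.maximum(0.0, scores + step), scores)
        newly = active & (scores >= limit - SIGNAL_TOL)
        signal_time[newly] = t
        active &= ~newly
    n_signal = int((signal_time > 0).sum())
    p_hat = n_signal / replicates
    times, counts = np.unique(signal_time[signal_time > 0], return_counts=True)
    pmf = {int(t): int(c) / replicates for t, c in zip(times, counts)}
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / replicates))
    return OCResult(
        signal_probability=p_hat,
        run_length_pmf=pmf,
        no_signal_probability=1.0 - p_hat,
        standard_error=se,
    )


def program_pass_probability(
    design: IntegerProgramDesign,
    true_failure_rate: Union[float, Sequence[float]],
    per_level_cap: Optional[int] = None,
) -> float:
    """Probability of passing the whole multi-level program.

    Procedures are independent Bernoulli trials; after shifting away the
    level floor every level is probabilistically identical, so with a
    constant rate the program pass probability is the single-level
    signal probability raised to the number of levels.  A sequence of
    per-level rates (one per level, e.g. reflecting retained skill) is
    also accepted.
    """
    cap = per_level_cap if per_level_cap is not None else design.per_level_cap
    if np.isscalar(true_failure_rate):
        rates = [float(true_failure_rate)] * design.n_levels
    else:
        rates = [float(r) for r in true_failure_rate]  # type: ignore[union-attr]
        if len(rates) != design.n_levels:
            raise DesignError(
                f"expected {design.n_levels} per-level rates, got {len(rates)}"
            )
    prob = 1.0
    cache: dict[float, float] = {}
    for r in rates:
        if r not in cache:
            res = signal_probability_exact(
                OCQuery(design=design, true_failure_rate=r, horizon=cap)
            )
            cache[r] = res.signal_probability
        prob *= cache[r]
    return prob


class UnattainableError(ValueError):
    """No grid limit achieves the requested signal probability."""

    def __init__(self, message: str, best_achievable: float) -> None:
        super().__init__(message)
        self.best_achievable = best_achievable


@dataclass(frozen=True)
class CalibrationResult:
    """Chosen signal limit plus the OC it achieves at both design rates."""

    signal_limit: float
    achieved_probability: float
    probability_at_acceptable: float
    probability_at_unacceptable: float


def calibrate_limit(
    acceptable_failure_rate: float,
    equivalence_delta: float,
    horizon: int,
    target_signal_probability: float,
    rate_for_target: float,
    grid_step: float = 0.01,
) -> CalibrationResult:
    """Choose the signal limit h on a grid to meet a power target.

    Returns the *largest* multiple of ``grid_step`` whose exact signal
    probability at ``rate_for_target`` meets or exceeds the target — the
    most conservative limit still delivering the requested power.  The
    result also reports the achieved probability at the acceptable and
    unacceptable failure rates (true positive / false positive over the
    horizon).

    Raises
    ------
    UnattainableError
        If no grid limit meets the target; carries the best achievable
        probability (at the smallest grid limit).
    """
    if not (0.0 < target_signal_probability < 1.0) and target_signal_probability != 1.0:
        raise DesignError(
            f"target_signal_probability must be in (0,1], got "
            f"{target_signal_probability}"
        )
    if grid_step <= 0.0:
        raise DesignError(f"grid_step must be > 0, got {grid_step}")

    def design_at(h: float) -> MonitoringDesign:
        return build_design(
            acceptable_failure_rate, equivalence_delta, signal_limit=h, horizon=horizon
        )

    max_reach = design_at(grid_step).success_increment * horizon
    k_max = int(np.floor((max_reach + SIGNAL_TOL) / grid_step))
    if k_max < 1:
        raise DesignError("grid_step exceeds the maximum reachable score")

    def prob_at(k: int) -> float:
        h = round(k * grid_step, 12)
        res = signal_probability_exact(
            OCQuery(design=design_at(h), true_failure_rate=rate_for_target)
        )
        return res.signal_probability

    # signal probability is non-increasing in h: binary search for the
    # largest grid index still meeting the target
    lo, hi = 1, k_max
    if prob_at(lo) < target_signal_probability:
        raise UnattainableError(
            f"target {target_signal_probability} unattainable at rate "
            f"{rate_for_target} over horizon {horizon}; best achievable is "
            f"{prob_at(lo)} at h={round(grid_step, 12)}",
            best_achievable=prob_at(lo),
        )
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if prob_at(mid) >= target_signal_probability:
            lo = mid
        else:
            hi = mid - 1
    h = round(lo * grid_step, 12)
    chosen = design_at(h)
    at_p1 = signal_probability_exact(
        OCQuery(design=chosen, true_failure_rate=chosen.acceptable_failure_rate)
    ).signal_probability
    at_p0 = signal_probability_exact(
        OCQuery(design=chosen, true_failure_rate=chosen.unacceptable_failure_rate)
    ).signal_probability
    return CalibrationResult(
        signal_limit=h,
        achieved_probability=prob_at(lo),
        probability_at_acceptable=at_p1,
        probability_at_unacceptable=at_p0,
    )
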