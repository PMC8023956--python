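"""Operating characteristics: exact DP, Monte Carlo oracle, calibration."""

import itertools
import math

import numpy as np
import pytest

from lccusum.charts import IntegerProgramDesign, build_design, run_chart
from lccusum.oc import (
    OCQuery,
    UnattainableError,
    calibrate_limit,
    program_pass_probability,
    signal_probability_exact,
    signal_probability_mc,
)

RATES = (0.0, 0.05, 0.10, 0.15, 0.30, 1.0)


def enumerate_signal_pmf(design, rate, horizon):
    """Brute-force oracle: weight every outcome sequence by its probability.

    Runs the chart engine (not the DP) over all 2^horizon sequences, so it
    is independent of the dynamic program it checks.
    """
    pmf = {}
    for outcomes in itertools.product([True, False], repeat=horizon):
        _, sig = run_chart(list(outcomes), design)
        if sig is None:
            continue
        # probability of the prefix that was actually consumed
        prob = 1.0
        for passed in outcomes[:sig]:
            prob *= (1.0 - rate) if passed else rate
        if prob == 0.0:
            continue
        # remaining outcomes are unconstrained; each full sequence carries
        # the prefix probability split over 2^(horizon - sig) continuations
        pmf[sig] = pmf.get(sig, 0.0) + prob / 2 ** (horizon - sig)
    return pmf


class TestExactDP:
    def test_zero_failure_rate_concentrates_at_minimum_signal_time(self, clinical_design):
        res = signal_probability_exact(OCQuery(clinical_design, 0.0))
        assert res.signal_probability == pytest.approx(1.0)
        assert res.run_length_pmf == {13: pytest.approx(1.0)}

    def test_certain_failure_never_signals(self, clinical_design):
        res = signal_probability_exact(OCQuery(clinical_design, 1.0))
        assert res.signal_probability == 0.0
        assert res.no_signal_probability == pytest.approx(1.0)

    @pytest.mark.parametrize("rate", RATES)
    def test_mass_conservation(self, clinical_design, rate):
        res = signal_probability_exact(OCQuery(clinical_design, rate))
        total = sum(res.run_length_pmf.values()) + res.no_signal_probability
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("rate", [0.05, 0.10, 0.30])
    def test_no_mass_before_minimum_signal_time(self, clinical_design, rate):
        res = signal_probability_exact(OCQuery(clinical_design, rate))
        assert res.run_length_pmf and min(res.run_length_pmf) == 13

    @pytest.mark.parametrize("rate", [0.0, 0.2, 0.5])
    def test_dp_matches_brute_force_enumeration(self, rate):
        # small design where 3 consecutive successes signal, horizon 8:
        # 2^8 sequences are exhaustively enumerable
        design = build_design(0.2, 0.2, signal_limit=0.8, horizon=8)
        oracle = enumerate_signal_pmf(design, rate, 8)
        res = signal_probability_exact(OCQuery(design, rate))
        assert set(res.run_length_pmf) == set(oracle)
        for t, p in oracle.items():
            assert res.run_length_pmf[t] == pytest.approx(p, abs=1e-12)

    def test_integer_single_level_equals_unit_increment_continuous_dp(self):
        # the +1/−7, h=13 level chart is the same stochastic process as a
        # continuous chart with those raw increments
        integer = IntegerProgramDesign()
        for rate in (0.05, 0.10, 0.15):
            res_int = signal_probability_exact(OCQuery(integer, rate, horizon=50))
            # continuous-style DP fed with unit steps via a raw design object
            from lccusum.charts import MonitoringDesign

            raw = MonitoringDesign(
                acceptable_failure_rate=0.10,
                equivalence_delta=0.05,
                signal_limit=13.0,
                horizon=50,
                unacceptable_failure_rate=0.15,
                success_increment=1.0,
                failure_increment=-7.0,
            )
            res_cont = signal_probability_exact(OCQuery(raw, rate, horizon=50))
            assert res_int.signal_probability == pytest.approx(
                res_cont.signal_probability, abs=1e-12
            )
            assert res_int.run_length_pmf == pytest.approx(res_cont.run_length_pmf)

    def test_monotone_in_rate_horizon_and_limit(self):
        probs = [
            signal_probability_exact(
                OCQuery(build_design(0.10, 0.05, 0.74, 50), r)
            ).signal_probability
            for r in RATES
        ]
        assert probs == sorted(probs, reverse=True)
        horizons = [15, 25, 50, 80]
        ph = [
            signal_probability_exact(
                OCQuery(build_design(0.10, 0.05, 0.74, h), 0.10)
            ).signal_probability
            for h in horizons
        ]
        assert ph == sorted(ph)
        limits = [0.3, 0.5, 0.74, 1.2]
        pl = [
            signal_probability_exact(
                OCQuery(build_design(0.10, 0.05, h, 50), 0.10)
            ).signal_probability
            for h in limits
        ]
        assert pl == sorted(pl, reverse=True)


class TestMonteCarlo:
    def test_zero_rate_estimate_is_exactly_one(self, clinical_design):
        res = signal_probability_mc(OCQuery(clinical_design, 0.0), replicates=500, seed=7)
        assert res.signal_probability == 1.0
        assert res.standard_error == 0.0

    def test_reproducible_under_fixed_seed(self, clinical_design):
        q = OCQuery(clinical_design, 0.10)
        a = signal_probability_mc(q, 2000, seed=11)
        b = signal_probability_mc(q, 2000, seed=11)
        assert a.signal_probability == b.signal_probability
        assert a.run_length_pmf == b.run_length_pmf

    def test_two_seeds_agree_within_six_se(self, clinical_design):
        q = OCQuery(clinical_design, 0.10)
        a = signal_probability_mc(q, 10_000, seed=1)
        b = signal_probability_mc(q, 10_000, seed=2)
        se = math.hypot(a.standard_error, b.standard_error)
        assert abs(a.signal_probability - b.signal_probability) <= 6 * se

    @pytest.mark.parametrize("rate", [0.05, 0.10, 0.30])
    def test_mc_within_three_se_of_dp(self, clinical_design, rate):
        q = OCQuery(clinical_design, rate)
        exact = signal_probability_exact(q).signal_probability
        mc = signal_probability_mc(q, 20_000, seed=123)
        assert abs(mc.signal_probability - exact) <= 3 * max(mc.standard_error, 1e-4)


class TestProgramPassProbability:
    def test_zero_rate_passes_certainly(self, integer_design):
        assert program_pass_probability(integer_design, 0.0) == pytest.approx(1.0)

    def test_impossible_last_level_zeroes_the_program(self, integer_design):
        assert program_pass_probability(integer_design, [0.0, 0.0, 1.0]) == 0.0

    def test_constant_rate_is_single_level_probability_cubed(self, integer_design):
        r = 0.10
        single = signal_probability_exact(
            OCQuery(integer_design, r, horizon=integer_design.per_level_cap)
        ).signal_probability
        assert program_pass_probability(integer_design, r) == pytest.approx(single**3)

    def test_agrees_with_direct_program_simulation(self, integer_design):
        from lccusum.charts import run_integer_program

        r, n = 0.10, 4000
        rng = np.random.default_rng(2024)
        passed = 0
        for _ in range(n):
            streams = [
                list(rng.random(integer_design.per_level_cap) >= r) for _ in range(3)
            ]
            if run_integer_program(streams, integer_design).program_passed:
                passed += 1
        p_hat = passed / n
        p = program_pass_probability(integer_design, r)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) <= 3 * se

    def test_wrong_rate_count_rejected(self, integer_design):
        from lccusum.charts import DesignError

        with pytest.raises(DesignError, match="per-level rates"):
            program_pass_probability(integer_design, [0.1, 0.1])


class TestCalibrateLimit:
    def test_self_consistency_recovers_the_chosen_limit(self, clinical_design):
        target = signal_probability_exact(
            OCQuery(clinical_design, 0.10)
        ).signal_probability
        res = calibrate_limit(0.10, 0.05, 50, target, 0.10, grid_step=0.01)
        assert res.signal_limit == pytest.approx(0.74)
        assert res.achieved_probability == pytest.approx(target)
        assert res.probability_at_acceptable == pytest.approx(target)
        assert res.probability_at_unacceptable < target

    def test_target_one_at_zero_rate_returns_largest_reachable_limit(self):
        res = calibrate_limit(0.10, 0.05, 50, 1.0, 0.0, grid_step=0.01)
        d = build_design(0.10, 0.05, 0.01, 50)
        assert res.signal_limit == pytest.approx(
            math.floor(50 * d.success_increment / 0.01) * 0.01
        )
        assert res.achieved_probability == 1.0

    def test_unattainable_target_raises_with_best_achievable(self):
        # at failure rate 0.9 even the smallest grid limit (one success
        # suffices) only reaches 1 - 0.9^50 ~ 0.9949
        with pytest.raises(UnattainableError) as exc:
            calibrate_limit(0.10, 0.05, 50, 0.999999, 0.9, grid_step=0.01)
        assert 0.0 <= exc.value.best_achievable < 0.999999
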