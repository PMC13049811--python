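"""Outcome taxonomy and operating-characteristic aggregation."""

import pytest

from adaptrial.design import ScenarioSpec
from adaptrial.outcomes import (
    OutcomeClass,
    adoption_probability,
    bias_summary,
    classify_outcome,
    coverage,
    mc_error,
    operating_characteristics,
)
from adaptrial.trial import StopReason, Winner

from conftest import make_result

DELTA = 0.01


def expected_class(stop: StopReason, winner: Winner, d_true: float) -> OutcomeClass:
    """Independent restatement of the taxonomy used as the test oracle."""
    if stop is StopReason.MAX_N:
        return OutcomeClass.INCONCLUSIVE
    equal = abs(d_true) < DELTA
    if stop is StopReason.EQUIVALENCE:
        return OutcomeClass.TRUE_EQUIVALENCE if equal else OutcomeClass.SPURIOUS_EQUIVALENCE
    if equal:
        return OutcomeClass.PARTIAL_EFFICACY
    superior_is_B = d_true > 0
    if (winner is Winner.B) == superior_is_B:
        return OutcomeClass.TRUE_EFFICACY
    return OutcomeClass.FALSE_EFFICACY


class TestClassifyOutcome:
    def test_exhaustive_enumeration(self):
        """Every valid (stop, winner, Delta_true) combination matches the
        taxonomy, including the sign-relabelling symmetry."""
        combos = [
            (StopReason.EFFICACY, Winner.A),
            (StopReason.EFFICACY, Winner.B),
            (StopReason.EQUIVALENCE, Winner.NONE),
            (StopReason.MAX_N, Winner.NONE),
        ]
        for d_true in (-0.02, -0.005, 0.0, 0.005, 0.01, 0.02):
            scenario = ScenarioSpec(0.5, 0.5 + d_true)
            for stop, winner in combos:
                r = make_result(stop, winner)
                assert classify_outcome(r, scenario, DELTA) is expected_class(
                    stop, winner, d_true
                )

    def test_relabelling_symmetry(self):
        """Swapping the arm labels together with the sign of the true
        difference leaves the class unchanged."""
        swap = {Winner.A: Winner.B, Winner.B: Winner.A, Winner.NONE: Winner.NONE}
        for d_true in (-0.03, 0.0, 0.02):
            for stop, winner in [
                (StopReason.EFFICACY, Winner.A),
                (StopReason.EFFICACY, Winner.B),
                (StopReason.EQUIVALENCE, Winner.NONE),
            ]:
                c1 = classify_outcome(
                    make_result(stop, winner), ScenarioSpec(0.5, 0.5 + d_true), DELTA
                )
                c2 = classify_outcome(
                    make_result(stop, swap[winner]), ScenarioSpec(0.5 + d_true, 0.5), DELTA
                )
                assert c1 is c2

    @pytest.mark.parametrize(
        "stop,winner,p_b,expected",
        [
            (StopReason.EFFICACY, Winner.B, 0.50, OutcomeClass.PARTIAL_EFFICACY),
            (StopReason.EQUIVALENCE, Winner.NONE, 0.51, OutcomeClass.SPURIOUS_EQUIVALENCE),
            (StopReason.EFFICACY, Winner.A, 0.52, OutcomeClass.FALSE_EFFICACY),
        ],
    )
    def test_documented_examples(self, stop, winner, p_b, expected):
        r = make_result(stop, winner)
        assert classify_outcome(r, ScenarioSpec(0.5, p_b), DELTA) is expected


class TestOperatingCharacteristics:
    def test_counting_and_quantiles(self):
        scenario = ScenarioSpec(0.5, 0.52)
        results = [
            make_result(StopReason.EFFICACY, Winner.B, total_n=100, replicate_id=0),
            make_result(StopReason.EQUIVALENCE, Winner.NONE, total_n=200, replicate_id=1),
            make_result(StopReason.MAX_N, Winner.NONE, total_n=400, replicate_id=2),
        ]
        oc = operating_characteristics(results, scenario, DELTA)
        third = pytest.approx(1 / 3)
        assert oc.rates["true_efficacy"] == third
        assert oc.rates["spurious_equivalence"] == third
        assert oc.rates["inconclusive"] == third
        assert sum(oc.rates.values()) == pytest.approx(1.0, abs=1e-12)
        assert oc.sample_size_median == 200
        assert oc.sample_size_min == 100 and oc.sample_size_max == 400
        assert (
            oc.sample_size_min <= oc.sample_size_q1 <= oc.sample_size_median
            <= oc.sample_size_q3 <= oc.sample_size_max
        )
        assert oc.mc_error_per_rate["true_efficacy"] == pytest.approx(
            mc_error(1 / 3, 3)
        )

    def test_impossible_classes_have_zero_rate(self):
        null = ScenarioSpec(0.5, 0.5)
        results = [
            make_result(StopReason.EFFICACY, Winner.A),
            make_result(StopReason.EQUIVALENCE, Winner.NONE),
        ]
        oc = operating_characteristics(results, null, DELTA)
        assert oc.rates["true_efficacy"] == 0.0
        assert oc.rates["false_efficacy"] == 0.0
        assert oc.rates["spurious_equivalence"] == 0.0
        assert oc.adoption_correct_bayes is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            operating_characteristics([], ScenarioSpec(0.5, 0.5), DELTA)


class TestCoverage:
    def test_trivial_cases(self):
        null = ScenarioSpec(0.5, 0.5)
        wide = [make_result(StopReason.MAX_N, Winner.NONE, cri=(-1, 1)) for _ in range(4)]
        assert coverage(wide, null) == 1.0
        above = [make_result(StopReason.MAX_N, Winner.NONE, cri=(0.1, 0.2)) for _ in range(4)]
        assert coverage(above, null) == 0.0

    def test_complementarity(self):
        scenario = ScenarioSpec(0.5, 0.51)
        results = [
            make_result(StopReason.EFFICACY, Winner.B, cri=c)
            for c in [(-0.01, 0.03), (0.02, 0.05), (-0.02, 0.0), (0.0, 0.02)]
        ]
        cov = coverage(results, scenario)
        missed = sum(
            1
            for r in results
            if not (r.final_posterior.cri_lower <= 0.01 <= r.final_posterior.cri_upper)
        )
        assert cov == pytest.approx(1.0 - missed / len(results), abs=1e-15)
        assert cov == 0.5


class TestBias:
    def test_symmetric_null_estimates_have_zero_mean_bias(self):
        null = ScenarioSpec(0.5, 0.5)
        results = [
            make_result(StopReason.EFFICACY, Winner.B, mean_diff=+0.02, observed_diff=+0.03),
            make_result(StopReason.EFFICACY, Winner.A, mean_diff=-0.02, observed_diff=-0.03),
        ]
        for mode in ("with_prior", "observed_only"):
            mean_bias, by_size = bias_summary(results, null, mode)
            assert mean_bias == pytest.approx(0.0, abs=1e-15)
            assert by_size["n_trials"].sum() == 2

    def test_shrinkage_and_early_stopping_signs(self):
        scenario = ScenarioSpec(0.5, 0.55)
        # posterior mean pulled toward null (under-), raw estimate inflated (over-)
        results = [
            make_result(StopReason.EFFICACY, Winner.B, mean_diff=0.04, observed_diff=0.06)
            for _ in range(3)
        ]
        with_prior, _ = bias_summary(results, scenario, "with_prior")
        observed, _ = bias_summary(results, scenario, "observed_only")
        assert with_prior < 0
        assert observed > 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            bias_summary([make_result(StopReason.MAX_N, Winner.NONE)],
                         ScenarioSpec(0.5, 0.5), mode="hybrid")


class TestAdoption:
    def test_all_correct_efficacy_stops(self):
        scenario = ScenarioSpec(0.5, 0.52)
        results = [
            make_result(StopReason.EFFICACY, Winner.B, mean_p_A=0.5, mean_p_B=0.52,
                        observed_diff=0.02)
            for _ in range(5)
        ]
        assert adoption_probability(results, scenario, "bayes") == 1.0
        assert adoption_probability(results, scenario, "observed") == 1.0

    def test_equivalence_trials_still_adopt_by_final_means(self):
        scenario = ScenarioSpec(0.5, 0.52)
        results = [
            make_result(StopReason.EQUIVALENCE, Winner.NONE, mean_p_A=0.51, mean_p_B=0.50),
        ]
        assert adoption_probability(results, scenario, "bayes") == 0.0

    def test_exact_tie_counts_half(self):
        scenario = ScenarioSpec(0.5, 0.52)
        results = [make_result(StopReason.MAX_N, Winner.NONE, mean_p_A=0.5, mean_p_B=0.5)]
        assert adoption_probability(results, scenario, "bayes") == 0.5

    def test_null_scenario_is_a_domain_error(self):
        with pytest.raises(ValueError, match="undefined"):
            adoption_probability(
                [make_result(StopReason.MAX_N, Winner.NONE)], ScenarioSpec(0.5, 0.5)
            )


class TestMcError:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.90, 1000, 0.009487), (0.95, 1000, 0.006892), (0.5, 100, 0.05)],
    )
    def test_known_values(self, p, n, expected):
        assert mc_error(p, n) == pytest.approx(expected, abs=5e-7)

    def test_domain(self):
        with pytest.raises(ValueError):
            mc_error(1.2, 100)
        with pytest.raises(ValueError):
            mc_error(0.5, 0)
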