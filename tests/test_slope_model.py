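import math

import numpy as np
import pytest

from slopespam import (
    KRange,
    KRangeError,
    ModelParams,
    compute_k_range,
    estimate_match_probability,
    expected_match_count,
    jukes_cantor_distance,
    jukes_cantor_match_probability,
    log_corrected_count,
    min_match_probability,
)


class TestExpectedMatchCount:
    def test_indel_free_direct_evaluation(self):
        # 9*1 + 9*8*(1/16)
        got = expected_match_count(10, 10, 2, p=1.0, q=0.25, model="indel_free_global")
        assert got == pytest.approx(13.5)

    def test_indel_free_collapses_when_p_equals_q(self):
        for L, k, p in [(100, 3, 0.3), (50, 5, 0.25)]:
            got = expected_match_count(L, L, k, p=p, q=p, model="indel_free_global")
            assert got == pytest.approx((L - k + 1) * (L - k + 1) * p**k)

    def test_general_two_strand_direct_evaluation(self):
        # 50*0.729 + 2*10^4/64
        got = expected_match_count(
            100, 100, 3, p=0.9, q=0.25, model="general_two_strand", L_H=50
        )
        assert got == pytest.approx(348.95)

    def test_general_requires_L_H(self):
        with pytest.raises(ValueError, match="L_H"):
            expected_match_count(100, 100, 3, 0.9, 0.25, "general_two_strand")

    def test_indel_free_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            expected_match_count(100, 90, 3, 0.9, 0.25, "indel_free_global")


class TestLogCorrectedCount:
    def test_general_background_subtraction(self):
        # ln(100 - 2*10*10*0.0625) = ln 87.5
        got = log_corrected_count(100, 10, 10, 2, q=0.25)
        assert got == pytest.approx(math.log(87.5), abs=1e-12)
        assert got == pytest.approx(4.4716, abs=5e-4)

    def test_zero_background(self):
        for model in ("general_two_strand", "indel_free_global"):
            assert log_corrected_count(100, 10, 10, 2, q=0.0, model=model) == pytest.approx(
                math.log(100)
            )

    def test_undefined_at_or_below_background(self):
        background = 2 * 10 * 10 * 0.25**2
        assert math.isnan(log_corrected_count(background, 10, 10, 2, q=0.25))
        assert math.isnan(log_corrected_count(0, 10, 10, 2, q=0.25))

    def test_indel_free_variant(self):
        got = log_corrected_count(100, 10, 10, 2, q=0.25, model="indel_free_global")
        assert got == pytest.approx(math.log(100 - 9 * 8 * 0.0625))


class TestKRange:
    def test_worked_example_genome_lengths(self):
        kr = compute_k_range((4_440_000 + 5_150_000) / 2)
        assert (kr.k_min, kr.k_max) == (19, 24)

    @pytest.mark.parametrize("L,expected", [(100_000, (14, 18)), (1_000_000, (17, 21))])
    def test_direct_evaluation(self, L, expected):
        kr = compute_k_range(L)
        assert (kr.k_min, kr.k_max) == expected

    def test_default_formula_matches_simplified_constants(self):
        # the default denominators round to the simplified 0.875 / 0.634 forms
        assert abs(math.log(0.6 / 0.25) - 0.875) < 1e-3
        assert abs(-math.log(0.53) - 0.634) < 1e-3
        for L in np.geomspace(1e4, 1e9, 40):
            kr = compute_k_range(L)
            assert kr.k_min == math.ceil((math.log(L) + math.log(2)) / math.log(2.4))
            assert kr.k_max == math.floor(math.log(L) / -math.log(0.53))

    def test_too_short_sequences_raise(self):
        with pytest.raises(KRangeError, match="k_min"):
            compute_k_range(100)

    def test_krange_validates_order(self):
        with pytest.raises(KRangeError):
            KRange(k_min=5, k_max=5, L_effective=1e3)


class TestMinMatchProbability:
    def test_degenerate_bound_when_beta_equals_L(self):
        L = 1000.0
        assert min_match_probability(L, ModelParams(beta=L)) == pytest.approx(1.0)

    def test_direct_evaluation_1gb(self):
        got = min_match_probability(1e9, ModelParams(alpha=10, beta=10))
        assert got == pytest.approx(0.546, abs=5e-4)

    def test_decreasing_in_length(self):
        vals = [min_match_probability(L) for L in np.geomspace(1e3, 1e9, 30)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestSlopeEstimator:
    def test_worked_example_slope(self):
        kr = KRange(19, 24, 4_795_000.0)
        est = estimate_match_probability(15.92, 15.81, kr)
        assert est.slope == pytest.approx(-0.022)
        assert est.p_hat == pytest.approx(0.978, abs=5e-4)
        assert est.jc_distance == pytest.approx(0.022, abs=5e-4)
        assert est.ok

    def test_equal_F_gives_identical_sequence_limit(self):
        est = estimate_match_probability(7.3, 7.3, KRange(10, 15, 1e4))
        assert est.slope == 0.0
        assert est.p_hat == 1.0
        assert est.jc_distance == 0.0

    def test_direct_evaluation(self):
        est = estimate_match_probability(5.0, 4.5, KRange(10, 15, 1e4))
        assert est.p_hat == pytest.approx(math.exp(-0.1))

    def test_undefined_F_propagates(self):
        est = estimate_match_probability(math.nan, 4.5, KRange(10, 15, 1e4))
        assert est.status == "F_undefined"
        assert math.isnan(est.jc_distance)

    def test_positive_slope_clamps_to_one(self):
        est = estimate_match_probability(4.5, 5.0, KRange(10, 15, 1e4))
        assert est.p_hat == 1.0
        assert est.clamped
        assert est.jc_distance == 0.0

    def test_deep_divergence_flags_out_of_range(self):
        # slope of ln(0.2) per k puts p̂ below the JC domain boundary 1/4
        est = estimate_match_probability(10.0, 10.0 + 5 * math.log(0.2), KRange(10, 15, 1e4))
        assert est.status == "p_out_of_range"
        assert math.isnan(est.jc_distance)


class TestJukesCantor:
    def test_printed_values(self):
        assert jukes_cantor_distance(0.978) == pytest.approx(0.022, abs=5e-4)
        assert jukes_cantor_distance(0.57) == pytest.approx(0.64, abs=5e-3)
        assert jukes_cantor_distance(1.0) == 0.0

    def test_mutual_inverse_over_domain(self):
        for d in np.linspace(0.0, 2.0, 201):
            p = jukes_cantor_match_probability(d)
            assert jukes_cantor_distance(p) == pytest.approx(d, abs=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            jukes_cantor_distance(0.25)
        with pytest.raises(ValueError):
            jukes_cantor_distance(1.01)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(q=0.0)
    with pytest.raises(ValueError):
        ModelParams(p_prime_kmax=0.7, p_prime_kmin=0.6)
    with pytest.raises(ValueError):
        ModelParams(beta=0.5)
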