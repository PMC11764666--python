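"""Ordinal symbolization and complexity measures against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    brute_complexity,
    brute_encode,
    brute_jsd,
    brute_patterns,
    brute_prob_vector,
    brute_variance,
)
from sleepops.errors import (
    DegenerateSignalError,
    InvalidDistributionError,
    NonFiniteDataError,
)
from sleepops.ordinal_core import (
    ComplexityPoint,
    OrdinalConfig,
    PatternDistribution,
    encode_pattern,
    enumerate_patterns,
    jensen_shannon_divergence,
    max_divergence,
    normalized_entropy,
    ordinal_distribution,
    q_sweep,
    segment_weight,
    shannon_entropy,
    statistical_complexity,
)

series_strategy = st.lists(
    st.floats(-100, 100, allow_nan=False, allow_infinity=False),
    min_size=8,
    max_size=60,
)


class TestEnumeratePatterns:
    @pytest.mark.parametrize("D", [2, 3, 4, 5])
    def test_matches_brute_force_enumeration(self, D):
        patterns = enumerate_patterns(D)
        assert len(patterns) == math.factorial(D)
        assert [p.ranks for p in patterns] == brute_patterns(D)
        assert [p.index for p in patterns] == list(range(len(patterns)))

    def test_default_dimension_has_24_patterns_monotone_first_and_last(self):
        patterns = enumerate_patterns(4)
        assert len(patterns) == 24
        assert patterns[0].ranks == (0, 1, 2, 3)
        assert patterns[-1].ranks == (3, 2, 1, 0)
        assert patterns[0].name == "0123"

    @pytest.mark.parametrize("D", [1, 9])
    def test_dimension_out_of_range_rejected(self, D):
        with pytest.raises(ValueError):
            enumerate_patterns(D)


class TestEncodePattern:
    def test_monotone_segments(self):
        assert encode_pattern([1.0, 2.0, 3.0, 4.0]).ranks == (0, 1, 2, 3)
        assert encode_pattern([4.0, 3.0, 2.0, 1.0]).ranks == (3, 2, 1, 0)

    def test_ties_earlier_sample_gets_lower_rank(self):
        assert encode_pattern([1.0, 1.0, 0.0]).ranks == (1, 2, 0)
        assert encode_pattern([2.0, 2.0, 2.0, 2.0]).ranks == (0, 1, 2, 3)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=4))
    def test_matches_argsort_oracle(self, segment):
        assert encode_pattern(segment).ranks == brute_encode(segment)

    def test_errors(self):
        with pytest.raises(ValueError):
            encode_pattern(list(range(9)))
        with pytest.raises(NonFiniteDataError):
            encode_pattern([0.5, np.nan, 0.9, 0.3])


class TestSegmentWeight:
    @pytest.mark.parametrize("c", [0.0, -3.5, 7.0])
    def test_constant_segment_has_zero_weight(self, c):
        assert segment_weight([c, c, c, c]) == 0.0

    def test_hand_computed_population_variance(self):
        assert segment_weight([0, 1, 0, 1]) == pytest.approx(0.25)
        assert segment_weight([1, 2, 3, 4]) == pytest.approx(1.25)

    def test_non_finite_rejected(self):
        with pytest.raises(NonFiniteDataError):
            segment_weight([1.0, np.inf, 2.0, 3.0])


class TestOrdinalDistribution:
    @pytest.mark.parametrize("q", [-5.0, 0.0, 2.0, 10.0])
    def test_monotone_ramp_is_a_delta_distribution(self, default_config, q):
        dist = ordinal_distribution(np.arange(100.0), default_config, q)
        assert dist.probs[0] == pytest.approx(1.0)
        assert dist.probs[1:].sum() == pytest.approx(0.0)
        assert dist.n_segments == 97

    def test_q_zero_equals_plain_counting(self, default_config, rng):
        x = rng.standard_normal(200)
        dist = ordinal_distribution(x, default_config, 0.0)
        counts = np.zeros(24)
        lookup = {p: i for i, p in enumerate(brute_patterns(4))}
        for t in range(197):
            counts[lookup[brute_encode(x[t : t + 4].tolist())]] += 1
        np.testing.assert_array_equal(dist.probs, counts / 197)

    @pytest.mark.parametrize("q", [-3.0, -1.0, 0.0, 1.0, 2.0, 7.0])
    def test_matches_exhaustive_enumeration_oracle(self, default_config, rng, q):
        x = rng.standard_normal(12)
        dist = ordinal_distribution(x, default_config, q)
        oracle = brute_prob_vector(x.tolist(), 4, 1, q)
        np.testing.assert_allclose(dist.probs, oracle, atol=1e-13)

    def test_series_too_short(self, default_config):
        with pytest.raises(ValueError):
            ordinal_distribution([1.0, 2.0, 3.0], default_config, 0.0)

    @pytest.mark.parametrize("q", [2.0, -2.0])
    def test_constant_series_degenerate_for_nonzero_q(self, default_config, q):
        with pytest.raises(DegenerateSignalError) as err:
            ordinal_distribution(np.ones(50), default_config, q)
        assert err.value.degenerate

    def test_constant_series_fine_at_q_zero(self, default_config):
        dist = ordinal_distribution(np.ones(50), default_config, 0.0)
        assert dist.probs[0] == pytest.approx(1.0)  # ties -> increasing pattern

    def test_zero_variance_plateau_excluded_at_negative_q(self, default_config):
        # 10 constant samples embedded in noise: the 7 all-constant windows
        # must be excluded (their weight diverges) and counted.
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.standard_normal(20), np.full(10, 2.0), rng.standard_normal(20)])
        dist = ordinal_distribution(x, default_config, -2.0)
        assert dist.n_degenerate == 7
        assert dist.probs.sum() == pytest.approx(1.0)
        at_q0 = ordinal_distribution(x, default_config, 0.0)
        assert at_q0.n_degenerate == 0


class TestEntropyAndComplexity:
    def test_delta_distribution_minimizes_entropy(self):
        assert shannon_entropy(PatternDistribution.delta(24)) == 0.0
        assert normalized_entropy(PatternDistribution.delta(24)) == 0.0

    def test_uniform_distribution_maximizes_entropy(self):
        assert shannon_entropy(PatternDistribution.uniform(24)) == pytest.approx(math.log(24))
        assert normalized_entropy(PatternDistribution.uniform(24)) == pytest.approx(1.0)

    def test_two_point_distribution_closed_form(self):
        p = np.zeros(24)
        p[[0, 5]] = 0.5
        dist = PatternDistribution(probs=p, q=0.0, n_segments=10)
        assert shannon_entropy(dist) == pytest.approx(math.log(2))
        assert normalized_entropy(dist) == pytest.approx(math.log(2) / math.log(24))

    def test_unnormalized_distribution_rejected(self):
        bad = PatternDistribution(probs=np.full(24, 1 / 24), q=0.0, n_segments=0)
        bad.probs[0] += 1e-3
        with pytest.raises(InvalidDistributionError):
            shannon_entropy(bad)

    def test_jsd_identical_distributions_is_zero(self):
        u = PatternDistribution.uniform(24)
        assert jensen_shannon_divergence(u, u) == pytest.approx(0.0, abs=1e-15)

    def test_jsd_delta_vs_uniform_attains_analytic_maximum(self):
        for M in (2, 6, 24):
            delta = PatternDistribution.delta(M)
            uniform = PatternDistribution.uniform(M)
            jsd = jensen_shannon_divergence(delta, uniform)
            assert jsd == pytest.approx(max_divergence(M), rel=1e-12)
            oracle = brute_jsd([1.0] + [0.0] * (M - 1), [1.0 / M] * M)
            assert jsd == pytest.approx(oracle, rel=1e-12)

    def test_jsd_matches_term_by_term_oracle(self, rng):
        p = rng.dirichlet(np.ones(24))
        u = PatternDistribution.uniform(24)
        P = PatternDistribution(probs=p, q=0.0, n_segments=1)
        assert jensen_shannon_divergence(P, u) == pytest.approx(
            brute_jsd(p.tolist(), u.probs.tolist()), abs=1e-14
        )
        assert jensen_shannon_divergence(u, P) == pytest.approx(
            jensen_shannon_divergence(P, u), abs=1e-15
        )

    def test_jsd_length_mismatch(self):
        with pytest.raises(ValueError):
            jensen_shannon_divergence(
                PatternDistribution.uniform(6), PatternDistribution.uniform(24)
            )

    def test_complexity_vanishes_at_both_boundaries(self):
        ordered = statistical_complexity(PatternDistribution.delta(24))
        assert ordered.H == 0.0 and ordered.C == 0.0
        random = statistical_complexity(PatternDistribution.uniform(24))
        assert random.Q == pytest.approx(0.0, abs=1e-12)
        assert random.C == pytest.approx(0.0, abs=1e-12)

    def test_disequilibrium_normalization_is_one_for_delta(self):
        assert statistical_complexity(PatternDistribution.delta(24)).Q == pytest.approx(
            1.0, rel=1e-12
        )

    def test_intermediate_distribution_matches_oracle(self):
        p = np.full(24, 0.5 / 23)
        p[0] = 0.5
        cp = statistical_complexity(PatternDistribution(probs=p, q=0.0, n_segments=5))
        S, H, Q, C = brute_complexity(p.tolist())
        assert cp.C > 0
        for got, want in zip((cp.S, cp.H, cp.Q, cp.C), (S, H, Q, C)):
            assert got == pytest.approx(want, rel=1e-12)


class TestQSweep:
    def test_default_grid_has_21_entries(self, default_config, rng):
        sweep = q_sweep(rng.standard_normal(100), default_config)
        assert len(sweep) == 21
        assert [p.q for p in sweep] == [float(q) for q in range(-10, 11)]

    def test_single_q_grid_equals_unweighted_computation(self, rng):
        x = rng.standard_normal(80)
        cfg = OrdinalConfig(q_grid=(0.0,))
        (entry,) = q_sweep(x, cfg)
        np.testing.assert_array_equal(
            entry.distribution.probs, ordinal_distribution(x, cfg, 0.0).probs
        )

    def test_entries_match_independent_single_q_calls(self, rng):
        x = rng.standard_normal(60)
        cfg = OrdinalConfig(q_grid=(0.0, 2.0))
        for entry in q_sweep(x, cfg):
            single = ordinal_distribution(x, cfg, entry.q)
            np.testing.assert_array_equal(entry.distribution.probs, single.probs)
            cp = statistical_complexity(single)
            assert entry.complexity == ComplexityPoint(cp.S, cp.H, cp.Q, cp.C, entry.q)


class TestConfig:
    def test_defaults_match_study_protocol(self, default_config):
        assert default_config.D == 4
        assert default_config.tau == 1
        assert default_config.q_grid == tuple(float(q) for q in range(-10, 11))
        assert default_config.n_patterns == 24

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"D": 1},
            {"D": 9},
            {"tau": 0},
            {"q_grid": ()},
            {"q_grid": (1.0, 1.0)},
            {"q_grid": (2.0, 1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OrdinalConfig(**kwargs)


class TestInvariants:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(series=series_strategy, q=st.sampled_from([-4.0, -1.0, 0.0, 1.0, 2.0, 6.0]))
    def test_normalization_and_bounds(self, default_config, series, q):
        try:
            dist = ordinal_distribution(series, default_config, q)
        except DegenerateSignalError:
            return  # constant-ish series with q != 0: no distribution defined
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.n_segments == len(series) - 3
        cp = statistical_complexity(dist)
        assert 0.0 <= cp.S <= math.log(24) + 1e-12
        assert 0.0 <= cp.H <= 1.0 + 1e-12
        assert 0.0 <= cp.Q <= 1.0 + 1e-12
        assert cp.C >= 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        # Distinct integers scaled by powers of two stay exactly ordered in
        # floating point, so the test isolates the mathematical invariance
        # from round-off-induced tie changes.
        series=st.lists(st.integers(-1000, 1000), min_size=8, max_size=40, unique=True),
        a=st.sampled_from([0.25, 0.5, 1.0, 2.0, 8.0, 1024.0]),
        b=st.integers(-8, 8),
        q=st.sampled_from([-2.0, 0.0, 2.0]),
    )
    def test_affine_invariance(self, default_config, series, a, b, q):
        """Patterns ignore offset and positive scale; weights rescale by a^2,
        which cancels in the weighted ratio, so every q is affine-invariant."""
        x = np.asarray(series, dtype=float)
        try:
            base = ordinal_distribution(x, default_config, q)
        except DegenerateSignalError:
            return
        transformed = ordinal_distribution(a * x + b, default_config, q)
        np.testing.assert_allclose(transformed.probs, base.probs, atol=1e-9)

    def test_q2_matches_brute_wpe_oracle_up_to_length_50(self, default_config, rng):
        for n in (10, 25, 50):
            x = rng.standard_normal(n)
            dist = ordinal_distribution(x, default_config, 2.0)
            np.testing.assert_allclose(
                dist.probs, brute_prob_vector(x.tolist(), 4, 1, 2.0), atol=1e-13
            )

    def test_monotone_event_probability_nondecreasing_in_q(self, default_config):
        """Low-amplitude noise plus sparse large monotone ramps: increasing q
        shifts weight onto the high-variance ramps, so the total probability
        of the two monotone patterns must not decrease along the grid."""
        rng = np.random.default_rng(7)
        n = 3000
        x = 0.05 * np.where(np.arange(n) % 2 == 0, -1.0, 1.0) * rng.uniform(0.8, 1.2, n)
        triangle = np.concatenate([np.linspace(0, 10, 9)[:-1], np.linspace(10, 0, 9)])
        for start in range(100, 2900, 250):
            x[start : start + 17] = triangle * rng.uniform(0.9, 1.1)
        sweep = q_sweep(x, default_config)
        mono = [p.distribution.probs[0] + p.distribution.probs[23] for p in sweep]
        assert all(b >= a - 1e-9 for a, b in zip(mono, mono[1:]))
        assert mono[-1] > mono[0] + 0.5  # large-amplitude ramps dominate at q >> 0
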