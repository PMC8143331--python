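"""Split strategies, Spearman–Brown, HDI, and sampled reliability."""

import math

import numpy as np
import pytest
from scipy import stats

from cwcst.reliability import (
    estimate,
    get_measure,
    hdi,
    half_scores,
    prepare_cohort,
    sample_reliability,
    sample_reliability_multi,
    spearman_brown,
    split_first_second,
    split_odd_even,
    split_random,
)
from cwcst.filtering import screen_participants

from .conftest import make_log, random_logs
from .reference import brute_half_score


class TestSplits:
    @pytest.mark.parametrize(
        "n, want_a",
        [(6, [1, 2, 3]), (7, [1, 2, 3, 4]), (2, [1])],
    )
    def test_first_second(self, n, want_a):
        split = split_first_second(n)
        assert (np.flatnonzero(split.in_a) + 1).tolist() == want_a

    @pytest.mark.parametrize("n, want_a", [(5, [1, 3, 5]), (4, [1, 3])])
    def test_odd_even(self, n, want_a):
        split = split_odd_even(n)
        assert (np.flatnonzero(split.in_a) + 1).tolist() == want_a

    @pytest.mark.parametrize("n", [2, 3, 17, 100, 500])
    def test_partition_property(self, n):
        for split in (split_first_second(n), split_odd_even(n),
                      split_random(n, np.random.default_rng(n))):
            n_a = int(split.in_a.sum())
            assert abs(2 * n_a - n) <= 1
            assert len(split.in_a) == n

    def test_random_split_n2_uniform_over_both_assignments(self):
        # exactly two balanced splits of two trials exist: {1}|{2} and {2}|{1}
        rng = np.random.default_rng(99)
        first_in_a = sum(bool(split_random(2, rng).in_a[0]) for _ in range(10_000))
        assert abs(first_in_a / 10_000 - 0.5) < 0.02

    def test_random_split_reproducible_under_seed(self):
        a = [split_random(11, np.random.default_rng(5)).in_a for _ in range(1)]
        b = [split_random(11, np.random.default_rng(5)).in_a for _ in range(1)]
        assert np.array_equal(a[0], b[0])

    @pytest.mark.parametrize("splitter", [split_first_second, split_odd_even])
    def test_too_few_trials_rejected(self, splitter):
        with pytest.raises(ValueError):
            splitter(1)


class TestSpearmanBrown:
    @pytest.mark.parametrize("r, want", [(0.0, 0.0), (1.0, 1.0), (1 / 3, 0.5)])
    def test_known_values(self, r, want):
        assert spearman_brown(r) == pytest.approx(want)

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(-0.999, 1.0, 1000)
        vals = [spearman_brown(r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_r_minus_one_undefined(self):
        assert math.isnan(spearman_brown(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(1.5)


class TestHDI:
    def test_mode_hugging_with_outlier(self):
        samples = np.array([0.0] * 99 + [100.0])
        assert hdi(samples, 0.95) == (0.0, 0.0)

    def test_all_equal_gives_zero_width(self):
        low, high = hdi(np.full(50, 3.14), 0.95)
        assert low == high == 3.14

    def test_no_wider_than_equal_tailed_on_unimodal_beta(self):
        rng = np.random.default_rng(0)
        samples = rng.beta(5, 2, size=10_000)
        low, high = hdi(samples, 0.95)
        eq_low, eq_high = np.quantile(samples, [0.025, 0.975])
        assert (high - low) <= (eq_high - eq_low) + 1e-12
        inside = ((samples >= low) & (samples <= high)).mean()
        assert inside >= 0.95

    def test_skewed_hdi_shifts_toward_mode(self):
        rng = np.random.default_rng(1)
        samples = rng.beta(8, 2, size=10_000)
        low, high = hdi(samples, 0.95)
        mode = 7 / 8
        eq_low, eq_high = np.quantile(samples, [0.025, 0.975])
        # the HDI hugs the mode more closely than the equal-tailed interval
        assert abs((low + high) / 2 - mode) <= abs((eq_low + eq_high) / 2 - mode)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(10), 0.95)


def _prepared_constant_rt_cohort(n=30):
    """Error-free participants whose RTs are constant per participant, so any
    half mean reproduces the participant's value exactly."""
    logs = [
        make_log(f"c{i}", [("shape", "shape")] * 24, rts=[800.0 + 40.0 * i] * 24)
        for i in range(n)
    ]
    return prepare_cohort(logs)


class TestEstimate:
    def test_identical_halves_give_perfect_reliability(self):
        prepared = _prepared_constant_rt_cohort()
        for strategy in ("first_second", "odd_even"):
            est = estimate(prepared, "rt_repeat", strategy)
            assert est.r == pytest.approx(1.0)
            assert est.r_sb == pytest.approx(1.0)
            assert est.n_pairs == 30

    def test_zero_variance_scores_flagged_undefined(self):
        logs = [make_log(f"z{i}", [("shape", "shape")] * 10) for i in range(5)]
        prepared = prepare_cohort(logs)
        est = estimate(prepared, "rt_repeat", "odd_even")
        assert not est.defined
        assert math.isnan(est.r_sb)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            estimate(_prepared_constant_rt_cohort(5), "pe", "thirds")

    def test_independent_noise_gives_near_zero_reliability(self):
        # identical agents, no between-participant signal: true reliability 0
        rng = np.random.default_rng(3)
        logs = [
            make_log(
                f"n{i}",
                [("shape", "shape")] * 40,
                rts=list(1000.0 + 400.0 * rng.standard_normal(40).clip(-2, 10)),
            )
            for i in range(200)
        ]
        prepared = prepare_cohort(logs)
        est = estimate(prepared, "rt_repeat", "odd_even")
        assert abs(est.r_sb) < 0.3


class TestHalfScores:
    def test_all_pe_in_first_half(self):
        # perseveration run early, clean repeats later
        log = make_log(
            "h",
            [("shape", "color")] * 4 + [("color", "color")] * 4,
        )
        prepared = prepare_cohort([log])
        split = split_first_second(prepared[0].n_trials)
        a, b = half_scores(prepared, [split], get_measure("pe"))
        assert a[0] == 3.0  # trials 2-4 repeat the shape set after negatives
        assert b[0] == 0.0

    def test_zero_error_cohort_scores_zero_pairs(self):
        logs = [make_log(f"z{i}", [("shape", "shape")] * 12) for i in range(4)]
        prepared = prepare_cohort(logs)
        splits = [split_odd_even(12)] * 4
        a, b = half_scores(prepared, splits, get_measure("pe"))
        assert (a == 0).all() and (b == 0).all()

    def test_matches_bruteforce_evaluator_on_random_splits(self):
        logs = random_logs(8, seed=31)
        prepared = prepare_cohort(logs)
        rng = np.random.default_rng(32)
        for _ in range(25):
            splits = [split_random(p.n_trials, rng) for p in prepared]
            for name in ("pe", "sle", "ie", "rt_switch", "rt_repeat", "rt_inference"):
                a, b = half_scores(prepared, splits, get_measure(name))
                for i, (prep, split) in enumerate(zip(prepared, splits)):
                    want_a = brute_half_score(prep.log, split.in_a.tolist(), name)
                    want_b = brute_half_score(prep.log, (~split.in_a).tolist(), name)
                    for got, want in ((a[i], want_a), (b[i], want_b)):
                        if math.isnan(want):
                            assert math.isnan(got)
                        else:
                            assert got == pytest.approx(want)


class TestSampledReliability:
    def test_degenerate_cohort_all_samples_identical(self):
        prepared = _prepared_constant_rt_cohort()
        s = sample_reliability(prepared, "rt_repeat", n_samples=200,
                               rng=np.random.default_rng(4))
        assert np.allclose(s.r_sb, 1.0)
        assert s.median == pytest.approx(1.0)
        assert s.hdi_high - s.hdi_low == pytest.approx(0.0)

    def test_systematic_splits_inside_random_split_range(self, small_cohort):
        result = screen_participants(small_cohort)
        logs = [l for l, ok in zip(small_cohort, result.included) if ok]
        prepared = prepare_cohort(logs)
        s = sample_reliability(prepared, "pe", n_samples=10_000,
                               rng=np.random.default_rng(5))
        fs = estimate(prepared, "pe", "first_second").r_sb
        oe = estimate(prepared, "pe", "odd_even").r_sb
        finite = s.r_sb[np.isfinite(s.r_sb)]
        assert finite.min() <= fs <= finite.max()
        assert finite.min() <= oe <= finite.max()

    def test_shared_splits_across_measures(self, small_cohort):
        # the multi-measure run must reproduce each single-measure summary
        # only up to split resampling noise; with the same rng state the
        # first measure's splits are identical
        prepared = prepare_cohort(small_cohort)
        multi = sample_reliability_multi(
            prepared, ("pe", "sle"), n_samples=100, rng=np.random.default_rng(6)
        )
        single = sample_reliability(prepared, "pe", n_samples=100,
                                    rng=np.random.default_rng(6))
        assert np.allclose(multi["pe"].r_sb, single.r_sb, equal_nan=True)

    def test_undefined_iterations_counted_not_silently_dropped(self):
        # only two participants ever have inference trials -> r undefined
        logs = [make_log(f"u{i}", [("shape", "shape")] * 20) for i in range(10)]
        prepared = prepare_cohort(logs)
        with pytest.raises(ValueError, match="undefined"):
            sample_reliability(prepared, "rt_inference", n_samples=50,
                               rng=np.random.default_rng(7))

    def test_stratified_mode_balances_within_strata(self, small_cohort):
        prepared = prepare_cohort(small_cohort[:20])
        s = sample_reliability(prepared, "pe", n_samples=50,
                               rng=np.random.default_rng(8), stratified=True)
        assert np.isfinite(s.median)

    def test_placebo_normal_vector_recovers_analytic_hdi(self):
        # feeding iid standard-normal values as if they were sampled r_SB:
        # the 95% HDI must approximate (-1.96, 1.96)
        rng = np.random.default_rng(9)
        low, high = hdi(rng.standard_normal(10_000), 0.95)
        z = stats.norm.ppf(0.975)
        assert low == pytest.approx(-z, abs=0.1)
        assert high == pytest.approx(z, abs=0.1)
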