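import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccnet.oneshot import (
    ConditionResult,
    ConditionSpec,
    UndefinedCorrelationError,
    asymmetric_similarity,
    build_window,
    correlation_vs_eccentricity,
    dprime,
    optimal_threshold,
    pearson,
    run_condition,
    symmetric_similarity,
)
from eccnet.networks import ENNExtractor
from eccnet.stimuli import FieldCalibration, GlyphSet, make_novel_pairs


def brute_force_threshold_accuracy(same, diff):
    """Independent oracle: try a threshold inside every interval of the
    sorted similarity values (and outside the range on both sides)."""
    values = sorted(set(same) | set(diff))
    candidates = [values[0] - 1.0, values[-1] + 1.0]
    candidates += [(a + b) / 2 for a, b in zip(values, values[1:])]
    candidates += [v - 1e-12 for v in values] + [v + 1e-12 for v in values]
    n = len(same) + len(diff)
    return max(
        (sum(s > t for s in same) + sum(d <= t for d in diff)) / n
        for t in candidates
    )


class TestPearson:
    def test_self_correlation(self, rng):
        v = rng.normal(size=20)
        assert pearson(v, v) == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        v = rng.normal(size=20)
        assert pearson(v, -v) == pytest.approx(-1.0)

    def test_hand_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 5.0, 9.0])
        # direct covariance formula
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert pearson(a, b) == pytest.approx(expected, abs=1e-12)
        assert pearson(a, b) == pytest.approx(0.9648, abs=1e-4)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert pearson(a, b) == pytest.approx(pearson(b, a), abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(np.ones(5), np.arange(5.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson(np.arange(4.0), np.arange(5.0))

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson(np.array([1.0]), np.array([2.0]))


class TestSymmetricSimilarity:
    def test_identical_features_unity(self, rng):
        v = rng.normal(size=30)
        assert symmetric_similarity(v, v) == pytest.approx(1.0)

    def test_swap_invariance(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert symmetric_similarity(a, b) == symmetric_similarity(b, a)

    def test_random_features_near_zero_mean(self, rng):
        rs = [
            symmetric_similarity(rng.normal(size=50), rng.normal(size=50))
            for _ in range(300)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_gives_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert symmetric_similarity(np.ones(5), np.arange(5.0)) == 0.0


class TestAsymmetricSimilarity:
    def test_exact_channel_match(self, rng):
        test = rng.normal(size=12)
        bank = rng.normal(size=(4, 12))
        bank[2] = test
        sim, k = asymmetric_similarity(bank, test)
        assert sim == pytest.approx(1.0)
        assert k == 2

    def test_single_channel_reduces_to_symmetric(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        sim, k = asymmetric_similarity(a[None, :], b)
        assert k == 0
        assert sim == pytest.approx(symmetric_similarity(a, b), abs=1e-12)

    def test_argmax_by_enumeration(self, rng):
        bank = rng.normal(size=(3, 25))
        test = rng.normal(size=25)
        sims = [pearson(bank[k], test) for k in range(3)]
        sim, k = asymmetric_similarity(bank, test)
        assert k == int(np.argmax(sims))
        assert sim == pytest.approx(max(sims), abs=1e-12)

    def test_metric_is_asymmetric(self):
        # bank(A) vs pooled(B) differs from bank(B) vs pooled(A)
        bank_a = np.array([[1.0, 2.0, 3.0, 1.0], [0.0, 5.0, 1.0, 2.0]])
        bank_b = np.array([[2.0, 1.0, 0.0, 4.0], [1.0, 1.0, 6.0, 0.0]])
        pooled_a = bank_a.max(axis=0)
        pooled_b = bank_b.max(axis=0)
        ab = asymmetric_similarity(bank_a, pooled_b)[0]
        ba = asymmetric_similarity(bank_b, pooled_a)[0]
        assert ab != pytest.approx(ba, abs=1e-6)

    def test_all_constant_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            asymmetric_similarity(np.ones((3, 5)), np.arange(5.0))

    def test_constant_channels_ignored(self, rng):
        test = rng.normal(size=10)
        bank = np.zeros((3, 10))
        bank[1] = test
        sim, k = asymmetric_similarity(bank, test)
        assert (sim, k) == (pytest.approx(1.0), 1)


class TestOptimalThreshold:
    def test_separable(self):
        t, acc = optimal_threshold([0.9, 0.8], [0.3, 0.4])
        assert acc == 1.0
        assert 0.4 < t < 0.8

    def test_tie_single_value(self):
        _, acc = optimal_threshold([0.6], [0.6])
        assert acc == 0.5

    def test_identical_lists(self):
        same = [0.1, 0.5, 0.9]
        _, acc = optimal_threshold(same, list(same))
        assert acc == pytest.approx(brute_force_threshold_accuracy(same, same))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold([], [0.1])
        with pytest.raises(ValueError):
            optimal_threshold([0.1], [])

    @given(
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, same, diff):
        t, acc = optimal_threshold(same, diff)
        assert acc == pytest.approx(brute_force_threshold_accuracy(same, diff), abs=1e-12)
        # returned threshold achieves the returned accuracy
        n = len(same) + len(diff)
        achieved = (sum(s > t for s in same) + sum(d <= t for d in diff)) / n
        assert achieved == pytest.approx(acc, abs=1e-12)


class TestDprime:
    def test_no_sensitivity(self):
        assert dprime(0.5, 0.5) == pytest.approx(0.0)

    def test_unit_dprime(self):
        # Phi(0.5) = 0.69146, Phi(-0.5) = 0.30854
        assert dprime(0.69146, 0.30854) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("rate", [0.1, 0.3, 0.7, 0.9])
    def test_equal_rates_zero(self, rate):
        assert dprime(rate, rate) == pytest.approx(0.0)

    def test_edge_rates_finite_with_counts(self):
        d = dprime(1.0, 0.0, n_same=20, n_diff=20)
        assert np.isfinite(d) and d > 3.0

    def test_log_linear_correction_value(self):
        from scipy.stats import norm

        expected = norm.ppf(20.5 / 21) - norm.ppf(0.5 / 21)
        assert dprime(1.0, 0.0, 20, 20) == pytest.approx(expected, abs=1e-12)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            dprime(1.2, 0.5)


class TestConditionSpec:
    def test_regime_consistency(self):
        with pytest.raises(ValueError):
            ConditionSpec(30, 30, target_ecc=1.0, test_ecc=2.0, regime="central")
        with pytest.raises(ValueError):
            ConditionSpec(30, 30, target_ecc=2.0, test_ecc=2.0, regime="opposite")
        ConditionSpec(30, 30, target_ecc=2.0, test_ecc=-2.0, regime="opposite")
        ConditionSpec(30, 30, target_ecc=2.0, test_ecc=0.0, regime="peripheral")

    def test_unknown_regime_and_metric(self):
        with pytest.raises(ValueError):
            ConditionSpec(30, 30, regime="diagonal")
        with pytest.raises(ValueError):
            ConditionSpec(30, 30, metric="cosine")


class _RandomFeatureStub:
    """Feature extractor that ignores the image entirely."""

    def __init__(self, seed=0, dim=40):
        self.rng = np.random.default_rng(seed)
        self.dim = dim

    def bank_and_pooled(self, image):
        v = self.rng.normal(size=self.dim)
        return v[None, :], v


class TestRunCondition:
    def test_baseline_accuracy_is_one(self, tiny_enn, small_calib, tiny_pyramid):
        pairs = make_novel_pairs(10, seed=21)
        extractor = ENNExtractor(tiny_enn, tiny_pyramid)
        spec = ConditionSpec(30, 30, 0.0, 0.0, "central", "symmetric")
        res = run_condition(spec, pairs, extractor, small_calib)
        assert res.accuracy == 1.0
        assert res.n_trials == 20  # one same + one distractor trial per pair
        assert res.hit_rate == 1.0 and res.fa_rate == 0.0

    def test_baseline_asymmetric_high(self, tiny_enn, small_calib, tiny_pyramid):
        """With the asymmetric metric a cross-pair template can occasionally
        out-correlate the identical-image match, so baseline accuracy is
        near-perfect rather than exactly 1 for weak random features."""
        pairs = make_novel_pairs(6, seed=22)
        extractor = ENNExtractor(tiny_enn, tiny_pyramid)
        spec = ConditionSpec(30, 30, 0.0, 0.0, "central", "asymmetric")
        assert run_condition(spec, pairs, extractor, small_calib).accuracy >= 0.8

    def test_degenerate_distractors_at_chance(self, tiny_enn, small_calib, tiny_pyramid):
        base = make_novel_pairs(4, seed=23)
        glyphs = {}
        pairing = {}
        for tid in base.target_ids:
            glyphs[tid] = base.glyphs[tid]
            glyphs["copy_" + tid] = base.glyphs[tid].copy()  # distractor == target
            pairing[tid] = "copy_" + tid
        degenerate = GlyphSet(glyphs, pairing)
        extractor = ENNExtractor(tiny_enn, tiny_pyramid)
        spec = ConditionSpec(30, 30, 0.0, 0.0, "central", "symmetric")
        res = run_condition(spec, degenerate, extractor, small_calib)
        assert res.accuracy <= 0.5 + 1e-9

    def test_random_stub_near_chance(self, small_calib):
        pairs = make_novel_pairs(60, seed=24)
        spec = ConditionSpec(30, 30, 0.0, 0.0, "central", "symmetric")
        res = run_condition(spec, pairs, _RandomFeatureStub(seed=1), small_calib)
        assert 0.45 <= res.accuracy <= 0.65

    def test_requires_two_pairs(self, tiny_enn, small_calib, tiny_pyramid):
        pairs = make_novel_pairs(1, seed=25)
        spec = ConditionSpec(30, 30, 0.0, 0.0, "central", "symmetric")
        with pytest.raises(ValueError):
            run_condition(spec, pairs, ENNExtractor(tiny_enn, tiny_pyramid), small_calib)

    def test_counterbalanced_sides(self, tiny_enn, small_calib, tiny_pyramid, monkeypatch):
        seen = []
        import eccnet.oneshot as oneshot_mod

        real_render = oneshot_mod.render_stimulus

        def spy(spec, glyphs, calib):
            seen.append(spec.eccentricity)
            return real_render(spec, glyphs, calib)

        monkeypatch.setattr(oneshot_mod, "render_stimulus", spy)
        pairs = make_novel_pairs(4, seed=26)
        spec = ConditionSpec(30, 30, 0.0, 1.0, "central", "symmetric")
        run_condition(spec, pairs, ENNExtractor(tiny_enn, tiny_pyramid), small_calib)
        eccs = [e for e in seen if e != 0.0]
        assert sorted(set(eccs)) == [-1.0, 1.0]
        assert eccs.count(1.0) == eccs.count(-1.0)


class TestInvarianceWindow:
    def test_boundary_bracketing(self):
        grid = {(30.0, 0.0): 1.0, (30.0, 2.0): 0.9, (30.0, 4.0): 0.6,
                (60.0, 0.0): 1.0, (60.0, 2.0): 0.95, (60.0, 4.0): 0.9}
        w = build_window(grid, "central")
        b30 = w.boundary_eccentricity(30.0, 0.85)
        assert 2.0 < b30 < 4.0
        assert b30 == pytest.approx(2.0 + 0.05 / 0.3 * 2.0)
        # 60' row never drops below threshold -> boundary at furthest node
        assert w.boundary_eccentricity(60.0, 0.85) == 4.0

    def test_boundary_below_threshold_at_zero(self):
        grid = {(30.0, 0.0): 0.7, (30.0, 1.0): 0.6, (60.0, 1.0): 0.9}
        w = build_window(grid, "central")
        assert w.boundary_eccentricity(30.0, 0.85) == 0.0

    def test_surface_matches_nodes(self):
        grid = {(30.0, 0.0): 1.0, (30.0, 2.0): 0.8, (60.0, 1.0): 0.9, (60.0, 3.0): 0.7}
        w = build_window(grid, "central")
        for (s, e), acc in grid.items():
            assert w.surface(np.array(s), np.array(e)) == pytest.approx(acc, abs=1e-9)

    def test_v_shape_boundaries_monotone(self):
        # monotone decreasing rows, larger sizes staying high further out
        grid = {}
        for i, size in enumerate((30.0, 60.0, 120.0)):
            for ecc, acc in zip((0.0, 1.0, 2.0, 4.0), (1.0, 0.95 - 0.2 / (i + 1),
                                                       0.8 - 0.2 / (i + 1) + 0.15 * i,
                                                       0.55 + 0.1 * i)):
                grid[(size, ecc)] = acc
        w = build_window(grid, "central")
        bounds = [w.boundary_eccentricity(s, 0.85) for s in (30.0, 60.0, 120.0)]
        assert bounds == sorted(bounds)

    def test_too_few_or_collinear_nodes(self):
        with pytest.raises(ValueError):
            build_window({(30.0, 0.0): 1.0, (30.0, 1.0): 0.9}, "central")
        with pytest.raises(ValueError):
            build_window({(30.0, 0.0): 1.0, (30.0, 1.0): 0.9, (30.0, 2.0): 0.8}, "central")

    def test_accepts_condition_results(self, tiny_enn, small_calib, tiny_pyramid):
        pairs = make_novel_pairs(3, seed=30)
        ex = ENNExtractor(tiny_enn, tiny_pyramid)
        results = {}
        for size, ecc in ((30.0, 0.0), (30.0, 1.0), (60.0, 0.5)):
            spec = ConditionSpec(size, size, 0.0, ecc, "central", "symmetric")
            results[(size, ecc)] = run_condition(spec, pairs, ex, small_calib)
        w = build_window(results, "central")
        assert w.grid[(30.0, 0.0)] == 1.0


class TestCorrelationVsEccentricity:
    def test_zero_eccentricity_unity_symmetric(self, tiny_enn, small_calib, tiny_pyramid):
        pairs = make_novel_pairs(3, seed=31)
        ex = ENNExtractor(tiny_enn, tiny_pyramid)
        df = correlation_vs_eccentricity(pairs, 30.0, [0.0], ex, small_calib, "symmetric")
        assert df["mean_correlation"].iloc[0] == pytest.approx(1.0)

    def test_table_shape(self, tiny_enn, small_calib, tiny_pyramid):
        pairs = make_novel_pairs(3, seed=31)
        ex = ENNExtractor(tiny_enn, tiny_pyramid)
        df = correlation_vs_eccentricity(pairs, 30.0, [0.0, 1.0, 2.0], ex,
                                         small_calib, "asymmetric")
        assert list(df["eccentricity_deg"]) == [0.0, 1.0, 2.0]
        assert (df["n_pairs"] == 3).all()
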