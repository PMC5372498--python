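"""Windowed trend scoring, key-residue identification and fold changes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdtrend as mt
from mdtrend.trend import TrendError, WindowSpec


def _series(values, times=None, residues=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    r, f = values.shape
    return mt.ResidueEnergySeries(
        residue_numbers=np.asarray(residues if residues is not None
                                   else np.arange(1, r + 1)),
        times=np.asarray(times if times is not None else np.arange(f) * 1000.0),
        ele=values, vdw=np.zeros_like(values),
    )


class TestWindowSpec:
    def test_defaults_are_the_three_analysis_windows(self):
        spec = WindowSpec()
        assert spec.windows == ((5.0, 10.0), (20.0, 25.0), (25.0, 30.0))

    def test_rejects_overlap_and_single_window(self):
        with pytest.raises(TrendError):
            WindowSpec(((5, 10), (8, 12)))
        with pytest.raises(TrendError):
            WindowSpec(((5, 10),))

    def test_parse(self):
        spec = WindowSpec.parse("0-1,2-3")
        assert spec.windows == ((0.0, 1.0), (2.0, 3.0))


class TestWindowMeans:
    def test_constant_series(self):
        spec = WindowSpec(((0, 2), (2, 4)))
        times = np.arange(8) * 500.0  # 0..3.5 ns
        out = mt.window_means(np.full(8, 5.0), times, spec)
        np.testing.assert_allclose(out, [5.0, 5.0])

    def test_frame_index_mean(self):
        spec = WindowSpec(((0, 10), (10, 20)))
        times = np.arange(20) * 1000.0
        out = mt.window_means(np.arange(20, dtype=float), times, spec)
        assert out[0] == pytest.approx(4.5)
        assert out[1] == pytest.approx(14.5)

    def test_half_open_boundaries(self):
        spec = WindowSpec(((0, 1), (1, 2)))
        times = np.array([0.0, 1000.0])  # exactly at the boundary
        out = mt.window_means(np.array([1.0, 2.0]), times, spec)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_matches_masked_mean_oracle(self, rng):
        spec = WindowSpec()
        times = np.arange(0, 30_000, 80.0)
        values = rng.normal(size=(4, len(times)))
        out = mt.window_means(values, times, spec)
        for w, (a, b) in enumerate(spec.windows):
            mask = (times / 1000 >= a) & (times / 1000 < b)
            np.testing.assert_allclose(out[:, w], values[:, mask].mean(axis=1))

    def test_empty_window_raises_naming_it(self):
        spec = WindowSpec(((0, 1), (50, 60)))
        with pytest.raises(TrendError, match="50.*60"):
            mt.window_means(np.ones(5), np.arange(5) * 100.0, spec)


class TestTrendScore:
    @pytest.mark.parametrize("deltas,expected_pairs,expected_total", [
        ((2.0, 3.0, 1.0), (1, 1), 2),
        ((1.0, -1.0, 1.0), (-1, -1), -2),
        ((1.0, 1.0, -1.0), (1, -1), 0),
        ((-4.0, -2.0, -9.0), (1, 1), 2),
    ])
    def test_sign_consistency_examples(self, deltas, expected_pairs,
                                       expected_total):
        pairs, total = mt.trend_score(np.zeros(3), np.asarray(deltas))
        assert tuple(pairs) == expected_pairs
        assert total == expected_total

    def test_deadband_zero_never_consistent(self):
        pairs, total = mt.trend_score([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        assert total == -2

    def test_length_mismatch_raises(self):
        with pytest.raises(TrendError):
            mt.trend_score([1.0, 2.0], [1.0, 2.0, 3.0])


class TestIdentifyKeyResidues:
    def test_planted_keys_recovered_exactly(self):
        spec = mt.SyntheticSpec(seed=5)
        a, b, truth = mt.plant_trend_series(spec)
        report = mt.identify_key_residues(a, b, spec.windows)
        assert report.key_residues == truth["key_residues"]
        assert np.all(report.total_score[report.key_flag] == 2)

    def test_constant_offset_flags_everything(self):
        times = np.arange(0, 30_000, 100.0)
        base = np.tile(np.linspace(-30, -10, 5)[:, None], (1, len(times)))
        a = _series(base, times)
        b = _series(base + 7.5, times)
        report = mt.identify_key_residues(a, b)
        assert report.key_flag.all()

    def test_swap_preserves_flagged_set(self):
        spec = mt.SyntheticSpec(seed=8)
        a, b, truth = mt.plant_trend_series(spec)
        fwd = mt.identify_key_residues(a, b, spec.windows)
        rev = mt.identify_key_residues(b, a, spec.windows)
        assert fwd.key_residues == rev.key_residues

    def test_restrict_shortlist(self):
        spec = mt.SyntheticSpec(seed=5)
        a, b, truth = mt.plant_trend_series(spec)
        report = mt.identify_key_residues(a, b, spec.windows,
                                          restrict=[10, 11, 12])
        assert set(report.residue_numbers) == {10, 11, 12}
        assert report.key_residues == [10]

    def test_residue_mismatch_raises(self):
        a = _series(np.ones((2, 4)))
        b = _series(np.ones((2, 4)), residues=[7, 8])
        with pytest.raises(TrendError):
            mt.identify_key_residues(a, b, WindowSpec(((0, 2), (2, 4)),))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_rescaling_invariance(self, seed, scale, shift):
        """Scoring depends only on delta signs: a*x+b on both series (a>0)
        leaves pair scores and the flagged set unchanged."""
        r = np.random.default_rng(seed)
        spec = WindowSpec(((0, 1), (1, 2), (2, 3)))
        times = np.arange(30) * 100.0
        va = r.normal(scale=20, size=(4, 30))
        vb = va + r.choice([-8.0, 8.0], size=(4, 1))
        a1, b1 = _series(va, times), _series(vb, times)
        a2 = _series(scale * va + shift, times)
        b2 = _series(scale * vb + shift, times)
        rep1 = mt.identify_key_residues(a1, b1, spec)
        rep2 = mt.identify_key_residues(a2, b2, spec)
        np.testing.assert_array_equal(rep1.pair_scores, rep2.pair_scores)
        np.testing.assert_array_equal(rep1.key_flag, rep2.key_flag)

    def test_within_mode_scores_temporal_slopes(self):
        times = np.arange(30) * 100.0
        spec = WindowSpec(((0, 1), (1, 2), (2, 3)))
        ramp = np.concatenate([np.full(10, 1.0), np.full(10, 2.0),
                               np.full(10, 3.0)])
        a = _series(ramp, times)
        b = _series(ramp * 2 + 1, times)
        report = mt.identify_key_residues(a, b, spec, mode="within")
        assert report.key_flag.all()  # both rise monotonically


class TestFolds:
    def test_vina_energies_give_published_fold(self):
        """25.9 vs 123.7 kJ/mol binding energies differ by 4.8-fold."""
        fold = mt.relative_fold(25.9, 123.7)
        assert round(fold.value, 1) == 4.8

    def test_identity_and_magnitude_convention(self):
        assert mt.relative_fold(3.0, 3.0).value == pytest.approx(1.0)
        assert mt.relative_fold(-2.0, 4.0).value == pytest.approx(2.0)

    def test_zero_reference_raises(self):
        with pytest.raises(TrendError):
            mt.relative_fold(0.0, 5.0)

    def test_inverse_composes_to_identity(self):
        f = mt.relative_fold(25.9, 123.7).value
        g = mt.relative_fold(123.7, 25.9).value
        assert f * g == pytest.approx(1.0)

    def test_average_fold(self, rng):
        assert mt.average_fold([2.0, 4.0]) == pytest.approx(3.0)
        assert mt.average_fold([7.7]) == pytest.approx(7.7)
        vals = rng.uniform(0.1, 10, 20)
        assert mt.average_fold(vals) == pytest.approx(vals.mean())
        with pytest.raises(TrendError):
            mt.average_fold([])


class TestRmsfTrend:
    def _profiles(self, matrix, residues=None):
        matrix = np.asarray(matrix, dtype=float)
        residues = np.asarray(residues if residues is not None
                              else np.arange(1, matrix.shape[0] + 1))
        return [
            mt.RmsfProfile(residues, matrix[:, w], "protein", (0, 1))
            for w in range(matrix.shape[1])
        ]

    def test_planted_amplitude_ratio_recovered(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(0.1, 0.01, size=(5, 3)))
        a = base.copy()
        a[2] *= 2.0  # crizotinib-side residue fluctuates twice as much
        report = mt.rmsf_trend(self._profiles(a), self._profiles(base))
        k = 2
        assert report.total_score[k] == 2
        assert report.fold[k] == pytest.approx(2.0, rel=1e-9)

    def test_identical_profiles_flag_nothing(self):
        base = np.full((4, 3), 0.12)
        report = mt.rmsf_trend(self._profiles(base), self._profiles(base))
        assert not report.key_flag.any()

    def test_swap_preserves_flags(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(0.1, 0.03, size=(6, 3)))
        b = np.abs(rng.normal(0.1, 0.03, size=(6, 3)))
        fwd = mt.rmsf_trend(self._profiles(a), self._profiles(b))
        rev = mt.rmsf_trend(self._profiles(b), self._profiles(a))
        np.testing.assert_array_equal(fwd.key_flag, rev.key_flag)


class TestRecoveryPower:
    def test_exact_recovery_at_high_contrast_and_degradation_below(self):
        """Recovery is perfect when the planted offset dominates the noise
        and degrades gracefully as the contrast shrinks."""
        def recovery_rate(ratio, seeds=40):
            hits = 0
            for seed in range(seeds):
                spec = mt.SyntheticSpec(
                    n_residues=20, key_residues=frozenset({7, 15}),
                    window_offsets=(ratio * 2.0,) * 3, noise_sigma=2.0,
                    n_frames=375, dt=80.0, seed=seed,
                )
                a, b, truth = mt.plant_trend_series(spec)
                report = mt.identify_key_residues(a, b, spec.windows)
                hits += report.key_residues == truth["key_residues"]
            return hits / seeds

        assert recovery_rate(5.0) == 1.0
        assert recovery_rate(0.02) < 1.0
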