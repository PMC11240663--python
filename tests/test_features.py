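"""Windowing, purity labelling and the per-window statistics against
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from broileracc import errors
from broileracc.features import (
    WindowSpec,
    count_peaks_troughs,
    extract_features,
    segment,
    shannon_entropy,
    spectral_peak_stats,
    stats9,
    window_label,
)
from broileracc.io import LabelTrack
from broileracc.names import FEATURE_FAMILIES, FEATURE_NAMES
from broileracc.signal import decompose
from broileracc.simulate import DEFAULT_PROFILES, SimConfig, simulate_bird


class TestSegment:
    def test_nine_seconds_gives_five_windows(self):
        spans = segment(450, 50.0, WindowSpec(3.0, 0.5))
        assert spans == [(0, 150), (75, 225), (150, 300), (225, 375), (300, 450)]

    def test_exactly_one_window(self):
        assert segment(150, 50.0, WindowSpec(3.0, 0.5)) == [(0, 150)]

    def test_short_trace_gives_no_windows(self):
        assert segment(145, 50.0, WindowSpec(3.0, 0.5)) == []

    @settings(deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=150, max_value=5000),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_window_count_formula(self, n, overlap):
        spec = WindowSpec(3.0, overlap)
        w = int(round(spec.length_s * 50))
        hop = int(round(spec.step_s * 50))
        expected = (n - w) // hop + 1
        assert len(segment(n, 50.0, spec)) == expected


class TestWindowLabel:
    def track(self, *intervals):
        return LabelTrack(bird_id="b", strain="CNV", intervals=list(intervals))

    def test_pure_window_at_full_threshold(self):
        t = self.track((0.0, 10.0, "sit"))
        assert window_label(2.0, 5.0, t, 1.0) == ("sit", 1.0)

    def test_majority_behaviour_above_threshold(self):
        t = self.track((0.0, 2.0, "sit"), (2.0, 3.0, "stand"))
        behaviour, purity = window_label(0.0, 3.0, t, 0.6)
        assert behaviour == "sit"
        assert purity == pytest.approx(2.0 / 3.0)

    def test_tie_below_threshold_is_discarded(self):
        t = self.track((0.0, 1.5, "sit"), (1.5, 3.0, "stand"))
        assert window_label(0.0, 3.0, t, 0.6) is None

    def test_unannotated_time_counts_against_purity(self):
        t = self.track((0.0, 2.0, "walk"))  # window 0-4 is half unannotated
        assert window_label(0.0, 4.0, t, 0.6) is None
        behaviour, purity = window_label(0.0, 4.0, t, 0.5)
        assert (behaviour, purity) == ("walk", pytest.approx(0.5))

    def test_other_counts_against_purity(self):
        t = self.track((0.0, 2.0, "sit"), (2.0, 3.0, "other"))
        assert window_label(0.0, 3.0, t, 0.7) is None


class TestStats9:
    def test_constant_series_degenerate_values(self):
        assert stats9(np.full(10, -2.5)) == pytest.approx(
            (-2.5, -2.5, 2.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        )

    def test_symmetric_series_has_zero_skew(self):
        assert stats9(np.array([-1.0, 0.0, 1.0]))[4] == pytest.approx(0.0)

    def test_moments_match_direct_formula_oracle(self):
        series = np.array([1.0, 2.0, 3.0, 4.0])
        n = len(series)
        mean = series.mean()
        sd = np.sqrt(((series - mean) ** 2).sum() / (n - 1))
        skew_oracle = ((series - mean) ** 3).sum() / (n - 1) / sd**3
        kurt_oracle = ((series - mean) ** 4).sum() / (n - 1) / sd**4
        out = stats9(series)
        assert out[4] == pytest.approx(skew_oracle)
        assert out[5] == pytest.approx(kurt_oracle)
        assert kurt_oracle == pytest.approx(1.23)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=60))
    def test_random_series_match_elementwise_oracles(self, values):
        series = np.asarray(values)
        out = stats9(series)
        assert out[0] == pytest.approx(min(values))
        assert out[1] == pytest.approx(max(values))
        assert out[2] == pytest.approx(np.mean(np.abs(series)))
        q25, q75 = np.percentile(series, [25, 75])
        assert out[3] == pytest.approx(q75 - q25)

    def test_too_short_series_rejected(self):
        with pytest.raises(errors.SeriesTooShort):
            stats9(np.array([1.0]))


class TestEntropy:
    def test_uniform_four_bins(self):
        series = np.repeat([0.1, 0.35, 0.6, 0.85], 25)
        assert shannon_entropy(series, n_bins=4) == pytest.approx(np.log(4))

    def test_single_bin_and_constant_are_zero(self):
        assert shannon_entropy(np.full(50, 3.3)) == 0.0
        assert shannon_entropy(np.linspace(0, 1, 50), n_bins=1) == 0.0

    def test_two_bin_asymmetric_split(self):
        series = np.concatenate([np.full(25, 0.1), np.full(75, 0.9)])
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert shannon_entropy(series, n_bins=2) == pytest.approx(expected)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_matches_histogram_oracle_on_random_input(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=200)
        counts, _ = np.histogram(series, bins=10, range=(series.min(), series.max()))
        p = counts[counts > 0] / counts.sum()
        assert shannon_entropy(series, n_bins=10) == pytest.approx(-(p * np.log(p)).sum())


class TestPeaksTroughs:
    def test_monotone_series(self):
        assert count_peaks_troughs(np.arange(10.0)) == (0, 0)

    def test_one_sine_cycle(self):
        t = np.linspace(0, 1, 200, endpoint=False)
        assert count_peaks_troughs(np.sin(2 * np.pi * t)) == (1, 1)

    def test_three_hz_sine_in_three_second_window(self):
        t = np.arange(150) / 50.0
        series = np.sin(2 * np.pi * 3.0 * t)
        assert count_peaks_troughs(series) == (9, 9)

    def test_plateau_counts_once(self):
        series = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0, 0.0])
        assert count_peaks_troughs(series) == (1, 1)

    def test_matches_scipy_find_peaks_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            series = np.round(rng.normal(size=80), 1)  # ties induce plateaus
            peaks = len(find_peaks(series)[0])
            troughs = len(find_peaks(-series)[0])
            assert count_peaks_troughs(series) == (peaks, troughs)


class TestSpectralPeaks:
    def test_pure_tone_frequency_recovered(self):
        fs = 50.0
        t = np.arange(150) / fs
        out = spectral_peak_stats(np.sin(2 * np.pi * 5.0 * t), fs)
        bin_width = fs / 150
        for stat in out[:3]:  # min, max, absmean of peak frequencies
            assert abs(stat - 5.0) <= bin_width
        assert out[3] == pytest.approx(0.0, abs=bin_width)  # single peak: IQR 0

    def test_two_tone_mean_frequency(self):
        fs = 50.0
        t = np.arange(150) / fs
        series = np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 8.0 * t)
        out = spectral_peak_stats(series, fs)
        assert out[0] == pytest.approx(3.0, abs=fs / 150)
        assert out[1] == pytest.approx(8.0, abs=fs / 150)
        assert out[2] == pytest.approx(5.5, abs=2 * fs / 150)

    def test_zero_signal_has_no_peaks(self):
        assert spectral_peak_stats(np.zeros(64), 50.0) == tuple([0.0] * 8)


@pytest.fixture(scope="module")
def bird_features(one_bird):
    trace, track = one_bird
    return extract_features(decompose(trace), track, purity_threshold=0.6)


class TestExtractFeatures:
    def test_exactly_99_finite_attributes(self, bird_features):
        assert len(bird_features) > 0
        values = bird_features[FEATURE_NAMES].to_numpy()
        assert values.shape[1] == 99
        assert np.isfinite(values).all()

    def test_family_sizes_are_27_27_9_12_24(self):
        sizes = [len(v) for v in FEATURE_FAMILIES.values()]
        assert sizes == [27, 27, 9, 12, 24]
        assert sum(sizes) == 99

    def test_extraction_is_deterministic(self, one_bird):
        trace, track = one_bird
        a = extract_features(decompose(trace), track, purity_threshold=0.6)
        b = extract_features(decompose(trace), track, purity_threshold=0.6)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_translation_covariance(self, one_bird):
        trace, track = one_bird
        a = extract_features(decompose(trace), track, purity_threshold=0.6)
        shifted = type(trace)(
            bird_id=trace.bird_id, strain=trace.strain, fs=trace.fs,
            t=trace.t + 100.0, x=trace.x, y=trace.y, z=trace.z,
        )
        b = extract_features(decompose(shifted), track_shift(track, 100.0), purity_threshold=0.6)
        np.testing.assert_allclose(
            b["window_start_s"].to_numpy(), a["window_start_s"].to_numpy() + 100.0
        )
        np.testing.assert_allclose(
            b[FEATURE_NAMES].to_numpy(), a[FEATURE_NAMES].to_numpy(), rtol=1e-9
        )


def track_shift(track: LabelTrack, dt: float) -> LabelTrack:
    return LabelTrack(
        bird_id=track.bird_id,
        strain=track.strain,
        intervals=[(s + dt, e + dt, b) for s, e, b in track.intervals],
    )
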