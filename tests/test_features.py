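import numpy as np
import pytest

from respiqual.augmentation import mirror
from respiqual.core import Segment, ValidationError
from respiqual.features import (
    DEFAULT_FEATURE_SUBSET,
    FEATURE_NAMES,
    autocorr_features,
    feature_subset,
    feature_vector,
    mrmr_select,
    psd_features,
    subsegment,
)
from respiqual.preprocessing import normalize_segment

from conftest import sinusoid_segment

FS = 16.0


class TestAutocorr:
    def test_pure_tone_peak_amplitude_and_lag(self):
        seg = normalize_segment(sinusoid_segment(0.25))
        ap1, ap2, ratio = autocorr_features(seg)
        assert ap1 >= 0.9
        # locate the first peak lag directly for the lag check
        x = seg.samples
        n = x.size
        acf = np.correlate(x, x, "full")[n - 1 :] / (n - np.arange(n)) * n / (x @ x)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(acf[: int(np.ceil(FS / 0.05)) + 1], prominence=0.01)
        first = peaks[peaks >= int(FS / 0.70)][0]
        assert abs(first - 64) <= 1  # 4-s period at 16 Hz
        assert ratio == pytest.approx(ap1 / ap2)

    def test_white_noise_has_weak_peaks(self, white_noise):
        ap1, _, _ = autocorr_features(normalize_segment(white_noise))
        assert ap1 < 0.2

    def test_no_peak_guard(self):
        # critically damped decay: ACF has no positive-lag local maximum
        t = np.arange(960) / FS
        seg = normalize_segment(Segment(np.exp(-t), FS, "r"))
        ap1, ap2, ratio = autocorr_features(seg)
        assert (ap1, ap2, ratio) == (0.0, 0.0, 0.0)

    def test_ap1_decreases_with_added_noise(self):
        rng = np.random.default_rng(0)
        base = sinusoid_segment(0.25).samples
        noise = rng.standard_normal(base.size)
        ap1s = []
        for snr_amp in (0.0, 0.5, 1.0, 2.0, 4.0):
            seg = normalize_segment(Segment(base + snr_amp * noise, FS, "r"))
            ap1s.append(autocorr_features(seg)[0])
        assert all(a >= b for a, b in zip(ap1s, ap1s[1:]))


class TestPsd:
    def test_pure_tone_band(self):
        seg = normalize_segment(sinusoid_segment(0.3))
        bw, f_low, f_up, npow = psd_features(seg)
        assert f_low <= 0.3 <= f_up
        assert bw <= 0.1
        assert npow >= 0.9

    def test_bandpassed_noise_spreads_power(self, white_noise):
        from respiqual.preprocessing import bandpass_filter

        x = bandpass_filter(white_noise.samples, FS)
        seg = normalize_segment(Segment(x, FS, "r"))
        *_, npow = psd_features(seg)
        assert npow < 0.5

    def test_two_equal_tones_split_power(self):
        t = np.arange(960) / FS
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 0.5 * t)
        *_, npow = psd_features(normalize_segment(Segment(x, FS, "r")))
        assert npow == pytest.approx(0.5, abs=0.1)


class TestSubsegment:
    @pytest.mark.parametrize(
        "duration,overlap,expected",
        [(60.0, 0.0, 4), (30.0, 10.0, 4), (15.0, 0.0, 1)],
    )
    def test_window_counts(self, duration, overlap, expected):
        seg = Segment(np.zeros(int(duration * FS)), FS, "r")
        assert len(subsegment(seg, 15.0, overlap)) == expected

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValidationError):
            subsegment(Segment(np.zeros(100), FS, "r"), 15.0)


class TestFeatureVector:
    def test_length_and_finiteness(self, breathing_segment):
        v = feature_vector(normalize_segment(breathing_segment))
        assert v.shape == (21,)
        assert np.all(np.isfinite(v))

    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_mirror_invariance(self, breathing_segment, axis):
        seg = normalize_segment(breathing_segment)
        v = feature_vector(seg)
        vm = feature_vector(normalize_segment(mirror(seg, axis)))
        assert np.max(np.abs(v - vm)) < 1e-9

    def test_scale_invariance_after_normalization(self, breathing_segment):
        v1 = feature_vector(normalize_segment(breathing_segment))
        scaled = breathing_segment.with_(samples=7.3 * breathing_segment.samples)
        v2 = feature_vector(normalize_segment(scaled))
        assert np.allclose(v1, v2, atol=1e-9)

    def test_single_subsegment_has_zero_stds(self):
        seg = normalize_segment(sinusoid_segment(0.25, duration_s=15.0))
        v = feature_vector(seg)
        assert np.all(v[14:] == 0.0)  # std block of a single observation

    def test_named_subset_extraction(self):
        v = np.arange(21.0)
        out = feature_subset(v, DEFAULT_FEATURE_SUBSET)
        idx = [FEATURE_NAMES.index(n) for n in DEFAULT_FEATURE_SUBSET]
        assert np.array_equal(out, v[idx])
        # the five selected descriptors, in order
        assert DEFAULT_FEATURE_SUBSET == (
            "whole_ap1",
            "sub_std_ap1",
            "whole_f_low",
            "sub_mean_bandwidth",
            "sub_mean_norm_power",
        )


class TestMrmr:
    def _data(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.standard_normal((n, 10))
        X[:, 3] = y + 0.05 * rng.standard_normal(n)  # informative feature
        return X, y

    def test_informative_feature_found(self):
        X, y = self._data()
        assert mrmr_select(X, y, k=1).names == ("f3",)

    def test_redundant_duplicate_not_picked_second(self):
        X, y = self._data()
        X[:, 7] = X[:, 3] + 1e-6  # near-duplicate of the informative feature
        sel = mrmr_select(X, y, k=2)
        assert sel.names[0] in ("f3", "f7")
        assert sel.names[1] not in ("f3", "f7")

    def test_k_equals_p_returns_ranking(self):
        X, y = self._data()
        sel = mrmr_select(X, y, k=10)
        assert sorted(sel.names) == sorted(f"f{i}" for i in range(10))

    def test_row_permutation_invariance(self):
        X, y = self._data(seed=5)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(y))
        assert mrmr_select(X, y, k=4).names == mrmr_select(X[perm], y[perm], k=4).names

    def test_single_class_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValidationError):
            mrmr_select(X, np.zeros(len(X)), k=2)
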