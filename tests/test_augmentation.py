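import numpy as np
import pytest
from scipy.signal import periodogram

from respiqual.augmentation import (
    AugmentationPolicy,
    amplitude_modulate,
    balance_augment,
    fast_concat,
    mirror,
    slow_stretch,
)
from respiqual.core import LabeledDataset, Segment, ValidationError

FS = 16.0


def _seg(samples, rec="r0", label="clean"):
    return Segment(np.asarray(samples, dtype=float), FS, rec, label=label)


def _sine(freq, duration=60.0, label="clean", rec="r0"):
    t = np.arange(int(duration * FS)) / FS
    return _seg(np.sin(2 * np.pi * freq * t), rec=rec, label=label)


def _peak_freq(x):
    f, p = periodogram(x - x.mean(), fs=FS)
    return f[np.argmax(p)], f[1] - f[0]


class TestMirror:
    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_involution(self, axis):
        rng = np.random.default_rng(0)
        seg = _seg(rng.standard_normal(480))
        back = mirror(mirror(seg, axis), axis)
        assert np.array_equal(back.samples, seg.samples)

    def test_class_and_type_preserved(self):
        seg = Segment(np.arange(480.0), FS, "r0", breathing_type="Ch", label="noisy")
        out = mirror(seg, "x")
        assert (out.label, out.breathing_type, out.provenance) == ("noisy", "Ch", "mirror-x")


class TestAmplitudeModulate:
    def test_all_ones_input_reveals_envelope(self):
        n = 101
        out = amplitude_modulate(_seg(np.ones(n)))
        expected = np.sin(np.pi * np.arange(n) / (n - 1))
        assert np.allclose(out.samples, expected)
        assert out.samples[0] == 0.0 and out.samples[-1] == pytest.approx(0.0, abs=1e-12)

    def test_center_sample_unchanged(self):
        seg = _seg(np.arange(1.0, 482.0))  # odd length 481, center index 240
        out = amplitude_modulate(seg)
        assert out.samples[240] == pytest.approx(seg.samples[240])

    def test_envelope_unimodal_with_central_maximum(self):
        seg = _sine(0.25)
        out = amplitude_modulate(seg)
        env = np.abs(out.samples)
        # block maxima of the envelope rise then fall, peaking mid-segment
        blocks = env[: 960 // 6 * 6].reshape(6, -1).max(axis=1)
        assert np.argmax(blocks) in (2, 3)
        assert blocks[0] < blocks[2] and blocks[-1] < blocks[3]

    def test_floor_lifts_the_ends(self):
        out = amplitude_modulate(_seg(np.ones(100)), floor=0.2)
        assert out.samples[0] == pytest.approx(0.2)


class TestSlowStretch:
    def test_cut_arithmetic(self):
        seg = _seg(np.random.default_rng(0).standard_normal(960))
        out = slow_stretch(seg)
        assert out.n_samples == 960          # 48 cut per end, 864 -> 960
        assert out.duration == seg.duration

    def test_slows_a_tone_by_ten_percent(self):
        out = slow_stretch(_sine(0.3))
        f, df = _peak_freq(out.samples)
        assert abs(f - 0.27) <= df

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            slow_stretch(_seg(np.ones(10)))


class TestFastConcat:
    def test_doubles_the_rate(self):
        a, b = _sine(0.2), _sine(0.2)
        out = fast_concat(a, b)
        assert out.n_samples == a.n_samples
        f, df = _peak_freq(out.samples)
        assert abs(f - 0.4) <= df

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fast_concat(_sine(0.2, label="clean"), _sine(0.2, label="noisy"))

    def test_recording_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fast_concat(_sine(0.2, rec="a"), _sine(0.2, rec="b"))


class TestBalanceAugment:
    def _dataset(self, n_clean, n_noisy):
        rng = np.random.default_rng(1)
        segs = [
            _seg(rng.standard_normal(480), rec=f"r{i % 5}", label="clean")
            for i in range(n_clean)
        ] + [
            _seg(rng.standard_normal(480), rec=f"r{i % 5}", label="noisy")
            for i in range(n_noisy)
        ]
        return LabeledDataset(segs)

    @pytest.mark.parametrize("n_minority,expected", [(202, 808), (208, 832), (26, 104), (83, 332)])
    def test_two_method_policy_quadruples_the_minority(self, n_minority, expected):
        ds = self._dataset(n_minority, n_minority + 40)
        policy = AugmentationPolicy(methods=("mirror", "modulate"), seed=0)
        out = balance_augment(ds, policy)
        assert out.class_counts()["clean"] == expected

    def test_majority_balanced_within_variant_count(self):
        ds = self._dataset(83, 216)
        policy = AugmentationPolicy(methods=("mirror", "modulate"), seed=0)
        out = balance_augment(ds, policy)
        counts = out.class_counts()
        assert counts == {"clean": 332, "noisy": 330}
        assert abs(counts["clean"] - counts["noisy"]) <= policy.variants_per_original

    def test_four_method_minority_arithmetic(self):
        rng = np.random.default_rng(2)
        segs = [
            _seg(rng.standard_normal(480), rec="r0", label="clean") for _ in range(10)
        ] + [
            _seg(rng.standard_normal(480), rec="r0", label="noisy") for _ in range(40)
        ]
        out = balance_augment(LabeledDataset(segs), AugmentationPolicy(seed=0))
        # 10 originals + 20 mirrored + 10 modulated + 10 slow + 10 fast
        assert out.class_counts()["clean"] == 60

    def test_label_preservation_and_determinism(self):
        ds = self._dataset(20, 35)
        policy = AugmentationPolicy(seed=4)
        out1 = balance_augment(ds, policy)
        out2 = balance_augment(ds, policy)
        assert all(
            s.label in ("clean", "noisy") and s.provenance != "corrupted"
            for s in out1.segments
        )
        assert len(out1) == len(out2)
        assert all(
            np.array_equal(a.samples, b.samples)
            for a, b in zip(out1.segments, out2.segments)
        )

    def test_empty_class_rejected(self):
        ds = self._dataset(5, 0)
        # constructing with zero noisy leaves a single class
        with pytest.raises(ValidationError):
            balance_augment(ds, AugmentationPolicy(seed=0))
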