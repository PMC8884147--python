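import numpy as np
import pytest
from scipy.signal import periodogram

from respiqual.core import Segment, ValidationError
from respiqual.models.heuristic import heuristic_sqi
from respiqual.synth import (
    ArtefactSpec,
    BlockSpec,
    CRITICAL_FRACTION,
    ProtocolSpec,
    default_protocol,
    generate_dataset,
    generate_recording,
    inject_artefact,
    uniform_protocol,
)

FS = 16.0


class TestGenerateRecording:
    def test_duration_and_coverage(self):
        spec = default_protocol()
        rec = generate_recording(spec, seed=1)
        assert rec.duration == spec.total_duration == 60 + 20 + 5 * 30
        covered = sum(iv.duration for iv in rec.intervals)
        assert covered == pytest.approx(rec.duration)

    def test_blockwise_dominant_frequency(self):
        spec = default_protocol(
            jitter_sigma=0.0, amplitude_sigma=0.0, noise_std=0.0, wander_amplitude=0.0
        )
        rec = generate_recording(spec, seed=3)
        rng = np.random.default_rng(3)
        for iv in rec.intervals:
            if iv.pattern == "Hold":
                continue
            x = rec.samples[int(iv.start * FS) : int(iv.end * FS)]
            f, p = periodogram(x - x.mean(), fs=FS)
            peak_bpm = f[np.argmax(p)] * 60.0
            # requested rate is drawn from the pattern range; peak must be
            # within +-20% of it (one bin of slack on short blocks)
            df_bpm = (f[1] - f[0]) * 60.0
            from respiqual.synth import PATTERN_RATE_RANGES

            lo, hi = PATTERN_RATE_RANGES[iv.pattern]
            assert lo * 0.8 - df_bpm <= peak_bpm <= hi * 1.2 + df_bpm

    def test_hold_is_near_constant(self):
        spec = default_protocol(noise_std=0.0, wander_amplitude=0.0)
        rec = generate_recording(spec, seed=2)
        hold = next(iv for iv in rec.intervals if iv.pattern == "Hold")
        x = rec.samples[int(hold.start * FS) : int(hold.end * FS)]
        assert np.ptp(x) < 1e-12

    def test_zero_jitter_block_has_exact_cycle_count(self):
        spec = ProtocolSpec(
            blocks=(BlockSpec("Sp", 30.0, rate_bpm=12.0),),
            hold_s=0.0, hold_after_block=0,
            jitter_sigma=0.0, amplitude_sigma=0.0, noise_std=0.0, wander_amplitude=0.0,
        )
        rec = generate_recording(spec, seed=0)
        # 0.2 Hz x 30 s -> exactly 6 cycles: 6 rising crossings of 0.5
        x = rec.samples
        crossings = np.sum((x[:-1] < 0.5) & (x[1:] >= 0.5))
        assert crossings == 6

    def test_determinism(self):
        spec = default_protocol()
        a = generate_recording(spec, seed=7)
        b = generate_recording(spec, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            BlockSpec("Sp", 30.0, rate_bpm=50.0)
        with pytest.raises(ValidationError):
            BlockSpec("Sp", -1.0)
        with pytest.raises(ValidationError):
            ProtocolSpec(blocks=())


class TestInjectArtefact:
    def _seg(self, duration=60.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + 0.01 * rng.standard_normal(t.size)
        return Segment(x, FS, "r0", label="clean")

    def test_zero_severity_changes_only_provenance(self):
        seg = self._seg()
        out = inject_artefact(seg, ArtefactSpec("noise-burst", 10.0, 5.0, 0.0), seed=1)
        assert np.array_equal(out.samples, seg.samples)
        assert out.provenance == "corrupted"

    def test_samples_outside_window_unchanged(self):
        seg = self._seg()
        out = inject_artefact(seg, ArtefactSpec("noise-burst", 10.0, 5.0, 2.0), seed=1)
        i0, i1 = int(10 * FS), int(15 * FS)
        assert np.array_equal(out.samples[:i0], seg.samples[:i0])
        assert np.array_equal(out.samples[i1:], seg.samples[i1:])
        assert not np.array_equal(out.samples[i0:i1], seg.samples[i0:i1])

    def test_clipping_attains_the_clip_level(self):
        seg = self._seg()
        out = inject_artefact(seg, ArtefactSpec("clipping", 0.0, 60.0, 1.0), seed=0)
        i0, i1 = 0, seg.n_samples
        level = np.max(np.abs(seg.samples)) / 2.0
        assert np.max(np.abs(out.samples[i0:i1])) == pytest.approx(level)

    def test_critical_coverage_flips_the_label(self):
        seg = self._seg()
        noisy = inject_artefact(seg, ArtefactSpec("amplitude-dropout", 0.0, 20.0, 1.0), seed=0)
        assert noisy.label == "noisy"  # 20/60 > 16.6%
        still_clean = inject_artefact(
            seg, ArtefactSpec("amplitude-dropout", 0.0, 5.0, 1.0), seed=0
        )
        assert still_clean.label == "clean"  # 5/60 < 16.6%

    def test_window_outside_segment_rejected(self):
        with pytest.raises(ValidationError):
            inject_artefact(self._seg(), ArtefactSpec("noise-burst", 55.0, 10.0, 1.0), seed=0)


class TestGenerateDataset:
    def test_prevalence_matches_requested_mix(self):
        mix = {"noise-burst": 0.25, "amplitude-dropout": 0.25}
        ds = generate_dataset(20, default_protocol(), mix, seed=0)
        frac_noisy = ds.class_counts()["noisy"] / len(ds)
        assert abs(frac_noisy - 0.5) <= 0.1

    def test_zero_mix_gives_all_clean(self):
        ds = generate_dataset(3, default_protocol(), {}, seed=0)
        assert ds.class_counts()["noisy"] == 0

    def test_different_seeds_differ(self):
        ds1 = generate_dataset(2, default_protocol(), {}, seed=0)
        ds2 = generate_dataset(2, default_protocol(), {}, seed=1)
        assert any(
            not np.array_equal(a.samples, b.samples)
            for a, b in zip(ds1.segments, ds2.segments)
        )

    def test_segments_grouped_by_breathing_type(self):
        ds = generate_dataset(2, default_protocol(), {}, seed=0)
        groups = ds.by_breathing_type()
        assert set(groups) == {"Sp", "Ch", "Sh", "Ab", "Sl", "Fa"}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            generate_dataset(0, default_protocol(), {}, seed=0)
        with pytest.raises(ValidationError):
            generate_dataset(1, default_protocol(), {"noise-burst": 1.5}, seed=0)


class TestHeuristicAgreement:
    """Generated classes must agree with the heuristic quality index."""

    def test_clean_segments_pass_and_corrupted_fail(self):
        spec = uniform_protocol(
            "Sp", 300.0, rate_range=(10, 16), noise_std=0.0, wander_amplitude=0.0
        )
        clean = generate_dataset(6, spec, {}, seed=3, seg_len_s=60.0).segments
        pass_rate = np.mean([heuristic_sqi(s) == "high" for s in clean])
        assert pass_rate >= 0.9

        rng = np.random.default_rng(4)
        corrupted = [
            inject_artefact(
                s,
                ArtefactSpec("noise-burst", 0.0, s.duration, severity=2.0),
                seed=int(rng.integers(2**31 - 1)),
            )
            for s in clean
        ]
        fail_rate = np.mean([heuristic_sqi(s) == "low" for s in corrupted])
        assert fail_rate >= 0.9
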