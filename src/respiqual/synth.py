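"""Synthetic respiration recordings with controllable patterns and artefacts.

No public accession exists for the clinical bio-impedance datasets this
framework targets, so every downstream stage is exercised on generated
waveforms.  A recording follows a controlled breathing protocol: a block of
spontaneous breathing, a breath hold (near-constant baseline), then blocks of
chest, shallow, abdominal, slow and fast breathing.  Each block is a train of
raised-cosine breath cycles at a pattern-specific rate with per-breath
lognormal period jitter; shallow breathing is attenuated in amplitude, and
abdominal breathing uses a more asymmetric inspiration/expiration split.
These choices reproduce the gross morphology differences between patterns
without claiming physiological fidelity.

Artefacts (baseline steps, noise bursts, amplitude dropouts, motion spikes,
clipping) are injected into known windows; a segment's ground-truth class is
*noisy* exactly when artefact windows cover at least the critical fraction
(16.6%) of its length — the same time-coverage guideline annotators use when
grading real segments as average/bad quality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    Interval,
    LabeledDataset,
    Recording,
    Segment,
    ValidationError,
    BREATH_HOLD,
)
from .preprocessing import segment_recording

#: Artefact coverage (fraction of segment length) at which a segment's
#: ground-truth class flips to noisy.
CRITICAL_FRACTION = 0.166

ARTEFACT_KINDS = (
    "baseline-step",
    "noise-burst",
    "amplitude-dropout",
    "motion-spike",
    "clipping",
)

#: Plausible breathing-rate range per pattern (breaths/min), inside the
#: 3-42 breaths/min filter passband.
PATTERN_RATE_RANGES: dict[str, tuple[float, float]] = {
    "Sp": (10, 16),
    "Ch": (10, 16),
    "Ab": (10, 16),
    "Sh": (12, 18),
    "Sl": (4, 7),
    "Fa": (25, 40),
}

#: Inspiration fraction of the breath cycle (abdominal more asymmetric,
#: chest sinusoidal-ish) and amplitude scale (shallow attenuated).
PATTERN_INSP_FRACTION = {"Ab": 0.35, "Ch": 0.50}
DEFAULT_INSP_FRACTION = 0.42
PATTERN_AMPLITUDE = {"Sh": 0.3}


@dataclass(frozen=True)
class BlockSpec:
    """One protocol block: ``rate_bpm=None`` means "draw from the pattern's
    plausible range" when a recording is generated."""

    pattern: str
    duration_s: float
    rate_bpm: float | None = None
    amplitude: float | None = None
    insp_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("block duration must be positive")
        if self.rate_bpm is not None and not 3.0 <= self.rate_bpm <= 42.0:
            raise ValidationError("breathing rate must lie in [3, 42] breaths/min")


@dataclass(frozen=True)
class ProtocolSpec:
    """Block sequence + breath hold + sampling rate of a recording protocol."""

    blocks: tuple[BlockSpec, ...]
    hold_s: float = 20.0
    hold_after_block: int = 1  # hold inserted after this many blocks (0 = none)
    fs: float = 16.0
    jitter_sigma: float = 0.05
    amplitude_sigma: float = 0.1
    noise_std: float = 0.02
    wander_amplitude: float = 0.15
    #: optional per-pattern overrides of the plausible rate range
    rate_ranges: dict | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("protocol needs at least one block")
        if self.hold_s < 0:
            raise ValidationError("hold duration must be non-negative")
        max_rate_hz = max((b.rate_bpm or PATTERN_RATE_RANGES.get(b.pattern, (3, 42))[1])
                          for b in self.blocks) / 60.0
        if self.fs <= 2 * max_rate_hz:
            raise ValidationError("sampling rate must exceed twice the fastest rate")

    @property
    def total_duration(self) -> float:
        hold = self.hold_s if self.hold_after_block > 0 else 0.0
        return sum(b.duration_s for b in self.blocks) + hold


def default_protocol(fs: float = 16.0, **kwargs) -> ProtocolSpec:
    """The six-block controlled breathing protocol: 1 min spontaneous,
    a breath hold, then 30-s blocks of chest, shallow, abdominal, slow and
    fast breathing."""
    blocks = (BlockSpec("Sp", 60.0),) + tuple(
        BlockSpec(p, 30.0) for p in ("Ch", "Sh", "Ab", "Sl", "Fa")
    )
    return ProtocolSpec(blocks=blocks, fs=fs, **kwargs)


def uniform_protocol(
    pattern: str = "Sp",
    total_s: float = 300.0,
    rate_range: tuple[float, float] | None = None,
    fs: float = 16.0,
    **kwargs,
) -> ProtocolSpec:
    """A single-pattern protocol with no breath hold — convenient for
    generating many same-pattern segments (e.g. a source-domain corpus)."""
    block = BlockSpec(pattern, total_s)
    ranges = {pattern: rate_range} if rate_range is not None else None
    return ProtocolSpec(
        blocks=(block,), hold_s=0.0, hold_after_block=0, fs=fs,
        rate_ranges=ranges, **kwargs,
    )


def _breath_train(
    rng: np.random.Generator,
    duration_s: float,
    fs: float,
    rate_bpm: float,
    insp_fraction: float,
    amplitude: float,
    jitter_sigma: float,
    amplitude_sigma: float,
) -> np.ndarray:
    """Concatenated raised-cosine breath cycles covering ``duration_s``."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    mean_period = 60.0 / rate_bpm
    start = 0.0
    while start < duration_s:
        period = mean_period * (
            float(rng.lognormal(0.0, jitter_sigma)) if jitter_sigma > 0 else 1.0
        )
        amp = amplitude * (
            float(rng.lognormal(0.0, amplitude_sigma)) if amplitude_sigma > 0 else 1.0
        )
        mask = (t >= start) & (t < start + period)
        tau = (t[mask] - start) / period
        r = insp_fraction
        breath = np.where(
            tau < r,
            0.5 * (1.0 - np.cos(np.pi * tau / r)),
            0.5 * (1.0 + np.cos(np.pi * (tau - r) / (1.0 - r))),
        )
        x[mask] = amp * breath
        start += period
    return x


def generate_recording(spec: ProtocolSpec, seed: int) -> Recording:
    """Generate one protocol-structured recording.

    Deterministic given (spec, seed).  Pattern blocks are quasi-periodic at
    their (possibly drawn) target rate; the breath-hold interval is a
    near-constant baseline; low-frequency baseline wander and white sensor
    noise are superimposed at the spec's (small) default levels.
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs
    pieces: list[np.ndarray] = []
    intervals: list[Interval] = []
    cursor = 0.0

    def emit_hold() -> None:
        nonlocal cursor
        if spec.hold_s <= 0:
            return
        pieces.append(np.zeros(int(round(spec.hold_s * fs))))
        intervals.append(Interval(BREATH_HOLD, cursor, cursor + spec.hold_s))
        cursor += spec.hold_s

    for i, block in enumerate(spec.blocks):
        if block.rate_bpm is not None:
            rate = block.rate_bpm
        else:
            ranges = spec.rate_ranges or {}
            lo, hi = ranges.get(
                block.pattern, PATTERN_RATE_RANGES.get(block.pattern, (10, 16))
            )
            rate = float(rng.uniform(lo, hi))
        amp = block.amplitude if block.amplitude is not None else PATTERN_AMPLITUDE.get(block.pattern, 1.0)
        insp = (
            block.insp_fraction
            if block.insp_fraction is not None
            else PATTERN_INSP_FRACTION.get(block.pattern, DEFAULT_INSP_FRACTION)
        )
        pieces.append(
            _breath_train(
                rng, block.duration_s, fs, rate, insp, amp,
                spec.jitter_sigma, spec.amplitude_sigma,
            )
        )
        intervals.append(Interval(block.pattern, cursor, cursor + block.duration_s))
        cursor += block.duration_s
        if i + 1 == spec.hold_after_block:
            emit_hold()

    x = np.concatenate(pieces)
    n = x.size
    if spec.wander_amplitude > 0:
        t = np.arange(n) / fs
        f1, f2 = rng.uniform(0.005, 0.02, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        x = x + spec.wander_amplitude * (
            np.sin(2 * np.pi * f1 * t + ph1) + 0.5 * np.sin(2 * np.pi * f2 * t + ph2)
        )
    if spec.noise_std > 0:
        x = x + spec.noise_std * rng.standard_normal(n)
    return Recording(samples=x, fs=fs, recording_id=f"synthetic-{seed}", intervals=intervals)


@dataclass(frozen=True)
class ArtefactSpec:
    """A corrupting event: kind, placement inside the host segment, severity.

    Severity is dimensionless and >= 0; severity 0 leaves the samples
    untouched (only the provenance changes).
    """

    kind: str
    onset_s: float
    duration_s: float
    severity: float

    def __post_init__(self) -> None:
        if self.kind not in ARTEFACT_KINDS:
            raise ValidationError(f"unknown artefact kind {self.kind!r}")
        if self.severity < 0:
            raise ValidationError("artefact severity must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("artefact duration must be positive")


def inject_artefact(
    seg: Segment,
    artefact: ArtefactSpec,
    seed: int,
    critical_fraction: float = CRITICAL_FRACTION,
) -> Segment:
    """Apply an artefact to a window of the segment.

    Samples outside the window are unchanged.  The output carries provenance
    ``"corrupted"`` and is labelled noisy when the window covers at least
    ``critical_fraction`` of the segment (otherwise the label is kept).
    """
    if artefact.onset_s < 0 or artefact.onset_s + artefact.duration_s > seg.duration + 1e-9:
        raise ValidationError("artefact window must lie inside the segment")
    rng = np.random.default_rng(seed)
    i0 = int(round(artefact.onset_s * seg.fs))
    i1 = min(seg.n_samples, int(round((artefact.onset_s + artefact.duration_s) * seg.fs)))
    x = seg.samples.copy()
    w = x[i0:i1]
    scale = seg.samples.std() or 1.0
    sev = artefact.severity
    if artefact.kind == "baseline-step":
        x[i0:i1] = w + sev * scale
    elif artefact.kind == "noise-burst":
        x[i0:i1] = w + sev * scale * rng.standard_normal(w.size)
    elif artefact.kind == "amplitude-dropout":
        # residual floor: real contact loss still carries sensor noise
        x[i0:i1] = w * max(0.02, 1.0 - min(sev, 1.0))
    elif artefact.kind == "motion-spike":
        n_spikes = max(1, int(artefact.duration_s))
        pos = rng.integers(0, w.size, size=n_spikes)
        x[i0:i1][pos] = w[pos] + sev * scale * rng.choice([-1.0, 1.0], size=n_spikes)
    elif artefact.kind == "clipping":
        level = np.max(np.abs(w)) / (1.0 + sev) if w.size else 0.0
        x[i0:i1] = np.clip(w, -level, level)
    label = seg.label
    if artefact.duration_s / seg.duration >= critical_fraction:
        label = "noisy"
    return seg.with_(samples=x, provenance="corrupted", label=label)


def generate_dataset(
    n_subjects: int,
    spec: ProtocolSpec,
    noise_mix: dict[str, float],
    seed: int,
    seg_len_s: float = 30.0,
) -> LabeledDataset:
    """Generate a labelled corpus of segments from ``n_subjects`` recordings.

    ``noise_mix`` maps artefact kinds to the fraction of segments corrupted
    with that kind (fractions sum to at most 1).  Corrupted segments receive
    an artefact window covering 25-60% of their length — above the critical
    fraction — with severity drawn in [1, 3], so ground-truth classes are
    known by construction.  Breath-hold intervals are excluded from
    segmentation.
    """
    if n_subjects < 1:
        raise ValidationError("need at least one subject")
    for kind, frac in noise_mix.items():
        if kind not in ARTEFACT_KINDS or not 0.0 <= frac <= 1.0:
            raise ValidationError(f"bad noise mix entry {kind!r}: {frac!r}")
    if sum(noise_mix.values()) > 1.0 + 1e-9:
        raise ValidationError("noise mix fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    kinds = list(noise_mix)
    probs = np.array([noise_mix[k] for k in kinds], dtype=float)
    for s in range(n_subjects):
        rec = generate_recording(spec, seed=int(rng.integers(2**31 - 1)))
        rec = replace(rec, recording_id=f"S{s:03d}")
        hold = [iv for iv in rec.intervals if iv.pattern == BREATH_HOLD]
        for seg in segment_recording(rec, seg_len_s, exclude=hold):
            seg = seg.with_(label="clean", recording_id=rec.recording_id,
                            segment_id=f"{rec.recording_id}:{len(segments)}")
            u = rng.uniform()
            acc = 0.0
            for kind, p in zip(kinds, probs):
                acc += p
                if u < acc:
                    dur = float(rng.uniform(0.25, 0.60)) * seg.duration
                    onset = float(rng.uniform(0.0, seg.duration - dur))
                    art = ArtefactSpec(kind, onset, dur, severity=float(rng.uniform(1.0, 3.0)))
                    seg = inject_artefact(seg, art, seed=int(rng.integers(2**31 - 1)))
                    break
            segments.append(seg)
    return LabeledDataset(segments)
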