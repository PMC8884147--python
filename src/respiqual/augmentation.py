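"""Label-preserving data augmentation for respiration segments.

Four transformations generate synthetic training segments whose quality class
is, by construction, that of their source:

* **mirror** — flip about the x-axis (sign) or the y-axis (time reversal);
  emulates different electrode placements.
* **amplitude modulation** — multiply by a half-period sinusoidal envelope
  (low at both ends, maximal at the centre); changes amplitude, not shape.
* **slow stretch** — drop 5% of the samples at each end, reinterpret the
  remaining 90% as spanning the original duration and resample back to the
  original rate: a 10% slower breathing rate.  The removed fraction stays
  below the 16.6% critical window that would change a quality annotation.
* **fast concatenation** — concatenate two same-label, same-recording
  segments and resample the pair to the original length: a doubled rate.

`balance_augment` applies the allowed methods to every segment of the
minority class and to a random subset of the majority class, so the two
classes end up approximately equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample

from .core import LabeledDataset, Segment, ValidationError

ALL_METHODS = ("mirror", "modulate", "slow", "fast")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which augmentations to apply and how to balance the classes.

    ``methods`` is a subset of ``{"mirror", "modulate", "slow", "fast"}``;
    mirror contributes two variants per original (one per axis), every other
    method one.  For 30-s protocol data only mirror and modulation are used,
    so the rate-changing methods do not blur the breathing-pattern groups.
    """

    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    modulation_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValidationError("augmentation policy needs at least one method")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValidationError(f"unknown augmentation method {m!r}")

    @property
    def variants_per_original(self) -> int:
        return sum(2 if m == "mirror" else 1 for m in self.methods)


def mirror(seg: Segment, axis: str) -> Segment:
    """Flip a segment about the x-axis (negate) or y-axis (reverse time)."""
    if axis == "x":
        return seg.with_(samples=-seg.samples, provenance="mirror-x")
    if axis == "y":
        return seg.with_(samples=seg.samples[::-1].copy(), provenance="mirror-y")
    raise ValidationError(f"mirror axis must be 'x' or 'y', got {axis!r}")


def amplitude_modulate(seg: Segment, floor: float = 0.0) -> Segment:
    """Multiply by a sinusoidal envelope with period twice the segment length.

    The envelope m(i) = sin(pi * i / (N-1)) is zero at both ends and one at
    the centre; ``floor`` > 0 lifts the envelope to ``floor + (1-floor)*m``
    so the ends are attenuated rather than silenced.
    """
    n = seg.n_samples
    if n < 2:
        raise ValidationError("modulation needs at least two samples")
    m = np.sin(np.pi * np.arange(n) / (n - 1))
    m = floor + (1.0 - floor) * m
    return seg.with_(samples=seg.samples * m, provenance="modulated")


def slow_stretch(seg: Segment) -> Segment:
    """Produce a 10% slower-breathing version of the segment.

    Removes floor(0.05 N) samples at each end, treats the remaining samples
    as covering the original duration (a lower implicit sampling rate) and
    resamples back to N samples with Fourier interpolation.
    """
    n = seg.n_samples
    if n < 20:
        raise ValidationError("slow stretch needs at least 20 samples")
    cut = math.floor(0.05 * n)
    core = seg.samples[cut : n - cut]
    return seg.with_(samples=resample(core, n), provenance="slow")


def fast_concat(a: Segment, b: Segment) -> Segment:
    """Produce a doubled-breathing-rate segment from two compatible segments.

    The inputs must share label, recording and length; their concatenation is
    resampled from 2N to N samples (time compression by two).
    """
    if a.label != b.label:
        raise ValidationError("fast concatenation requires equal labels")
    if a.recording_id != b.recording_id:
        raise ValidationError("fast concatenation requires the same recording")
    if a.n_samples != b.n_samples:
        raise ValidationError("fast concatenation requires equal lengths")
    joined = np.concatenate([a.samples, b.samples])
    return a.with_(samples=resample(joined, a.n_samples), provenance="fast")


def _variants(seg: Segment, policy: AugmentationPolicy, partner: Segment | None) -> list[Segment]:
    out: list[Segment] = []
    for m in policy.methods:
        if m == "mirror":
            out.append(mirror(seg, "x"))
            out.append(mirror(seg, "y"))
        elif m == "modulate":
            out.append(amplitude_modulate(seg, policy.modulation_floor))
        elif m == "slow":
            out.append(slow_stretch(seg))
        elif m == "fast":
            out.append(fast_concat(seg, partner if partner is not None else seg))
    return out


def _pick_partner(seg: Segment, pool: list[Segment], rng: np.random.Generator) -> Segment | None:
    candidates = [
        s for s in pool
        if s is not seg and s.recording_id == seg.recording_id
        and s.label == seg.label and s.n_samples == seg.n_samples
    ]
    if not candidates:
        return None  # self-concatenation fallback
    return candidates[rng.integers(len(candidates))]


def balance_augment(ds: LabeledDataset, policy: AugmentationPolicy) -> LabeledDataset:
    """Augment a labelled dataset so the two classes are approximately equal.

    Every minority-class original contributes all variants allowed by the
    policy; majority-class originals are augmented, one randomly chosen
    original at a time (all its variants), for as long as the majority total
    stays at or below the augmented minority total.  Originals are always
    retained, and the final class difference is at most the number of
    variants per original.
    """
    counts = ds.class_counts()
    if counts["clean"] == 0 or counts["noisy"] == 0:
        raise ValidationError("balancing requires both classes to be present")
    rng = np.random.default_rng(policy.seed)
    minority = "clean" if counts["clean"] <= counts["noisy"] else "noisy"
    majority = "noisy" if minority == "clean" else "clean"
    v = policy.variants_per_original

    by_class = {
        c: [s for s in ds.segments if s.label == c] for c in ("clean", "noisy")
    }
    out: list[Segment] = list(ds.segments)

    for seg in by_class[minority]:
        partner = _pick_partner(seg, by_class[minority], rng) if "fast" in policy.methods else None
        out.extend(_variants(seg, policy, partner))
    minority_total = counts[minority] * (1 + v)

    majority_total = counts[majority]
    order = rng.permutation(len(by_class[majority]))
    for idx in order:
        if majority_total + v > minority_total:
            break
        seg = by_class[majority][idx]
        partner = _pick_partner(seg, by_class[majority], rng) if "fast" in policy.methods else None
        out.extend(_variants(seg, policy, partner))
        majority_total += v
    return LabeledDataset(out)
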