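"""Core containers shared by every stage of the quality-assessment pipeline.

The pipeline operates on fixed-length excerpts (:class:`Segment`) cut from
continuous single-channel respiration recordings (:class:`Recording`), and on
collections of labelled segments (:class:`LabeledDataset`).  A segment carries
its provenance (original measurement vs. which augmentation produced it) and
its quality class, so that label preservation and class balance can be audited
at any point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Closed set of provenance tags a segment may carry.
PROVENANCE_TAGS = frozenset(
    {"original", "mirror-x", "mirror-y", "modulated", "slow", "fast", "corrupted"}
)

#: Quality classes.  "unknown" marks segments not yet labelled.
QUALITY_CLASSES = frozenset({"clean", "noisy", "unknown"})

#: Breathing-pattern identifiers of the controlled protocol: spontaneous,
#: chest, shallow, abdominal, slow and fast breathing, plus breath hold.
BREATHING_PATTERNS = ("Sp", "Ch", "Sh", "Ab", "Sl", "Fa")
BREATH_HOLD = "Hold"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Raised for inputs that are formally valid but carry no information
    (e.g. a constant segment, which has no standard deviation to divide by)."""


@dataclass(frozen=True)
class Interval:
    """A half-open time interval ``[start, end)`` in seconds, tagged with the
    breathing pattern occupying it."""

    pattern: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def shift(self, offset: float) -> "Interval":
        return Interval(self.pattern, self.start + offset, self.end + offset)


@dataclass
class Segment:
    """A fixed-duration excerpt of a respiration waveform.

    Parameters
    ----------
    samples:
        Real-valued waveform samples.
    fs:
        Sampling rate in Hz.
    recording_id:
        Identifier of the recording the segment was cut from.  Augmented
        segments inherit the id of their source.
    breathing_type:
        Dominant breathing pattern over the segment's span, if known.
    provenance:
        One of :data:`PROVENANCE_TAGS`.
    label:
        Quality class: ``"clean"``, ``"noisy"`` or ``"unknown"``.
    segment_id:
        Optional stable identifier (used by manifests).
    """

    samples: np.ndarray
    fs: float
    recording_id: str = ""
    breathing_type: str | None = None
    provenance: str = "original"
    label: str = "unknown"
    segment_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("segment samples must be one-dimensional")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValidationError(f"unknown provenance tag {self.provenance!r}")
        if self.label not in QUALITY_CLASSES:
            raise ValidationError(f"unknown quality class {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs

    def with_(self, **changes) -> "Segment":
        """Return a copy with the given fields replaced (samples are copied)."""
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        return replace(self, **changes)


@dataclass
class Recording:
    """A continuous single-channel respiration recording with protocol
    annotations (which breathing pattern occupies which interval)."""

    samples: np.ndarray
    fs: float
    recording_id: str
    intervals: list[Interval] = field(default_factory=list)
    artefact_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("recording samples must be one-dimensional")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class LabeledDataset:
    """A collection of segments, each carrying exactly one quality class."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.label not in ("clean", "noisy"):
                raise ValidationError(
                    "every segment of a LabeledDataset needs a clean/noisy label"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def recording_ids(self) -> list[str]:
        """Unique recording ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.recording_id)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        counts = {"clean": 0, "noisy": 0}
        for seg in self.segments:
            counts[seg.label] += 1
        return counts

    def subset(self, predicate) -> "LabeledDataset":
        return LabeledDataset([s for s in self.segments if predicate(s)])

    def by_breathing_type(self) -> dict[str, "LabeledDataset"]:
        groups: dict[str, list[Segment]] = {}
        for seg in self.segments:
            groups.setdefault(seg.breathing_type or "?", []).append(seg)
        return {k: LabeledDataset(v) for k, v in groups.items()}

    def labels(self) -> np.ndarray:
        """Binary label vector: 1 for clean, 0 for noisy."""
        return np.array([1 if s.label == "clean" else 0 for s in self.segments])


def concat_datasets(parts: Iterable[LabeledDataset]) -> LabeledDataset:
    segs: list[Segment] = []
    for p in parts:
        segs.extend(p.segments)
    return LabeledDataset(segs)
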