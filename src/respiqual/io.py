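"""Plain-text persistence: recordings as CSV + JSON sidecar, datasets as a
CSV manifest plus one CSV per segment."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Interval, LabeledDataset, Recording, Segment


def save_recording(rec: Recording, basepath: str | Path) -> None:
    """Write ``<basepath>.csv`` (samples) and ``<basepath>.json`` (metadata:
    recording id, sampling rate, protocol intervals, artefact log)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"value": rec.samples}).to_csv(base.with_suffix(".csv"), index=False)
    meta = {
        "recording_id": rec.recording_id,
        "fs": rec.fs,
        "intervals": [
            {"pattern": iv.pattern, "start": iv.start, "end": iv.end}
            for iv in rec.intervals
        ],
        "artefact_log": rec.artefact_log,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_recording(basepath: str | Path) -> Recording:
    base = Path(basepath)
    samples = pd.read_csv(base.with_suffix(".csv"))["value"].to_numpy()
    meta = json.loads(base.with_suffix(".json").read_text())
    intervals = [
        Interval(d["pattern"], d["start"], d["end"]) for d in meta["intervals"]
    ]
    return Recording(
        samples=samples,
        fs=meta["fs"],
        recording_id=meta["recording_id"],
        intervals=intervals,
        artefact_log=meta.get("artefact_log", []),
    )


def save_dataset(ds: LabeledDataset | list[Segment], directory: str | Path) -> Path:
    """Write a segment store: ``manifest.csv`` plus one samples CSV per
    segment under ``segments/``.  Accepts a labelled dataset or a plain list
    of (possibly unlabelled) segments.  Returns the manifest path."""
    directory = Path(directory)
    seg_dir = directory / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    segments = ds.segments if isinstance(ds, LabeledDataset) else list(ds)
    for i, seg in enumerate(segments):
        seg_id = seg.segment_id or f"seg{i:05d}"
        fname = f"seg{i:05d}.csv"
        pd.DataFrame({"value": seg.samples}).to_csv(seg_dir / fname, index=False)
        rows.append(
            {
                "segment_id": seg_id,
                "recording_id": seg.recording_id,
                "breathing_type": seg.breathing_type,
                "label": seg.label,
                "provenance": seg.provenance,
                "fs": seg.fs,
                "n_samples": seg.n_samples,
                "file": f"segments/{fname}",
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_segments(directory: str | Path) -> list[Segment]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    segments = []
    for row in manifest.itertuples(index=False):
        samples = pd.read_csv(directory / row.file)["value"].to_numpy()
        btype = None if pd.isna(row.breathing_type) else str(row.breathing_type)
        segments.append(
            Segment(
                samples=samples,
                fs=float(row.fs),
                recording_id=str(row.recording_id),
                breathing_type=btype,
                provenance=str(row.provenance),
                label=str(row.label),
                segment_id=str(row.segment_id),
            )
        )
    return segments


def load_dataset(directory: str | Path) -> LabeledDataset:
    return LabeledDataset(load_segments(directory))
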