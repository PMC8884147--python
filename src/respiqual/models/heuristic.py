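"""Heuristic breath-morphology quality baseline.

A rule-based signal quality index in the spirit of classic respiratory SQIs:
detect breaths as alternating peaks and troughs, then call a segment *high*
quality only if (a) the breath durations vary little (low coefficient of
variation), (b) plausible breaths cover most of the segment (well-formed
peak-trough structure), and (c) individual breaths correlate well with the
mean-breath template.  The thresholds are configurable conventions of this
package, not a replication of any published SQI's internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, resample

from ..core import Segment
from ..preprocessing import normalize_segment

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class HeuristicConfig:
    """Thresholds of the rule-based quality index.

    Breath durations outside [min_breath_s, max_breath_s] (3-42 breaths/min
    by default) are implausible; ``min_valid_fraction`` is the minimum
    fraction of the segment that plausible breaths must cover.
    """

    min_breath_s: float = 60.0 / 42.0
    max_breath_s: float = 60.0 / 3.0
    max_duration_cv: float = 0.25
    min_template_corr: float = 0.75
    min_valid_fraction: float = 0.6
    peak_prominence: float = 0.5
    template_len: int = 64


def _detect_breaths(x: np.ndarray, fs: float, cfg: HeuristicConfig):
    distance = max(1, int(0.5 * cfg.min_breath_s * fs))
    peaks, _ = find_peaks(x, prominence=cfg.peak_prominence, distance=distance)
    troughs, _ = find_peaks(-x, prominence=cfg.peak_prominence, distance=distance)
    return peaks, troughs


def heuristic_sqi(seg: Segment, cfg: HeuristicConfig = HeuristicConfig()) -> str:
    """Classify a segment as ``"high"`` or ``"low"`` quality.

    Fewer than two complete detected breaths is low quality by definition
    (not an error).
    """
    try:
        x = normalize_segment(seg).samples
    except Exception:
        return LOW  # constant segment: no breaths at all
    peaks, troughs = _detect_breaths(x, seg.fs, cfg)
    if peaks.size < 3:
        return LOW

    durations = np.diff(peaks) / seg.fs
    plausible = (durations >= cfg.min_breath_s) & (durations <= cfg.max_breath_s)
    if plausible.sum() < 2:
        return LOW

    # (a) breath-duration regularity
    d = durations[plausible]
    cv = d.std(ddof=1) / d.mean() if d.mean() > 0 else np.inf
    if cv > cfg.max_duration_cv:
        return LOW

    # (b) well-formed peak-trough coverage: plausible breaths that contain a
    # trough between their bounding peaks must cover enough of the segment
    covered = 0.0
    good_breaths = []
    for k in np.flatnonzero(plausible):
        i0, i1 = peaks[k], peaks[k + 1]
        if np.any((troughs > i0) & (troughs < i1)):
            covered += (i1 - i0) / seg.fs
            good_breaths.append(x[i0:i1])
    if covered / seg.duration < cfg.min_valid_fraction:
        return LOW

    # (c) morphology similarity to the mean-breath template
    resampled = np.stack([resample(b, cfg.template_len) for b in good_breaths])
    template = resampled.mean(axis=0)
    corrs = []
    for b in resampled:
        sb, st = b.std(), template.std()
        corrs.append(
            float(np.corrcoef(b, template)[0, 1]) if sb > 0 and st > 0 else 0.0
        )
    if np.mean(corrs) < cfg.min_template_corr:
        return LOW
    return HIGH


def heuristic_scores(segments, cfg: HeuristicConfig = HeuristicConfig()) -> np.ndarray:
    """Binary clean-probability scores (1 for high quality) for ROC handling."""
    return np.array([1.0 if heuristic_sqi(s, cfg) == HIGH else 0.0 for s in segments])
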