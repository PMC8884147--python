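"""ACF/PSD feature extraction and MRMR feature selection.

A clean breathing segment is quasi-periodic, so its autocorrelation function
shows strong positive-lag peaks and its power concentrates in a narrow
spectral band; noise flattens both.  Seven descriptors capture this:

* from the ACF — amplitude of the first positive-lag peak (Ap1), of the
  second peak (Ap2), and their ratio Ap1/Ap2;
* from the Welch PSD — the half-maximum bandwidth around the dominant peak,
  its lower and upper bound frequencies (f_low, f_up), and the power in that
  band normalized by the total power in the 0.05-0.70 Hz respiratory band.

Each descriptor is computed over the whole segment and over 15-s
sub-segments; mean and standard deviation across sub-segments give a
21-value feature vector.  The five descriptors used by the classifier by
default are: whole-segment Ap1, std of sub-segment Ap1, whole-segment f_low,
mean sub-segment bandwidth, and mean sub-segment normalized power — a subset
originally chosen by maximum-relevance minimum-redundancy (MRMR) selection,
which is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.metrics import mutual_info_score

from .core import DegenerateInputError, Segment, ValidationError
from .preprocessing import HIGH_CUTOFF_HZ, LOW_CUTOFF_HZ, normalize_segment

_DESCRIPTORS = ("ap1", "ap2", "ap_ratio", "bandwidth", "f_low", "f_up", "norm_power")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"whole_{d}" for d in _DESCRIPTORS]
    + [f"sub_mean_{d}" for d in _DESCRIPTORS]
    + [f"sub_std_{d}" for d in _DESCRIPTORS]
)

#: The five features the classifiers use by default (MRMR-derived).
DEFAULT_FEATURE_SUBSET: tuple[str, ...] = (
    "whole_ap1",
    "sub_std_ap1",
    "whole_f_low",
    "sub_mean_bandwidth",
    "sub_mean_norm_power",
)


def autocorr_features(seg: Segment, min_prominence: float = 0.01) -> tuple[float, float, float]:
    """(Ap1, Ap2, Ap1/Ap2) from the unbiased, lag-0-normalized ACF.

    Peaks are non-negative local maxima with at least ``min_prominence``
    prominence, with lags restricted to physiologically plausible breath
    periods (1/0.70 s to 1/0.05 s) — a quasi-periodic breathing segment has
    positive ACF peaks at multiples of its breath period.  Missing peaks
    yield zeros with a guarded ratio.
    """
    x = seg.samples - seg.samples.mean()
    n = x.size
    denom = x @ x
    if denom == 0:
        raise DegenerateInputError("ACF of a constant segment is undefined")
    full = np.correlate(x, x, mode="full")[n - 1 :]
    # unbiased estimate, normalized so lag 0 equals 1
    acf = full / (n - np.arange(n)) * n / denom
    lag_min = max(1, int(np.floor(seg.fs / HIGH_CUTOFF_HZ)))
    lag_max = min(n - 1, int(np.ceil(seg.fs / LOW_CUTOFF_HZ)))
    if lag_max <= lag_min:
        return 0.0, 0.0, 0.0
    window = acf[: lag_max + 1]
    peaks, _ = sps.find_peaks(window, prominence=min_prominence, height=0.0)
    peaks = peaks[peaks >= lag_min]
    ap1 = float(acf[peaks[0]]) if peaks.size >= 1 else 0.0
    ap2 = float(acf[peaks[1]]) if peaks.size >= 2 else 0.0
    ratio = ap1 / ap2 if ap2 != 0.0 else 0.0
    return ap1, ap2, ratio


def _welch_psd(x: np.ndarray, fs: float, nperseg: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Welch-style averaged periodogram with reversal-symmetric windows.

    Hann-tapered, mean-detrended windows of ``min(len(x), nperseg)`` samples
    at roughly 50% overlap, with start positions placed symmetrically about
    the signal midpoint so that the estimate is exactly invariant under time
    reversal (and hence under the mirror augmentations).
    """
    n = x.size
    nperseg = min(n, nperseg)
    span = n - nperseg
    if span == 0:
        starts = [0]
    else:
        nseg = span // (nperseg // 2) + 2  # ~50% overlap, full edge coverage
        nseg += nseg % 2  # even count: starts mirror pairwise about the midpoint
        half = [round(i * span / (nseg - 1)) for i in range(nseg // 2)]
        starts = half + [span - s for s in reversed(half)]
    taper = sps.windows.hann(nperseg, sym=True)
    scale = 1.0 / (fs * (taper @ taper))
    psd = np.zeros(nperseg // 2 + 1)
    for s in starts:
        w = x[s : s + nperseg]
        spec = np.fft.rfft(taper * (w - w.mean()))
        psd += scale * np.abs(spec) ** 2
    psd /= len(starts)
    psd[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, psd


def psd_features(
    seg: Segment,
    band: tuple[float, float] = (LOW_CUTOFF_HZ, HIGH_CUTOFF_HZ),
    nperseg: int | None = None,
) -> tuple[float, float, float, float]:
    """(bandwidth, f_low, f_up, normalized power) from the Welch PSD.

    f_low and f_up bound the contiguous half-maximum region around the
    dominant spectral peak, located by linear interpolation of the crossings
    of half the peak value; the power integrated over that region (including
    the crossing bins) is normalized by the total power inside the
    respiratory band.

    The default spectral estimate is a single Hann-tapered periodogram of
    the full segment: its fine frequency resolution keeps a breathing tone's
    half-maximum band narrow and power-concentrated while broadband noise
    spreads across many independent bins, which is exactly the contrast the
    normalized-power feature encodes.  Averaged shorter windows are
    available via ``nperseg``.
    """
    x = seg.samples
    if x.std() == 0:
        raise DegenerateInputError("PSD features of a constant segment are undefined")
    freqs, pxx = _welch_psd(x, seg.fs, nperseg=nperseg or x.size)
    k = int(np.argmax(pxx))
    half = pxx[k] / 2.0
    lo = k
    while lo > 0 and pxx[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < pxx.size - 1 and pxx[hi + 1] >= half:
        hi += 1
    df = freqs[1] - freqs[0]
    if lo > 0:  # interpolate the half-maximum crossing below the region
        f_low = float(freqs[lo] - df * (pxx[lo] - half) / (pxx[lo] - pxx[lo - 1]))
    else:
        f_low = float(freqs[0])
    if hi < pxx.size - 1:
        f_up = float(freqs[hi] + df * (pxx[hi] - half) / (pxx[hi] - pxx[hi + 1]))
    else:
        f_up = float(freqs[-1])
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    total = float(pxx[band_mask].sum())
    in_peak = float(pxx[max(lo - 1, 0) : hi + 2].sum())
    norm_power = min(in_peak / total, 1.0) if total > 0 else 0.0
    return f_up - f_low, f_low, f_up, norm_power


def subsegment(seg: Segment, window_s: float = 15.0, overlap_s: float = 0.0) -> list[Segment]:
    """Split a segment into ``window_s`` sub-segments with ``overlap_s`` overlap.

    60-s segments are split without overlap (starts every 15 s, 4 windows);
    30-s segments with a 10-s overlap (stride 5 s, also 4 windows).  Only
    full windows are kept.
    """
    if window_s > seg.duration:
        raise ValidationError("sub-segment window exceeds the segment duration")
    if overlap_s >= window_s:
        raise ValidationError("overlap must be smaller than the window")
    n_win = int(round(window_s * seg.fs))
    stride = int(round((window_s - overlap_s) * seg.fs))
    out = []
    for start in range(0, seg.n_samples - n_win + 1, stride):
        out.append(seg.with_(samples=seg.samples[start : start + n_win].copy()))
    return out


def _descriptors(seg: Segment) -> np.ndarray:
    if seg.samples.std() == 0:
        # a flat (dropout) window carries no breathing content
        return np.zeros(7)
    ap1, ap2, ratio = autocorr_features(seg)
    bw, f_low, f_up, npow = psd_features(seg)
    return np.array([ap1, ap2, ratio, bw, f_low, f_up, npow])


def feature_vector(seg: Segment, window_s: float = 15.0, overlap_s: float | None = None) -> np.ndarray:
    """The full 21-value feature vector of a segment.

    Whole-segment descriptors plus mean and sample standard deviation of the
    descriptors over 15-s sub-segments.  The sub-segment overlap defaults to
    0 s for 60-s segments and 10 s for shorter (30-s protocol) segments, so
    both yield four sub-segments.
    """
    if overlap_s is None:
        overlap_s = 0.0 if seg.duration >= 60.0 else 10.0
    whole = _descriptors(seg)
    subs = np.array([_descriptors(s) for s in subsegment(seg, window_s, overlap_s)])
    sub_mean = subs.mean(axis=0)
    sub_std = subs.std(axis=0, ddof=1) if subs.shape[0] > 1 else np.zeros(7)
    return np.concatenate([whole, sub_mean, sub_std])


def feature_subset(vec: np.ndarray, names=DEFAULT_FEATURE_SUBSET) -> np.ndarray:
    """Pick named entries out of a 21-value feature vector."""
    idx = [FEATURE_NAMES.index(n) for n in names]
    return np.asarray(vec)[idx]


def feature_matrix(segments, subset=DEFAULT_FEATURE_SUBSET, normalize: bool = True) -> np.ndarray:
    """Stack (optionally z-scored) segments into an (n, len(subset)) matrix."""
    rows = []
    for seg in segments:
        s = normalize_segment(seg) if normalize else seg
        v = feature_vector(s)
        rows.append(feature_subset(v, subset) if subset is not None else v)
    return np.array(rows)


@dataclass(frozen=True)
class SelectedFeatureSet:
    names: tuple[str, ...]
    method: str  # "mrmr" | "fixed"
    scores: tuple[float, ...] = ()


def _discretize(col: np.ndarray, bins: int) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, col)


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    feature_names=None,
    bins: int = 8,
) -> SelectedFeatureSet:
    """Greedy maximum-relevance minimum-redundancy feature selection.

    Features are discretized into quantile bins; relevance is the mutual
    information with the class label, redundancy the mean mutual information
    with already-selected features, and the greedy criterion their
    difference.  Deterministic given the input column order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if k > p:
        raise ValidationError("cannot select more features than available")
    if len(np.unique(y)) < 2:
        raise ValidationError("MRMR needs both classes present")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(p)
    )
    disc = np.column_stack([_discretize(X[:, j], bins) for j in range(p)])
    relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(p)])
    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(p))
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in remaining:
            if selected:
                redundancy = np.mean(
                    [mutual_info_score(disc[:, j], disc[:, s]) for s in selected]
                )
            else:
                redundancy = 0.0
            score = relevance[j] - redundancy
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(best_score)
        remaining.remove(best_j)
    return SelectedFeatureSet(
        names=tuple(names[j] for j in selected), method="mrmr", scores=tuple(scores)
    )
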