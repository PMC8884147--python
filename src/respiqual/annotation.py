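"""Consensus labelling from multiple annotators.

Each segment is rated 1-5 by several independent annotators: 1 (excellent)
and 2 (good) count as *clean*, 3 (average) and 4 (bad) as *noisy*, and 5 is
reserved for segments whose reference channel — not the signal itself — was
unusable.  Binarized votes are combined by strict majority; segments without
a strict majority, or whose majority is "bad reference", are excluded from
training and evaluation.  Inter-rater agreement is summarized by Fleiss'
kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .core import LabeledDataset, Segment, ValidationError

CLEAN, NOISY, REFERENCE_BAD = "clean", "noisy", "reference-bad"
EXCLUDED_NO_MAJORITY = "excluded:no-majority"
EXCLUDED_BAD_REFERENCE = "excluded:bad-reference"


def binarize_label(raw: int) -> str:
    """Map a raw 1-5 quality rating to clean / noisy / reference-bad."""
    if raw in (1, 2):
        return CLEAN
    if raw in (3, 4):
        return NOISY
    if raw == 5:
        return REFERENCE_BAD
    raise ValidationError(f"quality label must be in 1..5, got {raw!r}")


def majority_vote(raw_labels) -> str:
    """Consensus outcome for one segment's row of raw annotator labels.

    Voting runs over the three binarized categories.  A strict majority of
    clean or noisy yields that class; a strict majority of reference-bad
    excludes the segment as ``excluded:bad-reference``; anything else
    (including exact ties with an even annotator count) is
    ``excluded:no-majority``.
    """
    raw_labels = list(raw_labels)
    if len(raw_labels) < 2:
        raise ValidationError("majority voting needs at least two annotators")
    votes = [binarize_label(r) for r in raw_labels]
    n = len(votes)
    for category, outcome in (
        (CLEAN, CLEAN),
        (NOISY, NOISY),
        (REFERENCE_BAD, EXCLUDED_BAD_REFERENCE),
    ):
        if votes.count(category) * 2 > n:
            return outcome
    return EXCLUDED_NO_MAJORITY


@dataclass(frozen=True)
class AgreementSummary:
    kappa: float
    fraction_full_agreement: float
    fraction_majority_agreement: float


def fleiss_kappa(annotations: np.ndarray, categories=None) -> float:
    """Fleiss' kappa over a (segments x annotators) matrix of labels.

    ``categories`` fixes the category set (e.g. the raw labels 1..5, or the
    binarized classes); by default the categories observed in the matrix are
    used.  Requires at least two segments and two distinct categories overall.
    """
    ann = np.asarray(annotations)
    if ann.ndim != 2 or ann.shape[1] < 2:
        raise ValidationError("annotation matrix must be segments x (>=2) annotators")
    if ann.shape[0] < 2:
        raise ValidationError("kappa is undefined for a single segment")
    if categories is not None:
        cats = list(categories)
        idx = {c: i for i, c in enumerate(cats)}
        table = np.zeros((ann.shape[0], len(cats)), dtype=int)
        for i, row in enumerate(ann):
            for v in row:
                if v not in idx:
                    raise ValidationError(f"label {v!r} outside category set")
                table[i, idx[v]] += 1
    else:
        table, _ = aggregate_raters(ann)
    if table.shape[1] < 2 or (table.sum(axis=0) > 0).sum() < 2:
        raise ValidationError("kappa is undefined with a single category in use")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def agreement_summary(annotations: np.ndarray, categories=None) -> AgreementSummary:
    """Kappa plus the fractions of unanimous and strict-majority segments."""
    ann = np.asarray(annotations)
    n_seg, n_ann = ann.shape
    full = sum(1 for row in ann if len(set(row)) == 1)
    maj = 0
    for row in ann:
        votes = [binarize_label(r) for r in row]
        if max(votes.count(c) for c in set(votes)) * 2 > n_ann:
            maj += 1
    return AgreementSummary(
        kappa=fleiss_kappa(ann, categories),
        fraction_full_agreement=full / n_seg,
        fraction_majority_agreement=maj / n_seg,
    )


def build_labeled_dataset(segments: list[Segment], annotations: np.ndarray) -> LabeledDataset:
    """Apply consensus voting to segments and drop the excluded ones."""
    ann = np.asarray(annotations)
    if ann.size == 0 or len(segments) == 0:
        raise ValidationError("empty segments or annotation set")
    if ann.shape[0] != len(segments):
        raise ValidationError(
            f"{len(segments)} segments but {ann.shape[0]} annotation rows"
        )
    kept: list[Segment] = []
    for seg, row in zip(segments, ann):
        outcome = majority_vote(row)
        if outcome in (CLEAN, NOISY):
            kept.append(seg.with_(label=outcome))
    return LabeledDataset(kept)
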