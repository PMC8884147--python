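"""A self-contained two-domain synthetic study.

Emulates the structure of the clinical problem: a *source* corpus of long
spontaneous-breathing recordings at ordinary rates (10-16 breaths/min, 60-s
segments) to pre-train on, and a *target* corpus from a different
"population" breathing much faster (25-40 breaths/min, 30-s segments) on
which the pre-trained models are tested and adapted.  Half of the segments
in each corpus are corrupted with noise bursts, amplitude dropouts or motion
spikes (equal shares) covering 25-60% of the segment, so ground-truth
classes are known by construction.

These routines back the worked examples and the reproduction script; the
full six-pattern experiment is available through
:func:`respiqual.evaluation.run_experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import AugmentationPolicy, balance_augment
from .core import LabeledDataset
from .evaluation import roc_auc, split_by_recording
from .features import DEFAULT_FEATURE_SUBSET, feature_matrix
from .models import AdaptationConfig, CnnHyper, adapt_svm, train_cnn, train_svm
from .synth import generate_dataset, uniform_protocol

#: Artefact kinds (equal shares) used for the corrupted half of each corpus.
NOISE_KINDS = ("noise-burst", "amplitude-dropout", "motion-spike")


def _mix(noise_fraction: float) -> dict[str, float]:
    return {k: noise_fraction / len(NOISE_KINDS) for k in NOISE_KINDS}


def make_source_corpus(
    seed: int,
    n_subjects: int = 20,
    minutes_per_subject: float = 21.0,
    noise_fraction: float = 0.5,
) -> LabeledDataset:
    """Source-domain corpus: 60-s spontaneous-breathing segments at
    10-16 breaths/min (~n_subjects * minutes_per_subject segments)."""
    spec = uniform_protocol("Sp", total_s=minutes_per_subject * 60.0, rate_range=(10, 16))
    return generate_dataset(n_subjects, spec, _mix(noise_fraction), seed=seed, seg_len_s=60.0)


def make_target_corpus(
    seed: int,
    n_subjects: int = 20,
    minutes_per_subject: float = 10.5,
    noise_fraction: float = 0.5,
) -> LabeledDataset:
    """Target-domain corpus: 30-s fast-breathing segments at
    25-40 breaths/min — a deliberate rate shift from the source domain."""
    spec = uniform_protocol("Fa", total_s=minutes_per_subject * 60.0, rate_range=(25, 40))
    return generate_dataset(n_subjects, spec, _mix(noise_fraction), seed=seed, seg_len_s=30.0)


@dataclass
class SourceHoldoutResult:
    svm_auc: float
    cnn_auc: float
    n_train: int
    n_test: int


def source_holdout_aucs(
    source: LabeledDataset,
    seed: int = 0,
    svm_bo_calls: int = 15,
    cnn_hyper: CnnHyper = CnnHyper(max_epochs=30),
    include_cnn: bool = True,
) -> SourceHoldoutResult:
    """Train both classifiers on 70% of the source recordings and report
    held-out AUC on the remaining 30% (one subject-wise split)."""
    plan = split_by_recording(source, n_repeats=1, seed=seed)
    train_ids, test_ids = plan.repeats[0]
    tr = source.subset(lambda s: s.recording_id in set(train_ids))
    te = source.subset(lambda s: s.recording_id in set(test_ids))
    Xtr = feature_matrix(tr.segments)
    Xte = feature_matrix(te.segments)
    svm = train_svm(Xtr, tr.labels(), seed=seed, feature_names=DEFAULT_FEATURE_SUBSET,
                    n_calls=svm_bo_calls)
    svm_auc, _ = roc_auc(svm.predict_proba(Xte), te.labels())
    cnn_auc = float("nan")
    if include_cnn:
        cnn = train_cnn(tr.segments, tr.labels(), cnn_hyper, seed=seed)
        cnn_auc, _ = roc_auc(cnn.predict_proba(te.segments), te.labels())
    return SourceHoldoutResult(svm_auc=svm_auc, cnn_auc=cnn_auc,
                               n_train=len(tr), n_test=len(te))


@dataclass
class SvmTransferResult:
    auc_original: list[float]
    auc_da: list[float]
    auc_tl_da: list[float]

    def medians(self) -> dict[str, float]:
        return {
            "original": float(np.median(self.auc_original)),
            "da": float(np.median(self.auc_da)),
            "tl_da": float(np.median(self.auc_tl_da)),
        }


def svm_transfer_study(
    source: LabeledDataset,
    target: LabeledDataset,
    seed: int = 0,
    n_repeats: int = 10,
    svm_bo_calls: int = 15,
    adaptation: AdaptationConfig | None = None,
) -> SvmTransferResult:
    """Original vs. DA vs. TL+DA for the SVM over subject-wise target splits.

    Original is trained on the raw source corpus; DA on the source corpus
    balanced with all four augmentations; TL+DA adapts the DA model on each
    repeat's target training split, itself balanced with the
    mirror+modulation policy.  All three are scored on identical test
    splits.
    """
    adaptation = adaptation or AdaptationConfig(seed=seed)
    X_src = feature_matrix(source.segments)
    svm_orig = train_svm(X_src, source.labels(), seed=seed,
                         feature_names=DEFAULT_FEATURE_SUBSET, n_calls=svm_bo_calls)
    src_da = balance_augment(source, AugmentationPolicy(seed=seed))
    X_src_da = feature_matrix(src_da.segments)
    svm_da = train_svm(X_src_da, src_da.labels(), seed=seed,
                       feature_names=DEFAULT_FEATURE_SUBSET, n_calls=svm_bo_calls)

    target_policy = AugmentationPolicy(methods=("mirror", "modulate"), seed=seed + 1)
    plan = split_by_recording(target, n_repeats=n_repeats, seed=seed)
    res = SvmTransferResult([], [], [])
    # feature extraction is deterministic per segment: cache across repeats
    feats = {id(s): f for s, f in zip(target.segments,
                                      feature_matrix(target.segments))}
    for train_ids, test_ids in plan.repeats:
        tr = target.subset(lambda s: s.recording_id in set(train_ids))
        te = target.subset(lambda s: s.recording_id in set(test_ids))
        X_te = np.array([feats[id(s)] for s in te.segments])
        y_te = te.labels()
        tr_aug = balance_augment(tr, target_policy)
        X_tr = feature_matrix(tr_aug.segments)
        svm_tl = adapt_svm(svm_da, X_tr, tr_aug.labels(), adaptation)
        res.auc_original.append(roc_auc(svm_orig.predict_proba(X_te), y_te)[0])
        res.auc_da.append(roc_auc(svm_da.predict_proba(X_te), y_te)[0])
        res.auc_tl_da.append(roc_auc(svm_tl.predict_proba(X_te), y_te)[0])
    return res
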