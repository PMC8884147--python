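"""Subject-wise evaluation: splits, ROC/AUC, threshold metrics, paired
significance tests, and the Original / DA / TL+DA experiment.

Recordings — not segments — are the unit of splitting, so no subject's data
leaks between train and test.  Each of ``n_repeats`` random splits takes 70%
of the recordings for (transfer) training and 30% for testing; the same
splits are reused for every model variant so that paired Wilcoxon
signed-rank tests across repeats are valid.  AUC (clean as the positive
class) is the headline metric; accuracy, sensitivity (clean-detection rate)
and specificity (noisy-detection rate) are reported at a configurable
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .augmentation import AugmentationPolicy, balance_augment
from .core import LabeledDataset, ValidationError
from .features import DEFAULT_FEATURE_SUBSET, feature_matrix
from .models import (
    AdaptationConfig,
    CnnHyper,
    adapt_svm,
    heuristic_scores,
    train_cnn,
    train_svm,
    transfer_cnn,
)
from .models.heuristic import HeuristicConfig
from .preprocessing import normalize_segment


@dataclass(frozen=True)
class SplitPlan:
    """Recording-level train/test split ids for each repeat."""

    repeats: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.repeats)


def split_by_recording(
    ds: LabeledDataset,
    train_frac: float = 0.7,
    n_repeats: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Random recording-level splits (train_frac of the recordings, rounded
    to the nearest integer, per repeat).  Deterministic given the seed."""
    ids = ds.recording_ids
    if len(ids) < 4:
        raise ValidationError("need at least four recordings to split")
    n_train = int(round(train_frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(ids))
        train = tuple(sorted(ids[i] for i in perm[:n_train]))
        test = tuple(sorted(ids[i] for i in perm[n_train:]))
        repeats.append((train, test))
    return SplitPlan(repeats=tuple(repeats), seed=seed)


def roc_auc(scores, y) -> tuple[float, np.ndarray]:
    """AUC and ROC points; equals the Mann-Whitney concordance probability
    (ties count one half)."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes present")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return auc, np.column_stack([fpr, tpr])


def confusion_metrics(scores, y, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with clean as the positive class."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("confusion metrics need both classes present")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    sens = tp / int(np.sum(y == 1))
    spec = tn / int(np.sum(y == 0))
    acc = (tp + tn) / y.size
    return acc, sens, spec


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution for n <= 25 (zero differences dropped); all
    differences zero degenerates to p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValidationError("need equal-length paired samples, n >= 5")
    d = a - b
    if np.all(d == 0):
        return 1.0
    n_nonzero = int(np.sum(d != 0))
    method = "exact" if n_nonzero <= 25 else "auto"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the Original / DA / TL+DA experiment."""

    n_repeats: int = 10
    train_frac: float = 0.7
    seed: int = 0
    threshold: float = 0.5
    feature_subset: tuple[str, ...] = DEFAULT_FEATURE_SUBSET
    source_policy: AugmentationPolicy | None = None   # defaults to all four methods
    target_policy: AugmentationPolicy | None = None   # defaults to mirror+modulate
    adaptation: AdaptationConfig = AdaptationConfig()
    cnn_hyper: CnnHyper = CnnHyper()
    heuristic: HeuristicConfig = HeuristicConfig()
    svm_bo_calls: int = 20
    include_cnn: bool = True


@dataclass
class EvalResult:
    """Long-format per-repeat metrics plus summaries and pairwise tests."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Median and [25th, 75th] percentile of each metric per breathing
        type x classifier x variant (linear-interpolation percentiles)."""
        g = self.records.groupby(["breathing_type", "classifier", "variant"])
        rows = []
        for key, grp in g:
            row = dict(zip(["breathing_type", "classifier", "variant"], key))
            for metric in ("auc", "accuracy", "sensitivity", "specificity"):
                vals = grp[metric].to_numpy()
                row[f"{metric}_median"] = float(np.median(vals))
                row[f"{metric}_p25"] = float(np.percentile(vals, 25))
                row[f"{metric}_p75"] = float(np.percentile(vals, 75))
            rows.append(row)
        return pd.DataFrame(rows)

    def pairwise_pvalues(self, metric: str = "auc") -> pd.DataFrame:
        """Wilcoxon signed-rank p-values between variants, paired by repeat."""
        rows = []
        pairs = [("tl_da", "original"), ("tl_da", "da"), ("da", "original")]
        for (btype, clf), grp in self.records.groupby(["breathing_type", "classifier"]):
            wide = grp.pivot_table(index="repeat", columns="variant", values=metric)
            for va, vb in pairs:
                if va in wide.columns and vb in wide.columns:
                    sub = wide[[va, vb]].dropna()
                    if len(sub) >= 5:
                        rows.append(
                            {
                                "breathing_type": btype,
                                "classifier": clf,
                                "comparison": f"{va}_vs_{vb}",
                                "p_value": wilcoxon_signed_rank(
                                    sub[va].to_numpy(), sub[vb].to_numpy()
                                ),
                            }
                        )
        return pd.DataFrame(rows)


def _augment_if_possible(ds: LabeledDataset, policy: AugmentationPolicy) -> LabeledDataset:
    counts = ds.class_counts()
    if counts["clean"] == 0 or counts["noisy"] == 0:
        return ds
    return balance_augment(ds, policy)


def run_experiment(
    pretrain: LabeledDataset,
    target: LabeledDataset,
    cfg: ExperimentConfig = ExperimentConfig(),
) -> EvalResult:
    """Run the three-strategy evaluation on a source and a target corpus.

    Pre-trains each classifier twice on the source corpus — without
    augmentation (*Original*) and with the source augmentation policy (*DA*)
    — then, per subject-wise split repeat and per breathing type, adapts the
    DA model on the augmented target training split (*TL+DA*) and scores all
    three variants (plus the heuristic baseline) on identical test segments.
    Breathing-type groups whose test split lacks a class are skipped with a
    warning.
    """
    source_policy = cfg.source_policy or AugmentationPolicy(seed=cfg.seed)
    target_policy = cfg.target_policy or AugmentationPolicy(
        methods=("mirror", "modulate"), seed=cfg.seed + 1
    )

    # ---- pre-training on the source corpus ------------------------------
    X_pre = feature_matrix(pretrain.segments, subset=cfg.feature_subset)
    y_pre = pretrain.labels()
    svm_orig = train_svm(X_pre, y_pre, seed=cfg.seed, feature_names=cfg.feature_subset,
                         n_calls=cfg.svm_bo_calls)
    pre_da = balance_augment(pretrain, source_policy)
    X_pre_da = feature_matrix(pre_da.segments, subset=cfg.feature_subset)
    svm_da = train_svm(X_pre_da, pre_da.labels(), seed=cfg.seed,
                       feature_names=cfg.feature_subset, n_calls=cfg.svm_bo_calls)
    if cfg.include_cnn:
        cnn_orig = train_cnn(pretrain.segments, y_pre, cfg.cnn_hyper, seed=cfg.seed)
        cnn_da = train_cnn(pre_da.segments, pre_da.labels(), cfg.cnn_hyper, seed=cfg.seed)

    plan = split_by_recording(target, cfg.train_frac, cfg.n_repeats, cfg.seed)
    rows: list[dict] = []

    for repeat, (train_ids, test_ids) in enumerate(plan.repeats):
        train_set, test_set = set(train_ids), set(test_ids)
        target_train = target.subset(lambda s: s.recording_id in train_set)
        target_test = target.subset(lambda s: s.recording_id in test_set)
        train_groups = target_train.by_breathing_type()

        for btype, test_group in sorted(target_test.by_breathing_type().items()):
            y_test = test_group.labels()
            if len(np.unique(y_test)) < 2:
                warnings.warn(
                    f"repeat {repeat}: test split of {btype!r} has one class; skipped"
                )
                continue
            train_group = train_groups.get(btype, target_train)
            if len(np.unique(train_group.labels())) < 2:
                train_group = target_train  # fall back to all types for adaptation
            train_aug = _augment_if_possible(train_group, target_policy)

            X_test = feature_matrix(test_group.segments, subset=cfg.feature_subset)
            X_tr = feature_matrix(train_aug.segments, subset=cfg.feature_subset)
            svm_tl = adapt_svm(svm_da, X_tr, train_aug.labels(), cfg.adaptation)
            scored = {
                ("svm", "original"): svm_orig.predict_proba(X_test),
                ("svm", "da"): svm_da.predict_proba(X_test),
                ("svm", "tl_da"): svm_tl.predict_proba(X_test),
                ("heuristic", "heuristic"): heuristic_scores(
                    test_group.segments, cfg.heuristic
                ),
            }
            if cfg.include_cnn:
                norm_test = [normalize_segment(s) for s in test_group.segments]
                cnn_tl = transfer_cnn(cnn_da, train_aug.segments, train_aug.labels(),
                                      cfg.adaptation)
                scored[("cnn", "original")] = cnn_orig.predict_proba(norm_test)
                scored[("cnn", "da")] = cnn_da.predict_proba(norm_test)
                scored[("cnn", "tl_da")] = cnn_tl.predict_proba(norm_test)

            for (clf, variant), scores in scored.items():
                auc, _ = roc_auc(scores, y_test)
                acc, sens, spec = confusion_metrics(scores, y_test, cfg.threshold)
                rows.append(
                    {
                        "repeat": repeat,
                        "breathing_type": btype,
                        "classifier": clf,
                        "variant": variant,
                        "auc": auc,
                        "accuracy": acc,
                        "sensitivity": sens,
                        "specificity": spec,
                        "n_test": len(test_group),
                    }
                )
    return EvalResult(records=pd.DataFrame(rows))
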