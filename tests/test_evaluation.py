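import itertools
import warnings

import numpy as np
import pytest

from respiqual.core import LabeledDataset, Segment, ValidationError
from respiqual.evaluation import (
    ExperimentConfig,
    confusion_metrics,
    roc_auc,
    run_experiment,
    split_by_recording,
    wilcoxon_signed_rank,
)
from respiqual.models import AdaptationConfig, CnnHyper
from respiqual.synth import BlockSpec, ProtocolSpec, generate_dataset, uniform_protocol

FS = 16.0


def _dataset(n_recordings=20, per_rec=3):
    rng = np.random.default_rng(0)
    segs = []
    for r in range(n_recordings):
        for i in range(per_rec):
            segs.append(
                Segment(rng.standard_normal(64), FS, f"r{r:02d}",
                        label="clean" if (r + i) % 2 else "noisy")
            )
    return LabeledDataset(segs)


class TestSplitByRecording:
    def test_split_sizes(self):
        plan = split_by_recording(_dataset(20), seed=0)
        train, test = plan.repeats[0]
        assert len(train) == 14 and len(test) == 6

    def test_no_recording_leaks(self):
        plan = split_by_recording(_dataset(11), seed=1)
        for train, test in plan.repeats:
            assert not set(train) & set(test)
            assert len(train) + len(test) == 11

    def test_deterministic_given_seed(self):
        assert split_by_recording(_dataset(), seed=5) == split_by_recording(_dataset(), seed=5)

    def test_too_few_recordings_rejected(self):
        with pytest.raises(ValidationError):
            split_by_recording(_dataset(3), seed=0)


def _auc_bruteforce(scores, y):
    """Concordance-probability oracle: count all positive-negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_worked_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert auc == 0.75

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            auc, _ = roc_auc(scores, y)
            assert auc == pytest.approx(_auc_bruteforce(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.9], [1, 1])


class TestConfusionMetrics:
    def test_perfect_and_inverted(self):
        assert confusion_metrics([0.9, 0.1], [1, 0]) == (1.0, 1.0, 1.0)
        assert confusion_metrics([0.1, 0.9], [1, 0]) == (0.0, 0.0, 0.0)

    def test_counting_example(self):
        scores = [0.9, 0.6, 0.2, 0.7, 0.3]
        y = [1, 1, 1, 0, 0]
        acc, sens, spec = confusion_metrics(scores, y)
        assert (acc, sens, spec) == (3 / 5, 2 / 3, 1 / 2)


def _wilcoxon_enumeration(d):
    """Exact two-sided p by enumerating all sign assignments (oracle)."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        mask = absd == v
        ranks[mask] = ranks[mask].mean()
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_degenerate_to_one(self):
        a = np.arange(10.0)
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_all_positive_differences(self):
        a = np.arange(10.0) + 1.0
        b = np.arange(10.0)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 1024)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(size=(2, 10))
        assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            # distinct magnitudes with random signs (the exact null
            # distribution is only tabulated tie-free)
            d = rng.choice([-1.0, 1.0], size=10) * rng.permutation(np.arange(1.0, 11.0))
            a = d
            b = np.zeros_like(d)
            assert wilcoxon_signed_rank(a, b) == pytest.approx(
                _wilcoxon_enumeration(d), abs=1e-9
            )


@pytest.fixture(scope="module")
def tiny_result():
    mix = {"noise-burst": 0.25, "amplitude-dropout": 0.25}
    blocks = tuple(BlockSpec(p, 90.0) for p in ("Sp", "Ch", "Sh", "Ab", "Sl", "Fa"))
    tgt_spec = ProtocolSpec(blocks=blocks, hold_s=20.0, hold_after_block=1)
    target = generate_dataset(8, tgt_spec, mix, seed=21, seg_len_s=30.0)
    source = generate_dataset(
        6, uniform_protocol("Sp", 360.0, rate_range=(10, 16)), mix, seed=22,
        seg_len_s=60.0,
    )
    cfg = ExperimentConfig(
        n_repeats=2, seed=3, svm_bo_calls=8,
        cnn_hyper=CnnHyper(max_epochs=6),
        adaptation=AdaptationConfig(stage1_epochs=5, finetune_epochs=2, seed=3),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment(source, target, cfg), cfg


class TestRunExperiment:
    def test_result_structure(self, tiny_result):
        res, cfg = tiny_result
        df = res.records
        assert set(df["classifier"]) == {"svm", "cnn", "heuristic"}
        assert set(df[df.classifier == "svm"]["variant"]) == {"original", "da", "tl_da"}
        # every evaluated (repeat, type) carries all seven classifier/variant rows
        per_cell = df.groupby(["repeat", "breathing_type"]).size()
        assert (per_cell == 7).all()
        assert df["auc"].between(0, 1).all()

    def test_summary_percentiles_ordered(self, tiny_result):
        res, _ = tiny_result
        s = res.summary()
        assert (s["auc_p25"] <= s["auc_median"]).all()
        assert (s["auc_median"] <= s["auc_p75"]).all()
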