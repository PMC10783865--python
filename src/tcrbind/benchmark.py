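"""Zero-shot split construction and evaluation metrics.

The zero-shot regime is the hard case for TCR-pMHC predictors: every test
epitope is absent from training, so nothing can be memorised. The split
rule follows the frequency convention — epitopes occurring more than
`min_count` times in the master pair set are trainable, the rarer remainder
forms the epitope-disjoint test set.

Metrics are the field's standard ones: AUC-ROC (Mann–Whitney with midrank
ties), AUC-PR as average precision (step-wise, no linear interpolation),
positive predictive value among the top-k ranked calls, and the Youden
J = TPR − FPR operating threshold. `resampled_eval` repeats an evaluation
over many independent negative draws at a fixed positive:negative ratio to
quantify robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .seq_codec import PairRecord
from .binder import sample_negatives


@dataclass(frozen=True)
class SplitSpec:
    train: list[PairRecord]
    test: list[PairRecord]
    min_count: int

    @property
    def train_epitopes(self) -> set[str]:
        return {r.epitope for r in self.train}

    @property
    def test_epitopes(self) -> set[str]:
        return {r.epitope for r in self.test}


@dataclass(frozen=True)
class MetricReport:
    auc_roc: float
    auc_pr: float
    ppv: dict[int, float] = field(default_factory=dict)
    youden_threshold: float | None = None
    youden_j: float | None = None
    resampling: list[float] | None = None


def zero_shot_partition(pairs: list[PairRecord],
                        min_count: int = 10) -> SplitSpec:
    """Split by epitope frequency: > min_count occurrences → train.

    Epitope-disjointness of the two halves is guaranteed by construction
    and asserted.
    """
    if not pairs:
        raise ValueError("empty master set")
    counts: dict[str, int] = {}
    for r in pairs:
        counts[r.epitope] = counts.get(r.epitope, 0) + 1
    train = [r for r in pairs if counts[r.epitope] > min_count]
    test = [r for r in pairs if counts[r.epitope] <= min_count]
    spec = SplitSpec(train=train, test=test, min_count=min_count)
    assert not (spec.train_epitopes & spec.test_epitopes)
    return spec


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (ties counted ½, Mann–Whitney form)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def auc_pr(scores, labels) -> float:
    """Average precision: step-wise summation under the PR curve."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    if not np.any(labels == 1):
        raise ValueError("no positive examples")
    return float(average_precision_score(labels, scores))


def ppv_at_k(scores, labels, k: int) -> float:
    """Fraction of positives among the k top-scored items (stable ties)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    if not 1 <= k <= len(scores):
        raise ValueError(f"k={k} outside [1, {len(scores)}]")
    top = np.argsort(-scores, kind="stable")[:k]
    return float(labels[top].mean())


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximising J = TPR − FPR, at midpoints of adjacent scores.

    Predictions are positive when score > threshold; among maximisers the
    lowest threshold is returned.
    """
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    _check_two_class(labels)
    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 \
        else uniq - 0.5
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores > t
        tpr = np.sum(pred & (labels == 1)) / n_pos
        fpr = np.sum(pred & (labels == 0)) / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


def compute_metrics(scores, labels, ppv_ks=()) -> MetricReport:
    """Full metric panel for one scored test set."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    t, j = youden_cutoff(scores, labels)
    return MetricReport(
        auc_roc=auc_roc(scores, labels),
        auc_pr=auc_pr(scores, labels),
        ppv={k: ppv_at_k(scores, labels, k) for k in ppv_ks},
        youden_threshold=t, youden_j=j)


def resampled_eval(scorer, positives: list[PairRecord], pool: list[str],
                   ratio: int = 100, n_sets: int = 100, seed: int = 0,
                   ppv_ks=(10, 20, 30)) -> tuple[list[MetricReport], dict]:
    """Evaluate over repeated independent negative draws.

    Each of the `n_sets` test sets pairs the positives with ratio × |pos|
    freshly drawn background negatives, is scored by `scorer`
    (records → scores), and yields a MetricReport. The summary carries the
    median and IQR of the AUC-ROC distribution.
    """
    if not positives:
        raise ValueError("no positives to evaluate")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_sets):
        negatives = sample_negatives(positives, pool, ratio, rng)
        records = positives + negatives
        labels = np.array([r.label for r in records])
        scores = np.asarray(scorer(records), float)
        reports.append(compute_metrics(scores, labels, ppv_ks=ppv_ks))
    aucs = np.array([r.auc_roc for r in reports])
    q1, med, q3 = np.percentile(aucs, [25, 50, 75])
    summary = {"median_auc_roc": float(med), "iqr": (float(q1), float(q3)),
               "n_sets": n_sets, "ratio": ratio}
    return reports, summary
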