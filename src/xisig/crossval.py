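"""Exhaustive cross-validation, pooled confusion counts and the MCC.

Every way of choosing ``train_per_class`` samples from each of the two
sex classes forms one training set; each sample left out of that
training set is then tested individually. For two classes of six
samples with three training samples each this enumerates
C(6,3) · C(6,3) · 6 = 2400 evaluations. Predictions from all
evaluations are pooled into a single confusion matrix and summarized by
the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the random-predictor convention MCC = 0 whenever a denominator
factor vanishes. Genes with pooled MCC above a fixed threshold (default
0.995, strict inequality) are called *sex_differential*; the remainder
have *variable* X methylation.

Everything here is deterministic: the split enumeration is exhaustive
(no sampling) and the classifier has no random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import pca
from .signals import GeneSignal

__all__ = [
    "Split",
    "SplitPlan",
    "ConfusionCounts",
    "GeneScore",
    "enumerate_splits",
    "mcc",
    "score_gene",
    "partition_genes",
    "mcc_histogram",
]

logger = logging.getLogger(__name__)

MCC_THRESHOLD = 0.995
SEX_DIFFERENTIAL = "sex_differential"
VARIABLE = "variable"


@dataclass(frozen=True)
class Split:
    """One evaluation: a training set and a single held-out test sample."""

    train_ids: tuple[str, ...]  # sorted, both classes represented
    test_id: str
    true_label: str


@dataclass
class SplitPlan:
    """The full exhaustive enumeration of (training set, test sample) pairs."""

    splits: tuple[Split, ...]
    train_per_class: int

    @property
    def n_total(self) -> int:
        return len(self.splits)


@dataclass
class ConfusionCounts:
    """Pooled confusion matrix (female is the positive class)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class GeneScore:
    """Per-gene cross-validation summary and spectrum scores."""

    gene: str
    chromosome: str
    n_cpg: int
    mcc: float
    pca_ratio: float  # lambda2 / lambda1 of the full-data kernel
    pca_ratio_l1frac: float  # lambda1 / sum(lambda)
    classification: str
    counts: ConfusionCounts
    separable: bool = False  # unsupervised top-2 projections split the sexes with zero error
    degenerate: bool = False  # every sample pattern was flat
    n_ties: int = 0


def enumerate_splits(
    labels: Mapping[str, str], train_per_class: int
) -> SplitPlan:
    """Enumerate every training/test combination for a two-class design.

    ``labels`` maps sample id to class; both classes must have at least
    ``train_per_class + 1`` members so every training set leaves at
    least one sample to test.
    """
    if train_per_class < 1:
        raise ValueError(f"train_per_class must be >= 1, got {train_per_class}")
    by_class: dict[str, list[str]] = {}
    for sid in sorted(labels):
        by_class.setdefault(labels[sid], []).append(sid)
    if len(by_class) != 2:
        raise ValueError(f"exactly 2 classes required, got {sorted(by_class)}")
    for cls, members in sorted(by_class.items()):
        if len(members) < train_per_class + 1:
            raise ValueError(
                f"class {cls!r} has {len(members)} samples; needs at least "
                f"{train_per_class + 1} to train {train_per_class} and test 1"
            )
    (cls_a, ids_a), (cls_b, ids_b) = sorted(by_class.items())
    splits: list[Split] = []
    for tr_a, tr_b in product(
        combinations(ids_a, train_per_class), combinations(ids_b, train_per_class)
    ):
        train_ids = tuple(sorted(tr_a + tr_b))
        train_set = set(train_ids)
        for sid in ids_a + ids_b:
            if sid not in train_set:
                splits.append(
                    Split(train_ids=train_ids, test_id=sid, true_label=labels[sid])
                )
    return SplitPlan(splits=tuple(splits), train_per_class=train_per_class)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of pooled confusion counts.

    Returns 0.0 (random-predictor convention, logged) when any
    denominator factor is zero.
    """
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if 0 in factors:
        logger.debug("MCC denominator factor is 0 for %s; returning 0.0", c)
        return 0.0
    return num / math.sqrt(math.prod(factors))


def _positive_label(classes: Sequence[str]) -> str:
    """Positive class is 'female' when present, else the first sorted label."""
    return "female" if "female" in classes else sorted(classes)[0]


def score_gene(
    signal: GeneSignal,
    labels: Mapping[str, str],
    plan: SplitPlan,
    mcc_threshold: float = MCC_THRESHOLD,
) -> GeneScore:
    """Run every split of ``plan`` on one gene and pool the confusion.

    For each split the nearest-centroid PCA classifier is trained on the
    training rows of this gene's pattern and the held-out sample is
    classified; predictions are tallied into one confusion matrix
    (female positive) and summarized by a single pooled MCC. Eigenvalue
    ratios come from the full-data kernel. Fully deterministic.

    A degenerate gene (every sample pattern flat) yields MCC 0 with
    ``degenerate=True``.
    """
    sample_index = {sid: i for i, sid in enumerate(signal.sample_ids)}
    missing = [s.test_id for s in plan.splits if s.test_id not in sample_index]
    if missing:
        raise ValueError(f"plan references samples absent from signal: {missing[:3]}")

    normed, degenerate_rows = pca.normalize_patterns(signal.pattern)
    kernel = pca._kernel_from_normalized(normed, degenerate_rows)
    spectrum = pca.eigen_spectrum(kernel)
    ratio_l2l1 = pca.pca_ratio(spectrum, "lambda2_over_lambda1")
    ratio_l1frac = pca.pca_ratio(spectrum, "lambda1_fraction")
    all_degenerate = len(degenerate_rows) == kernel.n

    classes = sorted(set(labels.values()))
    positive = _positive_label(classes)

    counts = ConfusionCounts()
    n_ties = 0
    # group splits by training set: the training kernel and eigenpairs are
    # shared by all held-out samples of that training set
    grouped: dict[tuple[str, ...], list[Split]] = {}
    for split in plan.splits:
        grouped.setdefault(split.train_ids, []).append(split)

    for train_ids, group in grouped.items():
        ix = np.array([sample_index[sid] for sid in train_ids])
        train_labels = [labels[sid] for sid in train_ids]
        sub = kernel.matrix[np.ix_(ix, ix)]
        w, v = np.linalg.eigh(sub)
        order = np.argsort(w)[::-1][:2]
        lam = w[order]
        vecs = v[:, order]
        for c in range(2):
            vecs[:, c] = pca._fix_sign(vecs[:, c])
        proj_train = vecs * np.sqrt(np.maximum(lam, 0.0))[None, :]
        centroids = {
            cl: proj_train[[i for i, l in enumerate(train_labels) if l == cl], :].mean(axis=0)
            for cl in classes
        }
        for split in group:
            r = kernel.matrix[sample_index[split.test_id], ix]
            proj = pca._project_out_of_sample(r, lam, vecs)
            predicted, tie = pca._nearest_centroid(proj, centroids)
            if tie:
                n_ties += 1
            _tally(counts, predicted, split.true_label, positive)

    if n_ties:
        logger.info(
            "gene %s (%s): %d classification tie(s) resolved to the first-sorted label",
            signal.gene,
            signal.chromosome,
            n_ties,
        )

    pooled = mcc(counts)
    return GeneScore(
        gene=signal.gene,
        chromosome=signal.chromosome,
        n_cpg=signal.n_cpg,
        mcc=pooled,
        pca_ratio=ratio_l2l1,
        pca_ratio_l1frac=ratio_l1frac,
        classification=SEX_DIFFERENTIAL if pooled > mcc_threshold else VARIABLE,
        counts=counts,
        separable=_zero_error_separation(spectrum, labels, signal.sample_ids),
        degenerate=all_degenerate,
        n_ties=n_ties,
    )


def _tally(
    counts: ConfusionCounts, predicted: str, true: str, positive: str
) -> None:
    if true == positive:
        if predicted == positive:
            counts.tp += 1
        else:
            counts.fn += 1
    else:
        if predicted == positive:
            counts.fp += 1
        else:
            counts.tn += 1


def _zero_error_separation(
    spectrum: pca.Spectrum,
    labels: Mapping[str, str],
    sample_ids: Sequence[str],
) -> bool:
    """Whether the unsupervised top-2 projections split the classes cleanly.

    Each sample is assigned to the nearer of the two class centroids in
    full-data top-2 projection space; True iff every assignment matches
    the true label with no ties.
    """
    proj = spectrum.eigenvectors[:, :2] * np.sqrt(
        np.maximum(spectrum.eigenvalues[:2], 0.0)
    )[None, :]
    true = [labels[sid] for sid in sample_ids]
    classes = sorted(set(true))
    if len(classes) != 2:
        return False
    centroids = {
        c: proj[[i for i, l in enumerate(true) if l == c], :].mean(axis=0)
        for c in classes
    }
    for i, label in enumerate(true):
        assigned, tie = pca._nearest_centroid(proj[i], centroids)
        if tie or assigned != label:
            return False
    return True


def partition_genes(
    scores: Iterable[GeneScore], mcc_threshold: float = MCC_THRESHOLD
) -> tuple[list[GeneScore], list[GeneScore]]:
    """Split scores at MCC > threshold (strict) into
    (sex_differential, variable), refreshing each score's class call."""
    differential: list[GeneScore] = []
    variable: list[GeneScore] = []
    for s in scores:
        if s.mcc > mcc_threshold:
            differential.append(replace(s, classification=SEX_DIFFERENTIAL))
        else:
            variable.append(replace(s, classification=VARIABLE))
    return differential, variable


def mcc_histogram(
    scores: Iterable, bin_width: float
) -> list[tuple[float, float, int]]:
    """Histogram of MCC values over right-open bins covering [−1, 1].

    The last bin is closed so MCC = 1.0 is counted; counts sum to the
    number of scores. ``scores`` may be floats or :class:`GeneScore`.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    values = [s.mcc if isinstance(s, GeneScore) else float(s) for s in scores]
    n_bins = max(1, math.ceil(2.0 / bin_width - 1e-12))
    edges = np.array([-1.0 + i * bin_width for i in range(n_bins + 1)])
    counts, _ = np.histogram(values, bins=edges)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    ]
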