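"""PCA correlation-kernel classifier for methylation patterns.

Each sample's pattern (a gene's β values ordered by coordinate) is
zero-meaned and scaled to unit Euclidean norm, so the samples × samples
Gram matrix of the normalized patterns is exactly the matrix of Pearson
cross-correlation coefficients between patterns. PCA is carried out by
eigenvalue decomposition (EVD) of this kernel; because the kernel is the
Gram matrix of the normalized pattern matrix N, its eigenvalues equal
the squared singular values of N and the EVD and SVD routes agree
numerically.

Two scalar spectrum summaries are exposed as class-dissimilarity scores
(λ2/λ1 and λ1/Σλ), and a minimal supervised linear rule — nearest class
centroid in the space of the two largest PCA projections — provides the
classifier evaluated under exhaustive cross-validation.

Out-of-sample (test) patterns are projected by the kernel-extension
formula p_c = (r · v_c) / sqrt(λ_c), where r holds the correlations of
the normalized test pattern with the normalized training patterns; for a
training pattern this reproduces its in-sample projection sqrt(λ_c)·v_c
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signals import GeneSignal

__all__ = [
    "RATIO_MODES",
    "Kernel",
    "Spectrum",
    "TrainedClassifier",
    "normalize_pattern",
    "normalize_patterns",
    "correlation_kernel",
    "eigen_spectrum",
    "pca_ratio",
    "project_top2",
    "train_classifier",
    "classify",
]

logger = logging.getLogger(__name__)

#: Eigenvalues below this are treated as numerically zero.
EIG_TOL = 1e-9
#: Distance differences below this count as a classification tie.
TIE_TOL = 1e-12

RATIO_MODES = ("lambda2_over_lambda1", "lambda1_fraction")


@dataclass
class Kernel:
    """Samples × samples Pearson cross-correlation matrix.

    Rows whose pattern had zero variance are *degenerate*: their
    normalized pattern is the zero vector, so their off-diagonal
    correlations are set to 0 and the diagonal to 1.
    """

    matrix: np.ndarray
    degenerate_rows: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError(f"kernel must be square, got {self.matrix.shape}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Spectrum:
    """Eigen-decomposition of a kernel, eigenvalues non-increasing.

    Eigenvector signs follow a deterministic convention: each vector is
    scaled so its largest-magnitude entry (first index on ties) is
    positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns match eigenvalues

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)


@dataclass
class TrainedClassifier:
    """Nearest-centroid rule in the top-2 PCA projection space."""

    patterns: np.ndarray  # normalized training patterns, rows
    labels: tuple[str, ...]
    eigenvalues: np.ndarray  # top-2 eigenvalues of the training kernel
    eigenvectors: np.ndarray  # matching eigenvectors, columns (n_train x 2)
    centroids: dict[str, np.ndarray]  # label -> 2-vector
    n_ties: int = 0


def normalize_pattern(pattern: Sequence[float] | np.ndarray) -> np.ndarray:
    """Zero-mean, unit-Euclidean-norm version of a β vector.

    A zero-variance (flat) pattern has no direction and returns the
    all-zero vector; callers detect degeneracy via ``norm == 0``.
    """
    x = np.asarray(pattern, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"pattern must be a vector of length >= 2, got shape {x.shape}")
    centered = x - x.mean()
    norm = np.linalg.norm(centered)
    if norm < EIG_TOL:
        return np.zeros_like(centered)
    return centered / norm


def normalize_patterns(patterns: np.ndarray) -> tuple[np.ndarray, frozenset[int]]:
    """Row-wise :func:`normalize_pattern`; returns the degenerate row set."""
    patterns = np.asarray(patterns, dtype=float)
    centered = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = frozenset(int(i) for i in np.nonzero(norms < EIG_TOL)[0])
    safe = np.where(norms < EIG_TOL, 1.0, norms)
    out = centered / safe[:, None]
    if degenerate:
        out[list(degenerate), :] = 0.0
    return out, degenerate


def correlation_kernel(signal: GeneSignal) -> Kernel:
    """Pearson cross-correlation kernel between a gene's sample patterns."""
    normed, degenerate = normalize_patterns(signal.pattern)
    return _kernel_from_normalized(normed, degenerate)


def _kernel_from_normalized(
    normed: np.ndarray, degenerate: frozenset[int]
) -> Kernel:
    k = normed @ normed.T
    k = np.clip((k + k.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(k, 1.0)
    if degenerate:
        idx = list(degenerate)
        k[idx, :] = 0.0
        k[:, idx] = 0.0
        for i in idx:
            k[i, i] = 1.0
    return Kernel(matrix=k, degenerate_rows=degenerate)


def eigen_spectrum(kernel: Kernel) -> Spectrum:
    """EVD of the kernel with eigenvalues sorted non-increasing."""
    w, v = np.linalg.eigh(kernel.matrix)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    for c in range(v.shape[1]):
        v[:, c] = _fix_sign(v[:, c])
    return Spectrum(eigenvalues=w, eigenvectors=v)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Scale so the largest-magnitude entry (first on ties) is positive."""
    i = int(np.argmax(np.abs(vec)))
    if vec[i] < 0:
        return -vec
    return vec


def pca_ratio(spectrum: Spectrum, mode: str = "lambda2_over_lambda1") -> float:
    """Scalar class-dissimilarity summary of the kernel spectrum.

    ``lambda2_over_lambda1``
        λ2/λ1; small when one principal direction dominates
        (0 if λ1 is numerically zero).
    ``lambda1_fraction``
        λ1/Σλ, the fraction of total pattern correlation captured by the
        leading eigenvector (Σλ equals the number of samples for a
        correlation kernel).
    """
    if spectrum.eigenvalues.size < 2:
        raise ValueError("pca_ratio needs at least 2 eigenvalues")
    lam = np.maximum(spectrum.eigenvalues, 0.0)
    if mode == "lambda2_over_lambda1":
        if lam[0] <= EIG_TOL:
            return 0.0
        return float(lam[1] / lam[0])
    if mode == "lambda1_fraction":
        total = float(lam.sum())
        if total <= EIG_TOL:
            return 0.0
        return float(lam[0] / total)
    raise ValueError(f"unknown ratio mode {mode!r}; expected one of {RATIO_MODES}")


def project_top2(spectrum: Spectrum, kernel: Kernel | None = None) -> np.ndarray:
    """In-sample projections onto the two leading PCA features.

    Column c is sqrt(λc) · vc; when the kernel has rank <= 2 the pairwise
    dot products of the projection rows reproduce the kernel (Gram
    property).
    """
    if spectrum.eigenvalues.size < 2:
        raise ValueError("need at least 2 eigenvalues to project")
    lam = np.maximum(spectrum.eigenvalues[:2], 0.0)
    return spectrum.eigenvectors[:, :2] * np.sqrt(lam)[None, :]


def train_classifier(
    patterns: np.ndarray, labels: Sequence[str]
) -> TrainedClassifier:
    """Fit the supervised linear rule: PCA of the training kernel plus
    per-class centroids in top-2 projection space.

    Exactly two classes must be present, each with at least one row.
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = tuple(str(l) for l in labels)
    if patterns.shape[0] != len(labels):
        raise ValueError("one label per training row required")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"training requires exactly 2 classes, got {classes}")
    normed, degenerate = normalize_patterns(patterns)
    kernel = _kernel_from_normalized(normed, degenerate)
    spectrum = eigen_spectrum(kernel)
    proj = project_top2(spectrum, kernel)
    centroids = {
        c: proj[[i for i, l in enumerate(labels) if l == c], :].mean(axis=0)
        for c in classes
    }
    return TrainedClassifier(
        patterns=normed,
        labels=labels,
        eigenvalues=spectrum.eigenvalues[:2].copy(),
        eigenvectors=spectrum.eigenvectors[:, :2].copy(),
        centroids=centroids,
    )


def classify(model: TrainedClassifier, test_pattern: Sequence[float] | np.ndarray) -> str:
    """Predict the class of a held-out pattern by nearest centroid.

    The test pattern is normalized, projected out-of-sample via the
    kernel-extension formula, and assigned to the nearest class centroid
    (Euclidean). An exact tie goes to the label that sorts first and is
    logged.
    """
    x = np.asarray(test_pattern, dtype=float)
    if x.shape != (model.patterns.shape[1],):
        raise ValueError(
            f"test pattern length {x.size} != training pattern length "
            f"{model.patterns.shape[1]}"
        )
    xn = normalize_pattern(x)
    r = model.patterns @ xn
    proj = _project_out_of_sample(r, model.eigenvalues, model.eigenvectors)
    label, tie = _nearest_centroid(proj, model.centroids)
    if tie:
        model.n_ties += 1
        logger.info("classification tie resolved to %r", label)
    return label


def _project_out_of_sample(
    r: np.ndarray, eigenvalues: np.ndarray, eigenvectors: np.ndarray
) -> np.ndarray:
    proj = np.zeros(2)
    for c in range(2):
        lam = eigenvalues[c]
        if lam > EIG_TOL:
            proj[c] = float(r @ eigenvectors[:, c]) / np.sqrt(lam)
    return proj


def _nearest_centroid(
    proj: np.ndarray, centroids: dict[str, np.ndarray]
) -> tuple[str, bool]:
    classes = sorted(centroids)
    dists = [float(np.linalg.norm(proj - centroids[c])) for c in classes]
    if abs(dists[0] - dists[1]) <= TIE_TOL:
        return classes[0], True
    return classes[int(np.argmin(dists))], False
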