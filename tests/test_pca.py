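"""Kernel, spectrum, projections and the nearest-centroid classifier."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xisig.pca import (
    Kernel,
    classify,
    correlation_kernel,
    eigen_spectrum,
    normalize_pattern,
    normalize_patterns,
    pca_ratio,
    project_top2,
    train_classifier,
)
from xisig.signals import GeneSignal

from conftest import TOY_PATTERN


def _toy_kernel():
    sig = GeneSignal(
        gene="T",
        chromosome="X",
        coordinates=(1, 2, 3),
        sample_ids=("a", "b", "c", "d"),
        pattern=TOY_PATTERN.copy(),
    )
    return correlation_kernel(sig)


class TestNormalize:
    def test_known_vector(self):
        np.testing.assert_allclose(
            normalize_pattern([0.1, 0.5, 0.9]),
            [-0.70710678, 0.0, 0.70710678],
            atol=1e-8,
        )

    def test_flat_pattern_is_degenerate_zero_vector(self):
        np.testing.assert_array_equal(
            normalize_pattern([0.4, 0.4, 0.4]), np.zeros(3)
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            normalize_pattern([0.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    def test_postconditions_mean_zero_norm_one(self, values):
        v = normalize_pattern(values)
        if np.allclose(v, 0):  # degenerate input
            return
        assert abs(v.mean()) < 1e-12
        assert abs(np.linalg.norm(v) - 1.0) < 1e-12


class TestKernel:
    def test_mirror_image_classes_give_block_sign_kernel(self):
        expected = np.array(
            [
                [1, 1, -1, -1],
                [1, 1, -1, -1],
                [-1, -1, 1, 1],
                [-1, -1, 1, 1],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(_toy_kernel().matrix, expected, atol=1e-12)

    def test_identical_patterns_give_all_ones(self):
        sig = GeneSignal(
            gene="T",
            chromosome="X",
            coordinates=(1, 2, 3),
            sample_ids=("a", "b", "c"),
            pattern=np.tile([0.1, 0.5, 0.9], (3, 1)),
        )
        np.testing.assert_allclose(correlation_kernel(sig).matrix, np.ones((3, 3)))

    def test_symmetric_psd_unit_diagonal(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pattern = rng.uniform(0, 1, size=(5, 7))
            sig = GeneSignal(
                gene="T",
                chromosome="X",
                coordinates=tuple(range(1, 8)),
                sample_ids=tuple("abcde"),
                pattern=pattern,
            )
            k = correlation_kernel(sig).matrix
            np.testing.assert_array_equal(k, k.T)
            np.testing.assert_allclose(np.diag(k), 1.0)
            assert np.linalg.eigvalsh(k).min() > -1e-9

    def test_degenerate_row_isolated(self):
        pattern = np.array([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9], [0.9, 0.5, 0.1]])
        sig = GeneSignal(
            gene="T",
            chromosome="X",
            coordinates=(1, 2, 3),
            sample_ids=("a", "b", "c"),
            pattern=pattern,
        )
        k = correlation_kernel(sig)
        assert k.degenerate_rows == {0}
        np.testing.assert_array_equal(k.matrix[0], [1.0, 0.0, 0.0])


class TestSpectrum:
    def test_rank_one_sign_kernel_spectrum(self):
        spectrum = eigen_spectrum(_toy_kernel())
        np.testing.assert_allclose(spectrum.eigenvalues, [4, 0, 0, 0], atol=1e-9)

    def test_identity_kernel_spectrum(self):
        spectrum = eigen_spectrum(Kernel(matrix=np.eye(3)))
        np.testing.assert_allclose(spectrum.eigenvalues, [1, 1, 1])

    def test_trace_conservation_and_reconstruction(self):
        rng = np.random.default_rng(4)
        pattern = rng.uniform(0, 1, size=(6, 9))
        sig = GeneSignal(
            gene="T",
            chromosome="X",
            coordinates=tuple(range(1, 10)),
            sample_ids=tuple("abcdef"),
            pattern=pattern,
        )
        k = correlation_kernel(sig)
        spectrum = eigen_spectrum(k)
        assert spectrum.eigenvalues.sum() == pytest.approx(np.trace(k.matrix), abs=1e-9)
        recon = (
            spectrum.eigenvectors
            @ np.diag(spectrum.eigenvalues)
            @ spectrum.eigenvectors.T
        )
        assert np.abs(recon - k.matrix).max() < 1e-8


class TestPcaRatio:
    def test_modes_on_rank_one_spectrum(self):
        spectrum = eigen_spectrum(_toy_kernel())
        assert pca_ratio(spectrum, "lambda1_fraction") == pytest.approx(1.0, abs=1e-9)
        assert pca_ratio(spectrum, "lambda2_over_lambda1") == pytest.approx(0.0, abs=1e-9)

    def test_identity_kernel_lambda1_fraction(self):
        spectrum = eigen_spectrum(Kernel(matrix=np.eye(3)))
        assert pca_ratio(spectrum, "lambda1_fraction") == pytest.approx(1 / 3)

    def test_single_eigenvalue_rejected(self):
        from xisig.pca import Spectrum

        with pytest.raises(ValueError, match="at least 2"):
            pca_ratio(Spectrum(eigenvalues=np.array([1.0]), eigenvectors=np.eye(1)))


class TestProjections:
    def test_sign_convention_first_column(self):
        spectrum = eigen_spectrum(_toy_kernel())
        proj = project_top2(spectrum)
        assert (proj[:2, 0] > 0).all() and (proj[2:, 0] < 0).all()

    def test_zero_lambda2_gives_zero_second_column(self):
        spectrum = eigen_spectrum(_toy_kernel())
        proj = project_top2(spectrum)
        np.testing.assert_allclose(proj[:, 1], 0.0, atol=1e-7)

    def test_gram_property_rank_le_2(self):
        # two orthogonal normalized patterns duplicated -> rank-2 kernel
        a = normalize_pattern([0.1, 0.5, 0.9, 0.5])
        b = normalize_pattern([0.2, 0.8, 0.2, 0.8])
        b = normalize_pattern(b - (a @ b) * a)
        pattern = np.vstack([a, a, b, b])
        k = Kernel(matrix=np.clip(pattern @ pattern.T, -1, 1))
        spectrum = eigen_spectrum(k)
        proj = project_top2(spectrum)
        np.testing.assert_allclose(proj @ proj.T, k.matrix, atol=1e-8)


class TestClassifier:
    def test_mirror_centroids_distinct(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        f, m = model.centroids["F"], model.centroids["M"]
        np.testing.assert_allclose(f[0], -m[0], atol=1e-9)
        assert np.linalg.norm(f - m) > 1.0

    def test_duplicated_patterns_centroid_equals_projection(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        proj = project_top2(
            eigen_spectrum(Kernel(matrix=model.patterns @ model.patterns.T))
        )
        np.testing.assert_allclose(model.centroids["F"], proj[0], atol=1e-7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(TOY_PATTERN, ["F", "F", "F", "F"])

    def test_training_pattern_classified_to_own_class(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        assert classify(model, [0.1, 0.5, 0.9]) == "F"

    def test_mirror_test_pattern_lands_on_other_centroid(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        assert classify(model, [0.9, 0.5, 0.1]) == "M"

    def test_flat_test_pattern_tie_resolved_to_first_label(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        assert classify(model, [0.5, 0.5, 0.5]) == "F"
        assert model.n_ties == 1

    def test_length_mismatch_rejected(self):
        model = train_classifier(TOY_PATTERN, ["F", "F", "M", "M"])
        with pytest.raises(ValueError, match="length"):
            classify(model, [0.1, 0.9])

    def test_invariant_to_training_sample_order(self):
        rng = np.random.default_rng(8)
        pattern = rng.uniform(0, 1, size=(6, 5))
        labels = ["F", "M", "F", "M", "F", "M"]
        test = rng.uniform(0, 1, size=5)
        base = classify(train_classifier(pattern, labels), test)
        for seed in range(5):
            order = np.random.default_rng(seed).permutation(6)
            assert (
                classify(train_classifier(pattern[order], [labels[i] for i in order]), test)
                == base
            )

    def test_leave_one_out_zero_error_on_anticorrelated_classes(self):
        # 3v3 copies of mirror patterns with tiny distinct perturbations
        rng = np.random.default_rng(1)
        base = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        rows, labels = [], []
        for i in range(3):
            rows.append(base + rng.normal(0, 0.01, 5))
            labels.append("F")
        for i in range(3):
            rows.append(base[::-1] + rng.normal(0, 0.01, 5))
            labels.append("M")
        rows = np.clip(np.array(rows), 0, 1)
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            model = train_classifier(rows[keep], [labels[j] for j in keep])
            assert classify(model, rows[i]) == labels[i]


def test_evd_svd_equivalence_random_instances():
    """Kernel eigenvalues == squared singular values of the normalized patterns."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n, p = rng.integers(3, 9), rng.integers(3, 12)
        pattern = rng.uniform(0, 1, size=(n, p))
        normed, _ = normalize_patterns(pattern)
        sig = GeneSignal(
            gene="T",
            chromosome="X",
            coordinates=tuple(range(1, p + 1)),
            sample_ids=tuple(f"s{i}" for i in range(n)),
            pattern=pattern,
        )
        lam = eigen_spectrum(correlation_kernel(sig)).eigenvalues
        sv = np.linalg.svd(normed, compute_uv=False)
        sv2 = np.zeros(n)
        sv2[: sv.size] = np.sort(sv**2)[::-1]
        np.testing.assert_allclose(lam, sv2, atol=1e-8)
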