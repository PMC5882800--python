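"""Shared fixtures: toy signals with known geometry and a generated cohort.

All data is generated programmatically; nothing is read from checked-in
files except the packaged gene lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from xisig.crossval import enumerate_splits
from xisig.pipeline import PipelineConfig, run_pipeline
from xisig.signals import GeneSignal
from xisig.simulate import GeneSpec, SimConfig, make_example_cohort, simulate_dataset

TOY_PATTERN = np.array(
    [
        [0.1, 0.5, 0.9],
        [0.1, 0.5, 0.9],
        [0.9, 0.5, 0.1],
        [0.9, 0.5, 0.1],
    ]
)
TOY_LABELS = {"s1": "F", "s2": "F", "s3": "M", "s4": "M"}


@pytest.fixture
def toy_signal() -> GeneSignal:
    """Two mirror-image classes: perfectly anti-correlated patterns."""
    return GeneSignal(
        gene="TOY",
        chromosome="X",
        coordinates=(100, 200, 300),
        sample_ids=("s1", "s2", "s3", "s4"),
        pattern=TOY_PATTERN.copy(),
    )


@pytest.fixture
def toy_labels() -> dict[str, str]:
    return dict(TOY_LABELS)


def random_signal(
    seed: int, n_per_class: int = 3, n_cpg: int = 6
) -> tuple[GeneSignal, dict[str, str]]:
    """A random two-class gene with no planted structure."""
    rng = np.random.default_rng(seed)
    sample_ids = tuple(
        [f"F{i}" for i in range(n_per_class)] + [f"M{i}" for i in range(n_per_class)]
    )
    labels = {s: ("female" if s.startswith("F") else "male") for s in sample_ids}
    signal = GeneSignal(
        gene=f"RND{seed}",
        chromosome="X",
        coordinates=tuple(range(100, 100 + 10 * n_cpg, 10)),
        sample_ids=sample_ids,
        pattern=rng.uniform(0.0, 1.0, size=(2 * n_per_class, n_cpg)),
    )
    return signal, labels


@pytest.fixture(scope="session")
def example_cohort(tmp_path_factory) -> Path:
    """The bundled 12-sample, ~200-gene cohort written to disk once."""
    path = tmp_path_factory.mktemp("cohort")
    make_example_cohort(path, seed=2026)
    return path


@pytest.fixture(scope="session")
def example_run(example_cohort, tmp_path_factory) -> tuple[PipelineConfig, dict[str, Path]]:
    """One full pipeline run on the example cohort, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        beta=str(example_cohort / "beta.tsv"),
        manifest=str(example_cohort / "manifest.csv"),
        samplesheet=str(example_cohort / "samples.csv"),
        outdir=str(outdir),
    )
    return config, run_pipeline(config)


def small_cohort_config(seed: int = 5) -> SimConfig:
    """A 20-gene cohort small enough to score in well under a second."""
    genes = tuple(
        GeneSpec(f"INA{i}", "X", 6, "inactivated") for i in range(8)
    ) + tuple(GeneSpec(f"ESC{i}", "X", 6, "escape") for i in range(8)) + tuple(
        GeneSpec(f"AUT{i}", "7", 6, "autosomal") for i in range(4)
    )
    return SimConfig(genes=genes, seed=seed)


@pytest.fixture
def small_cohort():
    return simulate_dataset(small_cohort_config())


@pytest.fixture(scope="session")
def plan_6v6():
    labels = {f"F{i}": "female" for i in range(6)} | {f"M{i}": "male" for i in range(6)}
    return labels, enumerate_splits(labels, train_per_class=3)
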