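"""Synthetic HM450-like datasets with planted X-inactivation structure.

The generator emulates the methylation geometry that makes sex
classifiable from per-gene CpG signals:

* at CpGs of X-**inactivated** genes, males carry one active
  (hypomethylated) X while females average an active and a methylated
  inactive X, so female β values sit intermediate (~0.5) above the male
  baseline;
* **escape** genes evade Xi silencing and **autosomal** genes are
  untouched by it, so male and female generative distributions are
  identical there;
* every gene has its own per-CpG architecture (a reproducible "shape"
  shared by all samples) because CpG density, island/shore context and
  probe chemistry vary along a gene — this is what gives within-sex
  patterns high mutual correlation and exercises the coordinate-ordering
  logic.

For inactivated genes the female − male difference is Δ·w_j per CpG,
where the Xi-methylation gain w_j ∈ [0, 2] (mean 1, so the mean
female − male difference equals the configured Δ) is *anti-correlated*
with the active-X level: CpGs that are unmethylated on the active X
(promoter-proximal, low male β) gain the most methylation on the
inactive X, while CpGs already methylated on the active copy (gene
body) have little headroom to gain. The per-CpG variation of the gain
is essential: a constant shift would be removed exactly by the
zero-mean pattern normalization of the classifier, whereas the
anti-correlated gain reshapes — partially mirror-images — the female
signal, which is precisely the feature a correlation kernel detects.
Profiles are stratified uniform (a permuted, equally spaced grid over
the stated range) rather than iid draws, so every gene realizes the
nominal architecture variance; under iid draws a fraction of genes
would be uninformative by chance, which emulates nothing biological.

Noise is truncated Gaussian on the β scale (the pipeline consumes β
values only; array chemistry is out of scope). Term/preterm labels are
assigned orthogonally to sex and carry no effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    BetaMatrix,
    CpGSite,
    Sample,
    SampleSheet,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)

__all__ = [
    "CATEGORIES",
    "GeneSpec",
    "SimConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "make_example_cohort",
    "example_gene_panel",
]

CATEGORIES = ("inactivated", "escape", "autosomal")

#: Half-width of the per-gene CpG architecture profile around baseline.
PROFILE_SPREAD = 0.15
#: Half-width of the per-CpG jitter on the Xi-methylation gain.
GAIN_JITTER = 0.3
#: Region-group tokens cycled along each simulated gene, promoter first.
_REGION_CYCLE = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "Body", "Body", "3UTR")


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    chromosome: str
    n_cpg: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"gene {self.symbol}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        if self.n_cpg < 2:
            raise ValueError(f"gene {self.symbol}: n_cpg must be >= 2, got {self.n_cpg}")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``effect`` is the mean female − male β difference at CpGs of
    inactivated genes (unitless β); ``noise_sd`` the per-CpG Gaussian σ
    before clipping to [0, 1]; ``baseline`` the mean male β;
    ``profile_spread`` the half-width of the per-gene CpG architecture
    profile.
    """

    genes: tuple[GeneSpec, ...]
    n_male: int = 6
    n_female: int = 6
    effect: float = 0.4
    noise_sd: float = 0.05
    baseline: float = 0.05
    profile_spread: float = PROFILE_SPREAD
    seed: int = 0

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValueError("at least one gene spec required")
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("need at least one sample per sex")
        if not (0.0 <= self.baseline and self.baseline + self.effect <= 1.0):
            raise ValueError(
                f"require 0 <= baseline and baseline + effect <= 1, got "
                f"baseline={self.baseline}, effect={self.effect}"
            )
        if self.effect < 0:
            raise ValueError(f"effect must be >= 0, got {self.effect}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.profile_spread <= 0:
            raise ValueError(f"profile_spread must be > 0, got {self.profile_spread}")
        symbols = [(g.symbol, g.chromosome) for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate (symbol, chromosome) in gene specs")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort, cross-checkable against the files."""

    gene_categories: dict[str, str]  # "SYMBOL@CHROM" -> category
    sample_sex: dict[str, str]
    sample_gestation: dict[str, str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _stratified_grid(
    rng: np.random.Generator, low: float, high: float, n: int
) -> np.ndarray:
    """Permuted, equally spaced grid over (low, high) — mean (low+high)/2,
    fixed variance (no per-gene luck in profile informativeness)."""
    grid = low + (high - low) * (np.arange(n) + 0.5) / n
    return rng.permutation(grid)


def simulate_dataset(
    config: SimConfig,
) -> tuple[BetaMatrix, list[CpGSite], SampleSheet, SyntheticTruth]:
    """Draw one cohort: β matrix, manifest, sample sheet and truth table.

    Deterministic for a fixed config (same seed → byte-identical files
    when written through :mod:`xisig.io`).
    """
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"F{i + 1:02d}" for i in range(config.n_female)] + [
        f"M{i + 1:02d}" for i in range(config.n_male)
    ]
    sexes = ["female"] * config.n_female + ["male"] * config.n_male
    # gestation alternates within each sex: orthogonal to the sex design
    gestations = [
        "term" if i % 2 == 0 else "preterm" for i in range(config.n_female)
    ] + ["term" if i % 2 == 0 else "preterm" for i in range(config.n_male)]
    female_rows = np.array([s == "female" for s in sexes])

    probe_counter = 0
    chrom_cursor: dict[str, int] = {}
    manifest: list[CpGSite] = []
    probe_ids: list[str] = []
    blocks: list[np.ndarray] = []

    for spec in config.genes:
        start = chrom_cursor.get(spec.chromosome, 0) + 1_000_000
        gaps = rng.integers(50, 500, size=spec.n_cpg)
        coords = start + np.cumsum(gaps)
        chrom_cursor[spec.chromosome] = int(coords[-1])

        male_mean = config.baseline + _stratified_grid(
            rng, -config.profile_spread, config.profile_spread, spec.n_cpg
        )
        if spec.category == "inactivated":
            # Xi gain anti-correlated with the active-X level, jittered,
            # clipped to [0, 2]; mean 1 so E[female - male] = effect
            jitter = _stratified_grid(rng, -GAIN_JITTER, GAIN_JITTER, spec.n_cpg)
            xi_gain = np.clip(
                1.0
                - (male_mean - config.baseline) / config.profile_spread
                + jitter,
                0.0,
                2.0,
            )
            female_mean = male_mean + config.effect * xi_gain
        else:
            female_mean = male_mean
        means = np.where(female_rows[:, None], female_mean[None, :], male_mean[None, :])
        noise = rng.normal(0.0, config.noise_sd, size=means.shape)
        betas = np.clip(means + noise, 0.0, 1.0)  # samples x n_cpg
        blocks.append(betas.T)

        for j in range(spec.n_cpg):
            probe_counter += 1
            probe_id = f"cg{probe_counter:07d}"
            probe_ids.append(probe_id)
            manifest.append(
                CpGSite(
                    probe_id=probe_id,
                    chromosome=spec.chromosome,
                    coordinate=int(coords[j]),
                    gene_symbols=(spec.symbol,),
                    region_groups=(_REGION_CYCLE[j % len(_REGION_CYCLE)],),
                )
            )

    beta = BetaMatrix(
        probe_ids=probe_ids, sample_ids=sample_ids, values=np.vstack(blocks)
    )
    sheet = SampleSheet(
        samples=tuple(
            Sample(sample_id=sid, sex=sex, gestation=g)
            for sid, sex, g in zip(sample_ids, sexes, gestations)
        )
    )
    truth = SyntheticTruth(
        gene_categories={
            f"{g.symbol}@{g.chromosome}": g.category for g in config.genes
        },
        sample_sex=dict(zip(sample_ids, sexes)),
        sample_gestation=dict(zip(sample_ids, gestations)),
        seed=config.seed,
    )
    return beta, manifest, sheet, truth


def example_gene_panel() -> tuple[GeneSpec, ...]:
    """~200-gene panel for the bundled example cohort.

    A PGK1-like X-inactivated positive control, 109 further inactivated
    X genes, the 16 known escape-list symbols planted as escape genes,
    24 generic escape X genes and 50 autosomal null genes. CpG counts
    cycle over 4-12 to exercise variable signal lengths.
    """
    escape_named = (
        "ARSD", "DDX3X", "EIF1AX", "EIF2S3", "GEMIN8", "HDHD1", "KAL1", "KDM6A",
        "OFD1", "PRKX", "RPS4X", "TRAPPC2", "TXLNG", "USP9X", "ZFX", "ZRSR2",
    )
    panel: list[GeneSpec] = [GeneSpec("PGK1", "X", 10, "inactivated")]
    for i in range(109):
        panel.append(GeneSpec(f"XINACT{i + 1:03d}", "X", 4 + i % 9, "inactivated"))
    for i, sym in enumerate(escape_named):
        panel.append(GeneSpec(sym, "X", 5 + i % 8, "escape"))
    for i in range(24):
        panel.append(GeneSpec(f"XESC{i + 1:03d}", "X", 4 + i % 9, "escape"))
    for i in range(50):
        panel.append(GeneSpec(f"AUTO{i + 1:03d}", str(i % 22 + 1), 4 + i % 9, "autosomal"))
    return tuple(panel)


def make_example_cohort(
    outdir: str | Path | None = None, seed: int = 2026
) -> tuple[BetaMatrix, list[CpGSite], SampleSheet, SyntheticTruth]:
    """Generate the 12-sample example cohort (6 female / 6 male, balanced
    term/preterm) with a planted effect Δ = 0.45, and optionally write it.

    When ``outdir`` is given, writes ``beta.tsv``, ``manifest.csv``,
    ``samples.csv`` and ``truth.json`` there.
    """
    config = SimConfig(
        genes=example_gene_panel(),
        n_male=6,
        n_female=6,
        effect=0.45,
        noise_sd=0.05,
        baseline=0.05,
        seed=seed,
    )
    beta, manifest, sheet, truth = simulate_dataset(config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_beta_matrix(beta, outdir / "beta.tsv")
        write_manifest(manifest, outdir / "manifest.csv")
        write_sample_sheet(sheet, outdir / "samples.csv")
        truth.to_json(outdir / "truth.json")
    return beta, manifest, sheet, truth
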