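"""Assemble per-gene methylation signals.

A gene's *methylation signal* is the vector of its CpG β values ordered
by physical chromosomal coordinate; stacking one such vector per sample
gives the gene's pattern matrix, the object the PCA kernel classifier
consumes. Multi-mapped probes contribute to every gene they annotate;
probes with a missing β in any sample are dropped (complete-case across
samples) so the sample design stays intact for cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BetaMatrix, CpGSite

__all__ = [
    "PROMOTER_REGIONS",
    "GeneSignal",
    "NoGenesError",
    "build_gene_signals",
    "restrict_chromosome",
]

#: HM450-style gene-region tokens conventionally treated as the promoter.
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

GENOME = "genome"


class NoGenesError(RuntimeError):
    """No gene survived the CpG-count / region / completeness filters."""


@dataclass
class GeneSignal:
    """One gene's pattern matrix: samples × coordinate-ordered CpGs."""

    gene: str
    chromosome: str
    coordinates: tuple[int, ...]
    sample_ids: tuple[str, ...]
    pattern: np.ndarray  # samples x n_cpg, no missing values

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        if self.pattern.shape != (len(self.sample_ids), len(self.coordinates)):
            raise ValueError(
                f"gene {self.gene}: pattern shape {self.pattern.shape} != "
                f"({len(self.sample_ids)}, {len(self.coordinates)})"
            )
        if np.isnan(self.pattern).any():
            raise ValueError(f"gene {self.gene}: pattern contains missing values")
        coords = np.asarray(self.coordinates)
        if coords.size and not (np.diff(coords) > 0).all():
            raise ValueError(f"gene {self.gene}: coordinates not strictly increasing")

    @property
    def n_cpg(self) -> int:
        return len(self.coordinates)


def build_gene_signals(
    beta: BetaMatrix,
    manifest: Sequence[CpGSite],
    region_mode: str = "all",
    min_cpg: int = 3,
) -> list[GeneSignal]:
    """Group β values into per-gene, coordinate-ordered pattern matrices.

    Parameters
    ----------
    region_mode
        ``"all"`` keeps every CpG mapped to the gene;
        ``"promoter"`` keeps only CpGs whose gene-region token is one of
        :data:`PROMOTER_REGIONS`.
    min_cpg
        Minimum CpGs a gene must retain (after region filtering and
        missing-value removal) to be emitted. Must be >= 2; with fewer
        than 3 CpGs every zero-mean pattern is ±(x, −x) and the
        correlation kernel is degenerate, hence the default of 3.

    Returns signals sorted by (chromosome, gene); the output is invariant
    to manifest row order. Genes annotated on several chromosomes are
    kept as separate (gene, chromosome) records.
    """
    if region_mode not in ("all", "promoter"):
        raise ValueError(f"region_mode must be 'all' or 'promoter', got {region_mode!r}")
    if min_cpg < 2:
        raise ValueError(f"min_cpg must be >= 2, got {min_cpg}")

    probe_rows = beta.probe_index()
    unknown = [s.probe_id for s in manifest if s.probe_id not in probe_rows]
    if unknown:
        warnings.warn(
            f"{len(unknown)} manifest probes absent from the beta matrix "
            f"(e.g. {unknown[:3]}); they are skipped",
            stacklevel=2,
        )

    # complete-case filter: drop probes with any missing beta across samples
    complete = ~np.isnan(beta.values).any(axis=1)

    per_gene: dict[tuple[str, str], list[tuple[int, str, int]]] = {}
    for site in manifest:
        row = probe_rows.get(site.probe_id)
        if row is None or not complete[row]:
            continue
        for k, gene in enumerate(site.gene_symbols):
            if region_mode == "promoter":
                region = site.region_groups[k] if site.region_groups else ""
                if region not in PROMOTER_REGIONS:
                    continue
            per_gene.setdefault((gene, site.chromosome), []).append(
                (site.coordinate, site.probe_id, row)
            )

    signals: list[GeneSignal] = []
    for (gene, chromosome), entries in per_gene.items():
        entries.sort()  # by coordinate, then probe_id: manifest-order invariant
        kept: list[tuple[int, str, int]] = []
        for coord, probe_id, row in entries:
            if kept and kept[-1][0] == coord:
                warnings.warn(
                    f"gene {gene} ({chromosome}): probes {kept[-1][1]} and {probe_id} "
                    f"share coordinate {coord}; keeping {kept[-1][1]}",
                    stacklevel=2,
                )
                continue
            kept.append((coord, probe_id, row))
        if len(kept) < min_cpg:
            continue
        rows = [r for _, _, r in kept]
        signals.append(
            GeneSignal(
                gene=gene,
                chromosome=chromosome,
                coordinates=tuple(c for c, _, _ in kept),
                sample_ids=tuple(beta.sample_ids),
                pattern=beta.values[rows, :].T.copy(),
            )
        )

    if not signals:
        raise NoGenesError(
            "no genes passed filters "
            f"(region_mode={region_mode!r}, min_cpg={min_cpg})"
        )
    signals.sort(key=lambda s: (s.chromosome, s.gene))
    return signals


def restrict_chromosome(
    signals: Sequence[GeneSignal], chromosome: str = GENOME
) -> list[GeneSignal]:
    """Keep only signals on ``chromosome``; ``"genome"`` is the identity.

    An unknown chromosome token yields an empty list with a warning
    rather than an error, so a genome-wide scan can be narrowed safely.
    """
    if chromosome == GENOME:
        return list(signals)
    kept = [s for s in signals if s.chromosome == chromosome]
    if not kept:
        warnings.warn(
            f"no signals on chromosome {chromosome!r}; returning empty list",
            stacklevel=2,
        )
    return kept
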