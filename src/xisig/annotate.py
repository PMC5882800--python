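"""Gene-set operations downstream of the MCC partition.

X-linked genes that fail the MCC threshold (*variable* X methylation)
are candidates for escape from X inactivation. This module intersects
them with packaged, versioned gene lists:

* ``escape_x`` — 16 X-linked genes with confirmed escape status and
  female-biased lung expression;
* ``immune_x`` — 16 X-linked immune genes with escape or heterogeneous
  Xi status;
* ``female_biased_immune`` — the 3 immune escape genes with confirmed
  female-biased airway expression (DDX3X, PRKX, TXLNG).

Symbol matching is exact after upper-casing; no alias resolution is
attempted (alias maps are database-version dependent — mismatches are
reported, never guessed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .crossval import GeneScore
from .pca import RATIO_MODES

__all__ = [
    "GeneList",
    "BUNDLED_LISTS",
    "load_gene_list",
    "rank_top",
    "intersect_with_list",
    "cross_cohort_overlap",
]

logger = logging.getLogger(__name__)

BUNDLED_LISTS = ("escape_x", "immune_x", "female_biased_immune")


@dataclass(frozen=True)
class GeneList:
    """A named, sourced set of upper-cased gene symbols."""

    name: str
    symbols: frozenset[str]
    source: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene list {self.name!r} is empty")
        object.__setattr__(
            self, "symbols", frozenset(s.upper() for s in self.symbols)
        )


def load_gene_list(name: str) -> GeneList:
    """Load one of the packaged gene-list CSV fixtures by name."""
    if name not in BUNDLED_LISTS:
        raise ValueError(f"unknown gene list {name!r}; bundled: {BUNDLED_LISTS}")
    ref = resources.files("xisig.data").joinpath(f"{name}.csv")
    with ref.open("r") as handle:
        df = pd.read_csv(handle, dtype=str)
    sources = sorted(set(df["source"]))
    return GeneList(
        name=name,
        symbols=frozenset(df["symbol"]),
        source="; ".join(sources),
    )


def rank_top(
    scores: Sequence[GeneScore], n: int, ratio_mode: str = "lambda2_over_lambda1"
) -> list[GeneScore]:
    """Top ``n`` genes by the chosen eigenvalue ratio, descending.

    Ties are broken by gene symbol ascending and logged. ``n`` larger
    than the input returns everything, no padding.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if ratio_mode not in RATIO_MODES:
        raise ValueError(f"unknown ratio mode {ratio_mode!r}")
    key = (
        (lambda s: s.pca_ratio)
        if ratio_mode == "lambda2_over_lambda1"
        else (lambda s: s.pca_ratio_l1frac)
    )
    ordered = sorted(scores, key=lambda s: (-key(s), s.gene))
    values = [key(s) for s in ordered]
    if len(values) != len(set(values)):
        logger.info("rank_top: tied eigenvalue ratios broken by gene symbol")
    return ordered[:n]


def intersect_with_list(
    variable_genes: Iterable[str], gene_list: GeneList
) -> set[str]:
    """Case-insensitive intersection of gene symbols with a curated list."""
    return {g.upper() for g in variable_genes} & gene_list.symbols


def cross_cohort_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> set[str]:
    """Plain intersection of two cohorts' gene sets; the count is logged."""
    overlap = set(set_a) & set(set_b)
    logger.info("cross-cohort overlap: %d genes", len(overlap))
    return overlap
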