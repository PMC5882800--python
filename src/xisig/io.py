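"""Readers and writers for every on-disk artifact of the pipeline.

The pipeline exchanges five plain-text formats:

* **beta matrix** — TSV, probes in rows (GEO series-matrix orientation),
  samples in columns, values are Illumina-style β in [0, 1] or a missing
  token (default ``NA``);
* **probe manifest** — slim 5-column CSV mapping each probe to a
  chromosome, a 1-based coordinate and semicolon-joined gene symbols /
  gene-region groups (a light-weight surrogate for the vendor HM450
  manifest);
* **sample sheet** — CSV of sample id, sex and an optional term/preterm
  gestation label;
* **score report** — per-gene TSV with MCC, both eigenvalue-ratio
  variants and the binary class call;
* **histogram / heatmap** — TSV exports of the MCC distribution and the
  first-eigenvector projections.

Floats are written with 10 significant digits so that
``read(write(x)) == x`` holds on the decimal text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CpGSite",
    "BetaMatrix",
    "Sample",
    "SampleSheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_score_report",
    "read_score_report",
    "write_histogram",
    "read_histogram",
    "write_heatmap",
    "read_heatmap",
]

FLOAT_FMT = "%.10g"
SEXES = ("female", "male")
GESTATIONS = ("term", "preterm")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class CpGSite:
    """One manifest row: a probe anchored to a chromosome position.

    ``gene_symbols`` may be empty (intergenic probe); ``region_groups``
    is either empty or parallel to ``gene_symbols`` (one gene-region
    token such as ``TSS200`` or ``Body`` per mapped gene).
    """

    probe_id: str
    chromosome: str
    coordinate: int
    gene_symbols: tuple[str, ...] = ()
    region_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.coordinate < 1:
            raise FormatError(
                f"probe {self.probe_id}: coordinate must be >= 1, got {self.coordinate}"
            )
        if self.region_groups and len(self.region_groups) != len(self.gene_symbols):
            raise FormatError(
                f"probe {self.probe_id}: {len(self.region_groups)} region groups for "
                f"{len(self.gene_symbols)} gene symbols"
            )


@dataclass
class BetaMatrix:
    """Probes × samples grid of β methylation fractions.

    ``values`` is a float array with ``NaN`` marking missing entries;
    every non-missing entry lies in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _duplicates(self.probe_ids)
            raise FormatError(f"duplicate probe ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise FormatError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        bad = np.nonzero(~np.isnan(self.values) & ((self.values < 0) | (self.values > 1)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise FormatError(
                f"beta value out of [0, 1]: probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}, value {self.values[i, j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str
    gestation: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise FormatError(
                f"sample {self.sample_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.gestation is not None and self.gestation not in GESTATIONS:
            raise FormatError(
                f"sample {self.sample_id}: gestation must be one of {GESTATIONS}, "
                f"got {self.gestation!r}"
            )


@dataclass
class SampleSheet:
    """Per-sample metadata: sex (required) and optional gestation group."""

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate sample ids in sample sheet: {sorted(_duplicates(ids))}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sex_labels(self) -> dict[str, str]:
        return {s.sample_id: s.sex for s in self.samples}

    def gestation_labels(self) -> dict[str, str | None]:
        return {s.sample_id: s.gestation for s in self.samples}


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(
    path: str | Path, missing_token: str = "NA", transpose: bool = False
) -> BetaMatrix:
    """Parse a β-value TSV (probes in rows, header row of sample ids).

    ``missing_token`` cells become NaN; any other non-numeric cell, any
    value outside [0, 1] and any duplicate probe id raise
    :class:`FormatError` naming the offending probe/sample.
    ``transpose=True`` accepts the samples-in-rows orientation.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.T
    probe_ids = [str(p) for p in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    values = np.empty(raw.shape, dtype=float)
    cells = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = cells[i, j].strip()
            if cell == missing_token:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric beta value {cell!r} at probe {probe_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    return BetaMatrix(probe_ids=probe_ids, sample_ids=sample_ids, values=values)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    df = beta.to_frame()
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=missing_token)


# ---------------------------------------------------------------------------
# manifest

MANIFEST_COLUMNS = ["probe_id", "chromosome", "coordinate", "gene_symbols", "region_groups"]


def read_manifest(path: str | Path) -> list[CpGSite]:
    """Parse the slim 5-column probe manifest CSV.

    Gene symbols and region groups are semicolon-joined; an empty
    ``gene_symbols`` field yields an intergenic site with no genes.
    Row count in == sites out: any malformed row raises rather than
    being dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"manifest missing columns: {missing_cols}")
    sites: list[CpGSite] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        probe_id = str(row.probe_id)
        if probe_id in seen:
            raise FormatError(f"duplicate probe id in manifest: {probe_id!r}")
        seen.add(probe_id)
        try:
            coordinate = int(str(row.coordinate))
        except ValueError:
            raise FormatError(
                f"probe {probe_id!r}: non-integer coordinate {row.coordinate!r}"
            ) from None
        genes = tuple(g for g in str(row.gene_symbols).split(";") if g)
        regions = tuple(r for r in str(row.region_groups).split(";") if r)
        sites.append(
            CpGSite(
                probe_id=probe_id,
                chromosome=str(row.chromosome),
                coordinate=coordinate,
                gene_symbols=genes,
                region_groups=regions,
            )
        )
    return sites


def write_manifest(sites: Iterable[CpGSite], path: str | Path) -> None:
    rows = [
        {
            "probe_id": s.probe_id,
            "chromosome": s.chromosome,
            "coordinate": s.coordinate,
            "gene_symbols": ";".join(s.gene_symbols),
            "region_groups": ";".join(s.region_groups),
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise FormatError("sample sheet requires columns sample_id and sex")
    samples = []
    for row in df.itertuples(index=False):
        gestation = getattr(row, "gestation", "") or None
        samples.append(Sample(sample_id=str(row.sample_id), sex=str(row.sex), gestation=gestation))
    return SampleSheet(samples=tuple(samples))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "sex": s.sex, "gestation": s.gestation or ""}
        for s in sheet.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "sex", "gestation"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# score report

REPORT_COLUMNS = [
    "gene",
    "chromosome",
    "n_cpg",
    "mcc",
    "pca_ratio",
    "pca_ratio_l1frac",
    "separable",
    "class",
]


def write_score_report(
    scores: Sequence, path: str | Path, ratio_mode: str = "lambda2_over_lambda1"
) -> None:
    """Write the per-gene TSV report, sorted descending by the chosen
    eigenvalue ratio (ties broken by gene symbol ascending).

    ``scores`` is a sequence of :class:`xisig.crossval.GeneScore` (or any
    objects exposing the same attributes).
    """
    if not scores:
        raise FormatError("cannot write an empty score report")
    key = "pca_ratio" if ratio_mode == "lambda2_over_lambda1" else "pca_ratio_l1frac"
    rows = [
        {
            "gene": s.gene,
            "chromosome": s.chromosome,
            "n_cpg": s.n_cpg,
            "mcc": s.mcc,
            "pca_ratio": s.pca_ratio,
            "pca_ratio_l1frac": s.pca_ratio_l1frac,
            "separable": bool(s.separable),
            "class": s.classification,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df = df.sort_values([key, "gene"], ascending=[False, True], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_score_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"score report missing columns: {missing_cols}")
    return df


# ---------------------------------------------------------------------------
# histogram and heatmap


def write_histogram(
    bins: Sequence[tuple[float, float, int]], path: str | Path
) -> None:
    df = pd.DataFrame(bins, columns=["bin_left", "bin_right", "count"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_histogram(path: str | Path) -> list[tuple[float, float, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (float(l), float(r), int(c))
        for l, r, c in zip(df["bin_left"], df["bin_right"], df["count"])
    ]


def write_heatmap(values: pd.DataFrame, path: str | Path) -> None:
    """Genes × samples TSV of first-eigenvector projections."""
    values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_heatmap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index.name = None  # the "gene" label is file-format only
    return df
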