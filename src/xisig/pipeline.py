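"""End-to-end orchestration: files in, scored gene partition out.

``run_pipeline`` wires the stages together — read β matrix, manifest
and sample sheet; build coordinate-ordered gene signals; optionally
restrict to one chromosome; score every gene under exhaustive
cross-validation; partition at the MCC threshold; intersect the
variable set with the packaged escape/immune lists — and writes every
artifact as TSV/text plus a run log. Outputs contain no timestamps, so
two runs on the same inputs are byte-identical.

``fetch_validation_cohort`` is an OPTIONAL, network-gated driver that
downloads a GEO series matrix (e.g. GSE65163) into a local cache; no
part of the test suite or the offline pipeline depends on it.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import urllib.request
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import BUNDLED_LISTS, intersect_with_list, load_gene_list
from .crossval import (
    GeneScore,
    MCC_THRESHOLD,
    enumerate_splits,
    mcc_histogram,
    partition_genes,
    score_gene,
)
from .io import (
    BetaMatrix,
    SampleSheet,
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    write_heatmap,
    write_histogram,
    write_score_report,
)
from .pca import correlation_kernel, eigen_spectrum, project_top2
from .signals import GeneSignal, build_gene_signals, restrict_chromosome

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "run_pipeline",
    "fetch_validation_cohort",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any computation)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class PipelineConfig:
    """Flat configuration; every field mirrors a CLI flag one-to-one."""

    beta: str
    manifest: str
    samplesheet: str
    outdir: str
    region_mode: str = "all"
    chromosome: str = "X"
    min_cpg: int = 3
    train_per_class: int = 3
    mcc_threshold: float = MCC_THRESHOLD
    ratio_mode: str = "lambda2_over_lambda1"
    hist_bin_width: float = 0.05
    missing_token: str = "NA"
    gene_lists: tuple[str, ...] = ("escape_x", "immune_x", "female_biased_immune")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "gene_lists" in data:
            data["gene_lists"] = tuple(data["gene_lists"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("beta", "manifest", "samplesheet"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.min_cpg < 2:
            raise ConfigError(f"min_cpg must be >= 2, got {self.min_cpg}")
        if self.train_per_class < 1:
            raise ConfigError(f"train_per_class must be >= 1, got {self.train_per_class}")
        if not (-1.0 <= self.mcc_threshold <= 1.0):
            raise ConfigError(f"mcc_threshold must be in [-1, 1], got {self.mcc_threshold}")
        if self.hist_bin_width <= 0:
            raise ConfigError(f"hist_bin_width must be > 0, got {self.hist_bin_width}")
        unknown = [g for g in self.gene_lists if g not in BUNDLED_LISTS]
        if unknown:
            raise ConfigError(f"unknown gene lists {unknown}; bundled: {BUNDLED_LISTS}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write all artifacts into ``config.outdir``.

    Returns a name → path mapping of the written artifacts. Any stage
    failure removes partial outputs and raises :class:`PipelineError`
    naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log_lines: list[str] = []
    stage = "load_inputs"
    try:
        beta = read_beta_matrix(config.beta, missing_token=config.missing_token)
        manifest = read_manifest(config.manifest)
        sheet = read_sample_sheet(config.samplesheet)
        _check_samples(beta, sheet)

        stage = "build_signals"
        signals = build_gene_signals(
            beta, manifest, region_mode=config.region_mode, min_cpg=config.min_cpg
        )
        signals = restrict_chromosome(signals, config.chromosome)
        if not signals:
            raise PipelineError(
                f"no gene signals on chromosome {config.chromosome!r}"
            )

        stage = "cross_validation"
        labels = sheet.sex_labels()
        plan = enumerate_splits(labels, config.train_per_class)
        scores: list[GeneScore] = []
        for signal in signals:
            score = score_gene(
                signal, labels, plan, mcc_threshold=config.mcc_threshold
            )
            scores.append(score)
            log_lines.append(
                f"gene={score.gene}\tchromosome={score.chromosome}\t"
                f"n_cpg={score.n_cpg}\tmcc={score.mcc:.10g}\t"
                f"pca_ratio={score.pca_ratio:.10g}\tclass={score.classification}\t"
                f"separable={score.separable}\tties={score.n_ties}\t"
                f"degenerate={score.degenerate}"
            )

        stage = "partition"
        differential, variable = partition_genes(scores, config.mcc_threshold)
        all_scores = differential + variable

        stage = "write_report"
        paths = {"report": outdir / "score_report.tsv"}
        write_score_report(all_scores, paths["report"], ratio_mode=config.ratio_mode)
        created.append(paths["report"])

        stage = "write_histogram"
        paths["histogram"] = outdir / "mcc_histogram.tsv"
        write_histogram(mcc_histogram(all_scores, config.hist_bin_width), paths["histogram"])
        created.append(paths["histogram"])

        stage = "write_gene_lists"
        paths["sex_differential"] = outdir / "sex_differential_genes.txt"
        paths["variable"] = outdir / "variable_genes.txt"
        _write_symbols(sorted(s.gene for s in differential), paths["sex_differential"])
        _write_symbols(sorted(s.gene for s in variable), paths["variable"])
        created += [paths["sex_differential"], paths["variable"]]

        stage = "annotation_filters"
        variable_symbols = {s.gene for s in variable}
        for list_name in config.gene_lists:
            gene_list = load_gene_list(list_name)
            hits = intersect_with_list(variable_symbols, gene_list)
            path = outdir / f"variable_in_{list_name}.txt"
            _write_symbols(sorted(hits), path)
            paths[f"variable_in_{list_name}"] = path
            created.append(path)
            log_lines.append(
                f"genelist={list_name}\tsize={len(gene_list.symbols)}\thits={len(hits)}"
            )

        stage = "write_heatmap"
        paths["heatmap"] = outdir / "projection_heatmap.tsv"
        diff_names = [s.gene for s in differential]
        _export_heatmap(signals, diff_names, sheet, paths["heatmap"])
        created.append(paths["heatmap"])

        stage = "write_log"
        paths["log"] = outdir / "run_log.txt"
        _write_log(config, scores, log_lines, paths["log"])
        created.append(paths["log"])
    except ConfigError:
        raise
    except PipelineError:
        _cleanup(created)
        raise
    except Exception as exc:
        _cleanup(created)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return paths


def _check_samples(beta: BetaMatrix, sheet: SampleSheet) -> None:
    missing = [s for s in beta.sample_ids if s not in set(sheet.sample_ids)]
    if missing:
        raise ConfigError(f"samples missing from sample sheet: {missing[:5]}")


def _write_symbols(symbols: Sequence[str], path: Path) -> None:
    path.write_text("".join(f"{s}\n" for s in symbols))


def _export_heatmap(
    signals: Sequence[GeneSignal],
    gene_names: Sequence[str],
    sheet: SampleSheet,
    path: Path,
) -> None:
    """First-eigenvector projections per gene × sample, columns grouped
    by sex then gestation (the heatmap content, without a plotting stack)."""
    gestation = sheet.gestation_labels()
    sex = sheet.sex_labels()
    ordered_samples = sorted(
        sheet.sample_ids, key=lambda s: (sex[s], gestation[s] or "", s)
    )
    by_name = {s.gene: s for s in signals}
    rows = {}
    for name in gene_names:
        signal = by_name[name]
        spectrum = eigen_spectrum(correlation_kernel(signal))
        proj1 = project_top2(spectrum)[:, 0]
        series = dict(zip(signal.sample_ids, proj1))
        rows[name] = [series[s] for s in ordered_samples]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ordered_samples)
    write_heatmap(df, path)


def _write_log(
    config: PipelineConfig,
    scores: Sequence[GeneScore],
    log_lines: Sequence[str],
    path: Path,
) -> None:
    n_ties = sum(s.n_ties for s in scores)
    n_degenerate = sum(1 for s in scores if s.degenerate)
    header = [
        f"xisig_version={__version__}",
        "config=" + yaml.safe_dump(asdict(config), sort_keys=True).strip().replace("\n", "; "),
        f"genes_scored={len(scores)}",
        f"sex_differential={sum(1 for s in scores if s.mcc > config.mcc_threshold)}",
        f"ties_total={n_ties}",
        f"degenerate_genes={n_degenerate}",
    ]
    path.write_text("".join(f"{line}\n" for line in [*header, *log_lines]))


def _cleanup(created: Sequence[Path]) -> None:
    for p in created:
        try:
            p.unlink(missing_ok=True)
        except OSError:  # pragma: no cover - best effort
            logger.warning("could not remove partial output %s", p)


# ---------------------------------------------------------------------------
# optional GEO validation driver (network required; no test downloads)

GEO_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}nnn/{accession}/matrix/"
    "{accession}_series_matrix.txt.gz"
)


class ValidationFetchError(RuntimeError):
    """The GEO download or metadata extraction failed (never simulated)."""


def fetch_validation_cohort(
    accession: str, cache_dir: str | Path
) -> tuple[BetaMatrix, SampleSheet]:
    """Download and parse a GEO HM450 series matrix (OPTIONAL, needs network).

    The gzipped series matrix is cached under ``cache_dir`` and reused on
    later calls. Sex labels are taken from the series metadata
    (``!Sample_characteristics_ch1`` lines containing ``sex:`` or
    ``gender:``); if absent, the error lists the available
    characteristic fields. Failures are always surfaced — this cohort is
    never silently replaced by simulation.
    """
    accession = accession.strip().upper()
    if not accession.startswith("GSE"):
        raise ValidationFetchError(f"expected a GEO series accession (GSEnnn), got {accession!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached = cache_dir / f"{accession}_series_matrix.txt.gz"
    if not cached.exists():
        url = GEO_MATRIX_URL.format(stub=accession[:-3], accession=accession)
        logger.info("downloading %s", url)
        try:
            with urllib.request.urlopen(url, timeout=120) as response:
                payload = response.read()
        except Exception as exc:
            raise ValidationFetchError(
                f"could not download {accession} from GEO ({url}): {exc}. "
                "The validation cohort is optional and requires network access."
            ) from exc
        cached.write_bytes(payload)
    else:
        logger.info("using cached %s", cached)
    return _parse_series_matrix(cached, accession)


def _parse_series_matrix(
    path: Path, accession: str
) -> tuple[BetaMatrix, SampleSheet]:
    meta: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    with gzip.open(path, "rt", errors="replace") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key = line.split("\t", 1)[0]
                values = [v.strip('"') for v in line.split("\t")[1:]]
                meta.setdefault(key, []).append(values)
    if not table_lines:
        raise ValidationFetchError(f"{accession}: no expression/methylation table found")
    df = pd.read_csv(_stdio.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    sample_ids = [str(c) for c in df.columns]
    sexes = _extract_sex(meta, sample_ids, accession)
    beta = BetaMatrix(
        probe_ids=[str(p) for p in df.index],
        sample_ids=sample_ids,
        values=np.clip(df.to_numpy(dtype=float), 0.0, 1.0),
    )
    from .io import Sample, SampleSheet as _Sheet

    sheet = _Sheet(
        samples=tuple(
            Sample(sample_id=sid, sex=sexes[sid]) for sid in sample_ids
        )
    )
    return beta, sheet


def _extract_sex(
    meta: dict[str, list[list[str]]], sample_ids: Sequence[str], accession: str
) -> dict[str, str]:
    for values in meta.get("!Sample_characteristics_ch1", []):
        lowered = [v.lower() for v in values]
        if all(("sex:" in v or "gender:" in v) for v in lowered if v):
            out = {}
            for sid, v in zip(sample_ids, lowered):
                token = v.split(":", 1)[1].strip()
                out[sid] = {"f": "female", "m": "male"}.get(token[:1], token)
            return out
    available = sorted(meta)
    raise ValidationFetchError(
        f"{accession}: no sex/gender field in sample characteristics; "
        f"available metadata fields: {available}"
    )
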