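"""End-to-end orchestration: coverage contrasts and expression dynamics.

Two entry points mirror the two halves of the analysis:

* :func:`run_coverage` — peak files -> per-chromosome coverage summaries
  and autosomal-CI contrasts, one report per mark plus a combined
  long-format table;
* :func:`run_expression` — expression matrix -> threshold (fixed or
  estimated from exon/intergenic values) -> gene dynamics classification
  (optionally after family collapsing) -> chromosome summaries, RPKM
  histograms, and chromosome-vs-reference statistical contrasts with
  star coding.

Every run writes a manifest (config echo, input checksums, package
version) into the output directory; inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenomeTable,
    ValidationError,
    read_annotation,
    read_expression_matrix,
    read_genome_table,
    read_peaks,
    write_report,
    STAGES,
)
from .coverage import coverage_summary, coverage_contrast, coverage_report_frame
from .threshold import estimate_threshold, average_thresholds
from .dynamics import (
    classify_matrix,
    collapse_families,
    summarize_chromosomes,
    subset_rpkm,
    rpkm_histogram,
)
from .stats import chi_square_2x2, mann_whitney, significance_stars

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.22  # average exon/intergenic crossing of the reference datasets


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run."""

    genome: str
    out_dir: str
    annotation: str | None = None
    expression: str | None = None
    # list of (mark_name, path, dialect)
    peaks: list[tuple[str, str, str]] = field(default_factory=list)
    # list of (dataset_id, exon_values_path, intergenic_values_path)
    density_datasets: list[tuple[str, str, str]] = field(default_factory=list)
    threshold: float | str = DEFAULT_THRESHOLD  # fixed value or "estimate"
    bin_width: float = 2.0
    collapse: bool = False
    x_reference: list[str] | None = None  # autosomes to contrast X-class against
    y_reference: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if isinstance(self.threshold, (int, float)) and self.threshold <= 0:
            raise ValidationError("fixed threshold must be positive")
        if self.threshold == "estimate" and not self.density_datasets:
            raise ValidationError("threshold='estimate' requires exon/intergenic value files")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, out_dir: Path, extra: dict | None = None) -> None:
    from . import __version__

    inputs = [config.genome]
    inputs += [p for _, p, _ in config.peaks]
    for item in (config.annotation, config.expression):
        if item:
            inputs.append(item)
    for _, ex, ig in config.density_datasets:
        inputs += [ex, ig]
    manifest = {
        "pmsckit_version": __version__,
        "config": asdict(config),
        "input_checksums": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_coverage(config: RunConfig) -> dict[str, Path]:
    """Coverage summaries and autosomal-CI contrasts for every peak file."""
    config.validate()
    if not config.peaks:
        raise ValidationError("run_coverage: no peak files configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = read_genome_table(config.genome)

    tables: dict[str, pd.DataFrame] = {}
    combined = []
    contrast_rows = []
    for mark, path, dialect in config.peaks:
        peaks = read_peaks(path, mark, dialect)
        summary = coverage_summary(peaks, genome)
        contrast = coverage_contrast(summary, genome)
        frame = coverage_report_frame(summary, contrast)
        tables[f"coverage_{mark}"] = frame
        combined.append(frame)
        contrast_rows.append({
            "mark": mark,
            "genome_pct": summary.genome_pct,
            "autosome_mean_pct": contrast.autosome_mean,
            "autosome_sd_pct": contrast.autosome_sd,
            "ci_low_pct": contrast.ci_low,
            "ci_high_pct": contrast.ci_high,
            "flagged": ";".join(f"{c}:{d}" for c, d in contrast.flagged) or "-",
        })
        logger.info("mark %s: %d peaks, %d chromosome(s) flagged",
                    mark, len(peaks.intervals), len(contrast.flagged))
    tables["coverage_all_marks"] = pd.concat(combined, ignore_index=True)
    tables["coverage_contrasts"] = pd.DataFrame(contrast_rows)
    paths = write_report(tables, out_dir)
    _write_manifest(config, out_dir)
    return {p.stem: p for p in paths}


def resolve_threshold(config: RunConfig) -> tuple[float, pd.DataFrame | None]:
    """Fixed threshold, or the mean of per-dataset density crossings."""
    if config.threshold != "estimate":
        return float(config.threshold), None
    estimates = []
    for ds_id, exon_path, ig_path in config.density_datasets:
        exon = np.loadtxt(exon_path, ndmin=1)
        ig = np.loadtxt(ig_path, ndmin=1)
        estimates.append(estimate_threshold(exon, ig, dataset_id=ds_id))
    table = pd.DataFrame([
        {
            "dataset_id": e.dataset_id,
            "threshold_rpkm": e.threshold_rpkm,
            "n_exon": e.n_exon,
            "n_intergenic": e.n_intergenic,
            "crossing_log10": e.crossing_log10,
        }
        for e in estimates
    ])
    avg = average_thresholds(estimates)
    logger.info("estimated threshold %.4f RPKM from %d dataset(s)", avg, len(estimates))
    return avg, table


def _pick_reference(genome: GenomeTable, ann: pd.DataFrame, focal: str, n: int = 2) -> list[str]:
    """Autosomes closest to the focal chromosome in (length, gene count)."""
    counts = ann.groupby("chrom").size()
    lengths = genome.lengths
    f_len, f_cnt = lengths[focal], counts.get(focal, 0)
    scored = []
    for chrom in genome.autosomes():
        d = (np.log10(lengths[chrom] / f_len) ** 2
             + np.log10(max(counts.get(chrom, 1), 1) / max(f_cnt, 1)) ** 2)
        scored.append((d, chrom))
    return [c for _, c in sorted(scored)[:n]]


CONTRAST_CATEGORIES = (
    ("expressed_any", "n_genes_annotated", "n_expressed_any"),
    ("expressed_SB", "n_expressed_any", "n_expressed_SB"),
    ("expressed_PS", "n_expressed_any", "n_expressed_PS"),
    ("expressed_RS", "n_expressed_any", "n_expressed_RS"),
    ("expressed_ES", "n_expressed_any", "n_expressed_ES"),
    ("pachytene_repressed", "n_expressed_any", "n_pachytene_repressed"),
    ("rs_non_reactivated", "n_expressed_any", "n_rs_non_reactivated"),
    ("rs_enriched", "n_expressed_any", "n_rs_enriched"),
    ("rs_specific", "n_expressed_any", "n_de_novo_RS"),
)


def _category_counts(summary: pd.DataFrame, chroms: list[str]) -> dict[str, tuple[int, int]]:
    sub = summary[summary["chrom"].isin(chroms)]
    out = {}
    for cat, denom_col, num_col in CONTRAST_CATEGORIES:
        out[cat] = (int(sub[num_col].sum()), int(sub[denom_col].sum()))
    return out


def chromosome_contrasts(
    dynamics: pd.DataFrame,
    matrix,
    summary: pd.DataFrame,
    genome: GenomeTable,
    focal: str,
    references: list[str],
) -> pd.DataFrame:
    """Chi-square category contrasts and Mann-Whitney RPKM contrasts.

    The focal chromosome is compared against each reference autosome
    separately and against all autosomes pooled.
    """
    rows = []
    focal_counts = _category_counts(summary, [focal])
    ref_sets = [(r, [r]) for r in references] + [("autosomes", genome.autosomes())]
    for ref_label, ref_chroms in ref_sets:
        ref_counts = _category_counts(summary, ref_chroms)
        for cat, _, _ in CONTRAST_CATEGORIES:
            sa, ta = focal_counts[cat]
            sb, tb = ref_counts[cat]
            if ta == 0 or tb == 0:
                continue
            test = chi_square_2x2(sa, ta, sb, tb, label_a=focal, label_b=ref_label)
            rows.append({
                "comparison": f"{focal}_vs_{ref_label}",
                "quantity": cat,
                "test": "chi_square",
                "focal_count": sa, "focal_total": ta,
                "ref_count": sb, "ref_total": tb,
                "statistic": test.chi2,
                "p_value": test.p_value,
                "stars": significance_stars(test.p_value),
                "method": "chi2_df1" + ("_low_expected" if test.low_expected else ""),
            })
        for stage in STAGES:
            va = subset_rpkm(dynamics, matrix, focal, "expressed", stage)
            vb = np.concatenate([
                subset_rpkm(dynamics, matrix, c, "expressed", stage) for c in ref_chroms
            ]) if ref_chroms else np.array([])
            if va.size == 0 or vb.size == 0:
                continue
            test = mann_whitney(va, vb, label_a=focal, label_b=ref_label)
            rows.append({
                "comparison": f"{focal}_vs_{ref_label}",
                "quantity": f"rpkm_{stage}",
                "test": "mann_whitney",
                "focal_count": int(va.size), "focal_total": int(va.size),
                "ref_count": int(vb.size), "ref_total": int(vb.size),
                "statistic": test.u_statistic,
                "p_value": test.p_value,
                "stars": significance_stars(test.p_value),
                "method": test.method,
            })
    return pd.DataFrame(rows)


def run_expression(config: RunConfig) -> dict[str, Path]:
    """Threshold -> classification -> summaries -> contrasts, to TSV reports."""
    config.validate()
    if not (config.annotation and config.expression):
        raise ValidationError("run_expression: annotation and expression paths required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = read_genome_table(config.genome)
    annotation = read_annotation(config.annotation, genome)
    matrix = read_expression_matrix(config.expression, annotation)
    logger.info("loaded %d genes on %d chromosomes", len(matrix.genes), len(genome.chroms))

    threshold, threshold_table = resolve_threshold(config)
    if config.collapse:
        matrix = collapse_families(matrix)
        logger.info("collapsed families: %d rows remain", len(matrix.genes))

    dynamics = classify_matrix(matrix, threshold)
    summary = summarize_chromosomes(dynamics, matrix, genome, config.bin_width)
    if not dynamics["expressed_any"].any():
        logger.warning("no gene exceeds the threshold anywhere; summaries are zero, no tests run")

    tables: dict[str, pd.DataFrame] = {}
    gene_table = dynamics.reset_index().rename(columns={"index": "gene_id"})
    tables["gene_dynamics"] = gene_table
    tables["chromosome_summary"] = summary
    if threshold_table is not None:
        tables["thresholds"] = threshold_table

    hist_rows = []
    for chrom in genome.chroms:
        for subset in ("expressed", "rs_enriched", "rs_specific"):
            vals = subset_rpkm(dynamics, matrix, chrom, subset, "RS")
            hist = rpkm_histogram(vals, config.bin_width)
            hist.insert(0, "subset", subset)
            hist.insert(0, "chrom", chrom)
            hist_rows.append(hist)
    tables["rpkm_histograms"] = pd.concat(hist_rows, ignore_index=True)

    if dynamics["expressed_any"].any():
        contrast_frames = []
        for chrom, cls in genome.classes.items():
            if cls == "autosome":
                continue
            refs = (config.x_reference if cls == "X" else config.y_reference)
            if refs is None:
                refs = _pick_reference(genome, annotation, chrom)
            contrast_frames.append(
                chromosome_contrasts(dynamics, matrix, summary, genome, chrom, refs)
            )
        if contrast_frames:
            tables["contrast_tests"] = pd.concat(contrast_frames, ignore_index=True)

    paths = write_report(tables, out_dir)
    _write_manifest(config, out_dir, extra={"threshold_used": threshold})
    return {p.stem: p for p in paths}


def run_all(config: RunConfig) -> dict[str, Path]:
    """Coverage and expression halves in one call (shared output directory)."""
    out: dict[str, Path] = {}
    if config.peaks:
        out.update(run_coverage(config))
    if config.expression:
        out.update(run_expression(config))
    return out
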