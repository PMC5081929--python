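"""Per-chromosome peak-coverage statistics and autosomal CI contrasts.

Coverage of a chromatin mark on a chromosome is the total number of base
pairs under the union of its called peaks, expressed both as a percentage
of the chromosome's assembled length and as a percentage of the mark's
genome-wide covered bases.  Chromosomes (sex chromosomes in particular)
are then contrasted against the autosomal reference distribution: a
chromosome whose coverage percentage falls outside the autosomal
mean +/- 1.96 sd interval is flagged enriched or depleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeTable, PeakSet, ValidationError


@dataclass(frozen=True)
class CoverageSummary:
    """Per-chromosome covered bp and percentages for one mark."""

    mark_name: str
    rows: pd.DataFrame  # chrom, covered_bp, chrom_length_bp, pct_of_chrom, pct_of_total_mark
    genome_pct: float


@dataclass(frozen=True)
class CoverageContrast:
    """Autosomal reference interval and the chromosomes falling outside it."""

    mark_name: str
    autosome_mean: float
    autosome_sd: float
    ci_low: float
    ci_high: float
    flagged: list[tuple[str, str]]  # (chrom, "enriched" | "depleted")


def interval_union_length(
    intervals: list[tuple[str, int, int]] | pd.DataFrame,
) -> dict[str, int]:
    """Length of the union of intervals, per chromosome.

    Overlapping or adjacent intervals are counted once; order and
    duplication of the input are irrelevant.  Empty input yields {}.
    """
    if isinstance(intervals, pd.DataFrame):
        df = intervals
    else:
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    out: dict[str, int] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = np.sort(grp["start"].to_numpy(dtype=np.int64))
        ends = grp["end"].to_numpy(dtype=np.int64)[np.argsort(grp["start"].to_numpy(), kind="stable")]
        # sweep: a new block starts where start exceeds the running max end
        run_end = np.maximum.accumulate(ends)
        total = 0
        block_start = starts[0]
        block_end = run_end[0]
        for s, e in zip(starts[1:], run_end[1:]):
            if s > block_end:
                total += block_end - block_start
                block_start = s
            block_end = max(block_end, e)
        total += block_end - block_start
        out[str(chrom)] = int(total)
    return out


def coverage_summary(peaks: PeakSet, genome: GenomeTable) -> CoverageSummary:
    """One row per genome chromosome with covered bp and both percentages."""
    peaks.validate_against(genome)
    if genome.total_length <= 0:
        raise ValidationError("genome has zero total length")
    covered = interval_union_length(peaks.intervals)
    rows = genome.frame[["chrom", "length"]].rename(columns={"length": "chrom_length_bp"}).copy()
    rows.insert(1, "covered_bp", rows["chrom"].map(covered).fillna(0).astype(np.int64))
    rows["pct_of_chrom"] = 100.0 * rows["covered_bp"] / rows["chrom_length_bp"]
    total_covered = int(rows["covered_bp"].sum())
    if total_covered > 0:
        rows["pct_of_total_mark"] = 100.0 * rows["covered_bp"] / total_covered
    else:
        rows["pct_of_total_mark"] = 0.0
    genome_pct = 100.0 * total_covered / genome.total_length
    return CoverageSummary(peaks.mark_name, rows, genome_pct)


def coverage_contrast(summary: CoverageSummary, genome: GenomeTable) -> CoverageContrast:
    """Flag chromosomes outside the autosomal 95% interval of pct_of_chrom.

    The reference is mean +/- 1.96 sd (population sd, ddof=0) over
    autosomal per-chromosome coverage percentages; sex chromosomes are
    excluded from the reference but tested against it, and autosomes
    themselves can be flagged.
    """
    autosomes = genome.autosomes()
    if len(autosomes) < 2:
        raise ValidationError("cannot form autosomal reference: need >= 2 autosomes")
    rows = summary.rows
    auto_pct = rows.loc[rows["chrom"].isin(autosomes), "pct_of_chrom"].to_numpy()
    mean = float(np.mean(auto_pct))
    sd = float(np.std(auto_pct, ddof=0))
    ci_low, ci_high = mean - 1.96 * sd, mean + 1.96 * sd
    flagged: list[tuple[str, str]] = []
    for chrom, pct in zip(rows["chrom"], rows["pct_of_chrom"]):
        if pct > ci_high:
            flagged.append((chrom, "enriched"))
        elif pct < ci_low:
            flagged.append((chrom, "depleted"))
    return CoverageContrast(summary.mark_name, mean, sd, ci_low, ci_high, flagged)


def coverage_report_frame(
    summary: CoverageSummary, contrast: CoverageContrast
) -> pd.DataFrame:
    """Long-format per-chromosome report row set for one mark."""
    flags = dict(contrast.flagged)
    df = summary.rows.copy()
    df.insert(0, "mark", summary.mark_name)
    df["flagged"] = df["chrom"].map(lambda c: c in flags)
    df["direction"] = df["chrom"].map(lambda c: flags.get(c, "-"))
    return df
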