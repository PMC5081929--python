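"""Readers and writers for the pipeline's external tables.

All genomic intervals are held internally in BED convention: 0-based,
half-open.  MACS-style peak tables (1-based, closed) are converted once,
at read time, by subtracting 1 from the start; the dialect is consumed
there so no double conversion is possible.

Tables are plain TSV.  The genome table has columns ``chrom``, ``length``,
``class`` (``autosome`` / ``X`` / ``Y``); the gene annotation has
``gene_id``, ``chrom``, ``start``, ``end``, ``strand`` and optionally
``family_id`` and ``is_pseudogene``; the expression matrix has ``gene_id``
followed by the four stage columns ``SB``, ``PS``, ``RS``, ``ES``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("SB", "PS", "RS", "ES")

CHROM_CLASSES = ("autosome", "X", "Y")

PEAK_DIALECTS = ("bed3", "macs_xls")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome names, lengths (bp) and class labels, in file order."""

    frame: pd.DataFrame  # columns: chrom, length, class

    def __post_init__(self) -> None:
        df = self.frame
        if df.empty:
            raise ValidationError("no chromosomes in genome table")
        dup = df["chrom"][df["chrom"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate chromosome(s): {sorted(set(dup))}")
        bad = df.loc[df["length"] <= 0, "chrom"].tolist()
        if bad:
            raise ValidationError(f"non-positive length for chromosome(s): {bad}")
        unknown = df.loc[~df["class"].isin(CHROM_CLASSES), "class"].tolist()
        if unknown:
            raise ValidationError(
                f"unknown chromosome class(es) {unknown}; expected one of {CHROM_CLASSES}"
            )

    @property
    def chroms(self) -> list[str]:
        return self.frame["chrom"].tolist()

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.frame["chrom"], self.frame["length"].astype(int)))

    @property
    def classes(self) -> dict[str, str]:
        return dict(zip(self.frame["chrom"], self.frame["class"]))

    def autosomes(self) -> list[str]:
        return self.frame.loc[self.frame["class"] == "autosome", "chrom"].tolist()

    @property
    def total_length(self) -> int:
        return int(self.frame["length"].sum())


@dataclass(frozen=True)
class PeakSet:
    """A named chromatin mark's peak intervals (0-based, half-open).

    Intervals may overlap; downstream coverage takes their union.
    """

    mark_name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def validate_against(self, genome: GenomeTable) -> None:
        df = self.intervals
        unknown = sorted(set(df["chrom"]) - set(genome.chroms))
        if unknown:
            raise ValidationError(
                f"peak set {self.mark_name!r}: unknown chromosome(s) {unknown}"
            )
        lengths = df["chrom"].map(genome.lengths)
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"]) | (df["end"] > lengths)]
        if len(bad):
            raise ValidationError(
                f"peak set {self.mark_name!r}: {len(bad)} invalid interval(s), "
                f"first at {bad.iloc[0]['chrom']}:{bad.iloc[0]['start']}-{bad.iloc[0]['end']}"
            )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x stage RPKM values joined to the gene->chromosome/family map.

    ``values`` is indexed by gene_id with the four stage columns in
    developmental order; ``gene_info`` shares the index and carries at
    least ``chrom``, plus ``family_id`` when families are annotated.
    """

    values: pd.DataFrame
    gene_info: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(STAGES):
            raise ValidationError(
                f"stage columns must be {list(STAGES)} in order, got {list(self.values.columns)}"
            )
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative RPKM values")
        if not self.values.index.equals(self.gene_info.index):
            raise ValidationError("values and gene_info indexes differ")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate gene_id(s): {dups}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def chrom(self) -> pd.Series:
        return self.gene_info["chrom"]


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a TSV with columns chrom, length, class into a GenomeTable."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "class": str})
    missing = {"chrom", "length", "class"} - set(df.columns)
    if missing:
        raise ValidationError(f"genome table {path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"genome table {path}: no chromosomes")
    df = df[["chrom", "length", "class"]].copy()
    df["length"] = df["length"].astype(np.int64)
    return GenomeTable(df.reset_index(drop=True))


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    genome.frame.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path, genome: GenomeTable | None = None) -> pd.DataFrame:
    """Read a flat gene annotation table.

    Genes on chromosomes absent from ``genome`` (unplaced scaffolds) are
    dropped with a logged warning; only assembled chromosomes are analyzed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation {path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValidationError(f"annotation {path}: duplicate gene_id(s) {dups}")
    if "strand" not in df.columns:
        df["strand"] = "."
    if "family_id" in df.columns:
        df["family_id"] = df["family_id"].where(df["family_id"].notna(), None)
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValidationError(
            f"annotation {path}: {len(bad)} gene(s) with start >= end, "
            f"first gene_id {bad.iloc[0]['gene_id']!r}"
        )
    if genome is not None:
        placed = df["chrom"].isin(genome.chroms)
        n_drop = int((~placed).sum())
        if n_drop:
            logger.warning(
                "annotation %s: dropping %d gene(s) on chromosomes absent from the genome table",
                path, n_drop,
            )
            df = df[placed]
        over = df["end"] > df["chrom"].map(genome.lengths)
        if over.any():
            raise ValidationError(
                f"annotation {path}: {int(over.sum())} gene(s) extend past their "
                f"chromosome end, first gene_id {df.loc[over, 'gene_id'].iloc[0]!r}"
            )
    return df.reset_index(drop=True)


def read_peaks(path: str | Path, mark_name: str, dialect: str = "bed3") -> PeakSet:
    """Read a peak file into 0-based half-open intervals.

    dialect ``bed3``: headerless, first three columns chrom/start/end,
    already 0-based half-open.  dialect ``macs_xls``: MACS peak table
    with a commented preamble and a ``chr``/``start``/``end`` header,
    1-based closed coordinates, converted here by start - 1.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValidationError(f"unknown peak dialect {dialect!r}; expected one of {PEAK_DIALECTS}")
    if dialect == "bed3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        missing = {"chr", "start", "end"} - set(df.columns)
        if missing:
            raise ValidationError(f"MACS table {path}: missing column(s) {sorted(missing)}")
        df = df.rename(columns={"chr": "chrom"})[["chrom", "start", "end"]]
        df["start"] = df["start"].astype(np.int64) - 1  # 1-based closed -> 0-based half-open
        df["end"] = df["end"].astype(np.int64)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(
            f"peak file {path}: start >= end at data line {bad[0] + 1}"
        )
    return PeakSet(mark_name, df.reset_index(drop=True))


def write_peaks_bed3(peaks: PeakSet, path: str | Path) -> None:
    peaks.intervals.to_csv(path, sep="\t", index=False, header=False)


def read_expression_matrix(path: str | Path, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Read a gene x stage RPKM TSV and join it to the annotation.

    Genes absent from the annotation are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [s for s in STAGES if s not in df.columns]
    if missing:
        raise ValidationError(f"expression matrix {path}: missing stage column(s) {missing}")
    if "gene_id" not in df.columns:
        raise ValidationError(f"expression matrix {path}: missing gene_id column")
    df = df.set_index("gene_id")[list(STAGES)].astype(float)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"expression matrix {path}: negative RPKM value(s)")
    ann = annotation.set_index("gene_id")
    known = df.index.isin(ann.index)
    n_drop = int((~known).sum())
    if n_drop:
        logger.warning(
            "expression matrix %s: dropping %d gene(s) absent from the annotation",
            path, n_drop,
        )
        df = df[known]
    info_cols = [c for c in ("chrom", "family_id", "is_pseudogene") if c in ann.columns]
    info = ann.loc[df.index, info_cols]
    return ExpressionMatrix(df, info)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def _format_pct_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Render percentage-like float columns at 2 decimals (report style)."""
    out = df.copy()
    for col in out.columns:
        name = str(col).lower()
        if out[col].dtype.kind == "f" and ("pct" in name or name.endswith("_percent")):
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    return out


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table as <name>.tsv, percentages at 2 decimals.

    A full-precision sidecar <name>.full.tsv is written next to each
    rounded report.  Re-running on identical input is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for name in sorted(tables):
        df = tables[name]
        main = out_dir / f"{name}.tsv"
        _format_pct_frame(df).to_csv(main, sep="\t", index=False)
        sidecar = out_dir / f"{name}.full.tsv"
        df.to_csv(sidecar, sep="\t", index=False, float_format="%.12g")
        paths.append(main)
    return paths
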