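"""Stage-wise gene-expression dynamics classification and summaries.

Genes are tracked across four stages of spermatogenesis — spermatogonia B
(SB), pachytene spermatocytes (PS), round spermatids (RS), elongating
spermatids (ES) — and classified with simple threshold and twofold rules:

* expressed at a stage: RPKM strictly above the threshold;
* pachytene-repressed: expressed at SB and PS <= SB/2 (at least twofold
  down at meiosis);
* RS non-reactivated: pachytene-repressed and RS < SB/2 (does not recover
  at least half of the SB level after meiosis);
* RS-enriched: expressed at RS and RS >= 2*PS (at least twofold up in
  round spermatids);
* de novo at stage s: first stage whose RPKM exceeds the threshold, for
  genes silent at all earlier stages (SB-first genes carry no de novo
  label).  De-novo-RS genes are the "round spermatid-specific" genes.

Category flags are only assigned to genes expressed in at least one
stage; fully silent genes carry all-false flags.  Boundary semantics are
inclusive for the "at least twofold" rules (PS <= SB/2, RS >= 2*PS) and
exclusive for the recovery rule (RS < SB/2).

Multicopy gene families (ampliconic clusters such as Sly/Ssty or
alpha-takusan) defeat per-copy read assignment; ``collapse_families``
sums member RPKM into a single row per family before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenomeTable, ValidationError, STAGES

CATEGORY_COLUMNS = (
    "pachytene_repressed",
    "rs_non_reactivated",
    "rs_enriched",
)


@dataclass(frozen=True)
class GeneDynamics:
    """Per-gene boolean category flags across the four stages."""

    gene_id: str
    expressed_by_stage: tuple[bool, bool, bool, bool]  # SB, PS, RS, ES
    expressed_any: bool
    pachytene_repressed: bool
    rs_non_reactivated: bool
    rs_enriched: bool
    de_novo_stage: str  # none | PS | RS | ES


def classify_gene(
    rpkm_sb: float,
    rpkm_ps: float,
    rpkm_rs: float,
    rpkm_es: float,
    threshold: float,
    gene_id: str = "",
) -> GeneDynamics:
    """Classify a single gene's four-stage RPKM profile."""
    vals = (rpkm_sb, rpkm_ps, rpkm_rs, rpkm_es)
    if any(v < 0 for v in vals):
        raise ValidationError(f"negative RPKM in {vals}")
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    expressed = tuple(v > threshold for v in vals)
    expressed_any = any(expressed)
    if not expressed_any:
        return GeneDynamics(gene_id, expressed, False, False, False, False, "none")
    pr = expressed[0] and rpkm_ps <= rpkm_sb / 2
    nr = pr and rpkm_rs < rpkm_sb / 2
    en = expressed[2] and rpkm_rs >= 2 * rpkm_ps
    if expressed[0]:
        de_novo = "none"
    else:
        de_novo = next(s for s, e in zip(STAGES, expressed) if e)
    return GeneDynamics(gene_id, expressed, True, pr, nr, en, de_novo)


def classify_matrix(matrix: ExpressionMatrix, threshold: float) -> pd.DataFrame:
    """Vectorized classification of every gene in an expression matrix.

    Returns a DataFrame indexed by gene_id with boolean columns
    expressed_SB..expressed_ES, expressed_any, the three category flags,
    and de_novo_stage, plus the gene's chromosome.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    v = matrix.values
    expressed = v > threshold
    expressed.columns = [f"expressed_{s}" for s in STAGES]
    any_ = expressed.any(axis=1)
    sb, ps, rs = v["SB"], v["PS"], v["RS"]

    pr = expressed["expressed_SB"] & (ps <= sb / 2) & any_
    nr = pr & (rs < sb / 2)
    en = expressed["expressed_RS"] & (rs >= 2 * ps) & any_

    de_novo = pd.Series("none", index=v.index, dtype=object)
    not_sb = ~expressed["expressed_SB"] & any_
    de_novo[not_sb & expressed["expressed_PS"]] = "PS"
    de_novo[not_sb & ~expressed["expressed_PS"] & expressed["expressed_RS"]] = "RS"
    de_novo[
        not_sb & ~expressed["expressed_PS"] & ~expressed["expressed_RS"] & expressed["expressed_ES"]
    ] = "ES"

    out = expressed.copy()
    out["expressed_any"] = any_
    out["pachytene_repressed"] = pr
    out["rs_non_reactivated"] = nr
    out["rs_enriched"] = en
    out["de_novo_stage"] = de_novo
    out["chrom"] = matrix.gene_info["chrom"]
    return out


def collapse_families(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Treat highly similar gene-family members as a single gene ID.

    Rows sharing a ``family_id`` are summed stage-wise into one row whose
    gene_id is the family_id; genes without a family pass through
    unchanged.  A family whose members span chromosomes is rejected.
    Column (stage) sums of the matrix are conserved.
    """
    info = matrix.gene_info
    if "family_id" not in info.columns:
        return matrix
    fam = info["family_id"]
    has_fam = fam.notna() & (fam != "")
    singles_v = matrix.values[~has_fam]
    singles_i = info[~has_fam]
    if not has_fam.any():
        return matrix

    fam_info = info[has_fam]
    spans = fam_info.groupby("family_id")["chrom"].nunique()
    bad = spans[spans > 1]
    if len(bad):
        raise ValidationError(
            f"family spanning multiple chromosomes: {bad.index.tolist()}"
        )
    summed = matrix.values[has_fam].groupby(fam_info["family_id"]).sum()
    summed.index.name = "gene_id"
    fam_chrom = fam_info.groupby("family_id")["chrom"].first()
    new_info = pd.DataFrame({"chrom": fam_chrom})
    new_info["family_id"] = new_info.index
    for col in singles_i.columns:
        if col not in new_info.columns:
            new_info[col] = pd.NA
    new_info = new_info[singles_i.columns]

    values = pd.concat([singles_v, summed])
    ginfo = pd.concat([singles_i, new_info])
    return ExpressionMatrix(values, ginfo)


def rpkm_histogram(values, bin_width: float = 2.0) -> pd.DataFrame:
    """Left-closed right-open RPKM histogram (bins 0-2, 2-4, 4-6, ...)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    n_bins = int(np.floor(arr.max() / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def summarize_chromosomes(
    dynamics: pd.DataFrame,
    matrix: ExpressionMatrix,
    genome: GenomeTable,
    bin_width: float = 2.0,
) -> pd.DataFrame:
    """Per-chromosome expression-category summary (figure-table layout).

    Stage and category percentages use the chromosome's expressed-gene
    count as denominator; the expressed-any percentage uses the annotated
    count.  RPKM means are over genes expressed at the relevant stage.
    A chromosome with zero expressed genes gets zero percentages and a
    ``no_expressed_genes`` flag rather than an error.
    """
    rows = []
    for chrom in genome.chroms:
        d = dynamics[dynamics["chrom"] == chrom]
        v = matrix.values.loc[d.index]
        n_ann = len(d)
        n_any = int(d["expressed_any"].sum())
        row: dict = {
            "chrom": chrom,
            "n_genes_annotated": n_ann,
            "n_expressed_any": n_any,
            "pct_expressed_any": 100.0 * n_any / n_ann if n_ann else 0.0,
            "no_expressed_genes": n_any == 0,
        }
        denom = n_any if n_any else np.nan
        for s in STAGES:
            n_s = int(d[f"expressed_{s}"].sum())
            row[f"n_expressed_{s}"] = n_s
            row[f"pct_expressed_{s}"] = 100.0 * n_s / denom if n_any else 0.0
            expr_vals = v.loc[d[f"expressed_{s}"], s]
            row[f"rpkm_mean_{s}"] = float(expr_vals.mean()) if len(expr_vals) else 0.0
        for cat in CATEGORY_COLUMNS:
            n_c = int(d[cat].sum())
            row[f"n_{cat}"] = n_c
            row[f"pct_{cat}"] = 100.0 * n_c / denom if n_any else 0.0
        for stage in ("PS", "RS", "ES"):
            n_c = int((d["de_novo_stage"] == stage).sum())
            row[f"n_de_novo_{stage}"] = n_c
            row[f"pct_de_novo_{stage}"] = 100.0 * n_c / denom if n_any else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def subset_rpkm(
    dynamics: pd.DataFrame,
    matrix: ExpressionMatrix,
    chrom: str,
    subset: str = "expressed",
    stage: str = "RS",
) -> np.ndarray:
    """RPKM values at ``stage`` for a gene subset on one chromosome.

    subset: ``expressed`` (expressed at that stage), ``rs_enriched``,
    or ``rs_specific`` (de novo at RS).
    """
    d = dynamics[dynamics["chrom"] == chrom]
    if subset == "expressed":
        mask = d[f"expressed_{stage}"]
    elif subset == "rs_enriched":
        mask = d["rs_enriched"]
    elif subset == "rs_specific":
        mask = d["de_novo_stage"] == "RS"
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return matrix.values.loc[d.index[mask], stage].to_numpy()
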