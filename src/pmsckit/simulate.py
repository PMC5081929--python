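"""Synthetic genome / annotation / expression / peak generator with truth labels.

Every downstream stage is exercised against data whose ground truth is
known by construction:

* a genome table of autosome-, X- and Y-like chromosomes;
* a gene annotation with non-overlapping gene intervals and optional
  multicopy families (correlated low-RPKM members sharing a family_id,
  emulating ampliconic Sly/Ssty/alpha-takusan-like clusters);
* a gene x stage RPKM matrix in which each expressed gene is assigned to
  one expression-dynamics archetype (constitutive, pachytene-repressed
  reactivated, pachytene-repressed non-reactivated, round-spermatid
  enriched, de novo PS, de novo RS) so that per-chromosome category
  fractions match the planted fractions exactly, with a multiplicative
  safety margin keeping every gene clear of the twofold-rule boundaries;
* exon and intergenic RPKM samples whose log10 densities are
  equal-variance Gaussians centred symmetrically around
  log10(threshold_truth), so the analytic density crossing is the
  planted threshold;
* per-mark peak sets laid as non-overlapping intervals whose union hits
  the planted per-chromosome covered fraction exactly (to the base pair,
  after rounding the target to an integer bp count).

A single integer seed drives a hierarchy of numpy SeedSequence children,
one per component, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
import yaml

from .io import ExpressionMatrix, GenomeTable, PeakSet, STAGES

SAFETY = 1.2  # multiplicative margin away from every rule boundary


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome and its planted expression profile.

    Category fractions are over *expressed* genes except
    ``fraction_expressed_any`` (over annotated genes).  Consistency
    requirements: rs_non_reactivated <= pachytene_repressed <=
    sb_expressed; de_novo_rs <= rs_enriched; rs_enriched - de_novo_rs <=
    sb_expressed - pachytene_repressed (extra enriched genes are drawn
    from the non-repressed SB-expressed pool); sb_expressed + de_novo_rs
    <= 1 (the remainder becomes de-novo-PS genes).
    """

    name: str
    length_bp: int
    chrom_class: str  # autosome | X | Y
    n_genes: int
    fraction_expressed_any: float
    sb_expressed: float
    pachytene_repressed: float
    rs_non_reactivated: float
    rs_enriched: float
    de_novo_rs: float
    n_families: int = 0
    members_per_family: int = 0
    member_rpkm_scale: float = 1.0

    def validate(self) -> None:
        fr = {
            "fraction_expressed_any": self.fraction_expressed_any,
            "sb_expressed": self.sb_expressed,
            "pachytene_repressed": self.pachytene_repressed,
            "rs_non_reactivated": self.rs_non_reactivated,
            "rs_enriched": self.rs_enriched,
            "de_novo_rs": self.de_novo_rs,
        }
        for k, v in fr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {k}={v} outside [0, 1]")
        if self.rs_non_reactivated > self.pachytene_repressed:
            raise ValueError(f"{self.name}: rs_non_reactivated > pachytene_repressed")
        if self.pachytene_repressed > self.sb_expressed:
            raise ValueError(f"{self.name}: pachytene_repressed > sb_expressed")
        if self.de_novo_rs > self.rs_enriched:
            raise ValueError(f"{self.name}: de_novo_rs > rs_enriched")
        if self.rs_enriched - self.de_novo_rs > self.sb_expressed - self.pachytene_repressed:
            raise ValueError(
                f"{self.name}: rs_enriched exceeds the available non-repressed SB pool"
            )
        if self.sb_expressed + self.de_novo_rs > 1.0 + 1e-12:
            raise ValueError(f"{self.name}: sb_expressed + de_novo_rs > 1")
        n_fam_genes = self.n_families * self.members_per_family
        n_expr = round(self.n_genes * self.fraction_expressed_any)
        if n_fam_genes > round(self.de_novo_rs * n_expr):
            raise ValueError(
                f"{self.name}: family members ({n_fam_genes}) exceed de-novo-RS genes"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-conditions description for one synthetic dataset."""

    seed: int
    chromosomes: list[ChromosomeSpec]
    # mark -> chrom -> target covered fraction of the chromosome
    coverage_fractions: dict[str, dict[str, float]]
    threshold_truth: float = 0.22
    mu_expressed: float = 1.3     # log10 RPKM of expressed genes
    sigma_expressed: float = 0.8
    mu_background: float = -1.7   # log10 RPKM of silent stages
    sigma_background: float = 0.6
    n_exon: int = 10_000
    n_intergenic: int = 10_000
    # exon/intergenic log10 densities: equal widths, means symmetric about
    # log10(threshold_truth); separation/width ~ 1.4 keeps the density
    # valley shallow enough for the crossing to be estimable at n ~ 10^4
    exon_offset_log10: float = 0.85
    density_sigma_log10: float = 0.6

    def validate(self) -> None:
        if self.threshold_truth <= 0:
            raise ValueError("threshold_truth must be positive")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in config")
        for spec in self.chromosomes:
            spec.validate()
        for mark, per_chrom in self.coverage_fractions.items():
            for chrom, frac in per_chrom.items():
                if chrom not in names:
                    raise ValueError(f"mark {mark}: unknown chromosome {chrom}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"mark {mark}/{chrom}: fraction {frac} outside [0, 1]")


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth planted by the generator."""

    genes: pd.DataFrame            # gene_id, chrom, archetype + intended flags
    coverage_bp: dict[str, dict[str, int]]  # mark -> chrom -> covered bp
    threshold: float


@dataclass(frozen=True)
class SimulatedDataset:
    genome: GenomeTable
    annotation: pd.DataFrame
    matrix: ExpressionMatrix
    peaks: dict[str, PeakSet]
    exon_rpkm: np.ndarray
    intergenic_rpkm: np.ndarray
    truth: TruthLabels
    config: SimulationConfig


def _background(rng: np.random.Generator, mu: float, sigma: float,
                upper: float, n: int) -> np.ndarray:
    """Log-normal draws truncated below ``upper`` (inverse-CDF truncation)."""
    cap = norm.cdf((np.log10(upper) - mu) / sigma)
    u = np.clip(rng.random(n) * cap, 1e-12, None)
    return 10.0 ** (mu + sigma * norm.ppf(u))


def _expressed(rng: np.random.Generator, mu: float, sigma: float,
               floor: float, n: int) -> np.ndarray:
    """Log-normal draws clipped above ``floor`` (well clear of the threshold)."""
    return np.maximum(10.0 ** rng.normal(mu, sigma, n), floor)


def _archetype_counts(spec: ChromosomeSpec) -> dict[str, int]:
    n_expr = round(spec.n_genes * spec.fraction_expressed_any)
    n_dn = round(spec.de_novo_rs * n_expr)
    n_pr = round(spec.pachytene_repressed * n_expr)
    n_nr = round(spec.rs_non_reactivated * n_expr)
    n_sb = round(spec.sb_expressed * n_expr)
    n_extra_en = round((spec.rs_enriched - spec.de_novo_rs) * n_expr)
    n_dn_ps = n_expr - n_sb - n_dn
    n_const = n_sb - n_pr - n_extra_en
    counts = {
        "constitutive": n_const,
        "repressed_reactivated": n_pr - n_nr,
        "non_reactivated": n_nr,
        "extra_enriched": n_extra_en,
        "de_novo_ps": n_dn_ps,
        "de_novo_rs": n_dn,
        "silent": spec.n_genes - n_expr,
    }
    bad = {k: v for k, v in counts.items() if v < 0}
    if bad:
        raise ValueError(f"{spec.name}: infeasible archetype counts {bad}")
    return counts


def _simulate_chromosome_expression(
    spec: ChromosomeSpec, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM values and truth labels for one chromosome's genes."""
    T = cfg.threshold_truth
    s = SAFETY
    floor = 3.0 * T
    counts = _archetype_counts(spec)

    def bg(n: int) -> np.ndarray:
        return _background(rng, cfg.mu_background, cfg.sigma_background, T / s, n)

    def ex(n: int) -> np.ndarray:
        return _expressed(rng, cfg.mu_expressed, cfg.sigma_expressed, floor, n)

    blocks: list[pd.DataFrame] = []
    labels: list[pd.DataFrame] = []

    def emit(archetype: str, sb, ps, rs, es, *, expressed_any, sb_expr,
             pr, nr, en, de_novo) -> None:
        n = len(sb)
        if n == 0:
            return
        blocks.append(pd.DataFrame({"SB": sb, "PS": ps, "RS": rs, "ES": es}))
        labels.append(pd.DataFrame({
            "archetype": archetype,
            "expressed_any": expressed_any,
            "sb_expressed": sb_expr,
            "pachytene_repressed": pr,
            "rs_non_reactivated": nr,
            "rs_enriched": en,
            "de_novo_stage": de_novo,
        }, index=range(n)))

    n = counts["constitutive"]
    sb = ex(n)
    ps = sb * rng.uniform(0.6, 1.0, n)          # > SB/2: not repressed
    rs = ps * rng.uniform(0.5, 1.8, n)          # < 2*PS: not enriched
    es = rs * rng.uniform(0.5, 1.5, n)
    emit("constitutive", sb, ps, rs, es, expressed_any=True, sb_expr=True,
         pr=False, nr=False, en=False, de_novo="none")

    n = counts["repressed_reactivated"]
    sb = ex(n)
    ps = sb / (2.0 * s)                          # <= SB/2 with margin: repressed
    rs = sb * rng.uniform(0.6, 0.8, n)           # >= SB/2: reactivated; < 2*PS
    es = rs * rng.uniform(0.5, 1.5, n)
    emit("repressed_reactivated", sb, ps, rs, es, expressed_any=True, sb_expr=True,
         pr=True, nr=False, en=False, de_novo="none")

    n = counts["non_reactivated"]
    sb = ex(n)
    w = rng.uniform(1.0, 3.0, n)
    ps = sb / (2.0 * s * w)                      # repressed
    rs = ps * rng.uniform(0.5, 1.0, n)           # < SB/2: not recovered; < 2*PS
    es = rs * rng.uniform(0.5, 1.5, n)
    emit("non_reactivated", sb, ps, rs, es, expressed_any=True, sb_expr=True,
         pr=True, nr=True, en=False, de_novo="none")

    n = counts["extra_enriched"]
    sb = ex(n)
    ps = sb * rng.uniform(0.6, 0.9, n)           # not repressed
    rs = 2.0 * s * ps * rng.uniform(1.0, 2.0, n)  # >= 2*PS with margin
    es = rs * rng.uniform(0.5, 1.5, n)
    emit("extra_enriched", sb, ps, rs, es, expressed_any=True, sb_expr=True,
         pr=False, nr=False, en=True, de_novo="none")

    n = counts["de_novo_ps"]
    sb = bg(n)
    ps = ex(n)
    rs = ps * rng.uniform(0.5, 1.6, n)           # < 2*PS: not enriched
    es = rs * rng.uniform(0.5, 1.5, n)
    emit("de_novo_ps", sb, ps, rs, es, expressed_any=True, sb_expr=False,
         pr=False, nr=False, en=False, de_novo="PS")

    # de novo RS: family members first (correlated low RPKM), then singletons
    n_dn = counts["de_novo_rs"]
    n_fam = spec.n_families * spec.members_per_family
    fam_rs = np.empty(0)
    if n_fam:
        factor = 10.0 ** rng.normal(0.5, 0.3, spec.n_families)
        noise = 10.0 ** rng.normal(0.0, 0.2, n_fam)
        fam_rs = spec.member_rpkm_scale * T * s * np.repeat(factor, spec.members_per_family) * noise
    single_rs = ex(n_dn - n_fam)
    rs_all = np.concatenate([fam_rs, single_rs])
    sb = bg(n_dn)
    ps = bg(n_dn)
    rs = np.maximum(rs_all, np.maximum(T * s, 2.0 * s * ps))  # expressed & enriched
    es = rs * rng.uniform(0.5, 1.5, n_dn)
    emit("de_novo_rs", sb, ps, rs, es, expressed_any=True, sb_expr=False,
         pr=False, nr=False, en=True, de_novo="RS")

    n = counts["silent"]
    emit("silent", bg(n), bg(n), bg(n), bg(n), expressed_any=False, sb_expr=False,
         pr=False, nr=False, en=False, de_novo="none")

    values = pd.concat(blocks, ignore_index=True)
    truth = pd.concat(labels, ignore_index=True)
    # family ids attach to the first n_fam de-novo-RS genes, in block order
    family_id = np.full(len(values), None, dtype=object)
    if n_fam:
        offset = sum(counts[k] for k in (
            "constitutive", "repressed_reactivated", "non_reactivated",
            "extra_enriched", "de_novo_ps"))
        fam_names = [f"{spec.name}_fam{j}" for j in range(spec.n_families)]
        family_id[offset : offset + n_fam] = np.repeat(fam_names, spec.members_per_family)
    values["family_id"] = family_id
    truth["family_id"] = family_id

    order = rng.permutation(len(values))
    return values.iloc[order].reset_index(drop=True), truth.iloc[order].reset_index(drop=True)


def _place_intervals(rng: np.random.Generator, chrom_len: int,
                     lengths: np.ndarray) -> np.ndarray:
    """Non-overlapping starts for given interval lengths on one chromosome."""
    total = int(lengths.sum())
    slack = chrom_len - total
    if slack < 0:
        raise ValueError("intervals do not fit on the chromosome")
    k = len(lengths)
    gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts.astype(np.int64)


def _simulate_peaks(
    mark: str, fractions: dict[str, float], genome: GenomeTable,
    rng: np.random.Generator, mean_peak_len: int = 600
) -> tuple[PeakSet, dict[str, int]]:
    """Peak set whose per-chromosome union length is exactly the target bp."""
    rows = []
    truth: dict[str, int] = {}
    for chrom, length in genome.lengths.items():
        frac = fractions.get(chrom, 0.0)
        target = int(round(frac * length))
        truth[chrom] = target
        if target == 0:
            continue
        lens: list[int] = []
        acc = 0
        while acc < target:
            ln = int(rng.geometric(1.0 / mean_peak_len)) + 50
            ln = min(ln, target - acc)
            lens.append(ln)
            acc += ln
        lens_arr = np.array(lens, dtype=np.int64)
        starts = _place_intervals(rng, length, lens_arr)
        for st, ln in zip(starts, lens_arr):
            rows.append((chrom, int(st), int(st + ln)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(mark, df), truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset plus truth labels.

    Deterministic: identical config (including seed) gives byte-identical
    outputs.  Sub-seeds are spawned per component so regeneration of one
    component never perturbs another.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_expr, ss_ann, ss_peaks, ss_density = root.spawn(4)

    genome = GenomeTable(pd.DataFrame({
        "chrom": [c.name for c in config.chromosomes],
        "length": [c.length_bp for c in config.chromosomes],
        "class": [c.chrom_class for c in config.chromosomes],
    }))

    # expression + truth, one child stream per chromosome
    expr_children = ss_expr.spawn(len(config.chromosomes))
    ann_children = ss_ann.spawn(len(config.chromosomes))
    all_values, all_truth, ann_rows = [], [], []
    for spec, ss_e, ss_a in zip(config.chromosomes, expr_children, ann_children):
        rng_e = np.random.default_rng(ss_e)
        values, truth = _simulate_chromosome_expression(spec, config, rng_e)
        gene_ids = [f"{spec.name}_g{i:05d}" for i in range(len(values))]
        values.index = pd.Index(gene_ids, name="gene_id")
        truth.index = values.index
        truth.insert(0, "chrom", spec.name)

        rng_a = np.random.default_rng(ss_a)
        gene_lens = rng_a.integers(500, 3000, len(values))
        starts = _place_intervals(rng_a, spec.length_bp, gene_lens)
        strands = rng_a.choice(["+", "-"], len(values))
        ann_rows.append(pd.DataFrame({
            "gene_id": gene_ids,
            "chrom": spec.name,
            "start": starts,
            "end": starts + gene_lens,
            "strand": strands,
            "family_id": values["family_id"].to_numpy(),
        }))
        all_values.append(values.drop(columns="family_id"))
        all_truth.append(truth)

    values = pd.concat(all_values)
    truth_genes = pd.concat(all_truth).reset_index().rename(columns={"index": "gene_id"})
    annotation = pd.concat(ann_rows, ignore_index=True)
    gene_info = annotation.set_index("gene_id")[["chrom", "family_id"]].loc[values.index]
    matrix = ExpressionMatrix(values[list(STAGES)], gene_info)

    marks = sorted(config.coverage_fractions)
    peak_children = ss_peaks.spawn(max(len(marks), 1))
    peaks: dict[str, PeakSet] = {}
    coverage_truth: dict[str, dict[str, int]] = {}
    for mark, ss_m in zip(marks, peak_children):
        rng_m = np.random.default_rng(ss_m)
        pk, tr = _simulate_peaks(mark, config.coverage_fractions[mark], genome, rng_m)
        peaks[mark] = pk
        coverage_truth[mark] = tr

    rng_d = np.random.default_rng(ss_density)
    mid = np.log10(config.threshold_truth)
    d, sig = config.exon_offset_log10, config.density_sigma_log10
    exon = 10.0 ** rng_d.normal(mid + d, sig, config.n_exon)
    intergenic = 10.0 ** rng_d.normal(mid - d, sig, config.n_intergenic)

    truth = TruthLabels(truth_genes, coverage_truth, config.threshold_truth)
    return SimulatedDataset(genome, annotation, matrix, peaks, exon, intergenic, truth, config)


def paper_regime_config(seed: int = 0) -> SimulationConfig:
    """Preset emulating the qualitative chromosome profiles of mouse
    round-spermatid data.

    X-like: ~50% of genes expressed, high round-spermatid-specific
    fraction (18%) and RS-enriched fraction (30%).  Y-like: few genes
    expressed (~23%), very few before meiosis (8.4%), the vast majority
    of expressed genes de novo in round spermatids (83.5%) at low RPKM,
    carried by multicopy families.  A chr14-like autosome carries
    ampliconic spermatid-specific families; chr16/chr18-like autosomes
    are the Y's size-matched references, chr3/chr6-like the X's.
    Coverage fractions rank the repressive H3K9me3-like mark
    Y > chr14 > X > autosomes, deplete the Y and X for the
    H3K27me3-like mark, and keep the active H3K4me3-like mark flat.
    """
    def auto(name, length, n_genes, expr, sb, pr, nr, en, dn, **fam):
        return ChromosomeSpec(name, length, "autosome", n_genes, expr, sb, pr, nr, en, dn, **fam)

    chromosomes = [
        ChromosomeSpec("chrX", 20_000_000, "X", 4000,
                       0.5025, 0.78, 0.40, 0.32, 0.3046, 0.18,
                       n_families=6, members_per_family=5, member_rpkm_scale=3.0),
        ChromosomeSpec("chrY", 10_000_000, "Y", 1600,
                       0.23, 0.0838, 0.0754, 0.06, 0.84, 0.8352,
                       n_families=12, members_per_family=10, member_rpkm_scale=1.5),
        auto("chr3", 20_000_000, 4000, 0.50, 0.72, 0.40, 0.32, 0.2522, 0.1261),
        auto("chr6", 20_000_000, 4000, 0.50, 0.72, 0.40, 0.32, 0.2635, 0.1102),
        auto("chr14", 20_000_000, 2000, 0.50, 0.70, 0.38, 0.30, 0.3644, 0.1942,
             n_families=8, members_per_family=6, member_rpkm_scale=2.0),
        auto("chr16", 12_000_000, 1500, 0.6269, 0.7228, 0.40, 0.30, 0.25, 0.126),
        auto("chr18", 12_000_000, 1500, 0.6577, 0.7432, 0.40, 0.30, 0.26, 0.110),
    ]
    coverage = {
        "H3K9me3": {
            "chrY": 0.017, "chr14": 0.0078, "chrX": 0.0058,
            "chr3": 0.0010, "chr6": 0.0012, "chr16": 0.0009, "chr18": 0.0004,
        },
        "H3K27me3": {
            "chrY": 0.0005, "chrX": 0.0040,
            "chr3": 0.0100, "chr6": 0.0102, "chr14": 0.0098,
            "chr16": 0.0101, "chr18": 0.0099,
        },
        "H3K4me3": {
            "chrY": 0.0200, "chrX": 0.0185,
            "chr3": 0.0205, "chr6": 0.0195, "chr14": 0.0210,
            "chr16": 0.0190, "chr18": 0.0200,
        },
        "H3K27ac": {
            "chrY": 0.0790, "chrX": 0.0025,
            "chr3": 0.0020, "chr6": 0.0030, "chr14": 0.0026,
            "chr16": 0.0030, "chr18": 0.0020,
        },
    }
    return SimulationConfig(seed=seed, chromosomes=chromosomes, coverage_fractions=coverage)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all generated inputs in the formats the readers consume."""
    from .io import write_genome_table, write_peaks_bed3, write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.tsv"
    write_genome_table(dataset.genome, paths["genome"])
    paths["annotation"] = out / "annotation.tsv"
    dataset.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["expression"] = out / "expression.tsv"
    write_expression_matrix(dataset.matrix, paths["expression"])
    for mark, pk in sorted(dataset.peaks.items()):
        p = out / f"peaks_{mark}.bed"
        write_peaks_bed3(pk, p)
        paths[f"peaks_{mark}"] = p
    paths["exon_rpkm"] = out / "exon_rpkm.txt"
    np.savetxt(paths["exon_rpkm"], dataset.exon_rpkm, fmt="%.8g")
    paths["intergenic_rpkm"] = out / "intergenic_rpkm.txt"
    np.savetxt(paths["intergenic_rpkm"], dataset.intergenic_rpkm, fmt="%.8g")
    paths["truth_genes"] = out / "truth_genes.tsv"
    dataset.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    cov_rows = [
        {"mark": m, "chrom": c, "covered_bp": bp}
        for m in sorted(dataset.truth.coverage_bp)
        for c, bp in sorted(dataset.truth.coverage_bp[m].items())
    ]
    paths["truth_coverage"] = out / "truth_coverage.tsv"
    pd.DataFrame(cov_rows).to_csv(paths["truth_coverage"], sep="\t", index=False)
    cfg = asdict(dataset.config)
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
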