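import itertools

import numpy as np
import pandas as pd
import pytest

from pmsckit import (
    ExpressionMatrix,
    GenomeTable,
    ValidationError,
    classify_gene,
    classify_matrix,
    collapse_families,
    rpkm_histogram,
    summarize_chromosomes,
)


def rule_oracle(sb, ps, rs, es, t):
    """Independent statement of the classification rules (plain arithmetic)."""
    ex = [sb > t, ps > t, rs > t, es > t]
    if True not in ex:
        return dict(expressed_any=False, pr=False, nr=False, en=False, dn="none")
    pr = ex[0] and 2 * ps <= sb
    nr = pr and 2 * rs < sb
    en = ex[2] and rs / 2 >= ps
    dn = "none"
    if not ex[0]:
        dn = ["SB", "PS", "RS", "ES"][ex.index(True)]
    return dict(expressed_any=True, pr=pr, nr=nr, en=en, dn=dn)


class TestClassifyGene:
    def test_twofold_repression_and_no_recovery(self):
        d = classify_gene(10, 4, 4, 4, 0.22)
        assert d.pachytene_repressed and d.rs_non_reactivated

    def test_boundary_of_at_least_twofold_and_at_least_half(self):
        # PS exactly SB/2 counts as repressed; RS exactly SB/2 counts as recovered
        d = classify_gene(10, 5, 5, 5, 0.22)
        assert d.pachytene_repressed
        assert not d.rs_non_reactivated

    def test_de_novo_round_spermatid_gene_is_enriched(self):
        d = classify_gene(0.1, 0.1, 5, 6, 0.22)
        assert d.de_novo_stage == "RS"
        assert d.rs_enriched

    def test_silent_gene_carries_all_false_flags(self):
        d = classify_gene(0.1, 0.1, 0.1, 0.1, 0.22)
        assert not d.expressed_any
        assert d.de_novo_stage == "none"
        assert not (d.pachytene_repressed or d.rs_non_reactivated or d.rs_enriched)

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValidationError):
            classify_gene(-1, 0, 0, 0, 0.22)

    def test_exhaustive_grid_matches_independent_rule_table(self):
        levels = (0, 0.1, 0.3, 1, 2, 5, 10)
        for sb, ps, rs, es in itertools.product(levels, repeat=4):
            d = classify_gene(sb, ps, rs, es, 0.22)
            o = rule_oracle(sb, ps, rs, es, 0.22)
            got = (d.expressed_any, d.pachytene_repressed, d.rs_non_reactivated,
                   d.rs_enriched, d.de_novo_stage)
            want = (o["expressed_any"], o["pr"], o["nr"], o["en"], o["dn"])
            assert got == want, f"mismatch at {(sb, ps, rs, es)}"


def small_matrix(values, chroms, families=None):
    genes = [f"g{i}" for i in range(len(values))]
    v = pd.DataFrame(values, columns=["SB", "PS", "RS", "ES"],
                     index=pd.Index(genes, name="gene_id"))
    info = pd.DataFrame({"chrom": chroms}, index=v.index)
    if families is not None:
        info["family_id"] = families
    return ExpressionMatrix(v, info)


class TestClassifyMatrix:
    def test_agrees_with_scalar_classifier_on_random_genes(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 2, (300, 4))
        m = small_matrix(vals, ["c1"] * 300)
        dyn = classify_matrix(m, 0.22)
        for gid, row in zip(m.genes, vals):
            d = classify_gene(*row, 0.22)
            assert dyn.loc[gid, "pachytene_repressed"] == d.pachytene_repressed
            assert dyn.loc[gid, "rs_non_reactivated"] == d.rs_non_reactivated
            assert dyn.loc[gid, "rs_enriched"] == d.rs_enriched
            assert dyn.loc[gid, "de_novo_stage"] == d.de_novo_stage

    def test_category_subset_invariants(self, preset_dataset):
        dyn = classify_matrix(preset_dataset.matrix, 0.22)
        assert not (dyn["rs_non_reactivated"] & ~dyn["pachytene_repressed"]).any()
        assert not ((dyn["de_novo_stage"] == "RS") & dyn["expressed_SB"]).any()
        assert (dyn["expressed_any"] == dyn[[f"expressed_{s}" for s in "SB PS RS ES".split()]]
                .any(axis=1)).all()

    def test_raising_threshold_never_adds_expressed_genes(self, preset_dataset):
        lo = classify_matrix(preset_dataset.matrix, 0.22)
        hi = classify_matrix(preset_dataset.matrix, 1.0)
        by_chrom_lo = lo.groupby("chrom")["expressed_any"].sum()
        by_chrom_hi = hi.groupby("chrom")["expressed_any"].sum()
        assert (by_chrom_hi <= by_chrom_lo).all()


class TestCollapseFamilies:
    def test_family_rpkm_sums(self):
        m = small_matrix(
            [[1, 0, 1, 0], [2, 0, 2, 0], [3, 0, 3, 0]],
            ["c1"] * 3,
            families=["famA"] * 3,
        )
        c = collapse_families(m)
        assert c.genes == ["famA"]
        assert c.values.loc["famA", "RS"] == 6

    def test_singletons_unchanged(self):
        m = small_matrix([[1, 2, 3, 4]], ["c1"], families=[None])
        c = collapse_families(m)
        assert c.values.equals(m.values)

    def test_stage_sums_conserved_on_random_families(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(0, 1, (100, 4))
        fams = [f"f{i % 7}" if i % 3 else None for i in range(100)]
        m = small_matrix(vals, ["c1"] * 100, families=fams)
        c = collapse_families(m)
        assert np.allclose(c.values.sum(), m.values.sum())

    def test_family_spanning_chromosomes_rejected(self):
        m = small_matrix([[1] * 4, [1] * 4], ["c1", "c2"], families=["famA", "famA"])
        with pytest.raises(ValidationError, match="famA"):
            collapse_families(m)


class TestHistogram:
    def test_left_closed_right_open_bins(self):
        h = rpkm_histogram([0.5, 2.5, 3.9, 4.0], bin_width=2)
        assert h["count"].tolist() == [1, 2, 1]
        assert h["bin_low"].tolist() == [0.0, 2.0, 4.0]

    def test_counts_sum_to_input_size(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(5, 500)
        assert rpkm_histogram(vals)["count"].sum() == 500


class TestSummarize:
    def test_expressed_percentage_from_counts(self):
        # 2607 annotated, 1310 expressed -> 50.25% expressed in >=1 stage
        rng = np.random.default_rng(1)
        n_ann, n_expr = 2607, 1310
        vals = np.zeros((n_ann, 4))
        vals[:n_expr, 0] = 5.0  # expressed at SB only
        vals[: n_expr // 10, 2] = 12.0
        m = small_matrix(vals, ["chrX"] * n_ann)
        genome = GenomeTable(pd.DataFrame({"chrom": ["chrX"], "length": [171_000_000],
                                           "class": ["X"]}))
        s = summarize_chromosomes(classify_matrix(m, 0.22), m, genome)
        assert s.loc[0, "pct_expressed_any"] == pytest.approx(50.25, abs=0.005)

    def test_rs_specific_share_of_expressed(self):
        vals = [[5, 5, 5, 5]] * 7 + [[0, 0, 5, 5]] * 3
        m = small_matrix(vals, ["c1"] * 10)
        genome = GenomeTable(pd.DataFrame({"chrom": ["c1"], "length": [1000],
                                           "class": ["autosome"]}))
        s = summarize_chromosomes(classify_matrix(m, 0.22), m, genome)
        assert s.loc[0, "pct_de_novo_RS"] == pytest.approx(30.0)

    def test_zero_expressed_chromosome_flagged_not_error(self):
        m = small_matrix([[0.1] * 4] * 5, ["c1"] * 5)
        genome = GenomeTable(pd.DataFrame({"chrom": ["c1"], "length": [1000],
                                           "class": ["autosome"]}))
        s = summarize_chromosomes(classify_matrix(m, 0.22), m, genome)
        assert bool(s.loc[0, "no_expressed_genes"])
        assert s.loc[0, "pct_expressed_SB"] == 0.0

    def test_planted_category_fractions_recovered(self, preset_dataset):
        """Per-chromosome category percentages within 2 points of the design."""
        ds = preset_dataset
        dyn = classify_matrix(ds.matrix, ds.truth.threshold)
        s = summarize_chromosomes(dyn, ds.matrix, ds.genome).set_index("chrom")
        for spec in ds.config.chromosomes:
            row = s.loc[spec.name]
            assert row["pct_de_novo_RS"] == pytest.approx(100 * spec.de_novo_rs, abs=2)
            assert row["pct_rs_enriched"] == pytest.approx(100 * spec.rs_enriched, abs=2)
            assert row["pct_pachytene_repressed"] == pytest.approx(
                100 * spec.pachytene_repressed, abs=2)
            assert row["pct_expressed_any"] == pytest.approx(
                100 * spec.fraction_expressed_any, abs=2)
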