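import dataclasses

import numpy as np
import pytest

from pmsckit import (
    ChromosomeSpec,
    SimulationConfig,
    classify_matrix,
    coverage_summary,
    estimate_threshold,
    interval_union_length,
    paper_regime_config,
    simulate_dataset,
)
from pmsckit.simulate import write_dataset


def tiny_config(seed=0, **chrom_overrides):
    spec = dict(
        name="c1", length_bp=2_000_000, chrom_class="autosome", n_genes=300,
        fraction_expressed_any=0.5, sb_expressed=0.7, pachytene_repressed=0.3,
        rs_non_reactivated=0.2, rs_enriched=0.3, de_novo_rs=0.2,
    )
    spec.update(chrom_overrides)
    return SimulationConfig(
        seed=seed,
        chromosomes=[ChromosomeSpec(**spec),
                     ChromosomeSpec("c2", 2_000_000, "autosome", 300, 0.5,
                                    0.7, 0.3, 0.2, 0.3, 0.2)],
        coverage_fractions={"mark": {"c1": 0.01, "c2": 0.0}},
        n_exon=2000, n_intergenic=2000,
    )


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_files(self, tmp_path):
        d1 = simulate_dataset(tiny_config(seed=5))
        d2 = simulate_dataset(tiny_config(seed=5))
        p1 = write_dataset(d1, tmp_path / "a")
        p2 = write_dataset(d2, tmp_path / "b")
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        d1 = simulate_dataset(tiny_config(seed=1))
        d2 = simulate_dataset(tiny_config(seed=2))
        assert not d1.matrix.values.equals(d2.matrix.values)


class TestPlantedTruth:
    def test_zero_coverage_fraction_means_no_peaks(self):
        ds = simulate_dataset(tiny_config())
        assert not (ds.peaks["mark"].intervals["chrom"] == "c2").any()

    def test_peak_union_hits_target_exactly(self):
        ds = simulate_dataset(tiny_config())
        covered = interval_union_length(ds.peaks["mark"].intervals)
        assert covered["c1"] == ds.truth.coverage_bp["mark"]["c1"] == 20_000

    def test_classification_recovers_planted_flags_exactly(self):
        ds = simulate_dataset(tiny_config(n_families=5, members_per_family=4,
                                          member_rpkm_scale=2.0))
        dyn = classify_matrix(ds.matrix, ds.truth.threshold)
        truth = ds.truth.genes.set_index("gene_id").loc[dyn.index]
        for col in ("expressed_any", "pachytene_repressed", "rs_non_reactivated",
                    "rs_enriched", "de_novo_stage"):
            assert (dyn[col] == truth[col]).all(), col

    def test_family_members_share_chromosome_and_low_rpkm(self):
        ds = simulate_dataset(tiny_config(n_families=5, members_per_family=4,
                                          member_rpkm_scale=1.5))
        fam = ds.annotation[ds.annotation["family_id"].notna()]
        assert len(fam) == 20
        assert (fam.groupby("family_id")["chrom"].nunique() == 1).all()
        fam_rs = ds.matrix.values.loc[fam["gene_id"], "RS"]
        single_rs = ds.matrix.values.loc[
            ds.truth.genes.set_index("gene_id")["de_novo_stage"].eq("RS")
            & ~ds.matrix.values.index.isin(fam["gene_id"]), "RS"]
        assert fam_rs.median() < single_rs.median()

    def test_density_crossing_sits_at_planted_threshold(self):
        cfg = dataclasses.replace(tiny_config(), n_exon=10_000, n_intergenic=10_000)
        ds = simulate_dataset(cfg)
        est = estimate_threshold(ds.exon_rpkm, ds.intergenic_rpkm)
        assert est.threshold_rpkm == pytest.approx(cfg.threshold_truth, rel=0.05)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, message",
        [
            (dict(rs_non_reactivated=0.5), "rs_non_reactivated"),
            (dict(de_novo_rs=0.35), "de_novo_rs"),
            (dict(sb_expressed=0.9, de_novo_rs=0.3, rs_enriched=0.3), "> 1"),
            (dict(pachytene_repressed=0.8), "pachytene_repressed"),
            (dict(fraction_expressed_any=1.5), "outside"),
            (dict(n_families=40, members_per_family=10), "family members"),
        ],
    )
    def test_infeasible_fractions_rejected_before_sampling(self, overrides, message):
        with pytest.raises(ValueError, match=message):
            simulate_dataset(tiny_config(**overrides))

    def test_unknown_coverage_chromosome_rejected(self):
        cfg = tiny_config()
        bad = dataclasses.replace(cfg, coverage_fractions={"mark": {"nope": 0.1}})
        with pytest.raises(ValueError, match="nope"):
            simulate_dataset(bad)


class TestPaperRegimePreset:
    def test_category_orderings_by_construction(self):
        cfg = paper_regime_config()
        by_name = {c.name: c for c in cfg.chromosomes}
        assert by_name["chrY"].de_novo_rs > by_name["chrX"].de_novo_rs \
            > by_name["chr3"].de_novo_rs
        assert by_name["chrY"].sb_expressed < by_name["chr16"].sb_expressed

    def test_coverage_orderings_by_construction(self):
        cov = paper_regime_config().coverage_fractions
        k9 = cov["H3K9me3"]
        assert k9["chrY"] > k9["chr14"] > k9["chrX"] > max(
            k9[c] for c in ("chr3", "chr6", "chr16", "chr18"))
        k27 = cov["H3K27me3"]
        assert k27["chrY"] < min(k27[c] for c in ("chr3", "chr6", "chr14"))

    def test_recovered_coverage_rank_matches_planted_rank(self, preset_dataset):
        ds = preset_dataset
        s = coverage_summary(ds.peaks["H3K9me3"], ds.genome)
        recovered = dict(zip(s.rows["chrom"], s.rows["pct_of_chrom"]))
        planted = ds.config.coverage_fractions["H3K9me3"]
        rank = lambda d: sorted(d, key=d.get)  # noqa: E731
        assert rank(recovered) == rank(planted)

    def test_y_like_coverage_percentage(self, preset_dataset):
        """Y-like chromosome planted at 1.7% coverage is recovered exactly."""
        s = coverage_summary(preset_dataset.peaks["H3K9me3"], preset_dataset.genome)
        y_pct = float(s.rows.set_index("chrom").loc["chrY", "pct_of_chrom"])
        assert y_pct == pytest.approx(1.7, abs=1e-6)
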