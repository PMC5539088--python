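"""Planted-structure generators: cohort, LD blocks, GWAS, expression."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tescreen import genotype_io, linkage, synthetic_data
from tescreen.synthetic_data import (
    CohortSpec, GwasHit, LdBlockSpec, PlantedEqtl, ScenarioSpec, SyntheticTruth,
    generate_cohort, generate_expression, generate_gwas_table,
    generate_ld_block, generate_scenario, ld_bounds,
)


class TestCohort:
    def test_study_scale_group_sizes(self):
        cohort = generate_cohort(synthetic_data.DEFAULT_COHORT)
        assert len(cohort) == 445
        counts = cohort["group"].value_counts()
        assert counts["AFR"] == 87 and counts["EUR"] == 358
        assert cohort["sample_id"].is_unique

    def test_single_sample_and_determinism(self):
        spec = CohortSpec({"YRI": 1}, {"YRI": "AFR"}, seed=3)
        one = generate_cohort(spec)
        assert len(one) == 1
        pd.testing.assert_frame_equal(one, generate_cohort(spec))

    def test_non_positive_count_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            CohortSpec({"YRI": 0}, {"YRI": "AFR"})


def _block(p=0.3, q=0.3, r=0.6, **kw):
    args = dict(
        te_id="te", te_family="Alu", chrom="1", te_position=500_000,
        te_allele_freq=p, snp_ids=("s1",), snp_positions=(600_000,),
        snp_allele_freqs=(q,), target_r=(r,),
    )
    args.update(kw)
    return LdBlockSpec(**args)


class TestLdBlocks:
    def test_unattainable_r_error_names_the_bound(self):
        # at p = q = 0.3 the most negative attainable r is -pq/sqrt(...)
        lo, hi = ld_bounds(0.3, 0.3)
        assert lo == pytest.approx(-3 / 7) and hi == pytest.approx(1.0)
        with pytest.raises(ValueError, match="attainable"):
            _block(r=-0.9)

    def test_perfect_linkage_duplicates_the_te_vector(self):
        te, snp, haps = generate_ld_block(_block(r=1.0), 500, seed=1)
        np.testing.assert_array_equal(te, snp[0])
        np.testing.assert_array_equal(haps[:, 0], haps[:, 1])

    def test_zero_r_gives_near_zero_sample_correlation(self):
        te, snp, _ = generate_ld_block(_block(r=0.0), 10_000, seed=2)
        res = linkage.pairwise_r(te, snp[0])
        assert abs(res.r) < 3 / np.sqrt(10_000)

    def test_dosages_are_haplotype_sums(self):
        te, snp, haps = generate_ld_block(_block(), 200, seed=3)
        np.testing.assert_array_equal(te, haps[0::2, 0] + haps[1::2, 0])
        np.testing.assert_array_equal(snp[0], haps[0::2, 1] + haps[1::2, 1])

    def test_realized_frequency_within_binomial_error(self):
        n = 5_000
        te, _, _ = generate_ld_block(_block(p=0.3), n, seed=4)
        f = te.sum() / (2 * n)
        assert abs(f - 0.3) < 4 * np.sqrt(0.3 * 0.7 / (2 * n))

    def test_snp_outside_block_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            _block(snp_positions=(2_000_000,))


class TestGwasTable:
    META = pd.DataFrame({"id": ["rs1", "rs2"], "chrom": "1",
                         "pos": [100, 200]})

    def test_hits_and_decoys_straddle_the_threshold(self):
        table = generate_gwas_table(
            [GwasHit("rs1", "IgG glycosylation", "B4GALT1", "A", "-", 2e-6)],
            ["rs2"], self.META, seed=0)
        hits = table[table["p_value"] < 1e-5]
        assert hits["snp_id"].tolist() == ["rs1"]
        assert hits.iloc[0]["trait"] == "IgG glycosylation"
        assert hits.iloc[0]["mapped_gene"] == "B4GALT1"
        assert (table[table["snp_id"] == "rs2"]["p_value"] >= 1e-5).all()

    def test_empty_hit_list(self):
        table = generate_gwas_table([], [], self.META, seed=0)
        assert table.empty

    def test_unknown_snp_id_rejected(self):
        with pytest.raises(KeyError, match="rsX"):
            generate_gwas_table([GwasHit("rsX", "t", "g")], [], self.META, 0)


class TestExpression:
    def _cohort(self):
        return generate_cohort(CohortSpec(
            {"CEU": 40, "FIN": 40}, {"CEU": "EUR", "FIN": "EUR"}, seed=0))

    def _tes(self, cohort, p=0.3):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, p, len(cohort)).astype(float)
        variants = pd.DataFrame(
            {"id": ["te0"], "chrom": "1", "pos": [5_000_000], "kind": "TE",
             "te_family": "Alu", "ref": "N", "alt": "<INS:ME:ALU>"})
        return genotype_io.GenotypeMatrix(
            variants, cohort["sample_id"].tolist(), g.reshape(1, -1))

    def test_cis_flag_realized_by_gene_placement(self):
        cohort = self._cohort()
        tes = self._tes(cohort)
        _, models = generate_expression(
            cohort, tes,
            [PlantedEqtl("te0", "CIS_G", 1.0, cis_flag=True),
             PlantedEqtl("te0", "TRANS_G", 1.0, cis_flag=False)],
            n_null_genes=0, seed=0)
        m = models.set_index("gene_id")
        assert m.loc["CIS_G", "chrom"] == "1"
        assert abs(m.loc["CIS_G", "start"] - 5_000_000) <= 1_000_000
        assert m.loc["TRANS_G", "chrom"] != "1"

    def test_contradictory_explicit_coordinates_rejected(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="contradicting"):
            generate_expression(
                cohort, self._tes(cohort),
                [PlantedEqtl("te0", "G", 1.0, cis_flag=True,
                             gene_chrom="9", gene_start=1, gene_end=100)],
                n_null_genes=0, seed=0)

    def test_planted_effect_visible_in_raw_means(self):
        cohort = self._cohort()
        tes = self._tes(cohort)
        expr, _ = generate_expression(
            cohort, tes, [PlantedEqtl("te0", "G", 2.0, sigma=0.5)],
            n_null_genes=0, seed=0)
        g = tes.dosages[0]
        y = expr.loc["G"].to_numpy()
        assert y[g == 2].mean() - y[g == 0].mean() == pytest.approx(4.0, abs=1.0)


class TestScenario:
    def test_small_scenario_deterministic_and_round_trips(self, tmp_path):
        spec = ScenarioSpec(
            cohort=CohortSpec({"YRI": 20, "CEU": 30},
                              {"YRI": "AFR", "CEU": "EUR"}),
            n_null_genes=10, n_epigenomes=8, n_blood_immune=3)
        p1, t1 = generate_scenario(tmp_path / "a", seed=42, spec=spec)
        p2, t2 = generate_scenario(tmp_path / "b", seed=42, spec=spec)
        for key in ("te_vcf", "gwas", "expression", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
        # written VCF re-reads into a matrix consistent with the truth
        tes = genotype_io.read_genotypes(p1["te_vcf"])
        assert sorted(tes.variants["id"]) == sorted(t1.te_classes)
        # truth document round-trips
        back = SyntheticTruth.from_json(p1["truth"])
        assert back.expected_stages == t1.expected_stages
        assert back.ld_blocks == t1.ld_blocks

    def test_scenario_truth_is_internally_consistent(self, scenario):
        _, truth = scenario
        stages = truth.expected_stages
        assert set(stages["final_candidates"]) <= set(stages["eqtl_planted"])
        assert set(stages["blood_immune"]) <= set(stages["disease_linked"])
        assert set(stages["maf_pass"]) <= set(stages["input"])
        planted_tes = {e.te_id for e in truth.planted_eqtls}
        assert planted_tes == set(stages["eqtl_planted"])
        hit_ids = {h.snp_id for h in truth.gwas_hits}
        block_snps = {s for b in truth.ld_blocks for s in b.snp_ids}
        assert hit_ids <= block_snps
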