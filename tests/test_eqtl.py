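"""Additive eQTL model, BH control, cis/trans calls and per-TE selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tescreen import eqtl, synthetic_data
from tescreen.genotype_io import GenotypeMatrix


def _cohort(n, groups=("EUR",), pops=None, seed=0):
    rng = np.random.default_rng(seed)
    pops = pops or {"EUR": ["CEU", "FIN"], "AFR": ["YRI"]}
    rows = []
    i = 0
    for g in groups:
        for _ in range(n // len(groups)):
            pop = pops[g][i % len(pops[g])]
            sex = "female" if rng.random() < 0.5 else "male"
            rows.append((f"S{i:04d}", pop, g, sex))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "population", "group", "sex"])


def _te_matrix(dosages, ids=None, chrom="1", pos=None, samples=None):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    k, n = dosages.shape
    ids = ids or [f"te{i}" for i in range(k)]
    pos = pos or [10_000_000 * (i + 1) for i in range(k)]
    variants = pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": pos, "kind": "TE",
         "te_family": "Alu", "ref": "N", "alt": "<INS:ME:ALU>"}
    )
    samples = samples or [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(variants, samples, dosages)


def test_exact_linear_relationship_recovers_beta_with_floored_p(rng):
    g = rng.integers(0, 3, 40).astype(float)
    sex = np.where(rng.random(40) < 0.5, "female", "male")
    pop = np.where(rng.random(40) < 0.5, "CEU", "FIN")
    res = eqtl.fit_additive(2.0 * g, g, sex, pop)
    assert res.beta == pytest.approx(2.0, abs=1e-10)
    assert res.p <= np.finfo(float).tiny


def test_constant_dosage_is_untestable_not_a_crash(rng):
    y = rng.normal(size=20)
    res = eqtl.fit_additive(y, np.ones(20), ["male"] * 20, ["CEU"] * 20)
    assert not res.testable and "constant dosage" in res.reason


def test_rank_deficient_design_reported_with_reason(rng):
    # sex perfectly aliases population -> collinear covariates
    sex = np.array(["male", "female"] * 10)
    pop = np.where(sex == "male", "CEU", "FIN")
    res = eqtl.fit_additive(rng.normal(size=20), rng.integers(0, 3, 20), sex, pop)
    assert not res.testable and res.reason == "rank-deficient design"


def test_null_p_values_are_uniform():
    """1000 null genes at n = 445: KS against uniform does not reject."""
    cohort = _cohort(444)
    rng = np.random.default_rng(11)
    g = rng.binomial(2, 0.3, 444).astype(float)
    tes = _te_matrix(g, samples=cohort["sample_id"].tolist())
    expr, models = synthetic_data.generate_expression(
        cohort, tes, [], n_null_genes=1000, seed=3,
        sex_effect=0.4, population_effects={"CEU": 0.2, "FIN": -0.1},
    )
    rec = eqtl.run_screen(tes, expr, models, cohort, "EUR")
    ks = stats.kstest(rec["p"], "uniform")
    assert ks.pvalue > 0.01


def test_bh_edge_cases_and_monotonicity(rng):
    assert eqtl.bh_qvalues([0.01]) == pytest.approx([0.01])  # m = 1: q = p
    p = rng.uniform(size=200)
    q = eqtl.bh_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()
    assert (q <= 1).all() and (q >= p).all()


@pytest.mark.parametrize(
    "te_chrom,te_pos,expected",
    [
        ("1", 5_010_000, "cis"),              # inside the gene body
        ("1", 6_020_000 + 1_000_000, "cis"),  # exactly 1 Mb past the end
        ("1", 6_020_000 + 1_000_001, "trans"),
        ("1", 5_000_000 - 1_000_001, "trans"),
        ("2", 5_010_000, "trans"),            # different chromosome
    ],
)
def test_cis_trans_boundaries(te_chrom, te_pos, expected):
    label = eqtl.classify_cis_trans(te_chrom, te_pos, "1", 5_000_000, 6_020_000)
    assert label == expected


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["te_id", "gene_id", "beta", "se", "t_stat", "p", "q",
                 "n_used", "cis_trans", "reason"],
    )


def test_strongest_per_te_selection_and_thresholding():
    rec = _records([
        ("te1", "gA", 1.0, 0.1, 10.0, 1e-8, 1e-6, 100, "cis", None),
        ("te1", "gB", 1.0, 0.2, 5.0, 1e-3, 2e-2, 100, "trans", None),
        ("te2", "gC", 1.0, 0.3, 3.0, 0.2, 0.6, 100, "cis", None),
    ])
    out = eqtl.strongest_per_te(rec, 0.05)
    assert out["te_id"].tolist() == ["te1"]
    assert out["gene_id"].tolist() == ["gA"]


def test_strongest_per_te_tie_break_is_deterministic(rng):
    rows = [("te1", g, 1.0, 0.1, t, 1e-6, 1e-5, 100, "cis", None)
            for g, t in [("gB", 5.0), ("gA", 5.0), ("gC", -7.0)]]
    rec = _records(rows)
    picks = set()
    for _ in range(10):
        shuffled = rec.sample(frac=1, random_state=rng.integers(1 << 30))
        picks.add(eqtl.strongest_per_te(shuffled)["gene_id"].iloc[0])
    assert picks == {"gC"}  # largest |t| wins the p tie


def test_group_separation_other_groups_samples_are_inert():
    cohort = _cohort(120, groups=("EUR", "AFR"))
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.4, 120).astype(float)
    tes = _te_matrix(g, samples=cohort["sample_id"].tolist())
    expr, models = synthetic_data.generate_expression(
        cohort, tes, [synthetic_data.PlantedEqtl("te0", "GENE", 1.0)],
        n_null_genes=20, seed=9)
    base = eqtl.run_screen(tes, expr, models, cohort, "EUR")
    # scramble every AFR sample's genotype and expression
    afr = cohort.loc[cohort["group"] == "AFR", "sample_id"].tolist()
    expr2 = expr.copy()
    expr2[afr] = rng.normal(size=(len(expr), len(afr)))
    dos2 = tes.dosages.copy()
    for s in afr:
        dos2[0, tes.samples.index(s)] = rng.integers(0, 3)
    tes2 = GenotypeMatrix(tes.variants.copy(), list(tes.samples), dos2)
    again = eqtl.run_screen(tes2, expr2, models, cohort, "EUR")
    pd.testing.assert_frame_equal(base, again)


def test_zero_variance_genes_are_skipped():
    cohort = _cohort(60)
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.4, 60).astype(float)
    tes = _te_matrix(g, samples=cohort["sample_id"].tolist())
    expr, models = synthetic_data.generate_expression(
        cohort, tes, [], n_null_genes=5, seed=1)
    expr.loc["NULL_0002"] = 3.14  # constant across samples
    rec = eqtl.run_screen(tes, expr, models, cohort, "EUR")
    assert "NULL_0002" not in set(rec["gene_id"])
    assert len(rec) == 4


def test_empty_candidate_set_gives_empty_output():
    cohort = _cohort(30)
    tes = _te_matrix(np.zeros((0, 30)).tolist() or np.empty((0, 30)),
                     ids=[], pos=[], samples=cohort["sample_id"].tolist())
    expr = pd.DataFrame(
        np.random.default_rng(0).normal(size=(3, 30)),
        index=["g1", "g2", "g3"], columns=cohort["sample_id"],
    )
    models = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "chrom": "1",
                           "start": [1, 2, 3], "end": [10, 20, 30]})
    rec = eqtl.run_screen(tes, expr, models, cohort, "EUR")
    assert rec.empty
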