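"""Interval overlap, coordinate-frame conversion and regulatory potential."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tescreen import enhancer, synthetic_data
from tescreen.enhancer import EnhancerSet


def _set(intervals, chrom="1", **kw):
    return EnhancerSet("E001", intervals={chrom: np.array(intervals)}, **kw)


@pytest.mark.parametrize(
    "pos,inside",
    [(100, False), (101, True), (150, True), (200, True), (201, False)],
)
def test_bed_boundary_convention(pos, inside):
    """BED [100, 200) covers 1-based 101..200: half-open 0-based
    intervals against 1-based points, converted in exactly one place."""
    es = _set([[100, 200]])
    assert enhancer.overlaps(("1", pos), es) is inside


def test_unknown_chromosome_is_false_not_error():
    es = _set([[100, 200]])
    assert not enhancer.overlaps(("7", 150), es)


def test_overlap_invariant_to_duplication_and_abutting_merge():
    base = _set([[100, 200], [300, 400]])
    dup = _set([[300, 400], [100, 200], [100, 200], [150, 250], [250, 300]])
    # dup merges to [100,400): supersets differ, but on shared intervals
    merged = _set([[100, 200], [200, 300], [300, 400]])
    np.testing.assert_array_equal(merged.intervals["1"], [[100, 400]])
    for pos in (150, 250, 350):
        assert enhancer.overlaps(("1", pos), merged)
    assert dup.intervals["1"].tolist() == [[100, 400]]
    assert base.intervals["1"].tolist() == [[100, 200], [300, 400]]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
             min_size=1, max_size=20),
    st.integers(1, 600),
)
def test_overlap_invariant_to_interval_order(raw, pos):
    intervals = [[s, s + w] for s, w in raw]
    a = _set(intervals)
    rng = np.random.default_rng(0)
    b = _set([intervals[i] for i in rng.permutation(len(intervals))])
    assert enhancer.overlaps(("1", pos), a) == enhancer.overlaps(("1", pos), b)


def test_regulatory_potential_hand_computed_toy():
    """10 TEs / 4 overlapping and 200 SNPs / 20 overlapping: r = 4.0."""
    es = _set([[0, 1000]])
    tes = {f"te{i}": ("1", 500 if i < 4 else 5000) for i in range(10)}
    snps = {f"s{i}": ("1", 500 if i < 20 else 5000) for i in range(200)}
    pot = enhancer.regulatory_potential(tes, snps, [es])
    row = pot.iloc[0]
    assert (row["t"], row["s"], row["r"]) == (0.4, 0.1, 4.0)


def test_regulatory_potential_degenerate_cases():
    es_all = _set([[0, 10_000]])
    tes = {"te1": ("1", 500)}
    snps = {"s1": ("1", 600)}
    pot = enhancer.regulatory_potential(tes, snps, [es_all])
    assert pot.iloc[0]["r"] == 1.0  # t == s > 0
    es_none = _set([[0, 100]], chrom="2")
    pot2 = enhancer.regulatory_potential(tes, snps, [es_none])
    assert np.isnan(pot2.iloc[0]["r"])  # s = 0: undefined, flagged
    with pytest.raises(ValueError):
        enhancer.regulatory_potential({}, snps, [es_all])


def test_mean_relative_potential_arithmetic():
    pot = pd.DataFrame(
        {"epigenome_id": list("abcd"), "tissue_label": "",
         "blood_immune": [True, True, False, False],
         "t": 0.1, "s": 0.1, "r": [2.0, 4.0, 1.0, 1.0]}
    )
    assert enhancer.mean_relative_potential(pot) == (3.0, 1.0)
    pot["r"] = 1.0
    assert enhancer.mean_relative_potential(pot) == (1.0, 1.0)


def test_blood_immune_filter_counts_epigenomes_not_intervals():
    flagged1 = EnhancerSet("E001", blood_immune=True,
                           intervals={"1": np.array([[400, 600], [700, 900]])})
    flagged2 = EnhancerSet("E002", blood_immune=True,
                           intervals={"1": np.array([[450, 550]])})
    unflagged = EnhancerSet("E003", blood_immune=False,
                            intervals={"1": np.array([[400, 600], [950, 980]])})
    tes = {"te_in": ("1", 500), "te_out": ("1", 5000),
           "te_nonblood": ("1", 970)}
    out = enhancer.filter_blood_immune(tes, [flagged1, flagged2, unflagged])
    out = out.set_index("te_id")
    # te_nonblood only hits the unflagged epigenome: excluded
    assert set(out.index) == {"te_in"}
    # te_in sits in enhancers of 3 epigenomes (E001+E002+E003), counted per
    # epigenome even though one epigenome could contribute several intervals
    assert out.loc["te_in", "n_enhancer_overlaps"] == 3
    assert out.loc["te_in", "n_blood_immune_overlaps"] == 2


def test_no_flagged_epigenomes_is_a_clear_error():
    es = EnhancerSet("E001", blood_immune=False,
                     intervals={"1": np.array([[0, 10]])})
    with pytest.raises(ValueError, match="blood/immune"):
        enhancer.filter_blood_immune({"te": ("1", 5)}, [es])


def test_generated_enhancers_realize_the_plan():
    points = {"TE-1": ("1", 10_000), "TE-2": ("1", 20_000),
              "S-1": ("1", 30_000)}
    sets, manifest = synthetic_data.generate_enhancers(
        points, n_epigenomes=3, blood_immune_ids=["E001"],
        overlap_plan={"E001": ["TE-1"], "E002": ["TE-1", "S-1"]}, seed=0,
    )
    by_id = {s.epigenome_id: s for s in sets}
    assert enhancer.overlaps(points["TE-1"], by_id["E001"])
    assert not enhancer.overlaps(points["TE-2"], by_id["E001"])
    assert not enhancer.overlaps(points["S-1"], by_id["E001"])
    assert enhancer.overlaps(points["S-1"], by_id["E002"])
    # epigenome with an empty plan: no variant overlaps anywhere (t_i = 0)
    assert not any(enhancer.overlaps(p, by_id["E003"]) for p in points.values())
    assert manifest["blood_immune"].sum() == 1


def test_generated_manifest_scales_to_flagged_subset():
    points = {"TE-1": ("1", 10_000)}
    sets, manifest = synthetic_data.generate_enhancers(
        points, n_epigenomes=127,
        blood_immune_ids=[f"E{i + 1:03d}" for i in range(27)],
        overlap_plan={}, seed=0,
    )
    assert len(sets) == 127
    assert int(manifest["blood_immune"].sum()) == 27


def test_contradictory_plan_raises():
    points = {"A": ("1", 500), "B": ("1", 500)}
    with pytest.raises(ValueError, match="unsatisfiable"):
        synthetic_data.generate_enhancers(
            points, 1, [], {"E001": ["A"]}, seed=0)


def test_bed_round_trip(tmp_path):
    es = _set([[100, 200], [300, 400]], blood_immune=True)
    path = enhancer.write_bed(es, tmp_path / "e.bed")
    back = enhancer.read_bed(path, "E001", blood_immune=True)
    np.testing.assert_array_equal(back.intervals["1"], es.intervals["1"])
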