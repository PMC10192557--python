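import numpy as np
import pandas as pd
import pytest
import scipy.stats

import interevo as ie
from interevo import cluster_compare as cc
from interevo import expression_io as eio


def _norm(values, labels):
    values = np.asarray(values, dtype=float)
    cells = [f"c{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame({"species": "m", "cluster": labels},
                        index=pd.Index(cells, name="cell_id"))
    return ie.NormalizedMatrix(values=values, cell_ids=cells,
                               gene_ids=[f"g{j}" for j in range(values.shape[1])],
                               cell_meta=meta)


# ---------------------------------------------------------------------------
# subsampling


def test_subsample_caps_large_clusters_only():
    labels = ["big"] * 1000 + ["small"] * 150
    keep = cc.subsample_cells(labels, max_per_ident=200, seed=0)
    kept_labels = np.asarray(labels)[keep]
    assert (kept_labels == "big").sum() == 200
    assert (kept_labels == "small").sum() == 150
    assert len(set(keep.tolist())) == len(keep)


def test_subsample_deterministic_under_seed():
    labels = ["a"] * 500 + ["b"] * 500
    k1 = cc.subsample_cells(labels, 100, seed=42)
    k2 = cc.subsample_cells(labels, 100, seed=42)
    k3 = cc.subsample_cells(labels, 100, seed=43)
    np.testing.assert_array_equal(k1, k2)
    assert not np.array_equal(k1, k3)


# ---------------------------------------------------------------------------
# marker detection


def test_clean_marker_is_retained_with_welch_oracle():
    rng = np.random.default_rng(0)
    n = 50
    vals = rng.normal(1.0, 0.2, size=(2 * n, 3)).clip(min=0.01)
    vals[:n, 0] = rng.normal(5.0, 0.3, size=n)   # marker of cluster A
    vals[n:, 0] = 0.0
    norm = _norm(vals, ["A"] * n + ["B"] * n)
    table = cc.find_markers(norm, min_pct=0.2, alpha=0.05, max_per_ident=None)
    row = table[(table.gene == "g0") & (table.cluster == "A")]
    assert len(row) == 1
    # independent Welch oracle from group summaries
    t_ref, p_ref = scipy.stats.ttest_ind(vals[:n, 0], vals[n:, 0], equal_var=False)
    assert row.iloc[0]["t_statistic"] == pytest.approx(t_ref, rel=1e-9)
    assert row.iloc[0]["raw_p"] == pytest.approx(p_ref, rel=1e-6, abs=1e-300)
    assert row.iloc[0]["adjusted_p"] <= min(p_ref * 3, 1.0) + 1e-12


def test_low_detection_gene_not_tested():
    rng = np.random.default_rng(1)
    n = 100
    vals = rng.normal(2.0, 0.5, size=(2 * n, 5)).clip(min=0.01)
    # gene g0 detected in exactly 10% of cells in both groups
    g0 = np.zeros(2 * n)
    g0[::10] = 1.0
    vals[:, 0] = g0
    norm = _norm(vals, ["A"] * n + ["B"] * n)
    table = cc.marker_stats(norm, min_pct=0.2, max_per_ident=None)
    assert "g0" not in set(table["gene"])


def test_degenerate_variance_rules():
    vals = np.zeros((8, 2))
    vals[:, 0] = [1.0] * 4 + [1.0] * 4      # equal constant -> p = 1
    vals[:, 1] = [3.0] * 4 + [0.5] * 4      # unequal constants -> p -> 0 limit
    norm = _norm(vals, ["A"] * 4 + ["B"] * 4)
    stats = cc.marker_stats(norm, min_pct=0.2, max_per_ident=None)
    a = stats[stats.cluster == "A"].set_index("gene")
    assert a.loc["g0", "raw_p"] == 1.0
    assert a.loc["g1", "raw_p"] == np.finfo(float).tiny
    assert np.isfinite(a.loc["g0", "t_statistic"])
    assert not np.isnan(a.loc["g1", "raw_p"])


def test_bonferroni_uses_total_gene_count():
    rng = np.random.default_rng(2)
    vals = rng.normal(2.0, 0.5, size=(40, 10)).clip(min=0.01)
    norm = _norm(vals, ["A"] * 20 + ["B"] * 20)
    stats = cc.marker_stats(norm, min_pct=0.2, max_per_ident=None)
    expected = np.minimum(stats["raw_p"] * 10, 1.0)
    np.testing.assert_allclose(stats["adjusted_p"], expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# marker intersection


def test_intersect_identity_and_disjoint():
    a = pd.DataFrame({"gene": ["Elfn1", "Cbln4"], "cluster": "X"})
    b_same = pd.DataFrame({"gene": ["Elfn1", "Cbln4"], "cluster": "Y"})
    b_disj = pd.DataFrame({"gene": ["Sst", "Vip"], "cluster": "Y"})
    same = cc.intersect_markers(a, b_same)
    assert list(same["gene_a"]) == ["Cbln4", "Elfn1"]  # lexicographic
    with pytest.warns(UserWarning):
        assert cc.intersect_markers(a, b_disj).empty


def test_intersect_case_folding():
    a = pd.DataFrame({"gene": ["Elfn1"], "cluster": "X"})
    b = pd.DataFrame({"gene": ["ELFN1"], "cluster": "Y"})
    out = cc.intersect_markers(a, b)
    assert list(out.itertuples(index=False)) == [("Elfn1", "ELFN1")]


def test_intersect_with_orthology_table():
    a = pd.DataFrame({"gene": ["Elfn1", "Sst"], "cluster": "X"})
    b = pd.DataFrame({"gene": ["LOC1001", "SST"], "cluster": "Y"})
    orth = pd.DataFrame({"a": ["Elfn1"], "b": ["LOC1001"]})
    out = cc.intersect_markers(a, b, orthology=orth)
    assert list(out.itertuples(index=False)) == [("Elfn1", "LOC1001")]


# ---------------------------------------------------------------------------
# profiles, specificity, correlation


def test_cluster_profile_closed_forms():
    # x = 0 -> 0.1 ; x = e-1 -> 1.1
    vals = np.array([[0.0, np.e - 1.0]])
    norm = ie.NormalizedMatrix(values=vals, cell_ids=["c0"], gene_ids=["g0", "g1"],
                               cell_meta=pd.DataFrame({"species": "m", "cluster": "A"},
                                                      index=["c0"]))
    prof = cc.cluster_profile(norm)
    np.testing.assert_allclose(prof.loc["A"], [0.1, 1.1], atol=1e-12)


def test_cluster_profile_single_cell_cluster(toy_counts):
    scaled = eio.cp10k(toy_counts)
    sub = ie.NormalizedMatrix(values=scaled.values[:1], cell_ids=scaled.cell_ids[:1],
                              gene_ids=scaled.gene_ids,
                              cell_meta=scaled.cell_meta.iloc[:1])
    prof = cc.cluster_profile(sub)
    np.testing.assert_allclose(prof.to_numpy()[0],
                               np.log1p(scaled.values[0]) + 0.1, rtol=1e-12)


def test_specificity_direct_arithmetic():
    prof = pd.DataFrame({"g": [0.2, 0.2, 0.8], "h": [1.0, 1.0, 1.0]},
                        index=["c1", "c2", "c3"])
    out = cc.specificity(prof)
    np.testing.assert_allclose(out["g"], [0.5, 0.5, 2.0], rtol=1e-12)
    np.testing.assert_allclose(out["h"], 1.0)


def test_specificity_mean_is_one(toy_counts):
    prof = cc.cluster_profile(eio.cp10k(toy_counts))
    out = cc.specificity(prof)
    np.testing.assert_allclose(out.mean(axis=0), 1.0, atol=1e-12)


def test_correlate_hand_examples():
    a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["x"], columns=list("pqr"))
    b = pd.DataFrame([[2.0, 4.0, 6.0], [3.0, 2.0, 1.0]], index=["y", "z"],
                     columns=list("pqr"))
    r = cc.correlate(a, b, ["p", "q", "r"])
    assert r.loc["x", "y"] == pytest.approx(1.0)
    assert r.loc["x", "z"] == pytest.approx(-1.0)


def test_correlate_invariant_to_gene_order():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(12)]
    a = pd.DataFrame(rng.random((4, 12)), columns=genes)
    b = pd.DataFrame(rng.random((5, 12)), columns=genes)
    r1 = cc.correlate(a, b, genes)
    shuffled = list(rng.permutation(genes))
    r2 = cc.correlate(a[shuffled], b, shuffled)
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)


def test_correlate_zero_variance_gives_nan_with_warning():
    a = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"], columns=list("pqr"))
    b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["y"], columns=list("pqr"))
    with pytest.warns(UserWarning, match="zero-variance"):
        r = cc.correlate(a, b, ["p", "q", "r"])
    assert np.isnan(r.loc["flat", "y"])


def test_best_match_identity_ties_and_bruteforce():
    block = pd.DataFrame(np.eye(3) * 0.9 - 0.1, index=list("abc"), columns=list("xyz"))
    bm = cc.best_match(block)
    assert list(bm["best_match"]) == ["x", "y", "z"]

    tie = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["x", "y"])
    assert cc.best_match(tie).loc["a", "best_match"] == "x"

    rng = np.random.default_rng(4)
    r = pd.DataFrame(rng.uniform(-1, 1, size=(5, 4)),
                     index=[f"r{i}" for i in range(5)],
                     columns=[f"c{j}" for j in range(4)])
    bm = cc.best_match(r)
    for i in range(5):  # exhaustive argmax oracle
        best = max(range(4), key=lambda j: r.iloc[i, j])
        assert bm.iloc[i]["best_match"] == r.columns[best]
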