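import numpy as np
import pytest
import scipy.stats

import interevo as ie
from interevo import cluster_compare as cc
from interevo import expression_io as eio


# ---------------------------------------------------------------------------
# expression simulator


def _small_cfg(**kw):
    base = dict(n_types=3, cells_per_type=60, n_genes=400, n_markers_per_type=15,
                seed=0)
    base.update(kw)
    return ie.ExpressionSimConfig(**base)


def test_same_seed_reproduces_counts_exactly():
    a1, b1, _ = ie.simulate_expression(_small_cfg(seed=5))
    a2, b2, _ = ie.simulate_expression(_small_cfg(seed=5))
    np.testing.assert_array_equal(a1.counts, a2.counts)
    np.testing.assert_array_equal(b1.counts, b2.counts)
    a3, _, _ = ie.simulate_expression(_small_cfg(seed=6))
    assert not np.array_equal(a1.counts, a3.counts)


def test_marker_budget_validated():
    with pytest.raises(ValueError):
        ie.ExpressionSimConfig(n_types=6, n_markers_per_type=100, n_genes=500)


def test_counts_are_overdispersed():
    cfg = _small_cfg(nb_dispersion=0.4, seed=2)
    a, _, _ = ie.simulate_expression(cfg)
    scaled = eio.cp10k(a).values
    mean = scaled.mean(axis=0)
    var = scaled.var(axis=0)
    expressed = mean > 1.0
    # across expressed genes, variance exceeds mean (NB overdispersion)
    assert (var[expressed] > mean[expressed]).mean() > 0.9


def test_species_use_matchable_symbol_casings():
    a, b, truth = ie.simulate_expression(_small_cfg())
    assert a.gene_ids[0].casefold() == b.gene_ids[0].casefold()
    assert a.gene_ids[0] != b.gene_ids[0]
    for genes in truth.markers.values():
        assert set(genes) <= set(a.gene_ids)


def test_null_config_shows_no_structure_above_chance():
    cfg = _small_cfg(n_markers_per_type=0, marker_fold_change=0.0,
                     species_shift_sd=0.0, seed=9)
    a, b, _ = ie.simulate_expression(cfg)
    # without markers the species matrices are exchangeable draws: correlate
    # full-transcriptome specificity profiles and check no strong diagonal
    pa = cc.specificity(cc.cluster_profile(eio.cp10k(a), genes=a.gene_ids))
    pb = cc.specificity(cc.cluster_profile(eio.cp10k(b), genes=b.gene_ids))
    corr = cc.correlate(pa, pb, list(pa.columns))  # case-folded resolution
    diag = np.diag(corr.to_numpy())
    off = corr.to_numpy()[~np.eye(3, dtype=bool)]
    assert abs(diag.mean() - off.mean()) < 0.15


def test_large_fold_change_recovers_mapping_end_to_end():
    cfg = _small_cfg(marker_fold_change=4.0, seed=3)
    a, b, truth = ie.simulate_expression(cfg)
    ma = cc.find_markers(eio.lognormalize(a), seed=3)
    mb = cc.find_markers(eio.lognormalize(b), seed=3)
    shared = cc.intersect_markers(ma, mb)
    pa = cc.specificity(cc.cluster_profile(eio.cp10k(a), genes=list(shared["gene_a"])))
    pb = cc.specificity(cc.cluster_profile(eio.cp10k(b), genes=list(shared["gene_b"])))
    bm = cc.best_match(cc.correlate(pa, pb, shared))
    assert all(bm.loc[t, "best_match"] == t for t in truth.type_map["type_a"])


# ---------------------------------------------------------------------------
# sequence simulator


def test_zero_branch_lengths_copy_root(jtt_model):
    tree = ie.parse_newick("((a:0.0,b:0.0)x:0.0,c:0.0)r;")
    cfg = ie.SeqSimConfig(tree=tree, model=jtt_model, n_sites=50, seed=4)
    aln, ancestors = ie.evolve_sequences(cfg)
    root = ancestors["r"]
    assert all(seq == root for seq in aln.sequences.values())


def test_same_seed_identical_alignments(jtt_model):
    c = dict(n_sites=40, seed=8)
    a1, anc1 = ie.evolve_sequences(ie.SeqSimConfig(**c))
    a2, anc2 = ie.evolve_sequences(ie.SeqSimConfig(**c))
    assert a1.sequences == a2.sequences
    assert anc1 == anc2


def test_single_branch_substitution_fractions(jtt_model):
    t = 0.4
    tree = ie.parse_newick(f"(leaf:{t})root;")
    n = 4000
    root_seq = "L" * n
    cfg = ie.SeqSimConfig(tree=tree, model=jtt_model, n_sites=n,
                          root_sequence=root_seq, seed=17)
    aln, _ = ie.evolve_sequences(cfg)
    P = jtt_model.transition_matrix(t)
    li = jtt_model.state_index("L")
    for target in "LIVK":
        ti = jtt_model.state_index(target)
        p = P[li, ti]
        observed = aln["leaf"].count(target) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se + 1e-9


def test_long_branch_composition_converges_to_stationary(jtt_model):
    tree = ie.parse_newick("(leaf:50.0)root;")
    n = 10_000
    cfg = ie.SeqSimConfig(tree=tree, model=jtt_model, n_sites=n,
                          root_sequence="A" * n, seed=23)
    aln, _ = ie.evolve_sequences(cfg)
    counts = np.array([aln["leaf"].count(c) for c in jtt_model.alphabet])
    stat = scipy.stats.chisquare(counts, jtt_model.frequencies * n)
    assert stat.pvalue > 0.01


def test_gap_injection_adds_contiguous_blocks(jtt_model):
    cfg = ie.SeqSimConfig(n_sites=100, gap_rate=0.2, seed=12)
    aln, _ = ie.evolve_sequences(cfg)
    for seq in aln.sequences.values():
        gaps = [i for i, c in enumerate(seq) if c == "-"]
        assert len(gaps) == 20
        assert gaps == list(range(gaps[0], gaps[0] + 20))
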