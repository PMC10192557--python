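import math

import numpy as np
import pytest

import interevo as ie
from interevo.asr import (SitePosterior, alignment_loglik, alt_all,
                          marginal_posteriors, ml_sequence, site_loglik,
                          summarize_posterior)
from interevo.checks import random_column, random_tree_newick
from interevo.validation import enumerate_site_loglik, three_leaf_posterior


# ---------------------------------------------------------------------------
# likelihood


def test_single_leaf_is_log_prior(jtt_model):
    tree = ie.parse_newick("(A:0.2)r;")
    ll = site_loglik(tree, jtt_model, {"A": "A"})
    # one leaf, reversible model: the observed residue integrates to pi_A
    assert ll == pytest.approx(math.log(jtt_model.frequencies[0]), abs=1e-12)


def test_zero_branches_collapse_to_prior(jtt_model):
    tree = ie.parse_newick("(A:0.0,B:0.0)r;")
    idx = jtt_model.state_index("W")
    ll = site_loglik(tree, jtt_model, {"A": "W", "B": "W"})
    assert ll == pytest.approx(math.log(jtt_model.frequencies[idx]), abs=1e-12)


def test_pruning_matches_enumeration_on_small_trees(jtt_model):
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(2, 6))
        tree = ie.parse_newick(random_tree_newick(rng, n))
        col = random_column(rng, jtt_model, tree.leaf_names)
        a = site_loglik(tree, jtt_model, col)
        b = enumerate_site_loglik(tree, jtt_model, col)
        assert a == pytest.approx(b, rel=1e-10)


def test_alignment_loglik_additivity(jtt_model, amniote_tree):
    cfg = ie.SeqSimConfig(n_sites=20, seed=5)
    aln, _ = ie.evolve_sequences(cfg)
    doubled = ie.AlignedSeqs({t: s + s for t, s in aln.sequences.items()})
    ll = alignment_loglik(cfg.tree, jtt_model, aln)
    assert alignment_loglik(cfg.tree, jtt_model, doubled) == pytest.approx(2 * ll, rel=1e-12)


def test_all_gap_column_contributes_zero(jtt_model, amniote_tree):
    gap = ie.AlignedSeqs({t: "-" for t in amniote_tree.leaf_names})
    assert alignment_loglik(amniote_tree, jtt_model, gap) == pytest.approx(0.0, abs=1e-12)


def test_taxon_mismatch_lists_both_sets(jtt_model, amniote_tree):
    aln = ie.AlignedSeqs({"mouse": "A", "human": "A", "frog": "A", "turtle": "A"})
    with pytest.raises(ValueError, match="zebra_finch") as exc:
        alignment_loglik(amniote_tree, jtt_model, aln)
    assert "frog" in str(exc.value)


def test_invalid_character_rejected(jtt_model):
    tree = ie.parse_newick("(A:0.1,B:0.1)r;")
    with pytest.raises(ValueError):
        site_loglik(tree, jtt_model, {"A": "Z", "B": "A"})


def test_pulley_principle(jtt_model):
    cfg = ie.SeqSimConfig(n_sites=40, seed=11)
    aln, _ = ie.evolve_sequences(cfg)
    tree = cfg.tree
    ll0 = alignment_loglik(tree, jtt_model, aln)
    for e in range(tree.n_edges()):
        ll = alignment_loglik(tree.rerooted_at_edge(e, 0.4), jtt_model, aln)
        assert ll == pytest.approx(ll0, abs=1e-8)


def test_true_model_beats_frequency_permuted(jtt_model):
    rng = np.random.default_rng(13)
    wins = 0
    for k in range(10):
        cfg = ie.SeqSimConfig(n_sites=150, seed=200 + k)
        aln, _ = ie.evolve_sequences(cfg)
        ll_true = alignment_loglik(cfg.tree, jtt_model, aln)
        ll_perm = alignment_loglik(cfg.tree, jtt_model.permuted_frequencies(rng), aln)
        wins += ll_true > ll_perm
    assert wins >= 9


# ---------------------------------------------------------------------------
# posteriors


def test_posterior_degenerate_collapse(jtt_model):
    tree = ie.parse_newick("((A:0.0,B:0.0)inner:0.0,C:0.0)root;")
    aln = ie.AlignedSeqs({"A": "A", "B": "A", "C": "A"})
    p = marginal_posteriors(tree, jtt_model, aln, "inner")
    assert p.probs[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_posterior_rows_normalized(jtt_model):
    cfg = ie.SeqSimConfig(n_sites=50, seed=21, gap_rate=0.1)
    aln, _ = ie.evolve_sequences(cfg)
    p = marginal_posteriors(cfg.tree, jtt_model, aln, "amniote_ancestor")
    np.testing.assert_allclose(p.probs.sum(axis=1), 1.0, atol=1e-10)
    assert p.probs.min() >= 0


def test_posterior_matches_direct_bayes(jtt_model):
    tree = ie.parse_newick("((A:0.3,B:0.12)inner:0.25,C:0.4)root;")
    aln = ie.AlignedSeqs({"A": "L", "B": "F", "C": "-"})
    for focal in ("inner", "root"):
        p = marginal_posteriors(tree, jtt_model, aln, focal).probs[0]
        q = three_leaf_posterior(0.25, 0.3, 0.12, 0.4, jtt_model,
                                 ("L", "F", "-"), focal=focal)
        np.testing.assert_allclose(p, q, atol=1e-10)


def test_posterior_requires_internal_node(jtt_model, amniote_tree):
    cfg = ie.SeqSimConfig(n_sites=5, seed=1)
    aln, _ = ie.evolve_sequences(cfg)
    with pytest.raises(ValueError, match="leaf"):
        marginal_posteriors(cfg.tree, jtt_model, aln, "mouse")


# ---------------------------------------------------------------------------
# sequence calling


def _posterior(rows):
    rows = np.asarray(rows, dtype=float)
    return SitePosterior(node="n", probs=rows, alphabet=ie.AA_ALPHABET)


def test_ml_sequence_argmax_and_tie_break():
    probs = np.full((2, 20), 0.1 / 18)
    probs[0, ie.AA_ALPHABET.index("L")] = 0.9
    probs[1, ie.AA_ALPHABET.index("A")] = 0.45
    probs[1, ie.AA_ALPHABET.index("V")] = 0.45
    probs /= probs.sum(axis=1, keepdims=True)
    seq = ml_sequence(_posterior(probs))
    assert seq[0] == "L"
    assert seq[1] == "A"  # tie: earlier residue both alphabetically and canonically


def test_ml_sequence_matches_exhaustive_argmax():
    rng = np.random.default_rng(3)
    probs = rng.dirichlet(np.ones(20), size=30)
    seq = ml_sequence(_posterior(probs))
    for i in range(30):
        assert seq[i] == ie.AA_ALPHABET[int(np.argmax(probs[i]))]


def test_altall_uses_second_best_above_cutoff():
    probs = np.zeros((3, 20))
    probs[0, :2] = [0.60, 0.30]          # ambiguous: second > 0.25
    probs[1, :2] = [0.95, 0.03]          # confident
    probs[2, :2] = [0.75, 0.25]          # boundary: strict inequality keeps ML
    probs[:, 2:] = (1 - probs[:, :2].sum(axis=1, keepdims=True)) / 18
    r = alt_all(_posterior(probs), cutoff=0.25)
    assert r.ml_sequence == "AAA"
    assert r.altall_sequence == "RAA"
    assert r.ambiguous_sites == [0]


def test_altall_differs_exactly_at_ambiguous_sites(jtt_model):
    cfg = ie.SeqSimConfig(n_sites=120, seed=31)
    aln, _ = ie.evolve_sequences(cfg)
    p = marginal_posteriors(cfg.tree, jtt_model, aln, "amniote_ancestor")
    r = alt_all(p)
    differing = [i for i, (a, b) in enumerate(zip(r.ml_sequence, r.altall_sequence))
                 if a != b]
    assert differing == r.ambiguous_sites


@pytest.mark.parametrize("bad", [0.0, -0.1, 0.6, 1.0])
def test_altall_cutoff_validated(bad):
    probs = np.full((1, 20), 0.05)
    with pytest.raises(ValueError):
        alt_all(_posterior(probs), cutoff=bad)


def test_altall_count_monotone_in_cutoff(jtt_model):
    cfg = ie.SeqSimConfig(n_sites=100, seed=41)
    aln, _ = ie.evolve_sequences(cfg)
    p = marginal_posteriors(cfg.tree, jtt_model, aln, "amniote_ancestor")
    n25 = len(alt_all(p, 0.25).ambiguous_sites)
    n49 = len(alt_all(p, 0.49).ambiguous_sites)
    assert n49 <= n25


def test_summarize_posterior_arithmetic():
    probs = np.zeros((2, 20))
    probs[0, 0] = 1.0
    probs[1, :2] = [0.5, 0.3]
    probs[1, 2:] = 0.2 / 18
    r = alt_all(_posterior(probs), cutoff=0.25)
    s = summarize_posterior(r)
    assert s["mean_max_posterior"] == pytest.approx(0.75)
    assert s["n_ambiguous_sites"] == 1


def test_constructed_ambiguous_site_count():
    probs = np.full((10, 20), 0.01 / 18)
    probs[:, 0] = 0.69
    probs[:, 1] = 0.30
    probs[3:, 0] = 0.89
    probs[3:, 1] = 0.10
    probs /= probs.sum(axis=1, keepdims=True)
    r = alt_all(_posterior(probs), cutoff=0.25)
    assert len(r.ambiguous_sites) == 3
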