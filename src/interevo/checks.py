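"""Repeatable correctness and calibration measurements.

Each function here runs one of the package's validation studies from scratch
— comparing the pruning machinery against the brute-force oracles in
:mod:`interevo.validation`, measuring posterior calibration and cluster-type
recovery on synthetic data, or exercising determinism of the pipeline — and
returns plain numbers.  Both the test suite and ``scripts/acceptance.py``
call these, so the numbers reported anywhere are always recomputed.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import scipy.stats

from . import expression_io as eio
from . import cluster_compare as cc
from .asr import alignment_loglik, marginal_posteriors, ml_sequence, site_loglik
from .seqs import AlignedSeqs
from .substitution import AAModel, jtt
from .synthetic import ExpressionSimConfig, SeqSimConfig, evolve_sequences, simulate_expression
from .trees import PhyloTree, parse_newick
from .validation import enumerate_site_loglik, three_leaf_posterior

GAPPY = "-X"


def random_tree_newick(rng: np.random.Generator, n_leaves: int,
                       lo: float = 0.02, hi: float = 0.6) -> str:
    """Random rooted topology by sequential joining, U(lo, hi) branch lengths."""
    names = [f"t{i}" for i in range(n_leaves)]
    parts = list(names)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j), parts.pop(i)
        t1, t2 = rng.uniform(lo, hi, size=2)
        parts.append(f"({b[1]}:{t1:.6f},{b[0]}:{t2:.6f})")
    return parts[0] + ";"


def random_column(rng: np.random.Generator, model: AAModel, taxa: list[str],
                  p_gap: float = 0.1) -> dict[str, str]:
    col = {}
    for t in taxa:
        if rng.random() < p_gap:
            col[t] = GAPPY[rng.integers(len(GAPPY))]
        else:
            col[t] = model.alphabet[rng.integers(model.n_states)]
    return col


def pruning_oracle_error(n_trees: int = 200, seed: int = 0,
                         max_leaves: int = 5) -> float:
    """Max relative |pruning - enumeration| log-likelihood mismatch."""
    model = jtt()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(2, max_leaves + 1))
        tree = parse_newick(random_tree_newick(rng, n))
        col = random_column(rng, model, tree.leaf_names)
        a = site_loglik(tree, model, col)
        b = enumerate_site_loglik(tree, model, col)
        worst = max(worst, abs(a - b) / max(abs(b), 1.0))
    return worst


def posterior_oracle_error(n_instances: int = 50, seed: int = 0) -> float:
    """Max abs deviation of marginal posteriors from direct Bayes on 3-leaf trees."""
    model = jtt()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        # round so the Newick text and the oracle see identical lengths
        t_ab, t_a, t_b, t_c = np.round(rng.uniform(0.05, 0.8, size=4), 6)
        tree = parse_newick(
            f"((A:{t_a:.6f},B:{t_b:.6f})inner:{t_ab:.6f},C:{t_c:.6f})root;")
        chars = [model.alphabet[rng.integers(20)] for _ in range(3)]
        if rng.random() < 0.2:
            chars[int(rng.integers(3))] = "-"
        aln = AlignedSeqs(dict(zip("ABC", chars)))
        for focal in ("inner", "root"):
            p = marginal_posteriors(tree, model, aln, focal).probs[0]
            q = three_leaf_posterior(t_ab, t_a, t_b, t_c, model,
                                     tuple(chars), focal=focal)
            worst = max(worst, float(np.abs(p - q).max()))
    return worst


def pulley_deviation(n_instances: int = 20, seed: int = 0,
                     n_sites: int = 30) -> float:
    """Max |loglik change| under rerooting along every branch (reversibility)."""
    model = jtt()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_instances):
        n = int(rng.integers(3, 6))
        tree = parse_newick(random_tree_newick(rng, n))
        cfg = SeqSimConfig(tree=tree, model=model, n_sites=n_sites,
                           seed=int(rng.integers(2**31)))
        aln, _ = evolve_sequences(cfg)
        ll0 = alignment_loglik(tree, model, aln)
        for e in range(tree.n_edges()):
            frac = float(rng.uniform(0.1, 0.9))
            ll = alignment_loglik(tree.rerooted_at_edge(e, frac), model, aln)
            worst = max(worst, abs(ll - ll0))
    return worst


def posterior_calibration(n_reps: int = 50, n_sites: int = 200,
                          seed: int = 0) -> dict[str, float]:
    """Root-state recovery of the ML call vs mean max posterior.

    Simulates alignments on the four-amniote topology with branch lengths
    drawn U(0.1, 0.5) per replicate; under the true model the fraction of
    correctly recovered root sites should match the mean of the per-site
    max posterior (law of total probability).
    """
    model = jtt()
    rng = np.random.default_rng(seed)
    correct = total = 0
    post_sum = 0.0
    for _ in range(n_reps):
        bl = rng.uniform(0.1, 0.5, size=6)
        tree = parse_newick(
            f"((mouse:{bl[0]:.6f},human:{bl[1]:.6f})mammal_ancestor:{bl[2]:.6f},"
            f"(zebra_finch:{bl[3]:.6f},turtle:{bl[4]:.6f})sauropsid_ancestor:{bl[5]:.6f})"
            f"amniote_ancestor;")
        cfg = SeqSimConfig(tree=tree, model=model, n_sites=n_sites,
                           seed=int(rng.integers(2**31)))
        aln, ancestors = evolve_sequences(cfg)
        post = marginal_posteriors(tree, model, aln, "amniote_ancestor")
        ml = ml_sequence(post)
        truth = ancestors["amniote_ancestor"]
        correct += sum(a == b for a, b in zip(ml, truth))
        total += n_sites
        post_sum += float(post.probs.max(axis=1).sum())
    recovery = correct / total
    mean_max = post_sum / total
    return {"ml_recovery": recovery, "mean_max_posterior": mean_max,
            "calibration_gap": abs(recovery - mean_max)}


def type_recovery(n_runs: int = 20, seed: int = 0, **cfg_kwargs) -> dict[str, float]:
    """End-to-end cross-species class recovery on simulated data.

    For each seeded run: simulate two species, find markers, intersect,
    correlate specificity profiles, and check (a) best_match returns the true
    class for every cluster and (b) every matched-pair correlation exceeds
    every mismatched one.
    """
    all_recovered = separated = 0
    for k in range(n_runs):
        cfg = ExpressionSimConfig(seed=seed + k, **cfg_kwargs)
        a, b, truth = simulate_expression(cfg)
        na, nb = eio.lognormalize(a), eio.lognormalize(b)
        ma = cc.find_markers(na, seed=cfg.seed)
        mb = cc.find_markers(nb, seed=cfg.seed)
        shared = cc.intersect_markers(ma, mb)
        pa = cc.specificity(cc.cluster_profile(eio.cp10k(a), genes=list(shared["gene_a"])))
        pb = cc.specificity(cc.cluster_profile(eio.cp10k(b), genes=list(shared["gene_b"])))
        corr = cc.correlate(pa, pb, shared)
        bm = cc.best_match(corr)
        truth_map = dict(zip(truth.type_map["type_a"], truth.type_map["type_b"]))
        if all(bm.loc[t, "best_match"] == truth_map[t] for t in truth_map):
            all_recovered += 1
        r = corr.to_numpy()
        matched = np.array([corr.loc[ta, tb] for ta, tb in truth_map.items()])
        mask = np.ones_like(r, dtype=bool)
        for ta, tb in truth_map.items():
            mask[corr.index.get_loc(ta), corr.columns.get_loc(tb)] = False
        if matched.min() > r[mask].max():
            separated += 1
    return {"type_recovery_rate": all_recovered / n_runs,
            "pair_separation_rate": separated / n_runs}


def null_marker_check(n_runs: int = 20, seed: int = 0, n_genes: int = 1000,
                      cells_per_group: int = 200) -> dict[str, float]:
    """Type-I-error behaviour of the marker test on null data.

    Two clusters drawn from identical distributions: raw p-values should be
    uniform (per-run KS test) and Bonferroni should retain at most one marker
    in nearly every run.
    """
    ks_ok = few_markers = 0
    ks_ps = []
    for k in range(n_runs):
        cfg = ExpressionSimConfig(
            n_types=2, type_names=("g1", "g2"), cells_per_type=cells_per_group,
            n_genes=n_genes, n_markers_per_type=0, marker_fold_change=0.0,
            species_shift_sd=0.0, seed=seed + k)
        a, _, _ = simulate_expression(cfg)
        na = eio.lognormalize(a)
        stats = cc.marker_stats(na, seed=cfg.seed)
        pvals = stats[stats.cluster == "g1"]["raw_p"]
        ks_p = float(scipy.stats.kstest(pvals, "uniform").pvalue)
        ks_ps.append(ks_p)
        ks_ok += ks_p > 0.01
        markers = cc.find_markers(na, seed=cfg.seed)
        few_markers += markers[markers.cluster == "g1"]["gene"].nunique() <= 1
    return {"ks_uniform_rate": ks_ok / n_runs,
            "median_ks_p": float(np.median(ks_ps)),
            "few_false_markers_rate": few_markers / n_runs}


def determinism_check(workdir: str | Path, seed: int = 0) -> bool:
    """Two identical pipeline runs must produce bit-identical text outputs."""
    from .pipeline import run_reconstruct, run_simulate_seqs

    workdir = Path(workdir)
    outputs = []
    for rep in ("run1", "run2"):
        d = workdir / rep
        sim = d / "sim"
        run_simulate_seqs({"n_sites": 60, "seed": seed}, sim)
        run_reconstruct({"tree": str(sim / "tree.nwk"),
                         "alignment": str(sim / "leaves.fasta"),
                         "node": "amniote_ancestor", "reference": "mouse"},
                        d / "recon")
        outputs.append(d)
    files = ["sim/leaves.fasta", "sim/ancestors_true.fasta", "sim/tree.nwk",
             "recon/posteriors.tsv", "recon/ancestral.fasta", "recon/conservation.tsv"]
    return all(filecmp.cmp(outputs[0] / f, outputs[1] / f, shallow=False)
               for f in files)
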