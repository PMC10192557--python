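"""Likelihoods and marginal ancestral reconstruction on a fixed rooted tree.

The likelihood of an alignment column is computed with Felsenstein's pruning
algorithm: every leaf carries a 20-vector that is an indicator of its observed
residue (all ones for gaps/X, which are treated as missing data), and each
internal node's partial likelihood is the product over children of
``P(t_child) @ partial_child``.  At the root the partials are averaged under
the stationary frequencies pi, which also serve as the prior on ancestral
states (the natural choice for a reversible model).

Marginal posteriors at a focal internal node combine the "below" partials
from pruning with "outside" partials propagated root-to-tip: the posterior of
state ``a`` is proportional to the prior-weighted likelihood of all leaf data
given that the focal node is in state ``a``, normalized over the 20 states.

From the per-site posteriors two ancestral sequences are called: the ML
sequence (per-site argmax) and the "altAll" worst-case alternative, which
swaps in the second-best residue wherever its posterior exceeds a cutoff
(0.25 by default); those sites are the "ambiguous" sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .seqs import AlignedSeqs
from .substitution import AAModel
from .trees import PhyloTree, node_name

__all__ = [
    "SitePosterior", "AncestralResult",
    "site_loglik", "alignment_loglik", "site_logliks",
    "marginal_posteriors", "ml_sequence", "alt_all", "summarize_posterior",
    "posterior_table",
]


# ---------------------------------------------------------------------------
# pruning machinery


def _check_taxa(tree: PhyloTree, taxa) -> None:
    tree_leaves = set(tree.leaf_names)
    aln_taxa = set(taxa)
    if tree_leaves != aln_taxa:
        raise ValueError(
            f"tree leaves and alignment taxa differ; "
            f"tree={sorted(tree_leaves)} alignment={sorted(aln_taxa)}"
        )


def _leaf_partials(model: AAModel, seq: str) -> np.ndarray:
    """(L, 20) indicator partials; missing characters give a row of ones."""
    L = len(seq)
    out = np.zeros((L, model.n_states))
    for i, ch in enumerate(seq):
        idx = model.state_index(ch)
        if idx is None:
            out[i, :] = 1.0
        else:
            out[i, idx] = 1.0
    return out


def _below_partials(tree: PhyloTree, model: AAModel, aln: AlignedSeqs):
    """Post-order partials, per-site rescaled to avoid underflow.

    Returns (partials, logscale): dicts keyed by dendropy node id; partials
    are (L, 20), logscale (L,) holds the log of the factored-out per-site
    scale so that true_partials = partials * exp(logscale)[:, None].
    """
    partials: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    L = aln.length
    for node in tree.postorder():
        if node.is_leaf():
            partials[id(node)] = _leaf_partials(model, aln[node_name(node)])
            logscale[id(node)] = np.zeros(L)
            continue
        acc = np.ones((L, model.n_states))
        scale = np.zeros(L)
        for child in node.child_nodes():
            P = model.transition_matrix(child.edge.length)
            acc = acc * (partials[id(child)] @ P.T)
            scale += logscale[id(child)]
        m = acc.max(axis=1)
        # a site where every state has likelihood 0 cannot occur with valid input
        acc /= m[:, None]
        scale = scale + np.log(m)
        partials[id(node)] = acc
        logscale[id(node)] = scale
    return partials, logscale


def site_logliks(tree: PhyloTree, model: AAModel, aln: AlignedSeqs) -> np.ndarray:
    """Per-column log-likelihoods under the pruning algorithm."""
    _check_taxa(tree, aln.taxa)
    partials, logscale = _below_partials(tree, model, aln)
    root = tree.root
    site_lik = partials[id(root)] @ model.frequencies
    return np.log(site_lik) + logscale[id(root)]


def alignment_loglik(tree: PhyloTree, model: AAModel, aln: AlignedSeqs) -> float:
    """Total log-likelihood (sum over columns; all-gap columns contribute 0)."""
    return float(site_logliks(tree, model, aln).sum())


def site_loglik(tree: PhyloTree, model: AAModel, column: Mapping[str, str]) -> float:
    """Log-likelihood of a single alignment column given as taxon -> character."""
    aln = AlignedSeqs({taxon: ch for taxon, ch in column.items()})
    return float(site_logliks(tree, model, aln)[0])


# ---------------------------------------------------------------------------
# marginal ancestral posteriors


@dataclass
class SitePosterior:
    """Per-site posterior distribution over ancestral states at one node."""

    node: str
    probs: np.ndarray  # (L, 20), rows sum to 1
    alphabet: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.alphabet):
            raise ValueError(f"posterior matrix must be (L, {len(self.alphabet)})")
        if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("posterior rows must be probability distributions")
        self.probs = p

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]


def marginal_posteriors(tree: PhyloTree, model: AAModel, aln: AlignedSeqs,
                        node: str) -> SitePosterior:
    """Marginal posterior over states at internal node ``node``, per site.

    Posterior(a) is proportional to pi_a-weighted likelihood of the data below
    the node times the outside partials from the rest of the tree; per-site
    scale factors cancel in the row normalization.
    """
    _check_taxa(tree, aln.taxa)
    focal = tree.find_node(node)
    if focal.is_leaf():
        raise ValueError(f"focal node {node!r} is a leaf; choose an internal node")

    below, _ = _below_partials(tree, model, aln)
    L = aln.length
    pi = model.frequencies

    # child->parent messages as a function of the parent state
    down: dict[int, np.ndarray] = {}
    trans: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n is tree.root:
            continue
        P = model.transition_matrix(n.edge.length)
        trans[id(n)] = P
        down[id(n)] = below[id(n)] @ P.T

    above: dict[int, np.ndarray] = {id(tree.root): np.tile(pi, (L, 1))}
    for parent in tree.preorder():
        if parent.is_leaf():
            continue
        children = parent.child_nodes()
        for child in children:
            msg = above[id(parent)].copy()
            for sib in children:
                if sib is not child:
                    msg *= down[id(sib)]
            res = msg @ trans[id(child)]
            res /= res.max(axis=1)[:, None]  # per-site rescale; cancels later
            above[id(child)] = res

    post = below[id(focal)] * above[id(focal)]
    post /= post.sum(axis=1, keepdims=True)
    return SitePosterior(node=node, probs=post, alphabet=model.alphabet)


# ---------------------------------------------------------------------------
# sequence calling


def ml_sequence(p: SitePosterior) -> str:
    """Per-site most probable residue; ties go to the earlier residue in the
    canonical alphabet order."""
    idx = np.argmax(p.probs, axis=1)
    return "".join(p.alphabet[i] for i in idx)


@dataclass
class AncestralResult:
    """ML and altAll ancestral sequence calls with per-site posterior summaries."""

    node: str
    ml_sequence: str
    altall_sequence: str
    max_posterior: np.ndarray
    second_posterior: np.ndarray
    ambiguous_sites: list[int]  # 0-based site indices
    cutoff: float


def alt_all(p: SitePosterior, cutoff: float = 0.25) -> AncestralResult:
    """Call ML and altAll sequences from per-site posteriors.

    A site is ambiguous when its second-highest posterior strictly exceeds
    ``cutoff``; there the altAll sequence takes the second-best residue.
    Cutoffs above 0.5 are rejected: a runner-up can never exceed them while
    the sites remain genuinely ambiguous, so such a threshold is a mistake.
    """
    if not (0.0 < cutoff <= 0.5):
        raise ValueError(f"cutoff must be in (0, 0.5], got {cutoff}")
    # stable sort so equal posteriors resolve in canonical alphabet order
    order = np.argsort(-p.probs, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    rows = np.arange(p.n_sites)
    max_post = p.probs[rows, best]
    second_post = p.probs[rows, second]
    ambiguous = second_post > cutoff

    ml = "".join(p.alphabet[i] for i in best)
    alt = [p.alphabet[second[i]] if ambiguous[i] else p.alphabet[best[i]]
           for i in range(p.n_sites)]
    return AncestralResult(
        node=p.node,
        ml_sequence=ml,
        altall_sequence="".join(alt),
        max_posterior=max_post,
        second_posterior=second_post,
        ambiguous_sites=np.flatnonzero(ambiguous).tolist(),
        cutoff=cutoff,
    )


def summarize_posterior(r: AncestralResult) -> dict[str, float]:
    """Mean max posterior over sites and the ambiguous-site count."""
    return {
        "mean_max_posterior": float(np.mean(r.max_posterior)),
        "n_ambiguous_sites": len(r.ambiguous_sites),
    }


def posterior_table(p: SitePosterior, r: AncestralResult) -> pd.DataFrame:
    """Tidy per-site table (1-based sites) for TSV export."""
    df = pd.DataFrame(p.probs, columns=list(p.alphabet))
    df.insert(0, "site", np.arange(1, p.n_sites + 1))
    df["ml"] = list(r.ml_sequence)
    df["altall"] = list(r.altall_sequence)
    df["max_posterior"] = r.max_posterior
    df["second_posterior"] = r.second_posterior
    amb = np.zeros(p.n_sites, dtype=bool)
    amb[r.ambiguous_sites] = True
    df["ambiguous"] = amb
    return df
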