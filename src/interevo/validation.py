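"""Brute-force reference computations for validating the pruning machinery.

These deliberately avoid the pruning recursion: the column likelihood is the
literal sum of the joint probability over every assignment of states to the
interior nodes, and the three-leaf posterior is direct Bayes with explicitly
multiplied transition-matrix entries.  They are exponential in the number of
interior nodes and only usable on tiny trees, which is the point — they are
an independent oracle, not an alternative implementation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .substitution import AAModel
from .trees import PhyloTree

__all__ = ["enumerate_site_loglik", "three_leaf_posterior"]


def enumerate_site_loglik(tree: PhyloTree, model: AAModel,
                          column: Mapping[str, str]) -> float:
    """Column log-likelihood by exhaustive summation over interior states.

    likelihood = sum over all interior-state assignments s of
        pi[s_root] * prod over edges (p, c) of P(t_c)[s_p, s_c],
    where leaf states are fixed by the column (missing characters are summed
    over as free states).  Feasible for a handful of interior nodes only.
    """
    from .trees import node_name

    nodes = list(tree.preorder())
    interior = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    if len(interior) > 6:
        raise ValueError("enumeration oracle is limited to <= 6 interior nodes")
    k = model.n_states
    axis_of = {id(n): i for i, n in enumerate(interior)}
    n_ax = len(interior)

    def grid(vec_for_state, axis):
        """Broadcast a per-state quantity along one interior-node axis."""
        shape = [1] * n_ax
        shape[axis] = k
        return vec_for_state.reshape(shape)

    total = grid(model.frequencies, axis_of[id(tree.root)]).astype(float).copy()
    # interior-interior edges: factor[..., sp, ..., sc, ...] = P[sp, sc]
    for n in interior:
        if n is tree.root:
            continue
        P = model.transition_matrix(n.edge.length)
        pa, ca = axis_of[id(n.parent_node)], axis_of[id(n)]
        sp = np.arange(k).reshape([k if i == pa else 1 for i in range(n_ax)])
        sc = np.arange(k).reshape([k if i == ca else 1 for i in range(n_ax)])
        total = total * P[sp, sc]
    # leaf edges: known state -> a column of P; missing -> sum over leaf states = 1
    for leaf in leaves:
        state = model.state_index(column[node_name(leaf)])
        pa = axis_of[id(leaf.parent_node)]
        P = model.transition_matrix(leaf.edge.length)
        vec = np.ones(k) if state is None else P[:, state]
        total = total * grid(vec, pa)
    return float(np.log(total.sum()))


def three_leaf_posterior(t_ab: float, t_a: float, t_b: float, t_c: float,
                         model: AAModel, col: tuple[str, str, str],
                         focal: str = "inner") -> np.ndarray:
    """Direct-Bayes posterior for the rooted three-leaf tree ((A,B)inner,C)root.

    ``col`` gives the observed residues at (A, B, C); ``focal`` selects the
    inner node (ancestor of A and B) or the root.  Transition-matrix entries
    are multiplied out state by state, with no pruning shortcuts.
    """
    k = model.n_states
    P_ab = model.transition_matrix(t_ab)
    P_a = model.transition_matrix(t_a)
    P_b = model.transition_matrix(t_b)
    P_c = model.transition_matrix(t_c)
    xa, xb, xc = (model.state_index(c) for c in col)

    def leaf_p(P, parent_state, obs):
        return 1.0 if obs is None else P[parent_state, obs]

    post = np.zeros(k)
    for s in range(k):  # focal state
        acc = 0.0
        for r in range(k):  # the other internal node's state
            if focal == "inner":
                root, inner = r, s
            elif focal == "root":
                root, inner = s, r
            else:
                raise ValueError("focal must be 'inner' or 'root'")
            acc += (model.frequencies[root] * P_ab[root, inner]
                    * leaf_p(P_a, inner, xa) * leaf_p(P_b, inner, xb)
                    * leaf_p(P_c, root, xc))
        post[s] = acc
    return post / post.sum()
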