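"""Ground-truthed synthetic inputs for both pipeline arms.

Two generators:

* :func:`simulate_expression` draws two-species single-cell count matrices
  with shared interneuron-like cell classes.  Genes have log-normal baseline
  expression; each class elevates its private marker set by a log-scale fold
  change; each species perturbs every gene's log-mean by an independent
  Gaussian shift (lineage divergence); counts are negative-binomial
  (gamma-Poisson) with log-normal library sizes.  The truth table (class
  correspondence and marker lists) makes best-match recovery checkable.

* :func:`evolve_sequences` evolves amino-acid sequences down a rooted tree
  under a reversible substitution model: the root is drawn from the
  stationary frequencies (or supplied), and each branch samples child states
  from the rows of P(t).  All internal-node sequences are recorded so
  ancestral-reconstruction calibration can be measured against truth.

All randomness flows from one seed through named, independently spawned
substreams (per species, per matrix, per branch), so enlarging one component
does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import CountMatrix
from .seqs import AlignedSeqs
from .substitution import AAModel, jtt
from .trees import PhyloTree, amniote_fixture_tree, node_name

DEFAULT_TYPE_NAMES = ("PV-like", "SST-like", "VIP-like",
                      "Lamp5-like", "Sncg-like", "Meis2-like")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimConfig:
    """Two-species interneuron count simulation.

    ``marker_fold_change`` is on the natural-log scale (2.0 means markers are
    e^2 ≈ 7.4-fold elevated in their class); ``species_shift_sd`` is the SD of
    the per-gene, per-species log-mean perturbation modelling lineage
    divergence; ``nb_dispersion`` is the gamma-Poisson alpha with
    var = mu + alpha * mu^2.
    """

    n_types: int = 6
    type_names: Sequence[str] = DEFAULT_TYPE_NAMES
    cells_per_type: int = 200
    n_genes: int = 3000
    n_markers_per_type: int = 40
    marker_fold_change: float = 2.0
    nb_dispersion: float = 0.3
    library_size_log_mean: float = np.log(5000.0)
    library_size_log_sd: float = 0.35
    species_shift_sd: float = 0.3
    baseline_log_sd: float = 1.0
    species_names: Sequence[str] = ("mouse", "zebra_finch")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if len(self.type_names) < self.n_types:
            self.type_names = tuple(self.type_names) + tuple(
                f"type{i}" for i in range(len(self.type_names), self.n_types))
        self.type_names = tuple(self.type_names)[: self.n_types]
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                f"{self.n_markers_per_type} markers x {self.n_types} types "
                f"exceed {self.n_genes} genes")
        if self.marker_fold_change < 0 or self.nb_dispersion < 0:
            raise ValueError("effect sizes and dispersion must be >= 0")


@dataclass
class ExpressionTruth:
    """What the expression simulator knows: class map and marker genes."""

    type_map: pd.DataFrame           # columns: type_a, type_b (same class names)
    markers: dict[str, list[str]]    # class -> marker gene indices as symbols (species A casing)
    config: ExpressionSimConfig


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draws with var = mu + alpha mu^2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mu)
    rate = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(rate)


def _symbols(n: int, style: str) -> list[str]:
    base = [f"gene{i:04d}" for i in range(n)]
    if style == "title":   # mouse-style casing, e.g. Gene0001
        return [s.capitalize() for s in base]
    if style == "upper":   # bird/human-style casing, e.g. GENE0001
        return [s.upper() for s in base]
    return base


def simulate_expression(cfg: ExpressionSimConfig) -> tuple[CountMatrix, CountMatrix, ExpressionTruth]:
    """Simulate two species' count matrices with homologous cell classes.

    The two species share gene content but use different symbol casings
    (Gene0001 vs GENE0001), exercising the case-folded cross-species match.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("structure", "species_a", "species_b"), root.spawn(3))}

    rng = streams["structure"]
    baseline = rng.normal(0.0, cfg.baseline_log_sd, size=cfg.n_genes)
    marker_pool = rng.choice(cfg.n_genes, size=cfg.n_markers_per_type * cfg.n_types,
                             replace=False)
    marker_idx = {
        t: np.sort(marker_pool[i * cfg.n_markers_per_type:(i + 1) * cfg.n_markers_per_type])
        for i, t in enumerate(cfg.type_names)
    }

    matrices = []
    styles = ("title", "upper")
    for s_i, (species, style) in enumerate(zip(cfg.species_names, styles)):
        rng = streams["species_a" if s_i == 0 else "species_b"]
        shift = rng.normal(0.0, cfg.species_shift_sd, size=cfg.n_genes)
        gene_ids = _symbols(cfg.n_genes, style)
        blocks, cells, labels = [], [], []
        for t in cfg.type_names:
            logmu = baseline + shift
            logmu = logmu.copy()
            logmu[marker_idx[t]] += cfg.marker_fold_change
            weights = np.exp(logmu)
            props = weights / weights.sum()
            lib = rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd,
                                size=cfg.cells_per_type)
            mu = lib[:, None] * props[None, :]
            blocks.append(_nb_counts(rng, mu, cfg.nb_dispersion))
            cells += [f"{species}_{t}_{i}" for i in range(cfg.cells_per_type)]
            labels += [t] * cfg.cells_per_type
        counts = np.concatenate(blocks, axis=0)
        meta = pd.DataFrame({"species": species, "cluster": labels},
                            index=pd.Index(cells, name="cell_id"))
        matrices.append(CountMatrix(counts=counts, cell_ids=cells,
                                    gene_ids=gene_ids, cell_meta=meta))

    symbols_a = _symbols(cfg.n_genes, "title")
    truth = ExpressionTruth(
        type_map=pd.DataFrame({"type_a": cfg.type_names, "type_b": cfg.type_names}),
        markers={t: [symbols_a[i] for i in idx] for t, idx in marker_idx.items()},
        config=cfg,
    )
    return matrices[0], matrices[1], truth


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SeqSimConfig:
    """Sequence evolution along a rooted tree under a reversible model."""

    tree: PhyloTree = field(default_factory=amniote_fixture_tree)
    model: AAModel = field(default_factory=jtt)
    n_sites: int = 200
    root_sequence: str | None = None
    gap_rate: float = 0.0      # expected gapped fraction per leaf (one block), 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        if self.root_sequence is not None and len(self.root_sequence) != self.n_sites:
            raise ValueError("root_sequence length must equal n_sites")


def _sample_states(rng: np.random.Generator, P_rows: np.ndarray) -> np.ndarray:
    """Draw one categorical sample per row of a row-stochastic matrix."""
    cdf = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0])
    return (cdf < u[:, None]).sum(axis=1)


def evolve_sequences(cfg: SeqSimConfig) -> tuple[AlignedSeqs, dict[str, str]]:
    """Evolve sequences down the tree; returns (leaf alignment, ancestor map).

    Unnamed internal nodes receive stable preorder names so every ancestral
    sequence is addressable.  Sites evolve independently; each branch samples
    the child state from the parent state's row of P(t).
    """
    tree = cfg.tree
    tree.label_unnamed_internals()
    model = cfg.model
    nodes = list(tree.preorder())
    root_seq_stream, gap_stream, *branch_streams = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(cfg.seed).spawn(2 + len(nodes))
    )

    states: dict[int, np.ndarray] = {}
    if cfg.root_sequence is None:
        states[id(tree.root)] = root_seq_stream.choice(
            model.n_states, size=cfg.n_sites, p=model.frequencies)
    else:
        states[id(tree.root)] = np.array(
            [model.state_index(c) for c in cfg.root_sequence])

    for node, stream in zip(nodes, branch_streams):
        if node is tree.root:
            continue
        P = model.transition_matrix(node.edge.length)
        states[id(node)] = _sample_states(stream, P[states[id(node.parent_node)]])

    def to_seq(arr: np.ndarray) -> str:
        return "".join(model.alphabet[i] for i in arr)

    leaf_seqs = {node_name(n): to_seq(states[id(n)]) for n in tree.leaves()}
    if cfg.gap_rate > 0:
        block = int(round(cfg.gap_rate * cfg.n_sites))
        if block:
            for name in sorted(leaf_seqs):
                start = int(gap_stream.integers(0, cfg.n_sites - block + 1))
                s = leaf_seqs[name]
                leaf_seqs[name] = s[:start] + "-" * block + s[start + block:]
    ancestors = {node_name(n): to_seq(states[id(n)])
                 for n in tree.internal_nodes()}
    return AlignedSeqs(leaf_seqs), ancestors
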