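"""Reproducible pipeline runs from a single validated configuration.

Each stage takes a plain dict (usually loaded from YAML), validates it
against a schema of known keys with defaults mirroring the analysis
conventions (CP10K scale 10,000; min_pct 0.2; max cells per cluster 200;
alpha 0.05; altAll cutoff 0.25), echoes the resolved configuration into the
output directory, and persists every intermediate table so any number in the
log can be re-derived.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asr, cluster_compare as cc, conservation as cons, expression_io as eio
from .seqs import AlignedSeqs, write_fasta
from .synthetic import (ExpressionSimConfig, SeqSimConfig,
                        evolve_sequences, simulate_expression)
from .trees import PhyloTree, amniote_fixture_tree


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


_SPECIES_KEYS = {"matrix", "meta", "format", "orientation"}

COMPARE_DEFAULTS: dict = {
    "species_a": None, "species_b": None,
    "min_pct": 0.2, "alpha": 0.05, "max_per_ident": 200,
    "seed": 0, "orthology": None,
    "cell_class": None, "class_column": "class",
    "heatmap": False,
}

RECONSTRUCT_DEFAULTS: dict = {
    "tree": None, "alignment": None, "node": None,
    "cutoff": 0.25, "reference": None, "comparator_gaps": "mismatch",
}

SIM_EXPRESSION_DEFAULTS: dict = {
    "n_types": 6, "cells_per_type": 200, "n_genes": 3000,
    "n_markers_per_type": 40, "marker_fold_change": 2.0,
    "nb_dispersion": 0.3, "species_shift_sd": 0.3,
    "format": "mtx", "seed": 0,
}

SIM_SEQS_DEFAULTS: dict = {
    "tree": None, "n_sites": 200, "gap_rate": 0.0, "seed": 0,
}


def resolve_config(cfg: dict, defaults: dict, required: tuple[str, ...]) -> dict:
    unknown = set(cfg) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; "
                          f"known keys: {sorted(defaults)}")
    out = {**defaults, **cfg}
    missing = [k for k in required if out.get(k) is None]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    return out


def _setup_run(outdir: str | Path, resolved: dict, stage: str) -> tuple[Path, logging.Logger]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump({"stage": stage, **resolved}, sort_keys=True))
    logger = logging.getLogger(f"interevo.{stage}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    sh = logging.StreamHandler()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for h in (fh, sh):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.propagate = False
    return outdir, logger


def _load_species(entry: dict, label: str) -> eio.CountMatrix:
    if not isinstance(entry, dict):
        raise ConfigError(f"{label} must be a mapping with keys {sorted(_SPECIES_KEYS)}")
    unknown = set(entry) - _SPECIES_KEYS
    if unknown:
        raise ConfigError(f"{label}: unknown keys {sorted(unknown)}")
    for key in ("matrix", "meta"):
        if key not in entry:
            raise ConfigError(f"{label}: missing {key!r}")
        if not Path(entry[key]).exists():
            raise ConfigError(f"{label}: path {entry[key]} does not exist")
    return eio.read_counts(entry["matrix"], entry["meta"],
                           format=entry.get("format", "mtx"),
                           orientation=entry.get("orientation", "cells_by_genes"))


def _filter_class(m: eio.CountMatrix, column: str, value: str | None) -> eio.CountMatrix:
    if value is None:
        return m
    if column not in m.cell_meta.columns:
        raise ConfigError(f"class column {column!r} not in cell metadata")
    keep = np.flatnonzero((m.cell_meta[column] == value).to_numpy())
    if keep.size == 0:
        raise ConfigError(f"no cells with {column} == {value!r}")
    return eio.CountMatrix(
        counts=m.counts[keep],
        cell_ids=[m.cell_ids[i] for i in keep],
        gene_ids=list(m.gene_ids),
        cell_meta=m.cell_meta.iloc[keep],
    )


def run_compare(cfg: dict, outdir: str | Path) -> dict:
    """Full cross-species comparison; returns summary numbers, persists tables."""
    resolved = resolve_config(cfg, COMPARE_DEFAULTS, ("species_a", "species_b"))
    outdir, log = _setup_run(outdir, resolved, "compare")

    mats = {}
    for key in ("species_a", "species_b"):
        m = _load_species(resolved[key], key)
        mats[key] = _filter_class(m, resolved["class_column"], resolved["cell_class"])
        log.info("%s: %d cells x %d genes, %d clusters", key, *mats[key].shape,
                 mats[key].clusters.nunique())

    seed = int(resolved["seed"])
    markers = {}
    for key, m in mats.items():
        norm = eio.lognormalize(m)
        markers[key] = cc.find_markers(
            norm, min_pct=resolved["min_pct"], alpha=resolved["alpha"],
            seed=seed, max_per_ident=resolved["max_per_ident"])
        markers[key].to_csv(outdir / f"markers_{key}.tsv", sep="\t", index=False)
        log.info("%s: %d marker rows, %d unique genes", key,
                 len(markers[key]), markers[key]["gene"].nunique())

    orth = None
    if resolved["orthology"]:
        orth = pd.read_csv(resolved["orthology"], sep="\t")
    shared = cc.intersect_markers(markers["species_a"], markers["species_b"], orth)
    shared.to_csv(outdir / "shared_genes.tsv", sep="\t", index=False)
    log.info("shared marker genes: %d", len(shared))

    profiles = {}
    for key, genes in (("species_a", "gene_a"), ("species_b", "gene_b")):
        prof = cc.cluster_profile(eio.cp10k(mats[key]), genes=list(shared[genes]))
        profiles[key] = cc.specificity(prof)
    corr = cc.correlate(profiles["species_a"], profiles["species_b"], shared)
    corr.to_csv(outdir / "correlation.tsv", sep="\t")
    match = cc.best_match(corr)
    match.to_csv(outdir / "best_match.tsv", sep="\t")
    for cluster, row in match.iterrows():
        log.info("best match: %s -> %s (r = %.3f)", cluster, row["best_match"], row["r"])

    if resolved["heatmap"]:
        _heatmap(corr, outdir / "correlation.png")
        log.info("wrote heatmap")
    return {"n_shared_genes": len(shared), "correlation": corr, "best_match": match}


def _heatmap(corr: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * corr.shape[1], 1.0 + 0.5 * corr.shape[0]))
    im = ax.imshow(corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90)
    ax.set_yticks(range(corr.shape[0]), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_reconstruct(cfg: dict, outdir: str | Path) -> dict:
    """Likelihood, marginal posteriors, ML/altAll calls and conservation."""
    resolved = resolve_config(cfg, RECONSTRUCT_DEFAULTS, ("tree", "alignment", "node"))
    outdir, log = _setup_run(outdir, resolved, "reconstruct")

    for key in ("tree", "alignment"):
        if not Path(resolved[key]).exists():
            raise ConfigError(f"{key} path {resolved[key]} does not exist")
    tree = PhyloTree.from_file(resolved["tree"])
    aln = AlignedSeqs.from_fasta(resolved["alignment"])

    from .substitution import jtt
    model = jtt()
    ll = asr.alignment_loglik(tree, model, aln)
    log.info("alignment log-likelihood under %s: %.4f (%d taxa, %d sites)",
             model.name, ll, len(aln.taxa), aln.length)

    post = asr.marginal_posteriors(tree, model, aln, resolved["node"])
    result = asr.alt_all(post, cutoff=float(resolved["cutoff"]))
    summary = asr.summarize_posterior(result)
    log.info("node %s: mean max posterior %.4f, %d ambiguous sites (cutoff %.2f)",
             resolved["node"], summary["mean_max_posterior"],
             summary["n_ambiguous_sites"], result.cutoff)

    asr.posterior_table(post, result).to_csv(outdir / "posteriors.tsv",
                                             sep="\t", index=False)
    write_fasta(outdir / "ancestral.fasta",
                {f"{resolved['node']}_ML": result.ml_sequence,
                 f"{resolved['node']}_altAll": result.altall_sequence},
                descriptions={
                    f"{resolved['node']}_ML": "most-likely marginal reconstruction",
                    f"{resolved['node']}_altAll":
                        f"second-best residues at sites with posterior above {result.cutoff}",
                })

    out = {"loglik": ll, **summary}
    if resolved["reference"]:
        prof = cons.per_site_conservation(aln, resolved["reference"],
                                          comparator_gaps=resolved["comparator_gaps"])
        mc = cons.mean_conservation(prof)
        cons.conservation_table(prof, aln).to_csv(outdir / "conservation.tsv",
                                                  sep="\t", index=False)
        log.info("mean conservation vs %s: %.4f", resolved["reference"], mc)
        out["mean_conservation"] = mc
    return out


def run_simulate_expression(cfg: dict, outdir: str | Path) -> dict:
    resolved = resolve_config(cfg, SIM_EXPRESSION_DEFAULTS, ())
    outdir, log = _setup_run(outdir, resolved, "simulate-expression")
    fmt = resolved.pop("format")
    sim_cfg = ExpressionSimConfig(**{k: v for k, v in resolved.items()})
    a, b, truth = simulate_expression(sim_cfg)
    ext = "mtx" if fmt == "mtx" else "csv"
    for label, m in (("species_a", a), ("species_b", b)):
        eio.write_counts(m, outdir / f"{label}.{ext}", outdir / f"{label}.cells.tsv",
                         format=fmt)
        log.info("%s: %d cells x %d genes", label, *m.shape)
    truth.type_map.to_csv(outdir / "truth_type_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, g) for t, genes in truth.markers.items() for g in genes],
        columns=["type", "gene"],
    ).to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    return {"species_a": a, "species_b": b, "truth": truth}


def run_simulate_seqs(cfg: dict, outdir: str | Path) -> dict:
    resolved = resolve_config(cfg, SIM_SEQS_DEFAULTS, ())
    outdir, log = _setup_run(outdir, resolved, "simulate-seqs")
    tree = (PhyloTree.from_file(resolved["tree"]) if resolved["tree"]
            else amniote_fixture_tree())
    sim_cfg = SeqSimConfig(tree=tree, n_sites=int(resolved["n_sites"]),
                           gap_rate=float(resolved["gap_rate"]),
                           seed=int(resolved["seed"]))
    aln, ancestors = evolve_sequences(sim_cfg)
    aln.to_fasta(outdir / "leaves.fasta")
    write_fasta(outdir / "ancestors_true.fasta", ancestors)
    tree.write(outdir / "tree.nwk")
    log.info("simulated %d leaf sequences of length %d; %d ancestors recorded",
             len(aln.taxa), aln.length, len(ancestors))
    return {"alignment": aln, "ancestors": ancestors, "tree": tree}
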