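"""Cross-species cluster correlation analysis.

The pipeline quantifies transcriptomic similarity of cell clusters between
two species in five steps:

1. per species, find cluster marker genes with a one-vs-rest Welch t-test on
   log-normalized values (cells optionally capped per cluster, genes only
   tested when detected in at least ``min_pct`` of either group), keeping
   genes whose Bonferroni-adjusted p-value is below alpha;
2. intersect the two species' marker lists (case-insensitive symbol match, or
   an explicit orthology table);
3. build per-cluster pseudobulk profiles on the shared genes: with x the
   cluster mean of per-cell CP10K values, store log(1 + x) + 0.1;
4. divide each gene's profile by its mean across clusters — the "specificity
   score", invariant to a gene's overall expression level;
5. Pearson-correlate every cluster of species A against every cluster of
   species B over the shared genes, and report each cluster's best match.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .expression_io import CountMatrix, NormalizedMatrix, cp10k

PSEUDOBULK_OFFSET = 0.1

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# marker detection


def subsample_cells(labels, max_per_ident: int, seed: int) -> np.ndarray:
    """Indices of retained cells: at most ``max_per_ident`` per cluster,
    sampled uniformly without replacement; deterministic for a fixed seed."""
    if max_per_ident < 1:
        raise ValueError("max_per_ident must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cluster in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cluster)
        if len(idx) > max_per_ident:
            idx = np.sort(rng.choice(idx, size=max_per_ident, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test per column; handles zero-variance columns.

    When both group variances vanish: equal means give p = 1, unequal means
    give the smallest positive float (the p -> 0 limit), never NaN.
    """
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1, v2 = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degen = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = np.empty_like(m1)
    ok = ~degen
    p[ok] = 2.0 * scipy.stats.t.sf(np.abs(t[ok]), df[ok])
    eq = degen & (m1 == m2)
    p[eq] = 1.0
    t[eq] = 0.0
    ne = degen & (m1 != m2)
    p[ne] = _TINY
    t[ne] = np.sign(m1[ne] - m2[ne]) * np.inf
    return t, p


def marker_stats(norm: NormalizedMatrix, labels=None, min_pct: float = 0.2,
                 max_per_ident: int | None = 200, seed: int = 0) -> pd.DataFrame:
    """One-vs-rest Welch t statistics for every cluster and tested gene.

    Returns the full table (no significance filter); ``find_markers`` applies
    the Bonferroni cut.  The Bonferroni denominator is the total number of
    genes in the matrix, not just the genes passing the detection filter.
    """
    labels = np.asarray(norm.clusters if labels is None else labels)
    if max_per_ident is not None:
        keep = subsample_cells(labels, max_per_ident, seed)
        values = norm.values[keep]
        labels = labels[keep]
    else:
        values = norm.values
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    n_genes_total = values.shape[1]
    genes = np.asarray(norm.gene_ids)
    detected = values > 0

    rows = []
    for cluster in clusters:
        mask = labels == cluster
        if mask.sum() < 3 or (~mask).sum() < 3:
            raise ValueError(f"cluster {cluster!r} has fewer than 3 cells after subsampling")
        pct_in = detected[mask].mean(axis=0)
        pct_out = detected[~mask].mean(axis=0)
        tested = (pct_in >= min_pct) | (pct_out >= min_pct)
        if not tested.any():
            continue
        t, p = _welch(values[mask][:, tested], values[~mask][:, tested])
        adj = np.minimum(p * n_genes_total, 1.0)
        rows.append(pd.DataFrame({
            "gene": genes[tested],
            "cluster": cluster,
            "t_statistic": t,
            "raw_p": p,
            "adjusted_p": adj,
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "mean_diff": values[mask][:, tested].mean(axis=0)
                         - values[~mask][:, tested].mean(axis=0),
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene", "cluster", "t_statistic", "raw_p", "adjusted_p",
                 "pct_in", "pct_out", "mean_diff"])
    out.attrs["n_genes_total"] = n_genes_total
    out.attrs["bonferroni"] = "raw_p * total genes in matrix, capped at 1"
    return out


def find_markers(norm: NormalizedMatrix, labels=None, min_pct: float = 0.2,
                 alpha: float = 0.05, seed: int = 0,
                 max_per_ident: int | None = 200) -> pd.DataFrame:
    """Marker table: rows of ``marker_stats`` with Bonferroni-adjusted p < alpha.

    Both up- and down-regulated genes are retained.
    """
    stats = marker_stats(norm, labels, min_pct=min_pct,
                         max_per_ident=max_per_ident, seed=seed)
    out = stats[stats["adjusted_p"] < alpha].reset_index(drop=True)
    out.attrs.update(stats.attrs)
    return out


# ---------------------------------------------------------------------------
# cross-species gene matching


def intersect_markers(a: pd.DataFrame, b: pd.DataFrame,
                      orthology: pd.DataFrame | None = None) -> pd.DataFrame:
    """Genes that are markers (of any cluster) in both species.

    Matching is case-insensitive on the symbol, or via a two-column orthology
    table (symbol in A, symbol in B) when provided.  Returns a table with
    columns ``gene_a`` / ``gene_b`` sorted by case-folded ``gene_a``; an empty
    intersection yields an empty table with a warning.
    """
    if a.empty or b.empty:
        raise ValueError("marker tables must be non-empty")
    genes_a = {g.casefold(): g for g in a["gene"].unique()}
    genes_b = {g.casefold(): g for g in b["gene"].unique()}
    pairs: list[tuple[str, str]] = []
    if orthology is not None:
        ca, cb = orthology.columns[:2]
        for ga, gb in zip(orthology[ca], orthology[cb]):
            if ga.casefold() in genes_a and gb.casefold() in genes_b:
                pairs.append((genes_a[ga.casefold()], genes_b[gb.casefold()]))
    else:
        for key in genes_a.keys() & genes_b.keys():
            pairs.append((genes_a[key], genes_b[key]))
    pairs = sorted(set(pairs), key=lambda p: (p[0].casefold(), p[1].casefold()))
    if not pairs:
        warnings.warn("no shared marker genes between the two species")
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


# ---------------------------------------------------------------------------
# pseudobulk profiles and correlation


def cluster_profile(scaled: NormalizedMatrix | CountMatrix, labels=None,
                    genes=None) -> pd.DataFrame:
    """Clusters x genes pseudobulk profile, log(1 + mean CP10K) + 0.1.

    ``scaled`` should hold per-cell CP10K values (a raw CountMatrix is
    CP10K-normalized on the fly); ``x`` is the per-cluster mean of those
    values and the stored value is ``log(1 + x) + 0.1``.
    """
    if isinstance(scaled, CountMatrix):
        scaled = cp10k(scaled)
    labels = np.asarray(scaled.clusters if labels is None else labels).astype(str)
    gene_index = pd.Index(scaled.gene_ids)
    if genes is None:
        genes = list(gene_index)
    missing = set(genes) - set(gene_index)
    if missing:
        raise KeyError(f"genes not in matrix, e.g. {sorted(missing)[:5]}")
    cols = gene_index.get_indexer(genes)
    values = scaled.values[:, cols]
    out = {}
    for cluster in sorted(set(labels.tolist())):
        mask = labels == cluster
        if mask.sum() == 0:
            raise ValueError(f"cluster {cluster!r} has no cells")
        out[cluster] = np.log1p(values[mask].mean(axis=0)) + PSEUDOBULK_OFFSET
    return pd.DataFrame(out, index=genes).T


def specificity(profile: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene (column) by its mean across clusters.

    The result is scale-free per gene: the across-cluster mean of every
    column is exactly 1.
    """
    means = profile.mean(axis=0)
    if (means <= 0).any():
        raise ValueError("every gene must have positive mean across clusters")
    return profile / means


def correlate(a: pd.DataFrame, b: pd.DataFrame, genes) -> pd.DataFrame:
    """Pearson correlation of every cluster in A against every cluster in B
    over the shared gene list.

    ``genes`` is either a list of symbols present in both profiles
    (case-insensitively resolved) or a gene_a/gene_b pair table from
    ``intersect_markers``.  Zero-variance cluster vectors give NaN entries
    with a warning, never a silent 0.
    """
    if isinstance(genes, pd.DataFrame):
        genes_a, genes_b = list(genes["gene_a"]), list(genes["gene_b"])
    else:
        genes_a = genes_b = list(genes)
    if len(genes_a) < 3:
        raise ValueError(f"need at least 3 shared genes, got {len(genes_a)}")

    def resolve(profile: pd.DataFrame, wanted: list[str]) -> np.ndarray:
        lookup = {c.casefold(): c for c in profile.columns}
        try:
            cols = [lookup[g.casefold()] for g in wanted]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from profile") from None
        return profile[cols].to_numpy()

    va, vb = resolve(a, genes_a), resolve(b, genes_b)
    va = va - va.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    sa, sb = np.linalg.norm(va, axis=1), np.linalg.norm(vb, axis=1)
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        warnings.warn("zero-variance cluster vector(s); correlations set to NaN")
    sa[bad_a] = np.nan
    sb[bad_b] = np.nan
    r = (va @ vb.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    out = pd.DataFrame(r, index=a.index, columns=b.index)
    out.attrs["n_genes"] = len(genes_a)
    return out


def best_match(c: pd.DataFrame) -> pd.DataFrame:
    """Per row, the best-correlated column; ties go to the lowest column index.

    Rows whose entries are all NaN are reported unassigned (best = NA).
    """
    if c.empty:
        raise ValueError("correlation matrix is empty")
    rows = []
    for label, row in c.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            rows.append((label, pd.NA, np.nan))
            continue
        j = int(np.nanargmax(vals))
        rows.append((label, c.columns[j], vals[j]))
    return pd.DataFrame(rows, columns=["cluster", "best_match", "r"]).set_index("cluster")
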