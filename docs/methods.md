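# Methods

## Cross-species cluster comparison

### Model and procedure

The comparison asks whether cluster identity, not overall expression level,
is shared between species.  Starting from raw counts with per-cell cluster
labels:

1. **Normalization.**  Each cell is scaled to 10,000 total counts (CP10K)
   and log1p-transformed (natural log).  CP10K removes sequencing-depth
   differences; log1p stabilizes the variance of overdispersed counts.
2. **Markers.**  Per species, a one-vs-rest Welch *t*-test per gene on the
   log-normalized values.  Clusters are subsampled to at most
   `max_per_ident = 200` cells (uniformly, seeded) before testing, and a
   gene is tested only when detected (> 0) in at least `min_pct = 0.2` of
   the cluster **or** of the rest.  Raw p-values are Bonferroni-corrected by
   the **total** number of genes in the matrix (not the number tested) and
   retained at adjusted p < `alpha = 0.05`, in either direction of change.
   Welch's statistic uses the Satterthwaite degrees of freedom
   ν = (v₁/n₁ + v₂/n₂)² / [v₁²/(n₁²(n₁−1)) + v₂²/(n₂²(n₂−1))].
   When both group variances are zero the test is degenerate: equal means
   give p = 1, unequal means give the smallest positive double (a p → 0
   limit), never NaN.
3. **Intersection.**  Markers of any cluster in species A are matched to
   markers in species B case-insensitively by symbol (mouse *Elfn1* vs avian
   *ELFN1*), or through an explicit two-column orthology table.  The result
   is a pair table, since the two species' symbols may differ in casing.
4. **Pseudobulk specificity.**  For each cluster and shared gene,
   x̄ = mean per-cell CP10K value and the profile entry is log(1 + x̄) + 0.1.
   The mean is taken over CP10K values, not raw counts, so clusters with
   deeper-sequenced cells are not inflated.  Dividing each gene by its
   across-cluster mean yields the specificity score; the +0.1 offset keeps
   every denominator positive.  By construction each gene's cluster-mean
   specificity is exactly 1.
5. **Correlation and matching.**  Pearson correlation of specificity vectors
   over the shared genes, for every cluster pair.  A zero-variance vector
   yields NaN with a warning.  `best_match` takes the per-row argmax, ties
   to the lowest column index.

### Design choices

- Welch rather than Student's t: robust to unequal cluster variances, and
  the default of the common single-cell marker implementations.
- min_pct is an OR over the two groups, so strongly *depleted* genes are
  also testable.
- GABAergic vs glutamatergic populations are separate runs, selected by an
  optional class-column filter in the run configuration.
- `min.pct` is computed on the subsampled cells (subsampling precedes
  testing).

## Sequence likelihoods and ancestral reconstruction

### Model

A reversible 20-state continuous-time Markov chain: Q_ij = S_ij π_j for
i ≠ j, diagonal fixed by zero row sums, rescaled so −Σ π_i Q_ii = 1 (branch
lengths in expected substitutions per site).  S and π are the JTT empirical
values (Jones, Taylor & Thornton 1992), shipped in `src/interevo/data/jtt.dat`
in the standard lower-triangle layout.  P(t) = exp(Qt) is computed through
the eigendecomposition of the symmetric matrix diag(√π) Q diag(1/√π) —
exact for reversible Q; entries a few ulps below zero are clipped and rows
renormalized (tolerance 1e-12 per unit branch length).

Site independence and a single substitution rate across sites are assumed;
rate heterogeneity and model selection are out of scope and documented as
limitations.

### Likelihood

Felsenstein pruning with per-site rescaling (partials divided by their
per-site maximum, log-scale accumulated) to avoid underflow on longer trees.
Gaps, `X`, `?` and `.` are missing data: their leaf partial is a vector of
ones.  An all-gap column therefore contributes exactly 0 to the
log-likelihood.  The root prior is π — the stationary distribution is the
natural prior for a reversible model, and makes the likelihood independent
of root placement (pulley principle), which the tests verify to 1e-8.

### Marginal posteriors and sequence calling

Posterior(state a at focal node) ∝ below_a × above_a, where `below` are the
pruning partials of the focal subtree and `above` are outside partials
propagated root-to-tip: for child c of node u with siblings s,
above_c = (above_u × Π_s P(t_s) below_s) P(t_c), with above_root = π.
Per-site scale factors are state-independent and cancel in the row
normalization.

The ML sequence takes each site's argmax; exact ties resolve to the earlier
residue in the canonical order A R N D C Q E G H I L K M F P S T W Y V.  The
altAll sequence substitutes the second-best residue at sites where its
posterior **strictly** exceeds the cutoff (default 0.25; boundary ties keep
the ML call).  Cutoffs outside (0, 0.5] are rejected — above 0.5 a runner-up
can never qualify.  ML and altAll differ exactly at the ambiguous sites, a
structural invariant asserted on every run.

### Conservation

Per alignment column where the reference is ungapped: the fraction of the
other sequences sharing the reference residue.  Reference-gap columns are
undefined (NaN).  Comparator gaps count as mismatches by default; an
`exclude` mode drops them from the denominator instead (both are exposed
because published profiles rarely state the convention).  Sites are reported
1-based in alignment coordinates with a companion ungapped-reference
coordinate.

## Synthetic data

### Expression

Per gene, a baseline log-mean ~ N(0, 1).  Each of 6 classes (PV-, SST-,
VIP-, Lamp5-, Sncg-, Meis2-like) elevates its private 40-gene marker set by
a log-fold-change of 2.  Each species adds an independent N(0, 0.3²)
per-gene shift (lineage divergence).  Within a cell, gene log-means are
softmax-normalized to expression proportions, multiplied by a log-normal
library size (median 5,000, σ_log 0.35), and counts drawn gamma-Poisson
with dispersion α = 0.3 (variance μ + αμ²).  Defaults: 200 cells per class,
3,000 genes.  The two species use different symbol casings (Gene0001 vs
GENE0001) so the case-folded matching path is always exercised.

What the simulator does **not** model: ambient RNA, doublets, UMI
duplication, batch effects within species, partially overlapping class sets,
or genes with species-specific gain/loss.  Passing recovery tests therefore
shows the pipeline's statistics behave correctly under the assumed
generative structure, not that real cross-species comparisons are this
clean — real best-match correlations are far below the ≈ 0.98 the simulation
yields.

### Sequences

The root sequence is drawn from π (or supplied); each branch samples child
states from the parent state's row of P(t), site by site, recording every
internal node.  The default tree is the four-amniote topology
((mouse, human), (zebra finch, turtle)) with branch lengths 0.15–0.35 —
free simulation parameters, not literature estimates.  Optional gap
injection places one contiguous gap block per leaf covering a `gap_rate`
fraction of sites, to exercise missing-data handling; off by default.

All randomness flows from a single seed through named spawned substreams
(structure / species A / species B; root sequence / gap placement / one per
branch), so enlarging one component leaves the others' draws unchanged.

## Validation studies and problem sizes

The studies in `interevo.checks` (run by both the acceptance tests and
`scripts/acceptance.py`) use: 200 random trees of 2–5 leaves against the
exhaustive enumeration oracle (tolerance 1e-10 relative); 50 three-leaf
instances against direct Bayes (1e-10 absolute); 20 rerooting instances
(1e-8); 50 alignments × 200 sites for posterior calibration (recovery vs
mean max posterior within ±0.03); 20 seeded full-size expression datasets
for type recovery; 20 null datasets of 1,000 genes × 2 × 200 cells for
marker-test validity.  These sizes give binomial/KS resolution comfortably
finer than the thresholds they are checked against.

## Known limitations

- No rate variation across sites and no model selection; the JTT model is
  fixed.
- Branch lengths are inputs, never optimized.
- The marker test assumes approximate normality of log-normalized values at
  the tested group sizes; at very small clusters (< 3 cells it refuses) the
  t approximation would be poor.
- The orthology default (case-insensitive symbol equality) is a convenience;
  rigorous cross-species work should supply an explicit orthology table.
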