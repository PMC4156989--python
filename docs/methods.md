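# Methods

## Problem and model

The pipeline looks for existing drugs whose induced expression signatures
*reverse* a disease signature derived from paired tumor/normal expression.
Pairing (both tissues from the same patient) removes between-individual
heterogeneity, so the unit of analysis is the per-gene, per-patient log2
difference d_gj = tumor − normal. Disease stages (early/late) are analyzed
as independent runs of the same pipeline; "stage" is a label, not logic.

### Moderated paired t-test

For gene g with n pairs, the sample variance s²_g has d_g = n − 1 df. The
hierarchical model places a scaled inverse-chi-square prior on the true
variances; the hyperparameters (d₀, s₀²) are estimated by method of moments
on log s²_g: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the mean of e_g
estimates log s₀² (up to a digamma correction) and its excess variance over
ψ′(d_g/2) determines d₀ through the trigamma inverse (solved by Newton
iteration to 1e−10 relative tolerance). If the observed spread of log s²_g
does not exceed pure sampling noise, d₀ = ∞ and every gene uses s₀²; if
d₀ = 0 the ordinary paired t-test is recovered. Genes with s²_g = 0 are
excluded from hyperparameter estimation but still receive a shrunken
variance; an all-constant matrix is an error because no prior can be
estimated. The implementation agrees with limma's `eBayes` to machine
precision on the same input (cross-checked in the test suite via Rscript).

Multiple testing uses Benjamini–Hochberg (the convention of this style of
workflow; the adjustment method is configurable only through code). Note BH
is monotone and order-preserving but not idempotent, and the tests assert
exactly those properties.

Direction: up ⇔ log₂FC > 0, down ⇔ log₂FC < 0; genes with exactly zero fold
change are excluded from both signatures, making the two sets disjoint by
construction. The per-direction signatures are intersected across batches
(common DEGs), and the export step floors |log₂FC| at log₂50 ≈ 5.6439 with
sign preserved — a large-fold-change query is what a Connectivity-Map-style
search expects. The floor applies after DEG selection and intersection,
at signature export.

### Clique percolation

Standard (Palla-style) clique percolation for each k independently:
enumerate k-cliques, join cliques sharing k − 1 nodes, take unions per
connected component of the clique-adjacency graph. Communities may overlap;
the census counts distinct genes once. The implementation delegates clique
enumeration to networkx's `k_clique_communities` behind the module surface;
a brute-force oracle (exhaustive k-subset enumeration + union-find) checks
equivalence on random graphs in the tests. Because k-clique enumeration is
worst-case exponential, a node-count guard (default 10,000) refuses
oversized graphs rather than hanging; synthetic inputs are far below it.
Output order is deterministic: by decreasing community size, then by
lexicographically smallest member. k < 3 is rejected (a 2-community is just
a connected component).

### Over-representation

One-sided hypergeometric tail P(X ≥ observed overlap) with BH adjustment,
ranked by ascending raw p. The background universe is the set of genes on
the platform (not the genome): that is the convention for array-derived
queries and is configurable. Query genes outside the background are dropped
with a logged warning; an empty restricted query is an error. Reported
significance defaults to p < 0.05 for tables; the stricter 0.005 used for
signature construction is available as the same parameter.

### Meta-analysis of drug scores

Each batch contributes one enrichment score ρ per drug, transformed to
Y = arctanh(ρ) with variance V = 1/(N − 3); N < 4 is rejected because the
variance is undefined. Fixed-effect combination uses W_i = 1/V_i (or W_i = 1
in the unweighted mode, kept first-class because either may be preferred
when instance counts are unreliable): M = ΣWY/ΣW, V_M = (ΣW)⁻¹,
Z = M/SE_M — algebraically identical to the "weighted Z" form ΣWY/√ΣW —
and CI = M ± 1.96·SE_M with the literal 1.96 multiplier (bit-reproducible
against the defining formula rather than recomputed from a normal
quantile). Heterogeneity: Q = ΣW(Y − M)² with fixed-effect weights,
df = k − 1, p_het from the χ² upper tail, I² = max(0, (Q − df)/Q)·100, and
DerSimonian–Laird τ² = max(0, (Q − df)/C) with C = ΣW − ΣW²/ΣW. Model
choice: p_het ≥ 0.1 keeps the fixed-effect model, otherwise random effects
with weights 1/(V_i + τ²); the boundary 0.1 itself selects fixed. With
τ² = 0 the random-effects result equals the fixed-effect result exactly.

The one-tailed p-value is P(Z_std ≤ Z_obs): the pipeline screens for drugs
whose combined effect is *negative* (signature reversal). Two-tailed and
upper-tailed alternatives are available via the `alternative` argument.

Drugs observed in a single batch are passed through (k = 1) with a
`single_study` flag rather than dropped; drugs missing an instance count N
are skipped with a warning unless a global default N is configured — real
score resources do not always report N.

Fisher's combined test F = −2Σln p (χ², 2N df) is implemented as the
p-value-based alternative; zero p-values are floored at a configurable
ε = 1e−16 with a warning, since a zero would make F infinite.

Small-k caveat: with τ² *estimated* from k = 4 batches, the DL
random-effects CI undercovers (≈88% at nominal 95%) — a known property of
the estimator, not an implementation defect. The coverage check in the
tests therefore supplies the known τ² and verifies the CI construction
itself (measured 95.4% over 2,000 replicates).

### Ranking, comparison, targets

Candidate filtering keeps records with ρ < 0 strictly (ρ = 0 excluded) and
optionally a per-batch p cutoff (0.1 or 0.5 in the published comparisons);
ranking keeps meta-analysis p < 0.05, ordered by ascending p with
lexicographic tie-break for determinism. The Jaccard index is intersection
over union — the published formula's typeset denominator (|A|∪|B|) is
malformed, and intersection-over-union reproduces all six printed values —
with JI(∅, ∅) ≡ 0 by convention. Drug names are case-insensitive and
trimmed on comparison. Target mapping intersects each drug's known target
genes (user-supplied TSV emulating merged DrugBank/NCBI/STITCH links) with
the up- and down-community gene sets; the neighbor export lists edges
incident to target genes with node roles (target/partner) for plotting in
an external viewer.

## Synthetic data: what it emulates, what it does not

* **Expression.** Gene-level log2 paired differences: planted DEGs receive
  a global mean shift (magnitude ~ N(effect_mean, effect_sd²), sign by
  direction) shared across batches — the common-DEG structure of a
  multi-platform design — plus i.i.d. N(0, noise_sd²) pair noise, and an
  optional per-batch jitter (default 0). Defaults: 1,000 genes, 4 batches of
  15 pairs, 5% planted per direction, effect 3.0 (log2), noise 0.5 — a
  strong-signal paired microarray regime in which the moderated test should
  recover essentially all planted genes. Not emulated: probe-level
  structure, RMA normalization, probe-to-gene collapsing,
  platform-specific biases, correlated genes. Passing tests therefore
  demonstrate correctness of the statistics, not robustness to array
  preprocessing artifacts.
* **PPI.** Planted gene sets wired as chains of overlapping k-cliques
  (windows of size k over the sorted members, stride 1), guaranteeing each
  set is exactly one k-community at that k; background edges are
  Erdos-Renyi. Real interactome degree distributions are not emulated.
* **Drug scores.** z_obs ~ N(arctanh(true ρ), 1/(N−3) + τ²), back-transformed
  to ρ_obs ∈ (−1, 1); the per-batch p-value is the two-sided normal tail of
  z_obs/√(1/(N−3)) — a stand-in for the permutation p of a real score
  resource, defensible because downstream only thresholds it. Instance
  counts N are a free parameter (default 50) since real per-drug counts
  vary and are often unreported.

All generators are deterministic given their seed (numpy Generator,
PCG64).

## Numerical choices

* Trigamma inverse by Newton, 50 iterations max, relative tolerance 1e−10.
* Fisher z via `arctanh`/`tanh`; round trip verified to 1e−12 on
  ρ ∈ (−0.999, 0.999).
* I² floored at 0; τ² floored at 0; Q = 0 gives I² = 0 and p_het = 1.
* Ties in drug ranking broken lexicographically after case-folding.
* TSV floats written with `%.10g` so reruns are byte-identical.

## Problem sizes used in checks

Simulation-based checks run at deliberately modest sizes — 1,000 genes ×
15 pairs for DEG recovery, 100 random graphs ≤ 30 nodes for the community
oracle, 1,000–2,000 replicates for meta-analysis recovery and coverage —
sizes at which the Monte-Carlo error of each assertion is comfortably
inside its stated band.

## Known limitations

* The empirical study this pipeline mirrors depended on external resources
  (GEO raw arrays, BioGrid, DAVID/CPDB services, the Connectivity Map);
  its specific gene lists, community counts, and enrichment p-values are
  not reproducible from code alone and are not asserted anywhere. What is
  reproduced is the method: every statistic, rule, and threshold, verified
  against independent oracles and printed derivable values (the Jaccard
  matrix of the published candidate lists, the log₂50 floor).
* DL τ² at small k is noisy; see the coverage caveat above. Meta-regression
  for heterogeneous subsets is out of scope.
* ORA ignores the GO DAG and gene-set overlap structure.
* CPM on dense graphs can be expensive; the guard refuses rather than
  degrades.
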