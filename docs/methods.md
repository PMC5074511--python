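# Methods

## The problem

Cancer-subtype stem cells (CSCs) are thought to descend from a normal
cell population whose transcriptional program they partially retain.
`stemtrace` prioritizes that cell of origin: given expression profiles of
candidate normal populations and of CSC vs non-CSC contrasts per tumor
subtype, it asks which candidate's signature a subtype's stem-cell
signature most resembles — in membership, expression direction, annotated
function and interaction-network proximity — and fuses those four views
into one ranking per subtype.

## Signature calling

Signature genes pass a two-sided two-sample t test at raw p < 0.05
together with a 2-fold-change gate. Both thresholds are configurable
(`p_threshold`, `fc_threshold`); no multiple-testing correction is
applied by default, matching the raw-p convention of the procedure the
package implements (a Benjamini–Hochberg switch exists). Data are assumed
log2 scale, so fold change is the difference of group means of log2
values (a geometric-mean ratio); FC > 2 is log2FC > 1. The t test is
Welch by default (`ttest: pooled` selects the pooled-variance variant;
the classic arrays-era tooling used pooled, but Welch is the safer
default under unequal variances and the simulated data satisfy both).
Normal-population signatures come from one-vs-rest contrasts ("over" /
"under" genes); CSC signatures from CSC vs non-CSC per subtype ("up" /
"down"). Zero-variance genes with equal means get p = 1 and no call.

The origin-specific signature is the direction-consistent intersection of
CSC-vs-candidate-origin differentials across expression series. Because
the two groups live in different matrices, `cross_matrix_differential`
restricts to shared genes and offers optional per-matrix gene-wise
standardization (off by default) as a crude cross-series normalization;
cross-series batch structure is otherwise the user's responsibility.

## The four concordance measures

**Overlap enrichment.** Upper-tail hypergeometric probability
P(X >= q) of the observed overlap q between the CSC and population
signatures (up vs over, down vs under), with the expression matrix's
gene set as the universe. Implemented as the standard survival function
`hypergeom.sf(q-1, N, |A|, |B|)`; q = 0 returns 1. (Printed formulations
of this test sometimes index the sum from x = 1 and overload the symbol
for the universe size; the survival function is the equivalent intent.)

**Gene signature score (GSS).** For one normal sample,

    GSS = sum_g x_g (y_g - z_g) / sum_g |x_g|

over the directional signature genes, where x_g is the signature log2
fold change, y_g the sample's log2 value and z_g the gene's mean log2
value across all samples of the normal matrix (mean of log2 values, not
log2 of the mean). A population's score is the arithmetic mean over its
samples — the per-sample scores must be reduced somehow to rank
populations, and the mean is the least-structured choice. Genes absent
from the matrix are skipped and counted.

**Semantic similarity (SSS).** Term information content is
ic(t) = -ln(n_t / n_root) with n_t the number of genes annotated to t or
any descendant, computed from the supplied annotation corpus itself.
Term-term similarity is Lin's measure 2 ic(MICA)/(ic(t1)+ic(t2));
gene-gene and set-set similarity are combined by best-match averaging
(BMA): mean of row maxima and column maxima, averaged. Only the supplied
ontology namespace is used. Genes with identical term sets share one
profile internally, so the profile-profile BMA matrix is computed once
per ontology — same results, usable on signature-sized sets.

**Shortest path (SP).** Mean unweighted shortest-path length over all
ordered pairs (a, b), a in A, b in B, a != b, on the interaction network
(BFS via `scipy.sparse.csgraph`). Unreachable pairs are excluded and
counted rather than imputed with a penalty, so the exclusion is
auditable; a gene in both sets contributes only through its pairings
with other genes.

## Rank fusion

Within each expression series and subtype, the candidates are ranked on
each of the 8 lists (4 measures x 2 directions): ascending for the
enrichment p and SP, descending for GSS and SSS, average ranks on ties.
Ranks become ratios r = rank / k with k the number of candidates actually
ranked in that list. Each candidate's ascending ratio vector enters the
order-statistics statistic

    Q(r_1..r_N) = N! V_N,   V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_{N-k+1}^i / i!,  V_0 = 1,

the probability that N iid uniform(0,1) order statistics are
componentwise <= the observed ratios. A NaN measure removes that list for
the affected candidate (N shrinks) rather than imputing a worst rank; Q
values with different N remain comparable as probabilities, though a
candidate with fewer informative lists is judged on less evidence. Q is
clamped to [0, 1] (the alternating sum can drift by ~1e-16) with
compensated summation. Candidates are ranked by ascending Q with fully
deterministic tie-breaking (mean ratio, then candidate id). Per-series
fused ranks are averaged into the overall rank; a subtype measured in a
single series passes through unchanged.

## Origin-specific modules

Edges of a functional-interaction network are assigned the Pearson
correlation of their endpoint genes over one condition's samples (a
subtype's CSC samples; the origin population's samples). Louvain
modularity communities partition the network; modules smaller than
`module_min_size` (default 7 — the upstream tool's "default threshold"
is unrecorded) or with mean internal edge correlation below
`module_min_avg_pcc` (default 0.5, inclusive) are removed. Remaining
modules are tested for enrichment of the origin-specific signature
(hypergeometric, p < 0.05) and paired across conditions by shared
signature genes, sorted by shared count.

Two deliberate choices here. First, the partition is driven by topology
alone by default (`module_use_weights` turns on weight-driven
clustering with correlations mapped to [0,1] via (w+1)/2): with a
handful of samples per condition the edge correlations are noisy
estimates, and letting them drive the modularity objective selects
communities *for* sampling noise, biasing the post-hoc average-PCC
filter upward on null modules (in simulation, ~25% of null modules
passed the 0.5 filter under weight-driven partitions versus ~0% under
topology-driven ones). The correlations instead act where they are
meaningful in aggregate — the coherence filter. Second, the community
scale is set by `module_resolution` (default 4.0 in the analysis
configuration, matching the ~10-gene module scale; `detect_modules`
itself defaults to resolution 1.0, the classical modularity scale).
`avg_pcc` is always reported on the raw signed correlation scale.

## Promoter scanning

Count matrices become frequency profiles with pseudocount 1e-4
(avoids log of zero in the information weights);
I(i) = sum_b f(i,b) ln(4 f(i,b)) weights each position, and the five
consecutive positions with the largest total information form the core
(leftmost on ties). A window's matrix similarity score is the
information-weighted frequency sum min-max normalized to [0, 1], so the
consensus scores exactly 1 and the anticonsensus 0; the core similarity
score is the same quantity on the core positions. Ambiguous bases score
as the position minimum. Both strands are scanned; hits must pass the
core cutoff (default 1.0, the strictest setting) and then a per-matrix
MSS cutoff (`mss_cutoffs`, falling back to 0.95) — vendor-calibrated
minimum-false-positive profiles are proprietary, so cutoffs are explicit
user inputs here. Promoters are the `promoter_length` (default 2000)
bases upstream of the TSS, 0-based half-open, reverse-complemented on
the minus strand and truncated at contig boundaries.

## The synthetic study design

`simulate_all` emulates the three-series design the pipeline targets:
one normal series with 4 populations x 4 samples, and two stem-cell
series with 4 subtypes x (CSC, non-CSC) x 4 samples, 2000 genes.
Baselines are N(8, 1) log2 units with N(0, 0.5^2) sample noise; each
population has 150 over- and 150 under-expressed genes at ±2 log2 units;
each subtype's CSC signature takes 60% of its genes from its true
origin's signature (`shared_fraction`) and the rest from background.
The two stem-cell series differ by an independent noise draw and a
per-gene N(0, 0.2^2) series offset, exercising the cross-series
intersection and overall-rank averaging. The network connects each
signature set through a hub (planted shared genes sit within distance 2)
plus cliques for planted modules and 4000 uniform background edges
(average degree ~4, the sparsity regime of curated human interaction
networks). The ontology annotates each signature set to its own branch
of leaf terms under a single root, with background genes on noise terms,
so semantic similarity peaks at the true origin. Planted co-expression
modules (two of 10 genes per condition; the cross-condition pair shares
8) receive a shared latent factor inside the noise at correlation 0.9,
standardized over the condition's samples so the realized in-sample
shared variance is exact — the marginal noise variance is unchanged and
signature calling is unaffected. Promoters of module genes carry one
exact consensus site of a designated matrix; control promoters carry
none. `simulate_null` forces the shared fraction to 0 and draws CSC
signatures uniformly over all genes, for calibrating the fusion's
false-positive behavior. Everything derives from one integer seed.

What the generator does **not** emulate: probe-level artifacts and
normalization residue, correlated (batch) noise, heavy-tailed expression,
partial signature overlap between populations, scale-free network
topology, ontology depth and annotation sparsity of real GO, or motif
degeneracy beyond the count matrix itself. Passing tests therefore
demonstrate correctness and calibration of the machinery under a clean
generative model, not performance on real arrays.

## Numerical and degenerate-input conventions

Identical constant genes in a contrast get p = 1 and no call. A NaN
measure propagates to fusion by list removal, never by silent dropping
of a candidate. Degenerate PWM windows with Max = Min score 1 by
convention with a warning. Zero-variance genes give their network edges
weight 0. Duplicate expression rows collapse by the arithmetic mean of
log2 values. All tie-breaks (fusion order, module ordering, pair
ordering, core window) are deterministic; every stochastic step takes an
explicit seed. Floats are serialized with 6 significant digits.

## Problem sizes used in verification

The oracle checks enumerate all hypergeometric problems with universe
<= 15 (tests) / <= 12 (acceptance script), compare the Q statistic with
a 10^6-draw (tests) / 2x10^5-draw (script) Monte-Carlo order-statistics
oracle for N = 2..8, and a dense all-pairs BFS oracle on 50-node random
graphs. End-to-end recovery uses 100 simulation seeds at the default
conditions and 200 null seeds; the module stage uses 10 seeds (40
planted modules, ~1800 null modules). These sizes give binomial
uncertainties well below the asserted margins.

## Known limitations

Cross-series contrasts assume comparable scales between matrices; only
a crude standardization switch is provided. Q values across candidates
with unequal N are compared as probabilities without a small-N
correction. The IC corpus is the supplied annotation set, so similarity
values are not comparable across different annotation files. With very
few samples per condition the module stage's correlation filter has low
power per edge; it is reliable only in aggregate over a module's edges.
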