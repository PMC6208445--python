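# Methods

`floranet` reconstructs and analyses the gene-regulatory meta-network of
early flower development in *Arabidopsis thaliana*: the joint action of
master-regulator transcription factors (the MADS-box and associated
factors FLC, FLM, SVP, SOC1, LFY, AP1, AP2, AP3, PI, SEP3, AG, BLR, JAG,
ETT, RGA) and microRNAs on downstream TF genes. This note documents the
models, the statistical procedures, the synthetic-data generator that
stands in for the original sequencing data, and the numerical choices
made where the design was open.

## Coordinates and target assignment

All genomic intervals are handled 0-based half-open (BED convention);
GFF3 input (1-based inclusive) is converted once at the parsing boundary.
A gene is called a target of a TF when a binding event lies within a
window (default 3 kb, inclusive bound) of the gene's strand-aware TSS.
The binding point of a peak is its summit when reported, otherwise the
interval midpoint; distance is signed (negative = upstream). The window
is applied symmetrically — upstream and downstream — and one peak may be
assigned to several genes whose windows it falls in. Per (TF, stage,
gene) the maximum peak score and minimum |distance| are kept.

Co-binding between two TFs is the base-pair Jaccard index of their merged
peak sets; co-regulation is a one-sided hypergeometric test of
target-set overlap against the annotated-gene universe, P(X >= k) with
X ~ Hypergeom(N, K, n).

## Stage-series expression and the DE surrogate

Stage profiles summarize an FPKM-like matrix over four stages (S0, S2,
S4, S8 by default) as replicate means. The fold-change statistic is the
maximum |log2 ratio| between any two pseudocounted stage means
(pseudocount 1, configurable, shared across the package). A gene is
flagged differentially expressed when that statistic is >= 1 (two-fold)
and a per-gene one-way ANOVA across stages on log2 values passes a
Benjamini–Hochberg FDR of 0.05. This is a deliberate, self-contained
surrogate for a full count-model DE pipeline: it requires only the
abundance matrix, and externally computed DE labels can be substituted
and then take precedence.

The binding-degree analyses group genes by the number of distinct TFs
bound; consecutive groups are compared with two-sided Mann–Whitney tests
(exact U distribution for small tie-free samples, otherwise the normal
approximation with tie correction). The hub analysis compares the
per-in-degree gene histogram to a randomized null. Two nulls are
implemented: `resample` (default) keeps every TF's out-degree and redraws
its targets uniformly from the bound-gene universe, which is the
comparison under which genuine hubs stand out; `swap` performs
double-edge swaps preserving both degree sequences and serves as a
structural control — under it the histogram is invariant by construction,
since the per-degree counts are a function of the preserved in-degree
sequence alone.

## The meta-network

The meta-network is a typed directed graph. Node roles: `regulator`
(ChIP-profiled master TF), `miRNA` (expressed miRNA gene), `tf_target`
(stage-responsive TF gene); a master regulator that is itself a
responsive TF target is one node carrying both flags, so motif counts
never double-count it. Edge types: `binds` (regulator occupancy within
the TSS window of a miRNA or TF-gene locus) and `silences`
(miRNA-to-mRNA repression from a target-prediction table). Role/type
constraints — binds edges originate only from regulators, silences edges
only from miRNAs and only onto TF genes — are validated on every
construction. The default network is the union over stages;
stage-resolved networks come from filtering assignments by stage label.

## Motif census and null model

One-node motifs are autoregulatory self-edges; two-node motifs are
mutual pairs (any edge types, e.g. the AP2–MIR172 feedback); three-node
motifs are the 13 connected directed triad isomorphism classes in
Holland–Leinhardt MAN notation. The census ignores edge types (direction
only) and self-edges; it is computed through igraph's C-level triad
census after collapsing the typed graph, and is verified in the test
suite against an independent all-triples enumerator with canonical-code
classification. The feed-forward-loop topology is the transitive triad
030T.

The null model rewires by double-edge swaps restricted within each edge
class (TF→miRNA binding, TF→TF binding, miRNA silencing). This preserves
every node's per-class in- and out-degree, hence the layered structure of
the network; swaps that would create a self-edge or duplicate an ordered
pair are skipped, and existing self-edges are excluded from the pool, so
the autoregulation count is identical in every null draw (the census
ignores them anyway). About 10 × |E| swaps are attempted per draw.
Enrichment per class is reported as z = (obs − mean)/sd over the
ensemble, an empirical one-sided p = (1 + #{null ≥ obs})/(n_rand + 1),
and a Benjamini–Hochberg adjustment across the 13 classes. When the null
is degenerate (sd = 0) the z-score is reported as NaN and the empirical p
carries the conclusion. Note the structural floor of this construction:
the smallest achievable adjusted p is 13/(n_rand + 1) when a single class
is enriched, so resolving adjusted p below 0.05 requires an ensemble of
at least ~260 draws (the default is 1000).

A single-input module (SIM) is a regulator with a pair of bound TF
genes; a regulator with k targets contributes C(k, 2) pairs. The SIM–PPI
analysis asks whether regulators preferentially target physically
interacting pairs: per regulator, the observed percentage of its SIM
pairs present in the PPI table is compared with the mean percentage over
same-size target samples drawn from the union of all regulators'
targets; the two per-regulator vectors are compared with a two-tailed
two-sample Student's t-test (a paired variant is available).

## Feed-forward loops

An FFL is a triple (regulator, miRNA, target TF) with binds edges
regulator→miRNA and regulator→target and a silences edge miRNA→target.
Enumeration walks each regulator's bound miRNAs and their silencing
targets; it is exact and is checked against a brute-force triple scan.
Loops whose target is itself a master regulator are retained and flagged.

Arm signs are inferred as the sign of the Pearson correlation between
the two genes' stage-mean profiles when |r| >= 0.5 (configurable), else
unknown; an explicit user sign table overrides inference. The miRNA arm
is fixed repressive, so the indirect path sign is the negation of the
regulator→miRNA sign; a loop is *coherent* when the indirect sign equals
the direct-arm sign. Coherence is therefore invariant under jointly
flipping both inferred arms.

A loop is *developmentally dynamic* when its miRNA is DE across stages
or the regulator's binding score at either loop locus changes by >= 1
log2 unit (pseudocounted) between any two stages. Both the correlation
rule and the binding fold-change rule are explicit surrogates for
judgement calls the original analysis does not quantify, and both
thresholds are exposed as parameters.

## Robustness under targeted attack

Connectivity loss is measured on the undirected simple view: loss = 1 −
R/R0, where R counts unordered node pairs still connected (removed nodes
count as disconnected endpoints) and R0 is the intact network's count.
The default attack is cascading: betweenness centrality is recomputed
after every removal and the top node (ties broken lexicographically) is
removed. Cheaper `betweenness_initial`, `degree`, and seeded `random`
orders are provided as controls. Curves are compared as two samples of
loss values with a two-sided two-sample Kolmogorov–Smirnov test, plus the
trapezoidal area under the loss curve as an effect size (larger = more
fragile). Dropping silences edges before the attack yields the
"without miRNA regulation" comparator; on synthetic networks the
stripped network is reliably more fragile, mirroring the redundancy
miRNA-mediated edges contribute. The full cascade is O(n·m) per step;
analyses on paper-scale networks therefore default to a truncated
cascade (`max_fraction`), which preserves the comparison since losses
are accumulated identically on both networks.

## Domain-specific genes and quartet targets

Translatome abundances for the AP1, AP3 and AG expression domains at
stages S4 and S6 are screened per stage by a one-way ANOVA across the
three domains (log2, pseudocounted, replicate-level) combined with a
>2-fold filter on the largest pairwise ratio of domain means. Categories
follow the pairwise pattern of domain means: `X_specific` requires
mean(X) > 2× both others; `AP1_AP3_common` (petal) requires AP1 and AP3
both > 2× AG *and* neither > 2× the other — the second clause is our
disambiguation that prevents a gene from qualifying as both specific and
common; `AP3_AG_common` (stamen) is symmetric. A gene passing at both
stages must agree on the category, otherwise it is dropped to `none`
with a flag. With a single replicate the ANOVA is skipped (fold-change
mode, warned).

The floral quartet model fixes the organ complexes — sepal {AP1, SEP3},
petal {AP1, AP3, PI, SEP3}, stamen {AP3, PI, AG, SEP3}, carpel {AG,
SEP3}, with SEP represented by SEP3 throughout — and organ target sets
are plain intersections of the member TFs' ChIP target sets; a gene may
belong to several organs.

## Binding-to-expression model

For a pair of domains, the response Y_i is the average over S4 and S6 of
the log2 ratio of pseudocounted domain means for gene i; features x_ij
are per-TF binding scores (0 for unbound), scaled to unit variance and
mean-centered. The model Y_i = Σ_j β_j x_ij + ε_i is fitted with the
Lasso along a log-spaced penalty path; the penalty is selected by five
repeats of ten-fold cross-validation. Selection uses the
one-standard-error rule by default: the largest penalty whose mean CV
error is within one SE of the minimum, with the SE computed glmnet-style
over the n_folds fold groups (repeats are averaged; fold errors are
positively correlated across repeats, so dividing by the total fold
count would understate the SE). The raw CV-minimum is available via
`rule="min"`; it predicts marginally better but retains spurious
near-zero coefficients and does not recover sparse supports — the 1-SE
rule is the standard parsimony choice for interpreting which TFs drive
an organ contrast. The intercept is fitted but unpenalized; on centered
data it is ≈ 0 and is reported.

## Synthetic data generator

The generator replaces the study's raw sequencing data with a fully
planted synthetic study; its defaults are the published scale: 15 master
regulators, 144 expressed miRNA genes, 674 stage-responsive TF genes,
422 TF→miRNA and 273 miRNA→TF edges, 11 autoregulators, 1500 random
TF→TF-gene binding edges, 50 planted FFLs of which 73.3% are made
developmentally dynamic (half via a ≥4-fold miRNA expression change,
half via a 4-fold stage ramp of a binding score — 4-fold rather than
2-fold so the planted change clears the 1 log2-unit rule after the
shared pseudocount), 10 hub genes bound by 10 regulators each, a
translatome of 1013 category genes (66.9% of them bound by ≥2
regulators, emulating the observed binding/specificity coupling) plus
1000 null genes with 4-fold domain effects, PPI tables with a 5×
enrichment among co-targeted pairs at 5% background density, and a
sparse regression truth with 4 nonzero coefficients {±0.5, ±1} among 11
TFs at noise sd 0.5, n = 678. Expression uses log-normal replicate noise
at 20% CV over 4 stages × 3 replicates; a TF gene's planted fold change
grows with the number of regulators binding it (slope 0.3 per extra TF),
emulating the observed coupling of combinatorial binding and expression
dynamics. Genes that the study design declares detectably expressed
(responsive TF genes, dynamic-loop miRNAs) have floored baselines so
their planted changes are not erased by the pseudocount.

Genes are laid out one per 10 kb so that ±3 kb TSS windows never
overlap; every binding edge is realized as one peak per stage with its
summit within 2.5 kb of the target TSS, and decoy peaks (10% rate) are
placed mid-gap, beyond 3 kb of any TSS — target assignment on the
emitted peaks reconstructs the planted edge list exactly. Planted FFLs
use pairwise-disjoint miRNAs and targets so each loop's dynamic status
and arm signs are independent; all incidental FFLs closed by the random
fill are enumerated into the truth by brute force (an optional
closure-avoidance mode rejects closing edges instead). Every generator
stage draws from its own seeded stream, so outputs are byte-identical
for a given seed regardless of which stages are invoked.

What the generator does *not* emulate: read-level noise and mapping
artifacts, peak-calling uncertainty, correlated replicate structure,
genome sequence context, miRNA target-prediction error, and
regulator→regulator cross-regulation edges in the random fill (planted
autoregulation aside). Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
generative assumptions, not end-to-end performance on raw sequencing
data.

## Problem sizes and numerical choices

Analyses that are quadratic-or-worse run on proportionally scaled
networks in the routine test-suite configuration (15 regulators, 40
miRNAs, 120 TF genes, 110/70 typed edges) and at the full published
scale where the check depends on it (network counts, dynamic-loop
fraction, domain classification, Lasso recovery). The attack-curve
comparison truncates cascades at 15–30% of nodes removed. Ties in the
attack order break lexicographically; duplicate input edges merge with
pooled provenance; zero-variance regression features are dropped with a
warning; hypergeometric and Mann–Whitney routines are validated against
exact enumeration oracles to 1e-10 and machine precision respectively.

## Known limitations

The DE caller and the dynamic-binding rule are declared surrogates (see
above), sign inference needs at least three stages and a genuinely
varying profile, the swap null conditions on the typed degree sequences
(stricter than a size-and-density null), and the empirical-p floor makes
BH-adjusted motif significance unresolvable below 13/(n_rand + 1) when
only one class is enriched — use n_rand >= 1000 (the default) when
adjusted significance matters.
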