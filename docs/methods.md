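# Methods

This note records the models, algorithms and numerical choices behind
`cienet`, and what the synthetic-data tests do and do not establish.

## Study design and data model

The pipeline targets the standard CIE (chronic intermittent ethanol)
time-course design: two treatment arms (CIE vapor vs air control), four
collection points (0 h, 8 h, 72 h after the last exposure cycle, and 7 d
of abstinence), n = 6 animals per treatment/time cell, arrays hybridized
in batches, one brain region analyzed at a time. Expression values are
taken to be log2-scale summaries (RMA-style); nothing in the pipeline
re-logs the data, and one region is always one independent analysis.

## Synthetic cohort generator

`cienet.simulate` draws from a latent-factor model — the minimal
generative process under which correlation-network module recovery is a
well-posed question. Gene g in module m, sample s:

    x_gs = mu_g + l_g * F_m(s) + gamma_g(batch(s)) + eps_gs

- `mu_g ~ N(8, 1)`: baseline log2 level.
- `F_m(s) = z_s + e_m * sigma * w_m(t(s)) * [s is CIE]`, with `z_s ~ N(0,1)`
  the shared per-sample factor noise, `e_m` the module effect size (units:
  noise SD, default 4), `sigma` the noise SD (default 0.5) and `w_m` the
  kinetic profile weight per time point:
  null (0,0,0,0); decay (1, 0.5, 0, 0); withdrawal peak (0.25, 1, 0.25, 0);
  biphasic (1, 0, 0, 1); persistent (1, 1, 1, 1).
- `l_g`: loading with magnitude uniform in (0.5, 1.0) and **random sign**.
  Signed memberships are what an unsigned co-expression network expects
  (modules contain anti-correlated genes), and they keep per-sample value
  distributions comparable across groups. Without them, quantile
  normalization of a matrix where half the genes shift in one direction
  warps background genes in a treatment-correlated way, creating structure
  no module detector should be expected to undo.
- `gamma_g ~ N(0, 0.4)` per non-reference batch: additive per-gene batch
  shift. Batches are interleaved within each treatment/time cell so batch
  is never confounded with the design.
- Default shape: 2,000 genes, five modules of 100/150/200/250/300 genes
  (one per profile), 900 background genes of pure noise, 48 samples, two
  batches. The effect size of 4 noise-SD gives gene-level peak shifts of
  0.5–1 in absolute loading terms, i.e. 1–2 log2 units — strong but
  plausible responders — so that the default cohort exercises every
  pipeline stage (nonempty DE sets, enrichment-positive modules) at
  n = 6/group.

The generator returns the planted truth (labels, factors, loadings, batch
coefficients, per-gene planted group differences), which the tests use for
parameter recovery. What passing these tests shows: the pipeline recovers
structure of the kind it assumes (linear factors, additive batches,
Gaussian noise). What they do not show: robustness to heavy-tailed noise,
probe-level artifacts, outlier arrays, or correlated background — real
microarray pathologies the generator deliberately omits.

Synthetic 3'UTR sets plant the reverse complement of a query motif in an
exact fraction of sequences; the remainder are rejection-sampled to be free
of every ≥6-base window complement of the seed region, so match fractions
at seed lengths 6–8 equal the planted fraction exactly.

## Normalization and batch adjustment

Two-stage normalization: quantile-normalize within each hybridization
batch, concatenate, quantile-normalize all arrays together, then apply a
parametric empirical-Bayes location/scale adjustment. Quantile
normalization maps each column onto the across-column mean of order
statistics; ties receive the mean reference value over the tied ranks (the
common dialect). It is idempotent to 1e-10.

The batch adjustment standardizes each gene after removing covariate-group
means (treatment × time is protected by default — erasing it would erase
the very contrasts tested downstream), estimates per-batch locations and
scales, shrinks them toward normal / inverse-gamma priors fitted by
method of moments, and iterates the posterior equations to a 1e-8 fixed
point. Genes whose batch + group model fits exactly (zero residual
variance) are passed through unchanged — there is nothing left to
standardize. Only the parametric variant is implemented. The residual
*systematic* batch shift after adjustment is ~0.01 log2 units on planted
data; per-gene batch differences keep their irreducible sampling noise.

## Moderated differential expression

One cell-means model per gene over the 8 design cells; residual variance
s²_g pools all cells (df = n − 8). Empirical-Bayes moderation follows the
standard log-variance moment matching: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior df d₀ solves
ψ′(d₀/2) = var(e) − ψ′(d_g/2) (Newton iteration on the inverse trigamma,
tolerance 1e-10; d₀ = ∞ when the moment estimate is non-positive, in which
case the normal/χ² limits replace the t/F distributions). The contrast
CIE − Ctrl at each time point uses t = coef/(s̃_g·√(2/6)) on d₀ + d_g df;
the overall test is a moderated one-way F across the 8 groups (df1 = 7).
Constant genes are flagged and excluded from moderation and from the FDR
families. FDR is computed per contrast (per-column), Benjamini–Hochberg.
Against the reference empirical-Bayes implementation the t-contrast path
agrees to ~1e-14 on a fixed fixture (frozen oracle constants in the test
suite); the one-way F is intentionally different from the reference
default, which tests the four contrasts jointly (df1 = 4).

## Network construction and module detection

Unsigned Pearson adjacency raised to β (default 6; `pick_soft_threshold`
reports the signed scale-free fit R², regressing log10 binned frequency on
log10 mean connectivity over ≤10 equal-*width* bins — equal-count bins
would make the frequency constant by construction). Topological overlap is
the standard unsigned form with unit diagonal; 1 − TOM feeds
average-linkage clustering (`scipy.cluster.hierarchy`).

The tree cut is a documented stand-in for the published hybrid dynamic
cut, with the planted-module recovery ARI as its behavioral contract:

1. **Static cut** at `h_frac(ds) × root height`, deep split ds ∈ {0,1,2,3}
   mapping to fractions 0.990 / 0.985 / 0.980 / 0.972 — deeper splits cut
   lower, yielding more and smaller branches.
2. **Compactness filter**: a branch is kept only if the median of its
   internal merge heights is ≤ `core_frac(ds) × cut height`
   (0.90 / 0.93 / 0.96 / 0.98). Random agglomerations assemble just below
   the cut; genuine modules assemble far lower.
3. **Size filter**: branches smaller than `min_module_size` (default 30,
   consistent with reported smallest modules just under 35) go to grey.
4. **Membership purification**: genes whose |cor(gene, module eigengene)|
   (kME) is < 0.5 are released to grey, the eigengene is re-estimated, and
   undersized modules dissolve (2 passes). This removes background genes
   that average linkage accretes near the cut height; on the default
   design it is the difference between ARI ≈ 0.78 and ARI ≈ 0.95–0.99.

Modules are named by decreasing size along the conventional color
sequence (turquoise, blue, brown, ...); grey is reserved for unassigned
genes. No eigengene-similarity merging is applied (exposed nowhere; the
source analyses do not describe merging).

Deep-split selection ("auto") embeds genes in 2-D by classical (Torgerson)
MDS of 1 − TOM and scores each partition by the per-module fraction of
genes lying nearer another module's centroid; a partition is
non-overlapping when every module scores ≤ 0.05 (a numeric
operationalization of a visual criterion), and the largest non-overlapping
deep split wins. On data whose modules do not separate pairwise in two
dimensions this conservatively picks a shallower split; the acceptance
recovery property therefore pins deep split 2 explicitly.

Eigengenes are the first right singular vector of the standardized module
(unit norm), sign-oriented to correlate positively with the module's mean
standardized profile; variance explained is the first squared singular
value over the total. kIM(g) sums a gene's adjacencies to same-module
partners; scaled kIM divides by the module maximum (grey and singleton
modules get 0).

## Validation and overlap enrichment

Module validation compares observed mean off-diagonal within-module TOM
with the same statistic on `n_permutations` (default 100) gene sets of
identical size drawn **without replacement** from the network genes.
z = (obs − null mean)/null sd; p is the one-sided upper normal tail (with
100 permutations an empirical tail would floor at 0.01); BH FDR across
modules, significant at FDR ≤ 0.2; grey is excluded from the family.

Overlap enrichment: one-sided hypergeometric p = P(X ≥ a) plus the
cross-product odds ratio with Haldane 0.5 correction when a cell is zero
(the conditional-MLE variant differs negligibly at these table sizes; the
sample OR is deterministic and transparent). The compound significance
rule is p ≤ 0.005 AND OR > 3; the two-sided exact p is also reported but
does not drive flags. Note the published worked overlap (104 shared genes
between sets of 796 and 556 in a universe of 10,072) is significant by p
(1.8e-17) while its OR is 2.93 — the compound rule is for module×DE cells,
not for that statistic.

## Candidates and seed scan

Hub candidates: genes with DE FDR ≤ threshold at 0 h **or** 7 d, ranked by
scaled kIM descending, ties broken lexicographically by gene id, top 30 by
default. The seed scan declares a sequence a match if it contains the
reverse complement of any length-k window of the query motif's first 8
bases (k ≤ 8); the fraction matched is non-increasing in k. This direct
complement count replaces upstream motif-inference machinery while keeping
the same readout form (percent of sequences with 6/7/8-base matches).

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale by design: 2,000-gene
cohorts (dense 2,000² TOM ≈ 32 MB, seconds to build), 100-gene null
networks for permutation calibration (50 replicates), 400-gene cohorts for
the 20-replicate kinetic-fidelity check, 2,000-gene null matrices for
calibration and power. Exact oracles (BH step-up, triple-loop TOM,
hypergeometric enumeration for universes ≤ 60, naive seed scan) are exact
to 1e-9–1e-12. Statistical checks use fixed seeds with margins chosen from
the binomial/Monte-Carlo error of the check itself (e.g. type-I error in
[0.03, 0.07] at 2,000 genes; biphasic gap pattern in ≥ 14/20 replicates
against a 1/6 chance rate).

## Known limitations

- The tree cut is not the published hybrid algorithm; outside the tested
  regime (very unequal module tightness, nested modules) its behavior may
  differ from the reference implementation.
- The permutation null uses a normal tail for p; for very small networks
  the normal approximation of the permuted mean-TOM distribution thins.
- ComBat-style adjustment assumes additive/multiplicative batch effects on
  standardized data; batch × treatment interactions are out of model.
- The generator's Gaussian, independent-background world is a lower bound
  on difficulty; real-data performance claims require real data.
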