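# cienet

Time-course co-expression analysis of chronic intermittent ethanol (CIE)
exposure in brain tissue, packaged as a tested, reusable pipeline.

Studies of alcohol dependence expose mice to repeated cycles of ethanol
vapor (CIE) and profile brain-region transcriptomes at several withdrawal
time points (0 h, 8 h, 72 h, 7 d; CIE vs air controls, n = 6 per
treatment/time group). The analytical chain those studies rely on —
normalization and batch adjustment, moderated differential expression,
weighted co-expression modules, permutation validation, module–DE overlap
enrichment, eigengene kinetics, and hub-gene ranking — is implemented here
end-to-end, and exercised on synthetic data with planted structure so every
stage can be checked against known ground truth.

## What the package computes

- **Normalization** (`cienet.preprocess`): per-batch quantile
  normalization, a second global quantile pass, then parametric
  empirical-Bayes location/scale batch adjustment (ComBat-style) that
  protects the treatment × time group means. PCA scores support QC.
- **Differential expression** (`cienet.diffexpr`): an 8-group cell-means
  model per gene; residual variances are shrunk by empirical Bayes
  (s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), method-of-moments (d₀, s₀²)),
  giving moderated t contrasts CIE − Ctrl at each time point and a
  moderated one-way F across the 8 groups, with Benjamini–Hochberg FDR.
- **Network** (`cienet.network`): unsigned weighted adjacency
  a_ij = |cor(x_i, x_j)|^β (default β = 6, chosen by scale-free fit),
  topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
  average-linkage clustering of 1 − TOM with a deep-split-parameterized
  cut, eigengenes (first PC of the standardized module), intramodular
  connectivity kIM, and eigengene time courses.
- **Validation & enrichment** (`cienet.enrichment`): each module's mean
  within-module TOM is compared with 100 random same-size gene sets
  (z-score, one-sided normal p, BH FDR ≤ 0.2); module–DE overlap uses the
  one-sided Fisher exact test with the compound rule
  p ≤ 0.005 AND odds ratio > 3.
- **Candidates** (`cienet.candidates`): genes DE at 0 h or 7 d ranked by
  scaled kIM (hub candidates), and a microRNA seed-complement scan
  reporting the fraction of sequences carrying the reverse complement of a
  6–8-base seed.
- **Synthetic data** (`cienet.simulate`): a latent-factor generator
  planting co-expression modules with treatment × time kinetic profiles
  (null, decay, withdrawal-peak, biphasic, persistent), batch shifts and
  Gaussian noise, returning the planted truth for recovery tests.

## Worked example

```python
from cienet.simulate import SyntheticDesign, simulate_expression
from cienet.types import RunConfig
from cienet.pipeline import run_pipeline

em, truth = simulate_expression(SyntheticDesign(rng_seed=1))
run_pipeline({"PFC": em}, RunConfig(deep_split=2, rng_seed=1), "out")
```

On this default design (2,000 genes, five planted modules, 48 samples) the
pipeline selects 654 ANOVA-significant genes (FDR ≤ 0.01) for the network
and recovers the DE-responsive planted modules essentially perfectly
(adjusted Rand index 0.99 against the planted labels on the selected
genes). The validation table shows all three detected modules passing the
permutation test by wide margins:

```
   module  size  observed          z            fdr  significant
turquoise   300  0.396238  60.625212   0.000000e+00         True
     blue   201  0.370267  32.124591  1.500022e-226         True
    brown   135  0.279830  14.840198   4.025911e-50         True
```

and the overlap matrix flags the biologically coherent cells — e.g. the
turquoise (persistent-profile) module is enriched for DE genes at every
early time point (p = 5.5e-83 at 0 h, OR = 39), while the blue
(biphasic-profile) module is the one enriched at 7 d (p = 7.2e-11,
OR = 3.7). The same run ranks hub candidates by scaled kIM; the top ten are
all high-loading members of the persistent and biphasic planted modules.

The numbered drivers under `analysis/` replay this cohort stage by stage
(`01_simulate_cohort.py` … `06_candidates_seedscan.py`) and write their
tables under `results/`; each prints a short narrative of what it found.

A command-line interface mirrors the stages:

```bash
cienet simulate --seed 1 --outdir sim
cienet run-all --region PFC:sim/expression.tsv:sim/metadata.tsv --seed 1 --outdir out
cienet seedscan sim/utr_sequences.fasta --motif TGAGGTAGTAGGTTGT --k 8
```

## Layout

```
src/cienet/       library (types, io, simulate, preprocess, diffexpr,
                  network, enrichment, candidates, pipeline, cli)
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, and acceptance tests)
scripts/          acceptance.py
docs/methods.md   modeling and algorithmic notes
```
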