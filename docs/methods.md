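# Methods

This note records the statistical model, the parameter choices and their
rationale, what the synthetic data generator does and does not emulate,
and the numerical conventions that make results reproducible.

## 1. Region matching by rank differences

### Model and assumptions

The query is a bulk RNA-seq profile (counts, typically 2–3 replicates of
one culture condition); the reference is a microarray-style atlas of brain
regions sampled at several developmental stages, with one or more donors
per stage. The two platforms measure expression on incomparable scales, so
the matching statistic uses only **within-profile ranks**, under these
assumptions:

- Relative expression ordering across genes is largely preserved between
  platforms for the same biological state (the standard justification for
  rank-based cross-platform comparison).
- Regions at the same stage form a fair exchangeable background for one
  another: they were profiled on the same platform, with the same probe
  set and the same donors.
- Replicates and donors can be averaged before ranking (arithmetic mean on
  the analysis scale: log2(CPM + 1) for the query, the atlas's native
  log-intensity scale for the reference).

### Procedure

Given a shared gene index of size *G* (intersection of query genes and
probe-to-gene-mapped atlas probes, with multi-probe genes collapsed by
mean or median):

1. Rank the query profile and each region's stage-averaged profile
   (ranks `1..G`, average ranks at ties).
2. Per gene, compute the absolute rank difference
   `d_g = |rank_query(g) − rank_region(g)|` (a signed variant is
   available; signed differences of tie-free profiles sum to zero, which
   is used as an internal consistency check).
3. Score region *r* at stage *s* with a one-sided Wilcoxon rank-sum test:
   are *r*'s *G* differences stochastically **smaller** than the pooled
   differences of all other regions at stage *s*? The pooled background is
   capped at `background_cap × G` values (default 10 × *G*), subsampled
   without replacement with a seeded generator, so the test's
   computational cost and null behaviour do not depend on atlas size.
4. Report `−log10 p` per region, sorted descending (ties broken by region
   id for determinism).
5. Aggregate to structures with a second, one-sided rank-sum test of the
   member regions' `−log10 p` values against the non-members' (alternative
   "greater"). This is deliberately rank-based again: it asks whether the
   structure's regions are *consistently* near the top, not whether any
   single member is extreme.

Because steps 1–2 only use ranks, the whole pipeline is invariant under
strictly increasing transforms of the query — verified by a test that
feeds `3·log1p(x) + 7` and requires bit-identical output tables.

### Why a background of other regions, not a theoretical null

Rank differences between two *independent* random permutations have a
known distribution, but real profiles are far from independent: most genes
have conserved housekeeping ordering, so observed differences are much
smaller than the theoretical null everywhere. Testing against the
*empirical* background of sibling regions asks the practically relevant
question — is this region a better match than its peers — and is robust to
the global correlation level.

### Interpretation caveats

The per-region p-values are comparative, not absolute: a query unrelated
to the atlas still produces a best-ranked region, just without a small
p-value. The permutation analysis (100 gene-shuffled queries, family-wise
Bonferroni bound 0.05/30) shows that unrelated queries essentially never
reach significance, which is the intended guard against over-reading a
top rank.

## 2. Wilcoxon rank-sum implementation

- **Exact branch** (pooled *n* ≤ `exact_limit`, default 20): with average
  ranks at ties, doubled ranks are integers, so the exact tail probability
  is computed by a dynamic program over achievable doubled rank-sums
  (subset-size × sum table, descending-size update to avoid reuse of a
  rank within a subset). This handles ties exactly; it is validated
  against literal enumeration of all label assignments over 1000 random
  tied cases.
- **Normal branch** (larger *n*): mean `n1(N+1)/2`, tie-corrected
  variance `n1·n2/12 · (N+1 − Σ(t³−t)/(N(N−1)))`, continuity correction
  0.5, and the tail computed with `norm.logcdf` in log space so that deep
  tails (−log10 p in the hundreds) are representable rather than
  underflowing to 0.
- The two branches agree to |Δp| ≤ 0.01 at the crossover size.
- `−log10 p` is capped at 320 (just inside double precision's
  smallest-subnormal range); p-values are floored at 5e−324 before the
  log. The default exact limit 20 keeps the exact branch essentially free
  while covering all structure-level tests at realistic atlas sizes.

## 3. Normalization

- **CPM** and **RPKM** use the standard closed forms; effective library
  sizes may include TMM factors.
- **TMM** follows the published trimmed-mean-of-M-values procedure:
  M/A values against a reference library (chosen as the library whose
  upper quartile of scaled counts is closest to the mean), double trimming
  that removes the stated fraction from **each** tail (30% of M-values and
  5% of A-values per tail, rank-based with average ranks at ties), and a
  precision-weighted mean of surviving M-values with delta-method weights
  `(N−y)/(Ny)`. If all M-values are below 1e−6 in magnitude the factor is
  exactly 1. Factors are rescaled to geometric mean 1. The implementation
  reproduces edgeR's `calcNormFactors` to all printed digits on shared
  test data.
  One subtlety: TMM factors are *approximately*, not exactly, invariant
  to pure depth scaling of a library, because the precision weights depend
  on counts; the deviation is ~0.6% on typical data and the invariance
  test allows 2%.
- **log2-CPM (voom convention)**: `log2((count + 0.5)/(lib·factor + 1)·1e6)`.
- The query side of region matching uses plain `log2(CPM + 1)`; any
  monotone choice gives identical match results (see §1), so the simplest
  convention is used there.

## 4. Differential expression (simplified limma-voom)

A deliberately simplified pipeline, adequate for well-replicated two-group
designs:

1. Filter to genes with CPM ≥ 1 in **all** replicates of at least one
   group.
2. TMM-normalize; transform to voom-style log2-CPM.
3. Per gene, a pooled-variance two-sample t-test
   (df = n1 + n2 − 2). Pooled variances are floored at `var_floor`
   (1e−8 on the log2 scale) and flagged `low_variance`, preventing
   spuriously extreme statistics from near-constant genes.
4. Benjamini–Hochberg adjustment (via `statsmodels`, cross-checked
   against a direct O(m²) min-over-tails oracle).
5. A gene is *significant* iff adjusted p < `alpha` (0.01) **and**
   |log2 fold change| ≥ `lfc_threshold` (1.5 log2 units).

This omits limma's empirical-Bayes variance moderation and voom's
mean-variance weights, hence "approximate limma-voom" in the result
summary. Calibration is verified empirically: on null negative-binomial
data (3 vs 3, 2,000 genes, 10 simulations) the raw-p false-positive rate
at α = 0.01 stays inside its binomial 99% band, and power at
|log2FC| = 4 with low dispersion is 1.0.

## 5. Synthetic data generator

The generator's defaults define the study conditions: 2,000 probes
(1:1 probe→gene map), 30 regions in three structures (5 brainstem,
20 cortex, 5 cerebellum), three stages (`adult`, `pcw15_16`, `pcw21_22`)
× two donors = 180 atlas samples; query = 3 negative-binomial replicate
libraries (mean depth 5e6, dispersion 0.1) drawn from one region-stage
profile.

Signal structure, on the atlas's log2 scale (baseline N(6, 2), sample
noise SD 0.5):

- **Region signatures**: each region elevates its own disjoint 50-probe
  set by 2.0 — the identity signal for region recovery.
- **Structure cores**: each structure elevates a 60-probe set by 0.5 at
  every stage — a modest stage-invariant family resemblance.
- **Stage-specific structure markers**: per (structure, stage), a
  100-probe subset of a shared 320-probe developmental pool is elevated
  by 1.0. This is the deliberate design choice that makes *stage*
  recoverable: a globally shared stage shift would enter every region's
  rank-difference vector identically and cancel out of the
  region-vs-background test, so stage identity must be carried by
  markers that differ *between structures within a stage*.

Counts are negative-binomial with variance μ + φμ² (Poisson when
φ ≤ 1e−12); region coordinates are clustered in 3-D around per-structure
centres for the voxel-score export.

**Not emulated**: probe-level artifacts (cross-hybridisation, saturation),
batch/donor effects beyond i.i.d. noise, spatial autocorrelation between
neighbouring regions, gene–gene correlation, and library-composition bias
(each query replicate shares one expected composition). Conclusions about
robustness to those phenomena cannot be drawn from these simulations.

The default problem sizes (2,000 probes, 30 regions, 20-simulation
recovery studies, 100 permutations) are the package's own choice of a
study large enough for stable rates while keeping the full validation
suite quick to run end to end.

## 6. Tunable parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `min_samples` | 2 | samples required to keep a region; also the expression-support count for keeping a probe |
| `detection_threshold` | 0.0 | intensity above which a probe counts as expressed during filtering |
| `collapse` | mean | probe→gene collapse (mean or median) |
| `min_genes` | 100 | minimum shared gene index; below this, matching refuses to run |
| `background_cap` | 10 | background size cap, in multiples of *G* |
| `exact_limit` | 20 | pooled-n threshold for the exact Wilcoxon branch |
| `neglog10_cap` | 320 | cap on −log10 p |
| `alpha` | 0.01 | DE adjusted-p threshold |
| `lfc_threshold` | 1.5 | DE effect-size threshold, log2 units |
| `var_floor` | 1e−8 | pooled-variance floor, (log2 units)² |
| `pseudocount` | 1.0 | log2 transform offset for the query profile |
| `seed` | 0 | seed for background subsampling |

Atlas filtering applies region filtering *before* probe filtering; this is
the only order that is idempotent (probe support counts are taken over the
surviving samples).

## 7. Determinism

All floating-point table output is written with the `%.12g` format; all
randomness flows from explicit seeds (`numpy.random.default_rng`); sort
ties are broken by id. Running `simulate → match` twice on the same seed
produces byte-identical output files, which is asserted end-to-end in the
test suite.
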