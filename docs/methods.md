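# Methods

## Classifier construction

An m-way classifier is a map from the `3^m` multi-locus genotype cells of
m SNPs to a predicted ordinal class.  Cell `i` receives
`c(i) = argmax_j n_ij / n_+j`, the class most over-represented in that
cell relative to its overall frequency.  This is algebraically the argmax
of the per-cell odds ratio `θ̂_ij = (n_ij/n_i1)/(n_+j/n_+1)` against the
baseline class wherever the latter is defined (`n_i1 > 0`), but the ratio
form stays defined when the baseline count is zero, so it is the form
implemented.  `estimated_or` is still exposed for inspection and returns
`nan` where undefined.

Conventions and edge cases:

- **Cell indexing** is little-endian mixed-radix base 3: genotype vector
  `(g_1..g_m)` (minor-allele counts at the combination's SNPs in sorted
  order) maps to cell `Σ_k g_k·3^(k-1)`, 0-based.  Fixed and tested so
  results are reproducible across implementations.
- **Ties** in the argmax go to the largest class index, mirroring binary
  MDR's convention of calling a tied cell high risk; tied cells are
  recorded on the model (`tie_cells`) for audit.
- **Empty training cells** are marked unclassifiable, and test samples
  landing in them are excluded from the confusion matrix (counted in
  `n_excluded`).  Defaulting such cells to the top class is the binary-MDR
  convention but has no principled ordinal analogue, so exclusion is the
  conservative default; `empty_cell="largest"|"smallest"` restores the
  defaulting behaviour.
- **Missing genotypes** (`NA` on disk, `-1` in memory) exclude a sample
  from the contingency table of the combination under evaluation only
  (pairwise deletion), so an exhaustive scan never discards a sample
  globally.
- A class absent from a training fold drops out of the argmax (its ratio
  is undefined); stratified CV makes this rare by construction.

## Evaluation

Classifiers are scored with Kendall's tau-b between true and predicted
classes, `τ_b = (P−Q)/√((N₀−T_r)(N₀−T_c))`, computed in closed form from
the J×J confusion matrix: concordant/discordant pair counts are sums of
cell products (O(J⁴), exact — never the O(n²) per-sample enumeration,
which survives only as a test oracle).  A table whose mass lies in a
single row or column carries no ordinal information; its tau-b is
undefined and ranks below any defined value.  Unclassified samples are
omitted from the table; `n_effective` makes low-coverage classifiers
visible.  Balanced accuracy (macro-averaged recall) is included as the
conventional binary baseline measure.

## Cross-validation, top-K selection and GCVC

Samples are split into L folds (default 10), stratified by phenotype
class so fold class counts differ by at most one; a class smaller than L
degrades to best-effort stratification with a warning.  Per fold, every
candidate combination is fitted on the L−1 training folds and scored on
both splits.  For speed, the per-fold training table is obtained by
subtracting the held-out fold's table from the full-data table, and the
training/test confusion matrices come from the cell-sum identity
`x_jk = Σ_{i:c(i)=k} n_ij`, so each combination costs one pass over the
samples plus O(L·3^m·J) arithmetic.

The K combinations with the largest *training* score in a fold are its
top-K classifiers; `GCVC^K` sums these selections over folds.  Ties at
the rank-K boundary are broken towards the lexicographically smallest
SNP-index vector rather than admitting more than K combinations, keeping
GCVC deterministic and `Σ_combos I_l = min(K, #combos)` exact.  A fold
with undefined score is excluded from means and counted; a combination
undefined in every fold ranks last.

Reporting follows three criteria: `gcvc_positive` (every combination ever
selected), `gcvc_at_least:c` (high-consistency candidates, e.g. ≥ 9 of
10), and `top_n:N`.  Ranking is (GCVC desc, mean test score desc,
combination asc).  Where "maximum predictability" and "maximum GCVC"
disagree, GCVC is primary *within* an order (it is the selection-stability
criterion) and mean test score primary *across* orders (the
predictability headline), with remaining ties resolved to the smaller
order (parsimony); both rankings are recoverable from the emitted tables.

## Search strategies

Small panels are scanned exhaustively (all C(p, m) combinations, streamed
lexicographically).  For large panels the staged strategy carries the
union of SNPs appearing in the top `carry_k` combinations at order m−1
(same ranking key as reporting) into an exhaustive scan over that pool at
order m.  With `carry_k = ∞` staged search equals the exhaustive scan.
No stochastic search is provided.

## Simulator

A genetic model gives, per causal multi-locus genotype, either the odds
ratios `θ_ij` of each class against class 1 or the penetrance row
directly, plus class prevalences `p_j` and causal MAFs.  Penetrances
derive from odds ratios by proportional scaling
`p_{j|i} ∝ θ_ij · p_j / p_1`, row-normalised; with all θ = 1 this yields
`p_{j|i} = p_j` exactly.  When a spec supplies explicit penetrances, they
win over the derivation.  One consequence worth knowing: the *realized*
marginal class distribution is `Σ_i P(cell i)·p_{j|i}` (exposed as
`implied_prevalences`), which drifts from the nominal prevalences when
effects are present — and the odds-ratio estimator, whose denominator is
the realized marginal, therefore recovers the input θ exactly only for
the null model.  The cross-check tests account for this.

Sampling is prospective: causal and non-causal genotypes are drawn
per SNP under HWE (`(1−q)², 2q(1−q), q²`), each sample's class from its
causal cell's penetrance row, so class counts are multinomial around the
implied marginals rather than fixed by design.  Non-causal SNPs default
to MAF 0.3 (overridable); no linkage disequilibrium, covariates or family
structure are modelled.  Replicate r uses the seed stream
`SeedSequence([master_seed, r])`, so any replicate regenerates alone,
and fold seeds in replicate studies derive from the same stream.

Default study conditions: 3 classes with prevalences 0.3/0.4/0.3, n=1000
samples, 50 SNPs with one causal pair (MAFs 0.3/0.5 in the shipped
moderate model, 0.5/0.5 in the strong checkerboard model), 10-fold CV,
100 replicates.  Shipped models: `null_3class` (no effect),
`strong_checkerboard` (pure two-way interaction, no marginal effects:
alternating cells get class-3 odds 6 vs 0.2) and `demo_moderate` (jointly
dominant, odds 2/4 for classes 2/3 when both loci carry a minor allele).
Both effect models are synthetic constructions for demonstration and
testing; they are not estimates from any real cohort.

## What the synthetic data does and does not show

The generator emulates independent SNPs in HWE with a single causal
interaction and multinomial ordinal classes.  Passing power/calibration
tests therefore demonstrates correctness of the procedure under those
assumptions — they say nothing about robustness to linkage
disequilibrium, population structure, genotyping error, covariates or
ascertainment, none of which are simulated.

## Problem sizes in the shipped checks

The test suite exercises the two-locus power study at 20 replicates of
n=1000 × 50 SNPs with 10-fold CV (≈1225 combinations × 10 fits per
replicate), chosen as the smallest design that still separates causal
from non-causal pairs decisively; replicate counts in the examples are
similarly modest.  Larger studies (more replicates, order-3 exhaustive
scans at ~19,600 combinations per replicate) run with the same API and
scale linearly in combinations × folds × replicates.

## Known limitations

- Tau-b on training data is computed on the training fold's own confusion
  matrix (no refit or nested CV), so TRTB is optimistic by construction.
- GCVC carries no significance calibration; no permutation test is
  provided.
- The staged search's pool ranking uses the reporting key; other
  plausible keys (e.g. training tau-b alone) would carry different SNPs
  forward.
- Covariate adjustment, quantitative traits and family designs are out of
  scope.
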