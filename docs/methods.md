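# Methods

## Scope and data model

`emtscore` operates on log2-scale expression matrices (genes × samples)
and delimited gene-signature files. Values are assumed already
log2-transformed (all three scoring methods were defined on microarray
log-intensity data); a `log2_transform` flag applies log2(x+1) to raw
intensities. Missing cells are rejected, never imputed — the KS score
is an ECDF statistic and the 76GS weights are correlations, and silent
imputation would bias both. Gene symbols are matched case-insensitively
after whitespace trimming; duplicate rows (multiple probes mapping to
one gene) are collapsed to their per-sample arithmetic mean. The loader
makes no normalisation claim beyond this: quantile or other cross-array
normalisation, if wanted, is the caller's responsibility.

## 76GS

Weights are the Pearson correlation of each signature gene with CDH1
across the dataset's samples (CDH1 itself, if listed, gets weight 1 by
self-correlation; a constant gene gets weight 0 with a warning). The
per-sample raw score is the weighted sum of the signature genes'
expression, centred to a zero grand mean. Scoring uses expression as
loaded; a `zscore_rows` option standardises gene rows first for users
who prefer a variance-equalised variant. Signature genes absent from
the matrix are dropped with a logged warning and the coverage fraction
is reported per run; fewer than `min_genes` (default 5) present genes
is an error. Two properties worth remembering: the score is invariant
to adding a constant to the whole matrix, but it is *dataset-relative*
— weights are re-estimated per cohort, so subsetting a cohort changes
the scores of the retained samples. This is intrinsic to the method
and is asserted by a deliberate counterexample test.

## KS

Per sample, the epithelial-signature values and mesenchymal-signature
values are compared through their right-continuous empirical CDFs
evaluated on the pooled support; the statistic D is the uniform-norm
distance, implemented directly and cross-checked in tests against an
exhaustive enumeration oracle and against scipy's two-sided two-sample
statistic. Sign: one-sided two-sample KS tests of "E-CDF above M-CDF"
(mesenchymal direction, score +D) and the converse (epithelial, −D),
with p-values from `scipy.stats.ks_2samp` — exact for pooled n ≤ 25,
asymptotic otherwise (signature sizes in practice are hundreds of
genes, far inside the asymptotic regime). When neither one-sided test
reaches `alpha` (default 0.05), the sign of the dominant ECDF
deviation — the sign of F_E − F_M at the argmax of |F_E − F_M| — is
used. A hard zero in the non-significant case would make the score
discontinuous along the E–M axis and destroy downstream correlation
analyses, so the dominant-deviation rule is this package's documented
choice. Ties are handled identically on both ECDFs; the argmax takes
the first pooled point, making the sign deterministic. Tumor and
cell-line signature variants are just two signature files selected by
flag; nothing in the scorer differs.

## MLR

Predictor coordinates: for each sample, the per-sample median of the
normalizer genes is subtracted from the three predictor genes' log2
values (a minimal platform adjustment; the choice of median-shift is
surfaced in the API for replacement), and a dataset-level positivity
offset is added so every adjusted value is ≥ 1 — the x1 coordinate is
the ratio adjusted-VIM / adjusted-CDH1 and needs a positive
denominator. The offset used at training time is stored in the fitted
model and reused when scoring new data, so all datasets share one
predictor space. x2 is adjusted CLDN7.

The phenotype model is a three-class multinomial logistic regression
(L2-regularised, lbfgs, C = 10) over (x1, x2). The hybrid category is
treated nominally during fitting; the E < E/M < M order structure is
verified post hoc on the training data (mean predicted score must be
strictly increasing across the three labelled groups) and a violation
is an error. A proportional-odds ordinal logit (`kind="ordinal"`, via
statsmodels' cumulative-link model) is available as a sensitivity
variant. The EMT score is the expectation of the category values
{0, 1, 2} under the predicted probabilities — the unique affine map
sending the pure-E, pure-hybrid and pure-M probability corners to 0, 1
and 2.

No pretrained coefficients are shipped as data. `reference_model()`
deterministically retrains the frozen reference fit (synthetic
reference population and solver both seeded with 17) and caches it,
so every installation reproduces bit-identical coefficients;
`MLRModel.to_json`/`from_json` persist any fitted model, with training
provenance (seed, solver, data hash).

## Mixture curve

Purified E and M profiles are the per-gene mean (or median) of the
bottom/top `n_ref` = 35 samples by MLR score, over the MLR signature
genes. The curve is traced on a uniform grid of `grid_size` = 1001
mesenchymal fractions f ∈ [0, 1] (0.001 spacing: sub-0.1 % resolution
at negligible cost). Mixing happens on the linear intensity scale —
unlog, combine (1−f)·E + f·M, relog — because bulk expression of a
physical cell mixture adds linearly in transcript abundance; a
`mix_space="log"` switch mixes log2 profiles directly for sensitivity
analysis. Distances are plain l2 in raw predictor units (no axis
standardisation), minimised over the grid with ties going to the
smaller f; %M = 100·f at the argmin. Samples eligible for the
closest/farthest-N ranking are those called E/M by the MLR model; all
orderings break ties by sample ID so reruns are stable.

## Synthetic data

The generator emulates the study conditions every analysis assumes:

- One fixed **gene universe** (80 epithelial genes incl. CDH1 and
  CLDN7, 80 mesenchymal incl. VIM, 20 normalizers) with per-gene
  baseline offsets drawn once from a dedicated RNG (sd 2 log2 units,
  the marker trio anchored at 0). Sharing the universe across all
  generated datasets is what lets a model trained on one generated
  cohort score another, and gives the signature-gene value sets the
  within-sample spread the ECDF statistic needs.
- **E/M samples** put the two marker programs at base levels 10 and 4
  log2 units (a 64-fold marker dynamic range, typical of strong
  microarray markers); **hybrids** put both programs at the midpoint
  but keep CLDN7 at its epithelial level (+3 over the midpoint) —
  co-expressing hybrid cells retain claudin junctions — which places
  them off the admixture curve by construction; **admixtures** are
  linear-intensity convex combinations of the noiseless E and M
  prototypes at recorded fractions. Gaussian log2 noise (default
  sd 0.5) is added everywhere.
- The synthetic KS signature excludes the three MLR predictor genes.
  The published gene lists behind the methods were derived
  independently and overlap little; keeping the ECDF sets disjoint
  from the predictor trio means no single gene's noise is a shared
  channel between the KS and MLR scores, so concordance measured on
  generated data reflects the planted EMT axis, not marker-noise
  leakage.
- The **time course** interpolates the E and M prototypes log-linearly
  (a transitioning population, not a physical mixture) across
  time points, with noised replicates.
- The **dataset suite** plants concordant cohorts (spread E→M
  gradient, n = 60) and discordant ones (EMT-constant epithelial
  cohorts, n = 100, with two EMT-orthogonal nuisance axes: per-sample
  array-brightness shifts, which inflate 76GS but cancel in KS ranks
  and the MLR normalizer adjustment, and EMT-independent CLDN7
  variation, which dominates the MLR predictor point but is one gene
  among many for the others). With each score driven by its own
  nuisance axis and |R| sampling noise ≈ 0.1 at n = 100, the planted
  pass/fail outcome under the |R| > 0.3, p < 0.05 rule is reliable
  (measured 0/60 false passes, 0/40 false fails across seeds).

What the generator does **not** emulate: probe-level microarray
structure, batch effects, RNA-seq counts, correlated gene–gene noise,
or partially overlapping real signatures. Tests passing on this
generator show the statistics behave as defined under their own
assumptions; they do not certify performance on any real platform.

## Numerical and reproducibility choices

Pipeline outputs are written with 6-significant-digit float formatting
so identical runs are byte-identical; matrices written by
`ExpressionMatrix.to_tsv` use shortest-exact float repr and round-trip
bit-identically. All stochastic steps take explicit seeds;
`generate_*` are bit-reproducible under a fixed spec. Degenerate
inputs fail loudly: constant CDH1, empty signature sides, missing
predictor genes, non-finite values, size-1 groups in variance
rankings (flagged and excluded rather than ranked).

Concordance defaults follow the standard thresholds for this analysis
family: significance at p < 0.05 together with |R| > 0.3, both
configurable. Variance in group summaries is the unbiased sample
variance. Pearson p-values use the t-distribution transform.

## Known limitations

- The mesenchymal-fraction estimate f̂ from the mixture curve is noisy
  mid-curve: the curve's tangent speed in log-intensity predictor
  space is bounded (≈ 2.9 per coordinate per unit f at f = 0.5,
  independent of marker dynamic range), while per-gene log2 noise
  propagates almost undamped into the CLDN7 coordinate. At noise
  sd 0.5 the implied per-sample σ_f is ≈ 0.1 mid-curve (measured
  median |f̂ − f| ≈ 0.07 over uniformly drawn fractions), shrinking
  toward the ends. Rankings and the hybrid-vs-admixture separation
  are robust to this; single-sample %M values mid-curve should be read
  with that uncertainty in mind.
- The 76GS score is dataset-relative by construction; scores are not
  comparable across cohorts.
- The nominal-MLR-with-order-check construction reproduces the
  probability interface of the ordinal formulation but is not a
  cumulative-link fit; use `kind="ordinal"` where the proportional-
  odds structure matters.
- Three-way compositional deconvolution (relative proportions of E,
  hybrid and M cells in one sample) is out of scope.
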