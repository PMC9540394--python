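# Methods

This note records the statistical models implemented in `tgxddi`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that affect results.

## Sample QC

Five criteria are applied to the raw probe × sample count matrix, before
any normalization (the singleton criterion in particular runs on raw-count
ranks; Spearman correlation makes it invariant to library size and to any
monotone transform).

* **Depth**: total reads < 10% of the median library size (strict `<`; a
  library exactly at the cutoff is retained).
* **Outer fences**: samples outside Tukey's outer fences, Q1 − 3·IQR and
  Q3 + 3·IQR, on each of three complexity metrics — the number of probes
  capturing the top 80% of the signal, the Gini coefficient of the count
  distribution, and the number of active probes (≥ 5 reads, inclusive).
  Quartiles use linear interpolation between order statistics (the common
  statistical convention); the convention and the realized fences are
  recorded in the QC report so runs are reproducible across
  implementations. Fences are computed across the whole run by default; a
  per-chemical batch mode would only require subsetting the matrix first.
* **Singletons**: complete-linkage clustering on 1 − Spearman correlation
  between samples, dendrogram cut at dissimilarity 0.1; any cluster of
  size one is flagged. A sample with constant probe counts has undefined
  rank correlation; it is flagged with its own reason
  (`constant_counts`) and excluded from the clustering rather than
  aborting the run.

The Gini coefficient is computed as G = Σ_i (2i − n − 1) x_(i) / (n Σx)
over ascending-sorted values, identical to the mean-absolute-difference
form ΣΣ|x_i − x_j| / (2n²x̄); the tests hold the two to 1e−12 agreement.

Removal is the union of the criterion flags — a sample is removed iff it
trips at least one criterion, and the report lists every reason.

## Normalization and log ratios

Size factors are the median-of-ratios estimator: for sample j,
f_j = median over reference probes i of k_ij / (∏_l k_il)^(1/m), where
reference probes have positive counts in every sample. Two exactness
caveats worth knowing:

* Because the geometric-mean pseudo-reference is itself data-derived,
  scaling one of m columns by c scales its factor by c^(1−1/m), not c;
  ratios of factors scale exactly. Exact per-sample equivariance holds when
  the pseudo-reference is held fixed, so `size_factors` accepts an explicit
  reference vector; the acceptance checks use that form.
* Re-running the estimator on its own normalized output returns factors
  that are all equal (to the geometric mean of the original factors, close
  to 1) — the estimator's fixed point.

Probes mapping to the same gene symbol are arithmetically averaged on the
normalized scale. Expression input to the classifier is the per-replicate
log₂ ratio to the mean of the matched vehicle-control replicates,
log₂((t + p)/(c̄ + p)) with pseudocount p = 0.5 by default. The pseudocount
guards zero counts in targeted panels; it is a parameter and is recorded in
the output. Vehicle matching keys on the chemical (each chemical has its
own solvent series); an optional `vehicle_batch` metadata column restricts
matching within dose bands when several vehicle concentrations were run.

## The three-pronged classifier

**Nearest shrunken centroids (PA).** With class centroids x̄_ik, overall
centroid x̄_i, pooled within-class SD s_i and fudge constant s₀ =
median(s_i), the per-gene score is d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀)).
Soft-thresholding d′_ik = sign(d_ik)(|d_ik| − Δ)₊ gives the shrunken
centroid x̄′_ik = x̄_i + m_k (s_i + s₀) d′_ik. Class probabilities are the
softmax of −δ_k/2 with δ_k(x) = Σ_i (x_i − x̄′_ik)²/(s_i + s₀)² −
2 log π_k, computed after subtracting min_k δ_k for numerical stability.
Two conventions for the class-size factor circulate in the literature;
both are implemented (`class_size_factor="minus"` for √(1/n_k − 1/n),
`"plus"` for √(1/n_k + 1/n)). The default is "minus", which is the exact
standard error of x̄_ik − x̄_i when class k contributes to the overall
mean. The choice only affects which genes survive a given Δ — at Δ = 0 the
two models are identical, and the Δ grid in cross-validation adapts to
either scale. Priors default to class proportions; equal priors are
available. Δ defaults to 0 (no shrinkage — every panel gene is already a
biomarker gene); `select_delta_cv` picks Δ by stratified cross-validation
over a grid from 0 to max|d_ik| when gene selection is wanted, resolving
ties toward the smallest Δ.

A PA call requires the winning class probability to exceed 0.90 strictly;
anything at or below sits in the *unclassified* band.

**PCA.** Principal components are estimated from the training profiles
only (observations = profiles), centered by training gene means, unscaled —
the inputs are log₂ fold changes, already on a common scale, and per-gene
standardization would distort the biomarker's weighting. Eigenvector sign
is arbitrary, so PC1's orientation is fixed at fit time such that the mean
PC1 score of the DDI training profiles is negative; the decision rule
PC1 < 0 ⇒ DDI (0 falls to non-DDI, the "otherwise" branch) then has a
well-defined meaning for any query.

**HC.** The query profile is clustered jointly with all training profiles
(average linkage, Euclidean distance) and the dendrogram is cut at two
clusters. The query takes the majority training label in its cluster; if
it forms a singleton, or the vote ties, the call is *unknown*. The
two-cluster cut with majority voting is this package's formalization of
visual co-clustering; it reproduces the obvious cases exactly (a query at
a training profile inherits that label; a query far outside the training
cloud is unknown).

**Integration and condition profiles.** Any DDI prong ⇒ DDI; all three
non-DDI ⇒ non-DDI; otherwise unclassified. Conditions (chemical ×
concentration) are classified on the mean of their replicate log-ratio
profiles; single-replicate conditions are valid (n = 1), and per-replicate
calling is available via `per_replicate=True`.

## Cytotoxicity filter

Viability is the percentage of the matched vehicle's mean MTT absorbance.
A concentration is excluded from classifier input when its mean viability
across replicates falls strictly below 50% — a condition at exactly 50% is
retained ("surpassing" the threshold is read strictly), and exclusion is
decided on the replicate mean, not per replicate. Excluded doses remain in
the comet analysis flagged as cytotoxic.

## Comet decision procedure

Input values are per-experiment summaries of % tail DNA (by comet
convention the per-well median); group-level summaries report both the
mean and median of those values, and contrasts compare group means.

Per chemical: one-way ANOVA across vehicle + dose groups. Assumptions are
checked at α = 0.05 (configurable): Anderson–Darling on the pooled
group-mean residuals for normality, Fligner–Killeen across groups for
variance homogeneity. The A² statistic uses the composite-normal form with
the (1 + 0.75/n + 2.25/n²) small-sample correction, and its critical value
comes from a seeded Monte-Carlo null table (20,000 standard-normal samples
of the observed size; cached, fixed internal seed, so decisions are
identical across runs). A degenerate sample (zero variance) counts as an
assumption failure. If either assumption fails, the whole analysis — ANOVA
and contrasts — is repeated on global midranks.

Many-to-one contrasts use pooled-variance t statistics with df = N − k and
are FWER-adjusted by Dunnett's method: adjusted p_i = P(max_j |T_j| ≥
|t_i|) under the joint null multivariate t, whose correlation structure
comes from the group sizes (0.5 at equal n). The null distribution is
estimated by seeded Monte Carlo (default 100,000 draws), which handles
unequal group sizes uniformly; adjusted p-values are floored at the raw p
so adjusted ≥ raw holds exactly. Contrasts are two-sided; the overall
positivity condition is one-sided — a chemical is positive iff some
non-cytotoxic dose has adjusted p < α *and* a group mean above the
vehicle mean. Cytotoxic doses are tested and reported but can never drive
the call. The result also exposes the direction-free FWER event
(`any_significant`), which is the quantity the procedure controls at α and
the one used for type-I calibration; the directional positive rate under
the null sits below α by construction.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the emulated study design: a 64-gene biomarker panel,
28 training profiles (14 DDI / 14 non-DDI — the class split is a
configurable assumption), a 2,977-probe count matrix, ten concentrations
2.0–1,000 μM plus matched vehicles, three replicates per condition.

* **Training set**: DDI profiles shift half the panel (configurable) by
  ±effect_size (default 2 log₂ units) with alternating direction;
  everything else is N(0, noise_sd²), default noise 0.5. At effect 0 the
  classes are exchangeable.
* **Counts**: probe abundances are lognormal with σ = 2 (targeted panels
  span several orders of magnitude), library sizes gamma-distributed
  around depth_mean with squared CV `depth_dispersion` = 0.05, and counts
  negative-binomial with dispersion 0.02. The dispersion default encodes a
  clean, high-quality assay — inter-replicate Spearman correlation ≥ 0.95,
  as technical replicates of targeted panels show — so that the QC stage's
  false-flag rate on clean data stays below 5%. Injected failures: a
  low-depth library thinned to ~5% of the median; a distribution outlier
  with 95% of reads on five probes; a singleton with rank-scrambled
  intensities. A graded, DDI-like dose response can be injected on the
  responsive-gene probes (`ddi_log2fc`, scaled by c/c_max).
* **Comet**: Gaussian % tail DNA truncated to [0, 100] per group with
  optional per-dose mean shifts. The analysis stage assumes neither
  Gaussian nor Beta noise — the rank path covers departures.
* **Viability**: a Hill curve 100/(1 + (c/EC50)^h) with replicate noise;
  EC50 = 350 μM with a steep slope puts exactly the 500 and 1,000 μM doses
  below 50% in expectation.

Not emulated: probe-level sequence biases, batch effects, plate-position
effects, correlated gene-gene structure within the panel, inter-laboratory
variation, and anything upstream of the count matrix (demultiplexing,
trimming, alignment are out of scope). Passing tests on synthetic data
therefore demonstrate the correctness and calibration of the *procedures*,
not the biological performance of the biomarker on real exposures — the
published panel and training profiles must be supplied to reproduce real
classifications.

## Problem sizes and numerical conventions

The test suite and the acceptance script scale simulations to what the
checks need: QC fixtures use 300–400-probe matrices at ~50–80k reads
(metrics and thresholds are size-agnostic), calibration loops use 1,000
Monte-Carlo replicates with 20,000 Dunnett draws (p-value standard error
< 0.002 near 0.05), and hold-out accuracy uses 200 fresh profiles.
Tie-breaks: CV Δ selection prefers the smallest Δ; an HC majority tie is
*unknown*; fence and threshold comparisons are strict, with a 1e−9
relative guard against floating-point ties at the fence itself. Degenerate
inputs (all-zero libraries, zero-variance groups, classes smaller than
two) raise typed errors or, inside `run_qc`, become per-sample flags so a
batch run never aborts on one bad library.

## Known limitations

* The HC prong's two-cluster cut is one formalization of "clusters with
  the DDI compounds"; other cut heights could change borderline calls.
* Dunnett adjustment is Monte Carlo, so adjusted p-values carry ~1e−3
  noise at the default draw count; decisions at the 0.05 boundary can
  flip between seeds in pathological cases (the seed is recorded).
* The comet rank path tests the distribution of midranks, which under
  heavy ties (values clipped at 0 or 100) loses resolution with very small
  groups.
* With n = 3 replicates per dose group, the assumption tests have limited
  power; the parametric path will be chosen for moderately non-normal
  data. This mirrors the practical procedure rather than fixing it.
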