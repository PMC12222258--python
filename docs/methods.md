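# Methods

This note documents the models, conventions and numerical choices behind
`oligopath`, in the order data flows through the pipeline.

## Synthetic data: the stated world

The generators exist so every downstream stage can be tested against known
ground truth; their defaults encode the cohort the pipeline is designed
for, not tunable knobs.

**Feature cohorts** (`simulate.generate_feature_cohort`). Default design:
462 subjects, outcome prevalence 0.206 (the ~95-event cohort the model
targets), 120 features of which 6 are informative with a standardised mean
difference of 1.0 in the positive class, organised in equicorrelated blocks
(ρ = 0.5, block size 8) to emulate the strong redundancy of pathomics
panels. Features are affinely squashed to [0, 1] (±5 SD clipped) so they
live on the min-max normalisation scale; the map is monotone and leaves
rank statistics (Mann-Whitney, Spearman) untouched. Labels are i.i.d.
Bernoulli, so the realised prevalence fluctuates with binomial error —
tests compare against sampling bands, not the point value.

**Patches** (`simulate.generate_patch`). Hematoxylin density = irregular
elliptical nuclei (radial Fourier perturbation of harmonics 2–5, amplitude
= `nucleus_irregularity`, class defaults 0.06 / 0.25) plus a chromatin-like
speckle of disks at the class grain radius (3 px / 6 px); eosin density =
smooth stroma. RGB is the Beer-Lambert forward model
`I = 255·10^(−(h·v_H + e·v_E))` with the Ruifrok-Johnston stain vectors and
additive Gaussian read-out noise (SD 2 intensity units). Class 1 therefore
moves exactly the feature families the extractor measures (moments,
Zernike, granularity). What the generator does **not** emulate: scanner
optics, staining batch effects, tissue architecture, nucleus clustering —
a green test establishes algorithmic correctness, not histological realism.

**Replicates** (`generate_replicate_set`): base value + i.i.d. Gaussian
noise per replicate; with between-subject SD s_b the induced ICC is
s_b²/(s_b² + σ²), which the ICC tests exploit as a closed-form oracle.

## Feature extraction

* **Optical density**: base-10 log, I₀ = 255, ε = 1 added before the log;
  negative unmixing coefficients clipped at 0. Unmixing is per-pixel least
  squares on two unit stain vectors (collinear vectors are rejected).
* **Primary objects**: global Otsu on the hematoxylin OD, hole filling,
  watershed declumping seeded at smoothed distance-transform maxima
  (minimum peak separation = min_diameter/2), then an equivalent-diameter
  filter (defaults 10–40 px). The declumping heuristics of any particular
  screening software are not reproduced; the operations are implemented
  from their standard definitions, so survivor counts on real slides will
  differ from any published pipeline.
* **Secondary objects**: watershed flooding from the primary labels over
  `distance + w·(1 − eosin/eosin_max)` restricted to pixels within
  `max_expand` (default 10 px) of a nucleus. This guarantees a partition,
  distance tie-breaks on flat eosin, and `max_expand = 0` reduces to the
  identity.
* **Granularity** (length 16, subsample 0.25, background opening radius
  10): iterative erosion by a unit disk with morphological reconstruction;
  element i = 100·(I_{i−1} − I_i)/I₀. Elements are nonnegative and sum to
  ≤ 100 by the telescoping of nonincreasing reconstructions. Both variants
  seen in published feature lists are produced: image-level spectra per
  stain (`Granularity_i_<Stain>`) and per-object spectra averaged over
  objects (`Mean_Identify*Objects_Granularity_i_<Stain>`).
* **Central moments**: μ_pq over the binary mask, row power p, column
  power q, all p, q ≤ 4; exactly translation-invariant.
* **Zernike moments**: binary (shape-only) masks mapped onto their
  **minimum enclosing circle** (Welzl's algorithm) scaled to the unit
  disk; A_nm normalised by (n+1)/π and pixel area so the full disk gives
  |A00| = 1; magnitudes only (rotation-invariant). The lattice is the
  standard 0 ≤ m ≤ n ≤ 9 with n − m even. Published feature labels
  occasionally print out-of-lattice index pairs (e.g. `Zernike_2_6`,
  `Zernike_3_4`); the extraction config resolves such labels by swapping
  the indices when the swap is valid, else reducing m to the nearest
  parity-compatible value, and keeps the printed label as the column name.
* **Aggregation**: per-object → per-patch arithmetic mean (the `Mean_`
  prefix), per-patch → per-slide arithmetic mean; patches on which no
  nucleus is found are recorded as missing and excluded from the mean.

## Screening cascade

Stages run in fixed order; every stage's output is a subset of its input
and all intermediate statistics are kept in the report.

* **Min-max** is fitted on training data only; applied data are clipped to
  [0, 1]; constant training features are dropped with a warning.
* **ICC(2,1)** (two-way random effects, absolute agreement, single
  measurement) from the ANOVA decomposition, vectorised across features;
  retain ICC > 0.75. The replicate axis defaults to the per-slide patch
  vectors, the only replicates that exist in-pipeline.
* **Mann-Whitney U**, two-sided, exact for small tie-free samples and
  tie-corrected normal approximation otherwise; retain raw P < 0.05 with
  **no multiplicity adjustment** (the screening convention this pipeline
  reproduces).
* **Spearman pruning**: features visited in ascending U-test p (ties
  lexicographic); drop on |ρ| > 0.9 against an already-kept feature, so
  the smaller-p member of a correlated pair survives.
* **mRMR**, MID variant: mutual information on an equal-frequency 3-bin
  discretisation; greedy score = relevance − mean redundancy over the
  selected set; alphabetical tie-break. The stopping count k is a
  configuration parameter (default 30) — published survivor counts are
  data-determined, not a rule.
* **LASSO**: binomial (logistic) family on a glmnet-style log-spaced λ
  grid (λ_max down 3 decades, 60 points), stratified seeded 5-fold CV,
  λ_min = argmin mean deviance, refit at λ_min, nonzero coefficients
  selected. Features are standardised internally (coefficients are mapped
  back); the liblinear solver is pinned to a fixed random state for
  bit-reproducibility. A gaussian family is exposed for the orthonormal
  soft-threshold identity used in testing.

## DMS-PSO

Minimisation throughout. Defaults: 20 particles in 4 sub-swarms, inertia
linearly decreasing 0.9 → 0.4, c₁ = c₂ = 1.49445, regroup period R = 5,
v_max = 0.2 × range per dimension, 150 iterations, patience 20. r₁, r₂ are
drawn per particle **and** per dimension (the stronger-mixing convention).
Positions are clamped to the box with velocities left unchanged; pbest and
lbest update on strict improvement; regrouping randomly permutes particles
into equal-size sub-swarms without touching any best. With one sub-swarm
and no regrouping the algorithm is exactly plain local-best PSO, which is
tested against an independent implementation on the same RNG stream.
Non-finite fitness values are treated as +∞ rather than fatal. The
patience-based stop is a design choice; the original description reports an
iteration count without a stopping rule.

## Risk model

Hyperparameters are encoded as (log₂C, log₂γ) with default search box
log₂C ∈ [−5, 15], log₂γ ∈ [−15, 3]. The CV fitness is 1 − mean out-of-fold
AUC over stratified seeded 5-fold splits, computed on raw SVM decision
scores (rank-equivalent to probabilities and cheaper). The final SVM is
retrained on all training data; probabilities come from **Platt scaling**
fitted on out-of-fold decision scores (prior-corrected targets, Nelder-Mead
ML; the sign of the slope is constrained so probability increases with the
score). How the original study obtained probabilities is unstated; Platt is
the documented choice here. The decision cutoff defaults to the Youden-index
maximiser of the calibrated training probabilities — candidates are
midpoints of consecutive unique probabilities plus one candidate below the
minimum and one above the maximum, smallest cutoff on ties — and the
high-risk rule is probability **≥** cutoff. No class weighting by default
(a weighted option exists). The train/validation split utility is
stratified by default because a 20.6% prevalence makes unstratified 8:2
splits unstable.

## Evaluation

* **AUC**: Mann-Whitney identity with half-credit ties; DeLong structural
  components give the variance for the 95% CI and the paired curve test.
  Identical score vectors short-circuit to Δ = 0, p = 1.
* **Hosmer-Lemeshow**: g = 10 equal-count risk bins with ties kept
  together, χ² = Σ(O−E)²/(E(1−E/n_b)), df = g − 2; degenerate bins are
  merged into a neighbour with a warning and the df adjusted. The g − 2
  reference is calibrated for probabilities fitted in-sample; applied to
  externally fixed true probabilities the statistic is stochastically
  larger (≈ χ²_g), which the calibration tests account for.
* **Calibration curve**: logistic recalibration smoother on logit(p); the
  bias-corrected curve is the bootstrap estimate 2·S − mean_b S_b over 200
  resamples by default (resample count and smoother were unstated in the
  source procedure; both are configurable, and n_boot = 0 returns the
  apparent curve).
* **Decision curves**: threshold grid 0.01–0.99 step 0.01; label rule
  ≥ p_t (consistent with the ≥ 0.47 high-risk rule); treat-all
  NB = π − (1−π)p_t/(1−p_t); NNT = 1/NB reported rounded to the nearest
  integer when quoted as a headline number.
* **Kernel SHAP**: exact enumeration of all 2^M coalitions (M ≤ 16; the
  screened models here have ~6 features) with Shapley-kernel weighted
  least squares and the efficiency constraint folded in, against a
  background sample's conditional-expectation game on the model's decision
  function. Additivity holds to numerical precision by construction; there
  is no sampling approximation to tune.

## Known limitations

* CellProfiler-parity is approximate by design: feature definitions are
  implemented from their mathematical form, so absolute feature values and
  survivor counts will not match any specific software version.
* The synthetic world has independent Gaussian noise and idealised
  morphology; published headline AUCs (0.880/0.866) and survivor counts
  depend on a private cohort and are out of scope — tests assert
  properties (ordering, calibration, recovery rates), not those values.
* Exact SHAP cost grows as 2^M; above 16 features the explainer refuses
  rather than silently subsampling.
* The secondary-object propagation uses a single intensity-guidance weight
  rather than a per-image regularisation schedule.
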