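# Methods

This note records the models, conventions and design choices behind
`t1tex`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, and where the design
was genuinely open.

## Preprocessing conventions

**Coordinates.** Contours are polygons in millimetres with pixel (r, c)
centred at (r·row_mm, c·col_mm); images are 0-based, row-major. The
annular myocardial mask contains a pixel iff its centre is inside the
epicardial polygon and not inside the endocardial one, by an even-odd
ray-casting rule with a fixed half-open edge convention, so rasterization
is deterministic even for centres on polygon edges and matches a
per-pixel point-in-polygon enumeration exactly.

**Resampling.** Images are resampled to an isotropic 1.17 mm grid
(bilinear; masks nearest-neighbour). The output grid covers the same
physical extent anchored at the origin pixel centre.

**Intensity normalization.** In-mask intensities are *clipped* to
µ ± 3σ of the in-mask distribution. Clipping (rather than rescaling or
excluding) was chosen because it is idempotent, preserves the units (ms)
of first-order statistics, and matches the usual outlier-removal reading
of the µ ± 3σ convention. A constant ROI is passed through with a
degeneracy flag. Whether to clip, rescale or exclude was an open choice;
the alternatives would change first-order tails but not the rank-based
texture structure.

**Discretization.** The in-mask range is split into Ng = 32 equal-width
bins; level(x) = min(floor((x−min)/width)+1, Ng). A fixed bin *count*
(not width) bounds all matrix sizes and makes Ng-dependent features
(IDMN, IDN) comparable across cases. Together with the clipping step the
level image is invariant to affine intensity rescaling. Every filtered
variant is discretized independently by the same rule (LBP codes are
treated as gray levels like any other intensity).

## Filter bank

Nine shape-preserving variants: original; spacing-aware gradient
magnitude (central differences, one-sided borders); pixel-wise square
rescaled so the in-mask maximum absolute value is preserved;
rotation-invariant uniform LBP with 8 points at radii 1 and 2; and the
four sub-bands of a single-level *undecimated* 2D wavelet transform with
the Coiflet-1 kernel and symmetric boundaries. The undecimated form was
chosen so sub-bands keep the input shape and the myocardial mask applies
unchanged; the conjugate-mirror-filter identity |H|²+|G|²=2 per axis
gives the testable property that total sub-band energy ≈ 4× input
energy. The LBP encoding and wavelet kernel are configuration knobs; the
defaults follow common radiomics practice.

## Feature catalog

102 features per variant — 9 shape-2D, 18 first-order, 24 GLCM, 14 GLDM,
16 GLRLM, 16 GLSZM, 5 NGTDM — times 9 variants = 918 per case, with
names `<filter>__<family>__<feature>` pinned in
`t1tex.features.catalog` (single source of truth for the count).
Conventions: GLCM distance 1, four 2D angles, symmetric, normalized per
angle, features averaged over angles (making them invariant to 90°
rotations); GLRLM over the same four directions, averaged; GLSZM/GLDM
8-connected; GLDM dependence threshold α = 0 with dependence index
j = (number of agreeing Chebyshev-1 neighbours) + 1; NGTDM from
8-neighbour means. Shape-2D descriptors (mesh surface and perimeter from
marching-squares contours — an annulus counts both boundaries —
principal-axis lengths as 4√λ, maximum diameter over the convex hull)
are computed once per variant, which is what makes the printed catalog
arithmetic 102 × 9 consistent. Degenerate single-level ROIs follow limit
conventions: entropy-like features 0, homogeneity-like features 1.

Every matrix builder and feature formula is checked against brute-force
enumeration oracles (naive loops, flood fill, line walking) on hundreds
of random small level images; the vectorised implementation and the
loop oracles are written independently.

## Synthetic data model

The generator emulates a mid-ventricular short-axis native T1 study:

* **Geometry** — circular endo/epi contours (radii 18/26 mm) on a
  256×256 grid at 1.0 mm spacing; blood pool ≈ 1600 ms inside,
  low-intensity background outside, myocardium in an annulus.
* **Texture** — myocardial T1 = class mean + 45 ms × a unit-variance
  stationary Gaussian random field with squared-exponential covariance,
  synthesized spectrally (FFT), correlation length 2.0 px (LGE−) vs
  3.5 px (LGE+). Class means 1032/1044 ms follow the reported global
  native T1 of LGE−/LGE+ DMD cohorts; the per-pixel spread of 45 ms is
  of the order of reported segmental SDs (33–48 ms).
* **Lesions** — LGE+ cases receive Poisson(1.5) focal Gaussian bumps
  (amplitude 60 ms, σ 2–5 px) at mid-wall positions, *mean-centred over
  the annulus* so the configured class mean stays exact and the
  Monte-Carlo mean-recovery test exercises the random-field machinery
  rather than lesion bookkeeping.
* **Readers** — contour variants add smooth angular radial noise (first
  three Fourier modes, amplitude `jitter_px`), with bounded retries to
  keep endo strictly inside epi.
* **Longitudinal cohorts** — each patient has a latent severity driver
  d ~ N(0,1) and a random intercept b ~ N(0,1); yearly LGE status is
  drawn from logit⁻¹(−1 + 0.8·year + effect·d + b) and never reverts
  (monotone progression). Case texture tracks both status and driver
  (correlation length shifted by 0.5·d), so a texture feature genuinely
  carries the longitudinal signal.

The class-contrast direction was an open modelling question: a longer
LGE+ correlation length makes zone% lower and binned-histogram entropy
higher in LGE+ simultaneously; the wavelet-LL IDMN then also comes out
higher in LGE+ (more homogeneous), consistent with the direction the
generator targets. The generator does *not* simulate MOLLI physics,
motion, partial-volume effects, 3D geometry or inter-scanner bias, so
passing tests demonstrate the pipeline's statistical machinery, not
clinical performance on real maps.

## Reproducibility gate

ICC is the two-way consistency form ICC(C,1) = (MSR − MSE)/(MSR +
(k−1)·MSE) from the ANOVA mean squares, single-measure because
downstream analysis uses a single reader's values; it is invariant to
fixed per-rater shifts and equals the classical ANOVA decomposition
exactly (oracle-checked, and numerically identical to pingouin's
ICC(C,1)). Zero-total-variance tables return ICC 1 with a degeneracy
flag. The CV of a feature is sd/|mean| per case across the four
measurements (two readers × two passes, pooled), aggregated as the
median over gate cases — the median resists single-case blow-ups, and
|mean| keeps sign-varying filtered features meaningful. Gate rule:
intra-ICC ≥ 0.75 AND inter-ICC ≥ 0.75 AND CV ≤ 0.10.

## Selection cascade

Stratified 67/33 split with per-class floor rounding, then random
undersampling of the majority class within each split (seeded); with 23+
and 19− cases this yields exactly 24 balanced training and 14 balanced
testing cases. Boruta uses 500-tree random forests (pipeline default
300 at reduced problem sizes), impurity importances, and two-sided
Bonferroni-corrected binomial tests at α = 0.01 against p = 0.5 hits
over the running maximum shadow importance; confirmed features stay in
the forest design so the shadow bar remains honest. LASSO is
L1-penalized logistic regression with λ chosen by 5-fold CV deviance
(λ_min, the less conservative choice; the 1-SE rule would select
smaller sets). The *union* of Boruta-confirmed and LASSO-selected
features feeds average-linkage clustering on 1 − |Spearman ρ|, cut at
0.25 (i.e. |ρ| ≥ 0.75 merges); each cluster is represented by its
medoid (max mean |ρ| within the cluster, ties alphabetical). Because
pairwise clustering cannot exclude multi-feature collinearity, the
independent set is finally pruned greedily until all VIF < 5 — the
documented property of the final set. All-relevant selection is
in-sample: at small n, a noise feature with a chance label correlation
of ~2/√n can be legitimately confirmed.

## Classification and evaluation

Univariate logistic models are fitted by maximum likelihood on features
z-scored with *training-cohort* moments (the same scaler is applied to
the test cohort; a leakage test asserts this). Complete separation is
detected via the fitting warnings and handled by a Firth bias-reduced
fallback, flagged in the result. AIC = 2k − 2·logL with k = 2. Model
comparison is by ascending AIC with alphabetical tie-break. Evaluation
at probability 0.5 reports the confusion counts; accuracy with exact
Clopper–Pearson 95% CI (this reproduces the printed 0.572–0.982
interval for 12/14 to three decimals); balanced accuracy; Cohen's κ;
F1; AUC as the Mann–Whitney statistic with a DeLong normal-approximation
CI. The decision stump scans midpoints of sorted unique values,
minimizing Gini impurity with ties broken toward the widest margin; an
exhaustive-search oracle checks it.

## Longitudinal mixed model

Random-intercept logistic regression fitted by Laplace-approximated
maximum likelihood: per-patient intercept modes are found by a
vectorised Newton iteration; the marginal log-likelihood adds the
−½·Σ log(1 + σ²Wᵢ) curvature correction; the outer optimiser is
L-BFGS-B on (β₀, β₁, log σ) warm-started from the pooled logistic fit,
ftol 1e−12. Wald SE comes from the finite-difference Hessian of the
Laplace objective (central differences, step 1e−4), with a fixed-effect
block fallback at the σ → 0 boundary. AIC/BIC use k = 3. The feature is
z-scored across all longitudinal records by default. Validation: the
Laplace log-likelihood agrees with 15-node adaptive Gauss–Hermite
quadrature within 0.1 on ~8-patient datasets (per-group Laplace error
for Bernoulli data is ~0.01, which is what ties the absolute band to
the dataset size); simulation shows ~0.94 two-SE coverage for β at 200
patients × 3 years and type-I error within 0.05 ± 0.02. Random slopes,
time trends and transition models are out of scope.

## Group comparisons and power

Per continuous variable: Shapiro–Wilk in each group at α = 0.05; Welch
t with mean (SD) if both pass, otherwise Wilcoxon rank-sum with median
(IQR) — nonparametric wins whenever the groups disagree (conservative).
Categorical variables use χ². P-values are Benjamini–Hochberg adjusted
within each reported table. Identical samples short-circuit the rank
test to p = 1. The power routine inverts the two-sided two-sample
noncentral-t power function; d = 0.9, power 0.8, α = 0.05 gives n = 21
per group.

## Problem sizes and determinism

Default generator geometry is the full 256×256 grid; test and
acceptance runs use 64–128 px grids with proportionally scaled annuli
and reduced replicate counts, which exercise identical code paths at a
fraction of the cost. Every stochastic step takes an explicit seed;
pipeline runs write the exact configuration next to their artifacts, and
reruns with equal seeds produce byte-identical metric JSON (asserted in
the suite).

## Known limitations

* The synthetic texture model is stationary and isotropic within a
  class; real LGE patterns (subepicardial, transmural) are spatially
  structured in ways a GRF plus disc lesions only caricatures.
* Feature-family membership matches the printed cardinalities of the
  standard radiomics catalog, but third-party numeric parity (e.g. bin
  alignment, boundary conventions) is out of scope; correctness is
  established against in-repo enumeration oracles instead.
* The Laplace fit shares the known small-cluster attenuation of
  binary-outcome mixed models; with ≤ 3 observations per patient,
  slope estimates are mildly biased toward zero.
* No DICOM ingestion, motion correction, age matching, or 3D features.
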