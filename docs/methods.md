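# Methods

## Scene model

Every synthetic scene is defined by a target-species cover field
`c(p) ∈ [0, 1]` on a regular grid (default 400 × 400 px at 1 m GSD), a
background composition field `w(p)` (convex weights over `n_bg = 5`
background endmembers), and a spectral library. A pixel's reflectance is
the linear mixture

    r(p) = c(p)·S_t + (1 − c(p)) · Σᵢ wᵢ(p)·Bᵢ + ε,   ε ~ N(0, σ²I),

clipped to [0, 1]. Linear mixing is the structural assumption behind
sub-pixel cover: a plot with 30 % target cover contributes pixels whose
spectra are 70 % background. No radiative transfer, BRDF, sensor PSF or
atmospheric effects are modelled.

### Cover field

Seeded white noise is smoothed with a Gaussian kernel (correlation length
6 m by default) and transformed monotonically by rank: exactly the top
`prevalence` quantile of pixels (default 4.5 %, capped at 5 %) receives
cover ≥ 20 %, a same-width quantile fringe below ramps 0 → 20 % so patches
have soft margins, and everything else is zero. Within the covered tail,
ranks map through a piecewise-linear inverse CDF that places 30/30/40 % of
covered pixels into the cover classes 20–40 / 50–70 / 80–100 %. The
high-cover weighting is a design choice: it guarantees dense patch cores
large enough to host the 50 high-cover field plots the reference design
requires, mirroring a landscape where an expansive species has already
formed compact monospecific stands. Realized prevalence is exact by
construction; generation fails loudly if any stratum would be empty.

### Background composition

Each background endmember receives an independent smooth Gaussian field;
per-pixel weights are a softmax over the standardized fields with
concentration 3. Most locations are therefore dominated by one or two
background species with smooth transitions — a species-rich mosaic rather
than a homogeneous blend. (Averaging smoothed positive fields instead
would collapse the weights toward uniform and make the background
spatially homogeneous, which defeats the purpose of a heterogeneous
background.)

### Spectral library and separability

Endmembers are smooth vegetation-like curves — green peak near 550 nm,
chlorophyll trough near 680 nm, logistic red edge to a NIR plateau, water
absorption near 970/1200/1450/1940 nm — with seeded parameter jitter. The
target spectrum is the mean background signature displaced along a
vegetation-shaped direction; the `separability` parameter is the largest
per-band reflectance deviation from that mean (default 0.03).

The default separability/noise pair (0.03, 0.01) was fixed by one a-priori
criterion: the naive Stage-0 split should score in the Kappa ≈ 0.67–0.75
band that airborne campaigns of this design report for herbaceous targets.
At the defaults the mean Stage-0 Kappa over seeds 1–4 is 0.72. Real
separability between a species and its background is scene- and
date-specific; this knob is the single largest abstraction in the
simulator.

## Preprocessing

* **Savitzky–Golay smoothing** along the band axis, window 13, polynomial
  order 2; edge bands take the value of the polynomial fitted to the
  first/last full window.
* **Noise covariance** by the horizontal shift-difference estimator:
  `cov(r(p) − r(p_right)) / 2` over valid neighbor pairs. This assumes the
  signal is spatially smoother than one pixel; it is the standard choice
  when no dark measurements exist. The estimate is regularized by `εI`
  (`ε = 1e-8 · trace/B`) when not positive definite — synthetic noiseless
  cubes would otherwise be singular.
* **MNF** solves `Σ_total v = λ Σ_noise v` (scipy `eigh`), orders
  components by decreasing λ, and projects mean-centred spectra.
  Eigenvectors are scaled so `Vᵀ Σ_noise V = I` and signed so the
  largest-magnitude loading is positive, making outputs reproducible
  across eigensolvers. With isotropic noise the transform reduces exactly
  to PCA, which the tests exploit as an oracle. The first `k = 30`
  components feed classification.

## Sampling design

Reference plots are circles of radius 2 m; membership is by pixel centre,
which yields 13 pixels on a 1 m grid when the centre is pixel-aligned. The
nominal bookkeeping count remains 15 px/plot (110 plots ≈ 1650 nominal
target pixels). Cover is annotated as the mean over member pixels rounded
to the nearest 10 %; the decile grid makes the three strata exhaustive for
covers ≥ 20 %. Placement is seeded rejection sampling: target plots fill
the 30/30/50 stratum quotas, background plots require strictly zero target
cover at every member pixel, all plots are pairwise pixel-disjoint with a
minimum centre spacing (6 m at desk scale; 10 m in the survey-scale config —
at desk scale, 110 plots at 10 m spacing would exceed the packing capacity
of the ~7200 m² covered area). The fixed validation set (10 per stratum +
100 background) is chosen by greedy farthest-point spread for even spatial
coverage and is byte-identical across all Stage 1/2 runs, as is the
100-plot background training set.

## Scenario construction

Stage-1 training sets allocate their 30 target plots equally across the
strata intersecting the scenario's cover range, remainder to the highest
stratum. When a stratum cannot fill its share from the eligible pool the
shortfall spills to the next higher stratum (and back down if needed).
The spill rule matters only for SC3 (70–100 %), where the 50–70 stratum is
eligible solely at exactly 70 % cover — a strict equal split would demand
15 such plots, which no realistic design contains. Stage-2 sets reuse the
same seeded per-stratum permutations and take prefixes, so the 20-plot set
is nested in the 30-plot set (identical to the winning Stage-1 set) which
is nested in the 40-plot set; comparisons across Stage 2 therefore isolate
sample size.

## Classification and evaluation

Random Forest with 100 trees, Gini splits, √k features per split,
bootstrap, no tuning, no class-balance correction — deliberately the plain
algorithm, because its sensitivity to imbalance is part of what the
experiment measures. All pixels of a training plot inherit the plot label
regardless of cover. A polygon-level leakage assertion runs before every
fit. The presence–absence map thresholds the tree-vote fraction at 0.5.

Evaluation:

* **Kappa / F1** on validation pixels (plot-labelled truth).
* **Stratum TP fractions**: share of correctly labelled pixels in
  validation target plots per cover class; background validation FP share
  as the overestimation signal. The scalar used to rank scenarios on this
  criterion is `mean(stratum TP) − background FP` — any monotone
  combination is defensible; this one weighs the three strata equally.
* **Zonal field-map compatibility**: pixels whose centres fall in the
  control square are split by membership in the field-mappable patches
  (4-connected components of cover ≥ 20 % with area ≥ 10 m²) and by map
  label. TP + FN equals the species zone area and FP + TN the background
  zone area, exactly. Percentages normalize TP, FP, FN by the species zone
  area and TN by the background zone area, rounding half-up — the
  asymmetric convention of the campaign table this package bundles, under
  which FP % is an overestimation ratio that can exceed 100 %.
* **Winner selection**: per-criterion winners (mean of Kappa and F1;
  stratum score; zonal TP % with lower FP % as tie-break), then majority
  vote, with the field-mapping criterion deciding three-way splits.

The control square defaults to 4 ha at desk scale (a 10 ha square does not
fit a 16 ha scene while leaving sampling room; the survey-scale config uses
10 ha) and is placed on the candidate square containing the most
field-mappable species area.

## Determinism and problem sizes

All randomness derives from one master seed through named
`SeedSequence` children (library, scene, noise, sampling, splits, RF).
Rerunning a config reproduces every report byte-for-byte. The desk-scale
default — 60 bands, 400 × 400 px, ~2 s per scenario run — keeps a full
9-run experiment near 10 s and the 10-replicate property suite under two
minutes; the 430-band survey-scale config exists but is not exercised by
the test suite.

## What the synthetic experiments do and do not show

The replicated qualitative effects — low-cover-only training (SC0)
overestimates relative to high-cover-only training (SC4); SC4 is most
accurate in its own 80–100 % stratum; 20 training plots underestimate
relative to 30/40 — are consequences of labelled mixed pixels under linear
mixing and class imbalance, and they reproduce here without any airborne
data. What the simulator cannot show: phenology-driven signature shifts,
within-species spectral variability, georeferencing error, BRDF and
mosaicking artifacts, or the specific accuracy numbers of any real
campaign — those depend on true spectral separability, which is a free
parameter here. The bundled campaign table is used only for exact
arithmetic worked examples (percentage-convention recomputation and
winner-vote logic), never as a target for the simulation.
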