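# Methods

This note records the models, parameter choices and numerical details
behind `holopol`, and what the synthetic experiments do and do not show.

## Forward optical model

**Probe.** The illumination is ideal unit-amplitude circular
polarization, Jones vector (1, i)/√2, identical at every pixel.  The
quarter-wave plate of the physical bench is assumed perfect and the beam
uniform; source speckle, partial coherence and wavefront error are not
modeled.

**Sample plane.**  Each particle pixel multiplies the field by the Jones
matrix of an absorbing linear retarder,
J = t·e^{iφ₀}·R(θ)·diag(e^{+iδ/2}, e^{−iδ/2})·R(−θ), with amplitude
transmittance t ∈ [0, 1], phase thickness φ₀ (optical path difference ×
2π/λ), retardance δ ∈ [0, π] and fast-axis orientation θ (π-periodic).
The convention is fixed so that the circular probe maps to
(S1, S2, S3)/S0 = (−sin δ sin 2θ, sin δ cos 2θ, cos δ) with
S = (|Ex|²+|Ey|², |Ex|²−|Ey|², 2Re(Ex̄Ey), 2Im(Ex̄Ey)); the unit test
suite pins this against a Mueller-matrix hand calculation.  Background
pixels transmit unchanged.

**Propagation.**  Each Jones component propagates independently by the
angular-spectrum method: H(fx, fy) = exp(i2πz√(1/λ² − fx² − fy²)), with
evanescent components zeroed.  This scalar-per-component treatment of
vector diffraction is appropriate for the paraxial in-line geometry and
the short default distance (z = 5 mm).  At the default 3.45 µm pitch the
sampled band (|f| ≤ 145 mm⁻¹) lies entirely inside the propagating
circle (1/λ = 1880 mm⁻¹), so |H| = 1 across the band and propagation is
exactly unitary; energy conservation is asserted to 1e-9 relative in the
tests.  z = 0 returns the input field identically.  The FFT imposes
periodic boundaries; scenes keep particles away from the grid edge so
wrap-around fringes are negligible.

**Recording.**  Analyzer a projects the field, I_a = |p_a†E|², with
p_a = (cos α, sin α) for the linear states α ∈ {0°, 45°, 90°, 135°} and
p = (1, i)/√2 for the optional right-circular channel.  Intensities are
scaled so `full_scale` (default 2.0, leaving headroom above the unit
background for constructive fringes) maps to digital full scale.  With a
noise seed, the sensor model applies Poisson shot noise at the photon
budget (default 50 000 expected counts at full scale), additive Gaussian
read noise (default 2 counts RMS), and quantization to the configured
bit depth (default 16).  Without a seed the frame is noiseless, and with
`bit_depth=None` it stays real-valued — the configuration used when
validating the inversion to 1e-6 rad, a tolerance quantization alone
would violate (~1e-4 rad at 16 bits).

## Class profiles and the synthetic dataset

Eight built-in profiles: five microplastic-like (PC, PET, PP, PVC,
PMMA) and three biological-like (Chlorella, Daphnia magna, plant-root
sections).  The discriminating structure follows the physics of
semicrystalline polymers versus soft biological tissue: microplastics
get strong mean retardance in disjoint per-class bands
(0.60–0.80, 0.95–1.15, 1.30–1.50, 1.65–1.85, 2.00–2.20 rad) with smooth
(uniform or linearly varying) axis fields and elliptical shapes, while
biological classes get weak retardance (0.06–0.38 rad), patchy axis
domains, stronger retardance texture and irregular blob boundaries
(low-order harmonic perturbations of an ellipse).  Transmittance ranges
overlap across all classes.  Particle equivalent diameters default to
8–70 px depending on class, honoring a ≥6 px minimum (20 µm at 3.45 µm
pitch).  **The per-class retardance bands are this package's own
synthetic choices** — the true retardances of the reference materials
are not published values and these numbers must not be read as material
constants.

Retardance fields inside a particle are clipped to [0.05, π−0.02] so
the axis field remains observable everywhere (DoLP = sin δ stays above
the 0.02 estimation floor).  Texture noise is generated in
particle-anchored patches, so whole-pixel translation of a particle
translates its texture exactly — feature extraction is
translation-invariant by construction and tested as such.

What the generator does *not* emulate: water turbidity and scattering,
polychromatic illumination, sensor mosaic demosaicing, optical
aberrations, particle aggregation, and real intra-class material
variability (weathering, surface fouling).  A high AUC on this synthetic
dataset therefore demonstrates that the pipeline recovers and exploits
the encoded polarization/holographic/texture differences; it does not
predict the accuracy achievable on real specimens.

## Polarimetric inversion

With only the four linear analyzers, (S0, S1, S2) come from the closed
form; S3 is unobservable and retardance is estimated as
δ = arcsin(DoLP), which cannot distinguish δ from π − δ.  This fold is
surfaced as `retardance_branch="folded"` rather than silently resolved.
With the right-circular channel the full Stokes vector is solved by
least squares and δ = arccos(S3/S0) covers [0, π].  The simulated
datasets include the circular channel by default because the built-in
profiles place three microplastic classes above π/2.  Axis orientation
θ = (AoP − 45°) mod 180° is masked where DoLP < 0.02 (no usable axis
signal).  Pixels with S0 below 1e-6 × frame maximum are masked
everywhere.  Angular summaries (AoP, θ) use axial circular statistics on
doubled angles (circular mean, circular SD, IQR of deviations wrapped
around the circular mean), with a 180° period.

## Segmentation

Otsu thresholding of |S0 − median| applied directly to a hologram
segments each particle's fringe system into separate rings.  Detection
therefore runs on a 3 px Gaussian low-pass of the deviation image (the
fringes are zero-mean modulations and average out, while the absorbing
particle body survives), followed by 3×3 opening/closing and 8-connected
labeling; each detected region is then refined by a second Otsu
threshold on the *unsmoothed* deviation inside the region, recovering
the particle body without the fringe halo.  Measured on the built-in
profiles: one ROI per single-particle frame, mask IoU against ground
truth 0.86–0.95 at z = 5 mm and 0.97–1.0 in focus.  Each ROI carries a
10 px dilation-ring background annulus excluding all particle masks,
used by the holographic features.

## Features

- **C1 NGTDM** (Amadasun–King coarseness, contrast, busyness,
  complexity, strength): 3×3 neighborhoods excluding the center, with
  neighbors clipped at the mask boundary so background never
  contaminates the statistics; pixels with no in-mask neighbor are
  excluded.  Zero denominators are guarded by 1e-12 and coarseness is
  capped at 1e6 for flat ROIs.
- **C3 GLSZM**: 8-connected same-level zones (consistent with the
  segmentation topology); small/large zone emphasis, zone-size
  non-uniformity, zone-size entropy, large-zone high-gray-level
  emphasis, gray-level non-uniformity, all normalized by the total zone
  count.
- Both use equal-width quantization of in-mask values to 32 gray levels
  (a common radiomics default; configurable), and both are validated
  against exhaustive brute-force enumeration oracles on random small
  ROIs to 1e-12 relative.
- **C2 FPS**: power spectrum of the bounding-box crop zero-padded to a
  square power of two; 8 radial annuli and 8 angular half-plane sectors,
  both restricted to the inscribed Nyquist disc |f| ≤ 0.5 cycles/px
  (inside the disc every angular sector subtends equal spectral area;
  the square's corners would otherwise bias the diagonal sectors) and
  normalized by total non-DC in-disc power.  Computed on the S0 image —
  the total-intensity hologram.
- **C8 holographic**: percentile-robust Michelson fringe contrast
  (P98−P2)/(P98+P2) over the annulus (plain min/max is noise-dominated),
  and transparency = mean in-mask / mean annulus intensity, clipped to
  [0, 1.5].
- **C4–C7**: mean/SD/IQR of DoLP and retardance, circular
  mean/SD/IQR of AoP and axis orientation, over ROI ∩ validity masks.

The scalar set per group is frozen in `feature_registry` (41 features)
so tables are comparable across runs.  A feature that cannot be computed
(empty annulus, degenerate ROI) is NaN — flagged missing, never
fabricated — and median-imputed inside training folds at classification
time.

## Correlation and distribution summaries

Pearson correlations use pairwise-complete observations (per-feature
missingness comes from masked ROIs); zero-variance columns are excluded
and reported.  The group-level matrix aggregates each cross-group block
by its mean correlation with sign retained — how a many-feature group
pair should collapse to a single number is genuinely open, and the mean
is this package's choice.  Violin densities use a Gaussian KDE with
Silverman bandwidth on 64 support points; rendering is left to
notebooks.

## Classification

Features are standardized (zero mean, unit variance, training folds
only) and each column is multiplied by its category weight divided by
the category's feature count, with category weights in the ratio
polarization : holographic : texture : FPS = 4:2:2:2 (C4–C7 /
C8 / C1+C3 / C2).  Whether the reference analysis weighted columns,
resampled subsets or fused scores is unstated; column weighting after
standardization is this package's documented reading, and the division
by feature count makes the ratio a statement about category mass rather
than per-column gain.

Classifier presets (families only are fixed; hyperparameters are
toolbox-style defaults, overridable via `ClassifierSpec.params`):

- **ESD** — random-subspace ensemble of linear discriminants: 30
  learners, ⌈d/2⌉-dimensional subspaces, averaged posteriors (the
  standard construction behind "ensemble subspace discriminant");
- **KNN** — k = 10, Euclidean on the standardized/weighted features,
  distance-weighted votes;
- **NN** — one hidden layer of 25 units, max 500 epochs, seeded
  initialization;
- **SVM** — linear kernel, one-vs-one decision values pooled to
  per-class one-vs-rest scores.

Evaluation repeats stratified 5-fold cross-validation (default R = 20
repeats; the reference analysis used 500 — 20 keeps the default
experiment desk-scale and the across-repeat variance estimate already
stabilizes well below the reporting threshold) with reshuffled folds per
repeat, pooling out-of-fold scores into per-class one-vs-rest ROC curves
(own threshold-sweep implementation, trapezoid AUC, validated exactly
against the Mann–Whitney pairwise-concordance statistic).  The macro
(unweighted class-mean) AUC is reported per repeat with its
across-repeat mean and variance (ddof = 1); macro averaging is chosen
because the reference class histogram is imbalanced (126 vs 789).
Imputation, standardization and weighting are fitted strictly inside
training folds; an instrumentation hook exposes the fitted
preprocessing for leakage tests.  Per-category comparisons share fold
assignments across conditions so the polarization-vs-texture comparison
is paired per repeat.

## Reference experiment sizes

The default validation experiment uses 8 classes × 50 particles on
256 × 256 grids (the full 1028 × 1232 sensor format is available by
configuration), z = 5 mm, default noise, R = 20 repeats — about one
minute end to end on one CPU.  Unit-test experiments use 64–128 px
grids and fewer draws.

## Known limitations

- The linear-only retardance branch fold (δ ↔ π − δ) is inherent to the
  acquisition, not an implementation limit; classes straddling π/2
  require the circular channel.
- Segmentation assumes sparse, non-overlapping particles on a uniform
  background; touching particles merge into one ROI.
- The simulator's class separability is, by construction, carried
  primarily by the polarization channel; conclusions about the relative
  worth of feature families on real data require real data.
- No depolarization: every pixel is fully polarized by construction, so
  DoLP deficits only arise from noise, fringes and the retarder model,
  not from scattering.
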