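# holopol

Single-shot four-state polarization holography for particle
identification: a physics-based simulator of the optical bench, Stokes
polarimetry, radiomics-style feature extraction, and cross-validated
ROC/AUC classification — aimed at telling birefringent microplastic
particles (PC, PET, PP, PVC, PMMA) apart from weakly birefringent
natural particles (microalgae, zooplankton, plant tissue) in a single
camera exposure.

## The measurement

A 532 nm circularly polarized probe, Jones vector (1, i)/√2, passes
through a sample plane of particles.  A birefringent particle acts as a
linear retarder with retardance δ and fast-axis orientation θ:

    J = t · e^{iφ₀} · R(θ) · diag(e^{+iδ/2}, e^{−iδ/2}) · R(−θ)

The modulated field propagates ~5 mm to the sensor (band-limited
angular-spectrum diffraction), producing in-line holographic fringes,
and is recorded through a polarization mask in one shot: linear
analyzers at 0°, 45°, 90°, 135°, optionally a right-circular channel.

From the analyzer intensities the per-pixel Stokes vector is recovered
(S0 = (I0+I45+I90+I135)/2, S1 = I0−I90, S2 = I45−I135, plus S3 by least
squares when the circular channel is present), and from it the
polarization maps.  For the circular probe through a retarder,

    (S1, S2, S3)/S0 = (−sin δ sin 2θ,  sin δ cos 2θ,  cos δ),

so DoLP = sin δ, AoP = θ + 45°, δ = arccos(S3/S0) (full-Stokes) or
arcsin(DoLP) (linear-only, folded to [0, π/2]), θ = AoP − 45°.

Each segmented particle then yields eight feature groups: C1 NGTDM
texture, C2 Fourier-power-spectrum radial/angular profiles, C3 GLSZM
zone statistics, C4–C7 polarization summaries (DoLP, AoP, retardance,
axis orientation), C8 holographic (fringe contrast, transparency).
Classification combines the categories with a 4:2:2:2 weighting of
polarization : holographic : texture : FPS and evaluates with repeated
stratified 5-fold cross-validation, reporting the macro one-vs-rest AUC
and its across-repeat variance.

## Worked example

```python
from holopol.classify import ClassifierSpec, CVPlan, cross_validate
from holopol.io_core import OpticalConfig
from holopol.pipeline import synthetic_feature_table

table = synthetic_feature_table(per_class=10, optics=OpticalConfig(shape=(256, 256)), seed=7)
result = cross_validate(table, ClassifierSpec(kind="SVM"), CVPlan(folds=5, repeats=5, seed=7))
print(f"particles: {len(table.df)}")
print(f"mean macro AUC: {result.mean_macro_auc:.3f}")
print(f"across-repeat variance: {result.var_macro_auc:.2e}")
```

prints

```
particles: 81
mean macro AUC: 0.868
across-repeat variance: 1.30e-04
```

i.e. 81 particles were simulated and segmented across the eight built-in
class profiles (a frame occasionally contributes a second ROI), and an
SVM on the weighted feature combination separates the eight classes with
a mean macro one-vs-rest AUC of 0.868 that is stable across reshuffled
cross-validation repeats.

The same pipeline is available as a console tool:

```sh
holopol simulate --out data/ --seed 3 --per-class 10   # frames + ground truth + manifest
holopol extract  --manifest data/manifest.csv --out features.csv
holopol correlate --features features.csv --out corr
holopol evaluate --features features.csv --seed 0 --out eval/
```

## Layout

- `holopol.io_core` — TIFF/PNG frame I/O, CSV manifests and feature
  tables, YAML run configuration.
- `holopol.simulator` — class profiles, scene sampling, Jones-calculus
  forward optics, angular-spectrum propagation, sensor model, dataset
  generation.
- `holopol.polarimetry` — Stokes inversion, AoP/DoLP/retardance/axis
  maps, circular (axial) statistics, C4–C7 summaries.
- `holopol.features` — segmentation, NGTDM/GLSZM/FPS/holographic
  features (C1–C3, C8).
- `holopol.stats` — feature/group Pearson correlation, per-class
  distribution summaries.
- `holopol.classify` — category weighting, ROC/AUC, the four classifier
  families (ESD/KNN/NN/SVM), repeated cross-validation.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
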