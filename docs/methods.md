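# Methods

## Measurement model

The input is a pair of calibrated reflectance datacubes per test — bare skin
(`T0`) and immediately after foundation application (`Timm`) — on a common
wavelength grid (natively 420–730 nm at 10 nm, 32 bands) with a known pixel
pitch (nominally 160 µm/px). Calibration (white-reference division) is
assumed upstream; values slightly above 1 (specular glints) are flagged in
QC summaries but never clipped, since clipping would bias angle statistics.
No smoothing or denoising is applied before analysis.

No pixel registration between time points is assumed: the two reference
modes are defined per time point, and the same-time-point reference at
`Timm` is recomputed from the `Timm` cube.

## Spectral-angle statistics

The spectral angle θ between two spectra is the arccosine of their
normalised dot product, in degrees. It is computed internally through the
chord of the unit vectors, θ = 2·arcsin(‖û−v̂‖/2), which is algebraically
identical but numerically stable near θ = 0 where the arccosine loses half
its precision — this matters because the perfect-homogeneity limit drives
θ to exactly zero. For non-negative reflectance spectra θ ∈ [0°, 90°]; the
half-chord is clamped to [0, 1] to absorb floating rounding.

Per-ROI distributions are summarised by the mean μθ, the **population**
standard deviation σθ (the ROI is the entire population of interest; stated
explicitly so cross-implementation comparisons match), and a fixed-width
histogram from 0° with 0.1° bins by default (configurable; 0.1° resolves
the 2–7° structure typical of cheek regions). Pixels with zero-norm or
non-finite spectra have no defined angle: they are masked, counted in QC,
and excluded from μθ, σθ and the histogram.

Coverage factors for a (T0, Timm) pair over a working ROI, with references
taken as the mean spectrum of a nested reference ROI:

* α_HF = 100·(1 − μθ(Timm)/μθ(T0)), same-time-point references. Undefined
  when μθ(T0) = 0; `evaluate_pair` reports NaN with a QC flag when μθ(T0)
  falls below 1e-9° (pure floating residue — real scenes sit orders of
  magnitude above it, sensor noise alone contributing ~1°), while the
  low-level `homogeneity_factor` raises on non-positive μθ(T0).
* β_SF = μθ@T0(Timm) − μθ@T0(T0), reference fixed at T0. The sign is not
  clamped; negative values (possible under noise) are QC-flagged.
* Δμθ = μθ(Timm) − μθ(T0); negative means homogeneity increased.

Peak positions of an angle histogram are located on a 5-bin moving-average
smoothing with a minimum peak separation (default 0.5°); every bin's mass
is assigned to the nearest peak, so reported mass fractions sum to one.
This deterministic rule replaces visual peak reading; peaks closer than the
separation merge, which is the expected behaviour when a product pulls spot
spectra toward the skin. Full mixture-model decomposition of the histogram
is out of scope.

## ROI geometry

ROIs are axis-aligned rectangles in 0-based (row, col) coordinates with
half-open extents. Physical sizes convert as round(mm·1000/pitch), minimum
1 px — 12 mm is 75 px at 160 µm and 35 mm is 223 px at 156.95 µm; the pitch
is per-cube metadata, not a constant. Landmark-relative placement centres
the ROI at the centroid of configurable anchor landmarks (68-point
annotation) plus a millimetre offset; the centre-to-corner conversion is
floor(center − size/2), fixed for determinism. The shipped cheek rules
(anchors on the right jaw contour and nostril wing) reproduce the geometry
class of a nested cheek ROI pair; the exact anchors are package
conventions, since no published constants exist for this placement.
Placement is translation-equivariant and fails loudly when the ROI leaves
the image.

## Colorimetry baselines

Reflectance → XYZ uses the CIE 1964 10° observer and D65, tabulated at
10 nm over 380–780 nm and interpolated linearly onto the cube grid; the
summation is normalised by k = 100/Σ S·ȳ on the same grid, and the Lab
white point is the XYZ of a perfect reflector computed identically — so
R(λ)=1 maps exactly to L\*=100, a\*=b\*=0 regardless of grid truncation.
(On the full 380–780 grid the computed white is (94.83, 100, 107.38),
matching the published D65/10° white to <0.1.) Only D65/1964-10° is a
supported contract. ΔE defaults to CIE76 — the plain Euclidean metric,
with CIE94 and CIEDE2000 selectable and the formula always recorded in
reports. The Coxello index is σL·σa·σb with population SDs; its change is
reported as Timm − T0, and the reporting layer negates it for display so
that positive aligns with a homogeneity increase. It ignores spatial
arrangement entirely (as does α_HF) — a shared, documented limitation.
sRGB rendering clips out-of-gamut channels after gamma encoding and is
used for visualisation only.

## Product comparison

Per-metric product comparisons use classic one-way ANOVA (no Welch
correction) at α = 0.05, followed — only when the ANOVA rejects — by
all-pairs Tukey HSD. Products are partitioned as connected components of
the "not significantly different" relation: deterministic and invariant to
row and label order (a chain of pairwise-similar products merges into one
group; the full pairwise matrix is always reported so chain effects are
visible). Groups are ordered by ascending mean. Quartiles in box summaries
use linear interpolation between order statistics. Correlations are
Pearson r with a least-squares line.

## Multi-scale ROI analysis

To decouple the result from one arbitrary ROI, square ROIs with side
uniform in a millimetre range and position uniform over feasible placements
are drawn (overlap allowed; deterministic per seed) inside a working
region. Per ROI a metric is computed — μθ against the ROI's own mean
spectrum, a local-reference α_HF, or the ΔE76 of the ROI mean colour from
the region mean colour — and aggregated into log-spaced size bins (default
5) as across-ROI mean and population variance. The variance at a given
scale measures texture/evenness: freckle-sized ROIs scatter strongly,
ROIs much larger than the freckles average over many and settle. Defaults
(500 ROIs, 1–10 mm) are package conventions; the analysis itself does not
prescribe them.

## Synthetic scenes

The simulator emulates the study conditions end to end:

* **Skin**: logistic reflectance rise r_min + (r_max−r_min)/(1+exp(−(λ−λ0)/w))
  (defaults 0.18→0.60 around 590 nm) minus Gaussian haemoglobin dips at 540
  and 575 nm; parameters must keep values inside (0, 1).
* **Spatial structure**: a smooth random melanin "mottle" field (default SD
  0.04, 1.5 mm correlation length) plus disk spots (default 12 per patch,
  radii 0.4–1.2 mm, melanin strength 0.10–0.30) attenuating the base as
  exp(−m·(λ/550)⁻³). Inhomogeneity must enter through wavelength-dependent
  attenuation because spectral angles are blind to scalar gain.
* **Foundation**: linear spectral blend (1−o)·S + o·shade with opacity o —
  a deliberate simplification of film optics (no Kubelka–Munk) chosen for
  its analytic limits: at o = 1, noiseless, every spectrum equals the shade,
  so α_HF = 100 exactly and β_SF equals the skin-to-shade angle minus
  μθ@T0(T0).
* **Noise**: multiplicative Gaussian at detector SNR 47 (per-voxel
  σ = value/47, clipped at 0), independent realisations per time point,
  seeded. Additive dark noise is omitted.

The study preset holds 9 model presets spanning skin tones, mottle levels
and spot densities, crossed with three products of opacity 0.2/0.5/0.8
(Low/Medium/High). Scenes are 96×96 px patches at 160 µm (≈15 mm of skin)
with a 64×64 working ROI and 24×24 reference patch — sizes chosen so the
full 27-pair study evaluates in under a second while every ROI still holds
thousands of pixels. What passing tests show is that the *estimators*
behave correctly under these controlled conditions (recovering opacity
rankings, analytic limits, texture scales); synthetic scenes do not model
facial geometry, specular/BRDF effects, distinct lesion chemistries
(melasma vs. moles share one melanin law), or product-shade interactions
with skin chemistry, so they say nothing about absolute effect sizes on
real faces.

## Numerical choices and edge cases

* Angle computation via the chord formula (above); reference spectra with
  zero norm are hard errors.
* ENVI headers are written with 17-significant-digit wavelengths so grid
  round-trips are bit-exact; data are stored float64. The HDF5 container
  preserves metadata exactly; ENVI carries metadata as `meta <key>` header
  lines.
* Spectral resampling is per-pixel linear interpolation; extrapolation is
  refused.
* `compare_products` raises when every group has zero variance at
  different means (F undefined) and short-circuits to one group when all
  values are identical.
* Coxello requires ≥ 2 pixels per region (a single-pixel σ is degenerate).
* Multi-ROI bins with no draws are reported with count 0 and NaN
  statistics rather than dropped.

## Known limitations

α_HF and the Coxello index both ignore spatial arrangement — the
multi-scale analysis is the mitigation, not a fix. The homogeneity effect
depends on the chosen ROI and the model's initial inhomogeneity, so
absolute values are not comparable across panels. Only univariate product
comparisons are provided. The grouping rule's transitive merging differs
from compact-letter displays; consult the pairwise table when chains
matter.
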