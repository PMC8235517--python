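# Methods

## Scope

`ctperf` implements a complete desk-scale version of a CT-perfusion (CTP)
dose-reduction study: a seeded 4D phantom generator with known ground
truth, retrospective simulation of lower tube load (mAs) and lower
temporal sampling, gamma-variate indicator-dilution quantification into
six parametric maps, voxel-wise Pearson comparison of map sets, and
threshold-based lesion volumetrics with paired statistics. Motion
correction, raw-data (sinogram) noise insertion, anatomically realistic
phantoms and non-parametric (SVD) deconvolution are out of scope.

## Perfusion model

Tissue enhancement (ΔHU after baseline subtraction) is modelled as
`Ct = Ft·(AIF ⊛ R)` with the residue function `R = 1 − ∫h` of a delayed
gamma-variate transit-time density `h` with delay `t1` (s), scale `σ1`
(s) and shape `a1` (unitless); `h` is a gamma density with shape
`a1 + 1`, so `R` is evaluated as the regularized upper incomplete gamma
function `Q(a1 + 1, (t − t1)/σ1)` — numerically stable for all valid
parameters, exactly 1 for `t ≤ t1`. Note an implication of this
parametrization: tissue enhancement begins when contrast arrives (`R = 1`
on `[0, t1]`); the delay shifts the washout, not the onset.

The convolution is a causal rectangle rule on the uniform grid,
`Ct[k] = Ft·Δt·Σⱼ AIF[j]·R[k−j]`, shared between the phantom generator
and the fitter. The Δt factor makes the discretization consistent in
physical units, so maps are comparable across sampling intervals;
integral-type quantities (CBV, MSI) therefore do **not** inflate by the
subsampling factor under frame dropping (an implementation without the
Δt scaling would double/triple them at 1/2 and 1/3 sampling).

### Fitting

Per voxel, `(Ft, t1, σ1, a1)` minimize the sum of squared residuals via
bounded trust-region-reflective least squares. Choices:

* Bounds: `Ft ∈ [0, 1]` mL·mL⁻¹·s⁻¹, `t1 ∈ [0, 0.75·scan duration]`,
  `σ1 ∈ [0.1, 20]` s, `a1 ∈ [−0.9, 10]` — keeps the gamma family well
  defined and transit times physiologic.
* Initialization: `Ft` from the curve/AIF peak ratio, `t1` from the TTP
  lag (floored at 0), `σ1 = 1.5` s, `a1 = 1`.
* Tolerances `1e-8`, evaluation budget `max_nfev = 100` per voxel
  (pipeline default; a voxel that exhausts the budget is marked
  non-converged and excluded from the valid mask). Noise-free recovery
  at these settings is accurate to ~0.1% — far inside the 2% the tests
  assert; isolated low-amplitude noise-free curves may need a larger
  budget to satisfy the formal tolerance, which callers can grant
  per call (`max_nfev=400` in the recovery checks).
* Voxel inclusion: a voxel is fitted only if its baseline can be
  detected (sustained 3-sigma enhancement) and its peak ΔHU reaches
  `max(3 × temporal baseline SD, 0.1 HU)`; air/background voxels are
  excluded cheaply and marked invalid (NaN in maps, False in the mask).

For real series without a stored analytic AIF, `select_aif` picks the
arterial input as the highest-peak, earliest-TTP enhancing voxel inside
a user-supplied arterial search mask (baseline-detected and
-subtracted); phantoms bypass selection with their known bolus.

TMAX is reported as the fitted delay `t1`. TTP and MSI are model-free:
TTP is the time from end-of-baseline to the curve maximum; MSI is the
mean enhancement slope from baseline to peak, which telescopes to
`(peak − baseline)/(N·Δt)`.

## Phantom generator

The phantom emulates the studied acquisition groups, not anatomy: a
64×64×4 default grid (1.72×1.72×5 mm voxels) holding four homogeneous
tissue quadrants plus a small arterial disc, separated by background.
Defaults, chosen once as plausible textbook values:

| region      | Ft (mL·mL⁻¹·s⁻¹) | t1 (s) | σ1 (s) | a1 | MTT (s) | baseline HU |
|-------------|------------------|--------|--------|----|---------|-------------|
| gray matter | 0.010            | 2.0    | 1.0    | 1  | 4       | 38          |
| white matter| 0.005            | 2.5    | 1.25   | 1  | 5       | 30          |
| penumbra    | 0.010            | 8.0    | 1.0    | 1  | 10      | 38          |
| core        | 0.002            | 8.0    | 1.0    | 1  | 10      | 38          |

The penumbra's 8 s delay puts it across the `TMAX > 6 s` hypoperfusion
threshold; the core's flow (20% of gray matter) is below the 30%
relative-CBF threshold, and the core shares the 8 s delay so that (as in
stroke) core ⊂ hypoperfused territory — the true hypoperfusion volume is
penumbra + core. The AIF is an analytic gamma-variate bolus (arrival
8 s, peak 150 HU, shape 3, scale 1.5 s) stored with the phantom, so
quantification can be tested with a known input and AIF selection is
bypassed. Acquisition protocols follow the four studied site groups
(100/180/150/150 mAs, 1/1/1.25/1.34 s sampling, 50/45/35/35 frames) with
group-typical baseline noise means 7.81/6.09/3.08/3.20 HU.

What the phantom does **not** emulate: continuous anatomical variation
of perfusion values (regions are internally homogeneous), partial-volume
and beam-hardening effects, patient motion, and realistic AIF selection.
Passing tests therefore demonstrate correctness of the machinery and
recovery under controlled conditions, not clinical performance on
patient data.

## Dose reduction

Image noise obeys `SD ∝ 1/√mAs`. Lowering tube load from E1 to E2 adds
a noise field with `SD(E3) = SD(E1)·√(E1/E2 − 1)`, so the composite
image reaches `SD(E2) = SD(E1)·√(E1/E2)` by independence. The field is
white Gaussian noise convolved with an isotropic in-plane Gaussian
kernel (default σ = 1.5 voxels; slices and frames are independent, as
detection noise decorrelates across scans and slices), then shifted and
rescaled *exactly* to mean 0 / SD(E3) — the target is met by
construction rather than asymptotically. Convolution uses periodic
boundaries so the field is stationary and subset SDs are unbiased.
Values are not clipped at air HU: clipping would bias the noise
distribution. Temporal subsampling keeps frames
`phase, phase+K, phase+2K, …` (default phase 0 preserves the
pre-contrast baseline) and multiplies the protocol's sampling interval
by K.

### Paired noise across the protocol grid

Within one phantom, all degraded protocols share a single unit noise
realisation, scaled to each protocol's SD(E3) (common random numbers);
temporal subsampling then keeps the shared frames. This pairs the
protocol comparisons — differences in r between reduction levels
reflect the dose change, not independent noise draws — mirroring the
clinical design in which every degraded dataset derives from the same
original scan. With independent draws the Monte-Carlo scatter of r
between adjacent reduction levels exceeds the true decrement at
desk-scale voxel counts.

## Comparison and volumetrics

Pearson r pools all voxels of the imaged volume that are valid in both
map sets (invalid fits are excluded, never zero-filled, since zeros
would inflate r); the p-value is the two-sided t-transform with n − 2
degrees of freedom. Hypoperfusion volume counts valid voxels with
TMAX strictly above 6 s; core volume counts valid voxels with CBF below
30% of the reference region's **median** CBF (median for robustness; the
phantom's reference is the gray-matter label, standing in for the
contralateral hemisphere). Volumes are voxel counts × voxel volume from
the header pixdims only. Paired protocol comparisons report the median
and linear-interpolation IQR of per-subject differences
(degraded − original) and a two-sided Wilcoxon signed-rank test
(zero differences dropped, mid-rank ties); the "paired rank-sum" wording
sometimes used for this design is read as the signed-rank test, since
the rank-sum test is unpaired.

## Problem sizes

Chosen as the package's defaults for desk-scale runs: noise-law checks
on a 256×256×4×50 homogeneous phantom; pipeline-identity checks on the
default 64×64×4×50 phantom; ensemble experiments on 24×24×2×50 phantoms
(≈800 tissue voxels each) with 6–10 seeds across the full 8-protocol
grid (4 mAs reductions × {1/2, 1/3} sampling).

## Known limitations

* At the group-A conditions the voxel-level contrast-to-noise ratio is
  below 1 (tissue peak ≈ 4–6 ΔHU vs ≈ 8–10 HU noise), so single-voxel
  fits are noise-dominated and per-phantom r values scatter widely; only
  ensemble means are interpretable, and adjacent reduction levels differ
  by less than the ensemble's Monte-Carlo error for the least stable
  maps (MTT, TMAX) at feasible seed counts.
* Because phantom regions are internally homogeneous, map correlation is
  driven by between-region contrast plus fit noise. In this regime the
  model-free peak statistics (TTP, MSI) become *more* robust at coarser
  sampling — fewer noisy samples from which a spurious maximum can be
  picked — so their r at 1/3 sampling can exceed that at 1/2 sampling,
  the opposite of what patient data with continuous anatomical
  heterogeneity shows. The directional-finding acceptance test
  documents this honestly: CBF and CBV reproduce the expected
  degradation ordering; TTP/MSI/MTT/TMAX do not at this scale.
* The gamma-variate family is identifiable on noise-free curves, but
  under heavy noise fitted `(t1, σ1, a1)` trade off along flat valleys;
  MTT/TMAX maps inherit heavy-tailed errors up to the parameter bounds.
* The baseline detector assumes at least three pre-contrast frames; a
  curve enhancing from the first frames is assigned the minimum baseline
  index 2.
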