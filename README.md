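# ctperf

Dose-reduction study machinery for **cerebral CT perfusion (CTP)**: simulate
lower tube-load and lower sampling-rate acquisitions from a gold-standard
dynamic series, quantify perfusion with a gamma-variate indicator-dilution
model, and measure the degradation of the parametric maps by voxel-wise
correlation and lesion volumetrics. Everything is testable end to end on
synthetic 4D phantoms with known ground truth, so no patient data is needed.

Intended users: medical-physics and image-analysis researchers studying how
far CTP dose (tube load in mAs, temporal sampling rate) can be lowered before
the derived hemodynamic maps stop being clinically useful.

## The model

A dynamic CTP series is a 4D Hounsfield-unit volume `(x, y, z, t)`. After
baseline subtraction, each voxel's enhancement curve is modelled by
indicator-dilution theory as

```
Ct(t) = Ft · (AIF ⊛ R)(t)
```

where `AIF` is the arterial input function, `Ft` the flow, and
`R(t) = 1 − ∫₀ᵗ h(τ)dτ` the residue function of a delayed gamma-variate
transit-time density

```
h(t) = (t − t1)^a1 · exp(−(t − t1)/σ1) / A1,   t ≥ t1,
A1   = σ1^(1+a1) · Γ(1+a1).
```

The per-voxel parameters `(Ft, t1, σ1, a1)` are fitted by bounded
trust-region-reflective least squares (`scipy.optimize.least_squares`), and
six maps follow:

| map  | definition                      | units        |
|------|---------------------------------|--------------|
| CBF  | `Ft`                            | mL·mL⁻¹·s⁻¹  |
| MTT  | `t1 + σ1·(1 + a1)`              | s            |
| CBV  | `MTT · CBF` (central volume)    | mL·mL⁻¹      |
| TMAX | fitted delay `t1`               | s            |
| TTP  | time to curve peak (model-free) | s            |
| MSI  | mean slope of increase, `(peak − baseline)/(N·Δt)` (model-free) | HU/s |

**Dose reduction.** CT noise follows `SD ∝ 1/√mAs`, so an acquisition at
reduced load `E2 < E1` is emulated by adding spatially autocorrelated Gaussian
noise with `SD(E3) = SD(E1)·√(E1/E2 − 1)` (white noise convolved with an
in-plane Gaussian kernel, exactly rescaled). Reduced sampling rates keep one
out of every K frames. Lesion volumetrics use the clinical thresholds
hypoperfusion = `TMAX > 6 s` and infarct core = `CBF < 30%` of the
normoperfused reference.

## Worked example

```python
import numpy as np
from ctperf import (GROUP_PROTOCOLS, ReductionSpec, build_phantom, compute_maps,
                    added_noise_sd, hypoperfusion_volume, core_volume)
from ctperf.compare import degrade_series, compare_map_sets

# a noise-free phantom: four tissue regions with known hemodynamics
clean, truth = build_phantom(GROUP_PROTOCOLS["A"], baseline_noise_sd=0.0,
                             shape=(24, 24, 2), seed=0)
mask = np.isin(truth.label_volume, [1, 2, 3, 4])
gs = compute_maps(clean, truth.aif, mask)
```

Median fitted values per region recover the generating truth exactly
(gray matter was generated with CBF 0.01, MTT 4 s; penumbra with an 8 s
delay; core at 20% of normal flow):

```
gray matter : CBF 0.0100 mL/mL/s  MTT 4.00 s  TMAX 2.00 s
penumbra    : CBF 0.0100 mL/mL/s  MTT 10.00 s  TMAX 8.00 s
core        : CBF 0.0020 mL/mL/s  MTT 10.00 s  TMAX 8.00 s
hypoperfusion 5.92 mL (truth 5.92)   core 2.96 mL (truth 2.96)
```

Degrading a group-A phantom (100 mAs, 1 s sampling, baseline noise 7.81 HU)
by 40% tube load plus 2 s sampling, and correlating the degraded maps with
the gold-standard maps voxel by voxel:

```python
print(added_noise_sd(7.81, 100, 60))           # 6.377 HU added in quadrature
noisy, t = build_phantom(GROUP_PROTOCOLS["A"], baseline_noise_sd=7.81,
                         shape=(24, 24, 2), seed=0)
ngs = compute_maps(noisy, t.aif, mask)
deg, plan = degrade_series(noisy, ReductionSpec(0.40, 2), 7.81, 1.5, seed=7)
dm = compute_maps(deg, t.aif.subsample(2), mask)
for cr in compare_map_sets(ngs, dm):
    print(f"{cr.map_name:>4s}  r = {cr.r:+.3f}  (n = {cr.n_voxels})")
```

```
 cbf  r = +0.221  (n = 115)
 cbv  r = +0.102  (n = 115)
 mtt  r = +0.023  (n = 115)
 ttp  r = -0.039  (n = 115)
 msi  r = -0.193  (n = 115)
tmax  r = +0.042  (n = 115)
```

At this dose level single-voxel tissue enhancement (~4–6 HU) sits below the
image noise (≈10 HU after reduction), so per-voxel estimates — and hence r
on one small phantom — are strongly noise-dominated; ensemble means over
seeds (see `ctperf.study.run_full_study`) are the meaningful quantity.
`docs/methods.md` discusses this regime in detail.

A command-line interface mirrors the library
(`ctperf simulate-phantom | reduce-dose | quantify | compare | volumetrics |
full-run`); volumes travel as NIfTI with a JSON sidecar for acquisition
metadata, tables as CSV.

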