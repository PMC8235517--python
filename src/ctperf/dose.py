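"""Retrospective dose reduction for dynamic CT.

Two independent dose knobs are simulated from a full-dose acquisition:

* **Tube load (mAs).**  CT image noise follows SD ∝ 1/sqrt(mAs), so an
  acquisition at reduced load E2 < E1 has noise
  ``SD(E2) = SD(E1) * sqrt(E1/E2)``.  Because detection noise at the two
  exposures is independent, the noise to *add* to the full-dose image has
  ``SD(E3) = sqrt(SD(E2)^2 - SD(E1)^2) = SD(E1) * sqrt(E1/E2 - 1)``.
  The added field is spatially autocorrelated Gaussian noise (white noise
  convolved with an in-plane Gaussian kernel, then rescaled exactly to
  SD(E3)), which mimics the reconstruction noise texture of clinical CT.

* **Sampling rate.**  Lower frame rates are simulated by keeping one out
  of every K time points (K = 2 halves the dose again, K = 3 keeps a
  third).

Noise is drawn independently per frame and per slice: each dynamic scan
is a separate exposure, and CT noise decorrelates across slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import DynamicSeries, InvalidInputError

__all__ = [
    "NoisePlan",
    "ReductionSpec",
    "DegenerateSeriesError",
    "added_noise_sd",
    "measure_roi_noise",
    "measure_baseline_noise",
    "autocorrelated_noise_field",
    "simulate_reduced_dose",
    "downsample_temporal",
    "study_protocol_grid",
]

#: Default width (voxels) of the in-plane autocorrelation kernel.
DEFAULT_KERNEL_SIGMA = 1.5


class DegenerateSeriesError(ValueError):
    """Temporal downsampling left too few frames to be a usable series."""


def added_noise_sd(sd_e1: float, e1: float, e2: float) -> float:
    """SD of the noise to add when lowering tube load from ``e1`` to ``e2`` mAs.

    Returns ``sd_e1 * sqrt(e1/e2 - 1)``, the quadrature complement that
    raises measured noise ``sd_e1`` to the level of an ``e2``-mAs scan.
    """
    if e1 <= 0 or e2 <= 0:
        raise InvalidInputError(f"tube loads must be positive, got E1={e1}, E2={e2}")
    if e2 > e1:
        raise InvalidInputError(f"cannot remove noise: E2={e2} > E1={e1}")
    if sd_e1 < 0:
        raise InvalidInputError(f"sd_e1 must be >= 0, got {sd_e1}")
    return float(sd_e1 * np.sqrt(e1 / e2 - 1.0))


@dataclass(frozen=True)
class NoisePlan:
    """One reduced-dose simulation: exposure pair, noise SDs, kernel, seed.

    ``sd_e3`` is derived from (``sd_e1``, ``e1``, ``e2``) and checked
    against the quadrature law on construction.
    """

    e1: float
    e2: float
    sd_e1: float
    sd_e3: float
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.e2 <= self.e1):
            raise InvalidInputError(f"require 0 < E2 <= E1, got E1={self.e1}, E2={self.e2}")
        if self.sd_e1 < 0:
            raise InvalidInputError("sd_e1 must be >= 0")
        expected = added_noise_sd(self.sd_e1, self.e1, self.e2)
        if abs(self.sd_e3 - expected) > 1e-9:
            raise InvalidInputError(
                f"sd_e3={self.sd_e3} inconsistent with quadrature law (expected {expected})"
            )

    @classmethod
    def from_reduction(
        cls,
        sd_e1: float,
        e1: float,
        mas_reduction: float,
        kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
        seed: int = 0,
    ) -> "NoisePlan":
        """Plan for a fractional tube-load reduction (0.4 means −40% mAs)."""
        if not 0 <= mas_reduction < 1:
            raise InvalidInputError(f"mas_reduction must be in [0, 1), got {mas_reduction}")
        e2 = e1 * (1.0 - mas_reduction)
        return cls(e1, e2, sd_e1, added_noise_sd(sd_e1, e1, e2), kernel_sigma, seed)


@dataclass(frozen=True)
class ReductionSpec:
    """One degraded protocol: fractional mAs reduction + temporal keep-one-in-K."""

    mas_reduction: float = 0.0
    sampling_keep: int = 1
    phase: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mas_reduction < 1:
            raise InvalidInputError(f"mas_reduction must be in [0, 1), got {self.mas_reduction}")
        if self.sampling_keep < 1:
            raise InvalidInputError("sampling_keep must be >= 1")
        if not 0 <= self.phase < self.sampling_keep:
            raise InvalidInputError(
                f"phase must satisfy 0 <= phase < K, got {self.phase} for K={self.sampling_keep}"
            )

    @property
    def label(self) -> str:
        return f"mas-{int(round(self.mas_reduction * 100))}%_keep1in{self.sampling_keep}"


def study_protocol_grid() -> list[ReductionSpec]:
    """The 8 degraded protocols studied: {10,20,30,40}% mAs × keep-one-in-{2,3}."""
    return [
        ReductionSpec(r, k, 0)
        for k in (2, 3)
        for r in (0.10, 0.20, 0.30, 0.40)
    ]


def measure_roi_noise(series: DynamicSeries, roi: np.ndarray, frame_index: int) -> float:
    """Sample SD (ddof=1) of HU values inside a homogeneous ROI on one frame."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.spatial_shape:
        raise InvalidInputError(
            f"ROI shape {roi.shape} != series spatial shape {series.spatial_shape}"
        )
    n = int(roi.sum())
    if n == 0:
        raise InvalidInputError("empty ROI")
    if n < 25:
        warnings.warn(f"ROI has only {n} voxels; noise estimate will be unstable", stacklevel=2)
    if not 0 <= frame_index < series.n_frames:
        raise InvalidInputError(f"frame_index {frame_index} out of range")
    vals = series.data[..., frame_index][roi]
    return float(np.std(vals, ddof=1))


def measure_baseline_noise(series: DynamicSeries, roi: np.ndarray, n_baseline: int) -> float:
    """Mean of per-frame ROI noise SDs over the first ``n_baseline`` (pre-contrast) frames."""
    if not 1 <= n_baseline <= series.n_frames:
        raise InvalidInputError(f"n_baseline must be in [1, {series.n_frames}]")
    return float(np.mean([measure_roi_noise(series, roi, k) for k in range(n_baseline)]))


def autocorrelated_noise_field(
    shape: tuple[int, ...],
    kernel_sigma: float,
    target_sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spatially autocorrelated Gaussian noise with exact mean 0 and SD ``target_sd``.

    White standard-normal noise is convolved with an isotropic in-plane
    Gaussian kernel of width ``kernel_sigma`` voxels (applied per slice
    for 3D shapes; ``kernel_sigma = 0`` leaves the noise white), then
    shifted and rescaled so the returned field has exactly zero mean and
    SD ``target_sd``.
    """
    if target_sd < 0:
        raise InvalidInputError(f"target_sd must be >= 0, got {target_sd}")
    if kernel_sigma < 0:
        raise InvalidInputError(f"kernel_sigma must be >= 0, got {kernel_sigma}")
    if len(shape) not in (2, 3):
        raise InvalidInputError(f"shape must be 2D or 3D, got {shape}")
    if target_sd == 0:
        return np.zeros(shape, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = rng.standard_normal(shape)
    if kernel_sigma > 0:
        sigmas = (kernel_sigma, kernel_sigma) if len(shape) == 2 else (
            kernel_sigma, kernel_sigma, 0.0)  # in-plane only: slices decorrelate
        # periodic boundaries keep the smoothed field stationary (no edge
        # variance inflation), so subset SDs are unbiased
        field_ = gaussian_filter(field_, sigma=sigmas, mode="wrap")
    field_ -= field_.mean()
    field_ *= target_sd / field_.std()
    return field_


def simulate_reduced_dose(series: DynamicSeries, plan: NoisePlan) -> DynamicSeries:
    """Add autocorrelated noise emulating an acquisition at ``plan.e2`` mAs.

    Independent noise fields are drawn per frame and per slice, each
    exactly rescaled to SD(E3).  ``plan.e2 == plan.e1`` returns a
    bit-exact copy (no noise to add).  The output protocol carries the
    target tube load.
    """
    if abs(plan.e1 - series.protocol.tube_load) > 1e-9:
        raise InvalidInputError(
            f"plan E1={plan.e1} mAs does not match series tube load "
            f"{series.protocol.tube_load} mAs"
        )
    if plan.e2 == plan.e1:
        return series.with_data(series.data.copy(), tube_load=plan.e2)
    rng = np.random.default_rng(plan.seed)
    nx, ny, nz, nt = series.data.shape
    out = series.data.copy()
    for t in range(nt):
        for z in range(nz):
            out[:, :, z, t] += autocorrelated_noise_field(
                (nx, ny), plan.kernel_sigma, plan.sd_e3, rng
            )
    return series.with_data(out, tube_load=plan.e2)


def downsample_temporal(series: DynamicSeries, keep_one_in: int, phase: int = 0) -> DynamicSeries:
    """Keep frames ``phase, phase+K, phase+2K, ...`` (K = ``keep_one_in``).

    K = 2 drops one of every two time points, K = 3 drops two of every
    three; K = 1 is the identity.  The output sampling interval is
    K × the input interval.
    """
    k = int(keep_one_in)
    if k < 1:
        raise InvalidInputError(f"keep_one_in must be >= 1, got {keep_one_in}")
    if not 0 <= phase < k:
        raise InvalidInputError(f"phase must satisfy 0 <= phase < K, got {phase}")
    if k > 3:
        warnings.warn(f"keep_one_in={k} is beyond the studied range (1-3)", stacklevel=2)
    if k == 1:
        return series.copy()
    idx = np.arange(phase, series.n_frames, k)
    if idx.size < 8:
        raise DegenerateSeriesError(
            f"downsampling leaves {idx.size} frames; at least 8 are required"
        )
    proto = replace(
        series.protocol,
        sampling_interval=series.protocol.sampling_interval * k,
        n_frames=int(idx.size),
    )
    return DynamicSeries(
        series.data[..., idx].copy(), series.time[idx].copy(), series.voxel_dims, proto
    )
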