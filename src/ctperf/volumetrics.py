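"""Lesion volumetrics from parametric maps.

Clinical decision thresholds: hypoperfused tissue is TMAX > 6 s and the
infarcted core is CBF below 30% of the normoperfused reference region
(median CBF).  Volumes are voxel counts × voxel volume, in mL.  Paired
protocol comparisons report the median and IQR of per-subject volume
differences plus a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import InvalidInputError

__all__ = [
    "VolumeEstimate",
    "VolumeComparison",
    "TMAX_THRESHOLD_S",
    "CBF_CORE_FRACTION",
    "hypoperfusion_volume",
    "core_volume",
    "estimate_volumes",
    "volume_differences",
]

#: Hypoperfusion threshold on the TMAX map, seconds.
TMAX_THRESHOLD_S = 6.0
#: Core threshold: CBF below this fraction of the normoperfused reference.
CBF_CORE_FRACTION = 0.30


@dataclass(frozen=True)
class VolumeEstimate:
    hypoperfusion_ml: float
    core_ml: float
    protocol_label: str = ""
    reference_cbf: float = float("nan")

    def __post_init__(self) -> None:
        if self.hypoperfusion_ml < 0 or self.core_ml < 0:
            raise InvalidInputError("volumes must be >= 0")


@dataclass(frozen=True)
class VolumeComparison:
    median_diff_ml: float
    iqr: tuple[float, float]
    wilcoxon_p: float
    n_subjects: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.iqr[0] > self.iqr[1]:
            raise InvalidInputError("Q1 must be <= Q3")


def _voxel_ml(voxel_dims: Sequence[float]) -> float:
    return float(np.prod(voxel_dims)) / 1000.0


def hypoperfusion_volume(
    tmax_map: np.ndarray,
    valid_mask: np.ndarray,
    voxel_dims: Sequence[float],
    threshold_s: float = TMAX_THRESHOLD_S,
) -> float:
    """Volume (mL) of valid voxels with TMAX strictly above ``threshold_s``."""
    valid_mask = np.asarray(valid_mask, bool)
    if not valid_mask.any():
        raise InvalidInputError("empty valid mask")
    tmax = np.asarray(tmax_map, dtype=np.float64)
    n = int(np.sum(valid_mask & (tmax > threshold_s)))
    return n * _voxel_ml(voxel_dims)


def core_volume(
    cbf_map: np.ndarray,
    valid_mask: np.ndarray,
    reference_region_mask: np.ndarray,
    voxel_dims: Sequence[float],
    fraction: float = CBF_CORE_FRACTION,
) -> tuple[float, float]:
    """Core volume (mL) and the reference CBF it was thresholded against.

    The reference is the median CBF over valid voxels of the
    normoperfused reference region; core voxels are valid voxels with
    CBF < fraction × reference.
    """
    valid_mask = np.asarray(valid_mask, bool)
    ref_mask = np.asarray(reference_region_mask, bool) & valid_mask
    if not ref_mask.any():
        raise InvalidInputError("reference region holds no valid voxels")
    cbf = np.asarray(cbf_map, dtype=np.float64)
    reference_cbf = float(np.median(cbf[ref_mask]))
    if reference_cbf <= 0:
        raise InvalidInputError(f"reference median CBF must be > 0, got {reference_cbf}")
    n = int(np.sum(valid_mask & (cbf < fraction * reference_cbf)))
    return n * _voxel_ml(voxel_dims), reference_cbf


def estimate_volumes(
    maps,
    reference_region_mask: np.ndarray,
    voxel_dims: Sequence[float],
    protocol_label: str = "",
) -> VolumeEstimate:
    """Both lesion volumes from one ParametricMaps set."""
    hypo = hypoperfusion_volume(maps.tmax, maps.valid_mask, voxel_dims)
    core, ref = core_volume(maps.cbf, maps.valid_mask, reference_region_mask, voxel_dims)
    return VolumeEstimate(hypo, core, protocol_label, ref)


def volume_differences(
    original_ml: Sequence[float], degraded_ml: Sequence[float]
) -> VolumeComparison:
    """Paired per-subject differences (degraded − original).

    Reports the median, linear-interpolation (Q1, Q3), and the two-sided
    Wilcoxon signed-rank p-value (zero differences dropped, mid-rank
    ties).  All-zero differences give a degenerate result with p = 1.
    """
    orig = np.asarray(original_ml, dtype=np.float64)
    deg = np.asarray(degraded_ml, dtype=np.float64)
    if orig.shape != deg.shape or orig.ndim != 1:
        raise InvalidInputError("paired volume lists must be 1D and equal length")
    n = orig.size
    if n < 6:
        raise InvalidInputError(f"need >= 6 pairs for a meaningful test, got {n}")
    diffs = deg - orig
    q1, q3 = np.percentile(diffs, [25, 75])
    median = float(np.median(diffs))
    if np.all(diffs == 0):
        return VolumeComparison(0.0, (float(q1), float(q3)), 1.0, n, degenerate=True)
    p = float(stats.wilcoxon(diffs, zero_method="wilcox", method="auto").pvalue)
    return VolumeComparison(median, (float(q1), float(q3)), p, n)
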