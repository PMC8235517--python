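"""Voxel-wise comparison of parametric maps across degraded protocols.

Gold-standard maps (GSmaps) come from the original full-dose series;
each degraded protocol (reduced mAs and/or temporal subsampling) yields
its own map set, and similarity is the pooled voxel-wise Pearson r over
the whole imaged volume, restricted to voxels valid in both map sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DynamicSeries, InvalidInputError
from .dose import NoisePlan, ReductionSpec, downsample_temporal, simulate_reduced_dose
from .quant import AIFCurve, ParametricMaps, compute_maps

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationError",
    "pearson_pair",
    "compare_map_sets",
    "run_protocol_grid",
    "aggregate_mean_r",
]


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance in one of the maps)."""


@dataclass(frozen=True)
class CorrelationResult:
    map_name: str
    protocol_label: str
    r: float
    p_value: float
    n_voxels: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise InvalidInputError(f"|r| must be <= 1, got {self.r}")
        if self.n_voxels < 3:
            raise InvalidInputError("correlation needs at least 3 voxels")


def pearson_pair(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray,
    map_name: str = "",
    protocol_label: str = "",
) -> CorrelationResult:
    """Pooled Pearson r between two maps over masked, finite voxels.

    All slices are pooled into one sample; the two-sided p-value uses the
    t transform with n − 2 degrees of freedom.
    """
    map_a, map_b, mask = np.asarray(map_a), np.asarray(map_b), np.asarray(mask, bool)
    if not map_a.shape == map_b.shape == mask.shape:
        raise InvalidInputError("maps and mask must share one shape")
    sel = mask & np.isfinite(map_a) & np.isfinite(map_b)
    a, b = map_a[sel], map_b[sel]
    if a.size < 3:
        raise InvalidInputError(f"only {a.size} voxels available; need >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {'first' if np.ptp(a) == 0 else 'second'} map"
        )
    res = stats.pearsonr(a, b)
    return CorrelationResult(
        map_name=map_name,
        protocol_label=protocol_label,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n_voxels=int(a.size),
    )


def compare_map_sets(
    gs: ParametricMaps,
    degraded: ParametricMaps,
    brain_mask: np.ndarray | None = None,
    protocol_label: str = "",
) -> list[CorrelationResult]:
    """One CorrelationResult per map, on the intersection of valid masks."""
    mask = gs.valid_mask & degraded.valid_mask
    if brain_mask is not None:
        mask &= np.asarray(brain_mask, bool)
    return [
        pearson_pair(gs[name], degraded[name], mask, name, protocol_label)
        for name in gs.map_names
    ]


def degrade_series(
    series: DynamicSeries,
    spec: ReductionSpec,
    sd_e1: float,
    kernel_sigma: float,
    seed: int,
) -> tuple[DynamicSeries, "NoisePlan"]:
    """Apply one ReductionSpec: add reduced-mAs noise, then drop frames."""
    plan = NoisePlan.from_reduction(
        sd_e1, series.protocol.tube_load, spec.mas_reduction, kernel_sigma, seed
    )
    noisy = simulate_reduced_dose(series, plan)
    return downsample_temporal(noisy, spec.sampling_keep, spec.phase), plan


def run_protocol_grid(
    original: DynamicSeries,
    specs: list[ReductionSpec],
    aif: AIFCurve,
    mask: np.ndarray,
    sd_e1: float,
    kernel_sigma: float = 1.5,
    seed: int = 0,
    brain_mask: np.ndarray | None = None,
    **quant_kwargs,
) -> pd.DataFrame:
    """GSmaps vs one map set per degraded protocol; one row per (map, spec).

    ``sd_e1`` is the measured baseline noise of the original series.
    All specs share one noise realisation (common random numbers): the
    added field of every protocol is the same unit field scaled to that
    protocol's SD(E3), and temporal subsampling keeps the shared frames.
    This pairs the protocol comparisons, so per-phantom differences in r
    reflect the dose change rather than independent noise draws.  The
    whole table is deterministic given (inputs, seed).
    """
    if len(set(specs)) != len(specs):
        raise InvalidInputError("reduction specs must be distinct")
    gs_maps = compute_maps(original, aif, mask, **quant_kwargs)
    rows = []
    noise_seed = (seed * 1000 + 7) % (2**31)
    for spec in specs:
        degraded, _ = degrade_series(original, spec, sd_e1, kernel_sigma, noise_seed)
        aif_k = aif.subsample(spec.sampling_keep, spec.phase)
        deg_maps = compute_maps(degraded, aif_k, mask, **quant_kwargs)
        for cr in compare_map_sets(gs_maps, deg_maps, brain_mask, spec.label):
            rows.append(
                {
                    "map": cr.map_name,
                    "mas_reduction": spec.mas_reduction,
                    "sampling_keep": spec.sampling_keep,
                    "phase": spec.phase,
                    "protocol_label": cr.protocol_label,
                    "r": cr.r,
                    "p_value": cr.p_value,
                    "n_voxels": cr.n_voxels,
                }
            )
    return pd.DataFrame(rows)


def aggregate_mean_r(
    rows: pd.DataFrame,
    by: list[str] = ("map", "mas_reduction", "sampling_keep"),
) -> pd.DataFrame:
    """Mean, SD and count of r per (protocol × map) group."""
    if rows.empty:
        raise InvalidInputError("no correlation rows to aggregate")
    out = (
        rows.groupby(list(by))["r"]
        .agg(mean_r="mean", sd_r="std", n="count")
        .reset_index()
    )
    return out
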