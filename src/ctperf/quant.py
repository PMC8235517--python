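"""Perfusion quantification by gamma-variate indicator-dilution modelling.

The tissue enhancement curve Ct(t) (in ΔHU, after baseline subtraction)
is modelled as the arterial input convolved with the tissue impulse
response::

    Ct(t) = Ft · (AIF ⊛ R)(t)

where Ft is the flow (mL·mL⁻¹·s⁻¹) and R(t) = 1 − ∫₀ᵗ h(τ)dτ is the
residue function of the transport (transit-time density) function h.
h is a delayed gamma-variate,

    h(t) = (t − t1)^a1 · exp(−(t − t1)/σ1) / A1   for t ≥ t1, else 0,
    A1 = σ1^(1+a1) · Γ(1+a1),

i.e. a gamma density with shape a1 + 1, scale σ1 and delay t1; its mean
transit time is MTT = t1 + σ1·(1 + a1).  The per-voxel parameters
(Ft, t1, σ1, a1) are obtained by bounded trust-region-reflective least
squares, and the six parametric maps follow:

    CBF = Ft                      (flow)
    MTT = t1 + σ1·(1 + a1)        (mean transit time, s)
    CBV = MTT · Ft                (central volume principle, mL·mL⁻¹)
    TMAX = t1                     (impulse-response delay, s)
    TTP  = argmax Ct − t(t0)      (model-free time to peak, s)
    MSI  = mean slope of increase from bolus arrival to peak (HU/s)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaincc, gammaln

from .core import DynamicSeries, InvalidInputError

__all__ = [
    "TransportFunctionParams",
    "FitResult",
    "AIFCurve",
    "ParametricMaps",
    "NoBolusError",
    "detect_baseline",
    "to_concentration",
    "gamma_transport",
    "residue_function",
    "forward_model",
    "tissue_curve",
    "fit_voxel",
    "default_bounds",
    "initial_guess",
    "compute_maps",
    "select_aif",
    "msi",
]

#: Minimum peak enhancement (ΔHU) for a voxel to be fitted at all.
MIN_PEAK_HU = 0.1

MAP_NAMES = ("cbf", "cbv", "mtt", "ttp", "msi", "tmax")


class NoBolusError(ValueError):
    """No sustained contrast enhancement was found in the curve."""


@dataclass(frozen=True)
class TransportFunctionParams:
    """Gamma-variate transit parameters of one voxel: (Ft, t1, σ1, a1)."""

    ft: float
    t1: float
    sigma1: float
    a1: float

    def __post_init__(self) -> None:
        if self.ft < 0:
            raise InvalidInputError(f"Ft must be >= 0, got {self.ft}")
        if self.t1 < 0:
            raise InvalidInputError(f"t1 must be >= 0, got {self.t1}")
        if self.sigma1 <= 0:
            raise InvalidInputError(f"sigma1 must be > 0, got {self.sigma1}")
        if self.a1 <= -1:
            raise InvalidInputError(f"a1 must be > -1, got {self.a1}")

    @property
    def mtt(self) -> float:
        """Mean transit time t1 + σ1·(1 + a1), in seconds."""
        return self.t1 + self.sigma1 * (1.0 + self.a1)

    @property
    def log_a1_norm(self) -> float:
        """log A1 = (1 + a1)·log σ1 + log Γ(1 + a1)."""
        return (1.0 + self.a1) * np.log(self.sigma1) + float(gammaln(1.0 + self.a1))


@dataclass(frozen=True)
class FitResult:
    params: TransportFunctionParams
    residual_norm: float
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise InvalidInputError("residual_norm must be >= 0")


@dataclass
class AIFCurve:
    """Arterial input function: time grid, baseline-corrected ΔHU, baseline index."""

    time: np.ndarray
    concentration: np.ndarray
    t0: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.concentration = np.asarray(self.concentration, dtype=np.float64)
        if self.time.shape != self.concentration.shape or self.time.ndim != 1:
            raise InvalidInputError("time and concentration must be 1D vectors of equal length")
        if not 0 <= self.t0 < len(self.time):
            raise InvalidInputError(f"t0 index {self.t0} out of range")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def subsample(self, keep_one_in: int, phase: int = 0) -> "AIFCurve":
        """AIF on the reduced time grid matching a temporally downsampled series."""
        idx = np.arange(phase, len(self.time), keep_one_in)
        t0 = int(np.searchsorted(idx, self.t0, side="right") - 1)
        return AIFCurve(self.time[idx], self.concentration[idx], max(t0, 0))


# ---------------------------------------------------------------------------
# curve preprocessing

def detect_baseline(curve: np.ndarray, time: np.ndarray) -> int:
    """Index of the last pre-contrast sample of an enhancement curve.

    Scans i = 2, 3, ... and returns the first i for which the next three
    samples all exceed mean + 3·SD of the baseline window [0..i] (i.e.
    enhancement starts, and is sustained, at i + 1).  A curve that rises
    from the very first frames has no detectable baseline and returns
    the minimum allowed index 2; a curve with no enhancement at all
    raises :class:`NoBolusError`.
    """
    curve = np.asarray(curve, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    n = curve.size
    if n < 8:
        raise InvalidInputError("need at least 8 samples to detect a baseline")
    for i in range(2, n - 3):
        base = curve[: i + 1]
        thr = base.mean() + 3.0 * base.std(ddof=1)
        if np.all(curve[i + 1 : i + 4] > thr):
            return i
    # No sustained 3-sigma crossing: either flat (no bolus) or enhancement
    # begins before a baseline can be formed.
    head = curve[:3]
    if curve.max() > head.mean() + 3.0 * head.std(ddof=1) and curve.max() > head.mean():
        return 2
    raise NoBolusError("no sustained enhancement found in curve")


def to_concentration(curve: np.ndarray, t0: int) -> np.ndarray:
    """Baseline-subtract a HU curve: subtract the mean of samples [0..t0]."""
    curve = np.asarray(curve, dtype=np.float64)
    if not 0 <= t0 < curve.size:
        raise InvalidInputError(f"t0 index {t0} out of range")
    return curve - curve[: t0 + 1].mean()


def select_aif(series: DynamicSeries, search_mask: np.ndarray) -> AIFCurve:
    """Pick the arterial input from a user-supplied arterial search mask.

    The AIF voxel is the one with the highest peak enhancement inside
    the mask, ties broken by the earliest time to peak; its curve is
    baseline-detected and -subtracted.  Phantoms carry an analytic AIF
    instead, which bypasses this selection.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    if search_mask.shape != series.spatial_shape:
        raise InvalidInputError(
            f"mask shape {search_mask.shape} != series spatial shape {series.spatial_shape}"
        )
    if not search_mask.any():
        raise InvalidInputError("empty arterial search mask")
    best: tuple[float, float] | None = None  # (-peak, ttp): minimize
    best_curve, best_t0 = None, None
    for xyz in np.argwhere(search_mask):
        raw = series.data[tuple(xyz)]
        try:
            t0 = detect_baseline(raw, series.time)
        except NoBolusError:
            continue
        conc = to_concentration(raw, t0)
        key = (-float(conc.max()), float(series.time[int(np.argmax(conc))]))
        if best is None or key < best:
            best, best_curve, best_t0 = key, conc, t0
    if best_curve is None:
        raise NoBolusError("no enhancing voxel found in the arterial search mask")
    return AIFCurve(series.time.copy(), best_curve, best_t0)


# ---------------------------------------------------------------------------
# transport / residue / forward model

def _check_shape_params(sigma1: float, a1: float) -> None:
    if sigma1 <= 0:
        raise InvalidInputError(f"sigma1 must be > 0, got {sigma1}")
    if a1 <= -1:
        raise InvalidInputError(f"a1 must be > -1, got {a1}")


def gamma_transport(time: np.ndarray, t1: float, sigma1: float, a1: float) -> np.ndarray:
    """Gamma-variate transit-time density h(t), in s⁻¹ (integrates to 1)."""
    _check_shape_params(sigma1, a1)
    t = np.asarray(time, dtype=np.float64)
    x = (t - t1) / sigma1
    out = np.zeros_like(x)
    pos = x > 0
    log_norm = (1.0 + a1) * np.log(sigma1) + gammaln(1.0 + a1)
    with np.errstate(divide="ignore"):
        out[pos] = np.exp(a1 * np.log(t[pos] - t1) - x[pos] - log_norm)
    if a1 == 0:
        out[x == 0] = 1.0 / sigma1
    return out


def residue_function(time: np.ndarray, t1: float, sigma1: float, a1: float) -> np.ndarray:
    """Residue function R(t) = 1 − ∫₀ᵗ h(τ)dτ (fraction of tracer still in tissue).

    Computed as the regularized upper incomplete gamma function
    Q(a1 + 1, (t − t1)/σ1), which is 1 for t ≤ t1 and decays to 0.
    """
    _check_shape_params(sigma1, a1)
    t = np.asarray(time, dtype=np.float64)
    x = np.maximum(t - t1, 0.0) / sigma1
    return gammaincc(a1 + 1.0, x)


def tissue_curve(
    aif_conc: np.ndarray,
    time: np.ndarray,
    ft: float,
    t1: float,
    sigma1: float,
    a1: float,
) -> np.ndarray:
    """Ct on the grid: Ct[k] = Ft·Δt·Σⱼ AIF[j]·R[k−j] (causal rectangle rule)."""
    aif_conc = np.asarray(aif_conc, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    if aif_conc.shape != time.shape:
        raise InvalidInputError("AIF and time vectors must have the same length")
    if ft == 0:
        return np.zeros_like(aif_conc)
    dt = float(time[1] - time[0])
    r = residue_function(time - time[0], t1, sigma1, a1)
    return ft * dt * np.convolve(aif_conc, r)[: aif_conc.size]


def forward_model(aif: AIFCurve, params: TransportFunctionParams) -> np.ndarray:
    """Model tissue curve Ct = Ft·(AIF ⊛ R) for one parameter set."""
    return tissue_curve(
        aif.concentration, aif.time, params.ft, params.t1, params.sigma1, params.a1
    )


# ---------------------------------------------------------------------------
# fitting

def default_bounds(scan_duration: float) -> tuple[np.ndarray, np.ndarray]:
    """Parameter box (Ft, t1, σ1, a1) keeping the gamma family well defined."""
    lo = np.array([0.0, 0.0, 0.1, -0.9])
    hi = np.array([1.0, 0.75 * scan_duration, 20.0, 10.0])
    return lo, hi


def initial_guess(
    curve: np.ndarray, aif: AIFCurve, bounds: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """In-basin start: Ft from the curve/AIF peak ratio, t1 from the TTP lag."""
    lo, hi = bounds
    aif_peak = float(aif.concentration.max())
    ft0 = float(curve.max()) / aif_peak if aif_peak > 0 else 0.01
    ttp_tissue = float(aif.time[int(np.argmax(curve))])
    ttp_aif = float(aif.time[int(np.argmax(aif.concentration))])
    t1_0 = max(ttp_tissue - ttp_aif, 0.0)
    x0 = np.array([ft0, t1_0, 1.5, 1.0])
    return np.clip(x0, lo + 1e-9, hi - 1e-9)


def fit_voxel(
    curve: np.ndarray,
    aif: AIFCurve,
    init: TransportFunctionParams | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    max_nfev: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Fit (Ft, t1, σ1, a1) to one baseline-corrected tissue curve.

    Bounded trust-region-reflective least squares on the forward model;
    non-convergence is reported via ``converged`` rather than raised, so
    callers can exclude the voxel from the valid mask.
    """
    curve = np.asarray(curve, dtype=np.float64)
    if curve.shape != aif.time.shape:
        raise InvalidInputError("curve and AIF grids must have the same length")
    if bounds is None:
        bounds = default_bounds(float(aif.time[-1] - aif.time[0]))
    lo, hi = bounds
    if init is None:
        x0 = initial_guess(curve, aif, bounds)
    else:
        x0 = np.clip(np.array([init.ft, init.t1, init.sigma1, init.a1]), lo + 1e-12, hi - 1e-12)

    conc, t = aif.concentration, aif.time

    def resid(x: np.ndarray) -> np.ndarray:
        return tissue_curve(conc, t, *x) - curve

    res = least_squares(
        resid,
        x0,
        bounds=(lo, hi),
        method="trf",
        x_scale=np.maximum(np.abs(x0), [1e-3, 0.5, 0.5, 0.5]),
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )
    params = TransportFunctionParams(*np.clip(res.x, [0, 0, 1e-6, -1 + 1e-9], None))
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# model-free metrics and maps

def msi(curve: np.ndarray, time: np.ndarray, t0: int) -> float:
    """Mean slope of increase from the end of baseline to the curve peak (HU/s).

    With p = argmax(curve) and N = p − t0 increments, the mean of the
    successive differences telescopes to (curve[p] − curve[t0])/(N·Δt).
    Degenerate curves (peak at or before t0) return 0.
    """
    curve = np.asarray(curve, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    p = int(np.argmax(curve))
    if p <= t0:
        return 0.0
    n = p - t0
    dt = float(time[1] - time[0])
    return float((curve[p] - curve[t0]) / (n * dt))


@dataclass
class ParametricMaps:
    """The six 3D perfusion maps plus the fit-validity mask.

    Invalid voxels (no bolus, sub-threshold peak, or non-converged fit)
    are NaN in every map and False in ``valid_mask``.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    msi: np.ndarray
    tmax: np.ndarray
    valid_mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name.lower() not in MAP_NAMES:
            raise KeyError(name)
        return getattr(self, name.lower())

    @property
    def map_names(self) -> tuple[str, ...]:
        return MAP_NAMES


def compute_maps(
    series: DynamicSeries,
    aif: AIFCurve,
    mask: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    min_peak_hu: float = MIN_PEAK_HU,
    max_nfev: int = 100,
) -> ParametricMaps:
    """Voxel-wise parametric maps over ``mask``.

    Per voxel: detect the baseline, subtract it, require the peak ΔHU to
    reach max(3 × temporal baseline SD, ``min_peak_hu``), fit the
    transport model, and evaluate the six maps.  TTP and MSI are
    model-free (from the measured curve); CBF/MTT/CBV/TMAX come from the
    fitted parameters; CBV = MTT·Ft by the central volume principle.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} != series spatial shape {series.spatial_shape}"
        )
    if not mask.any():
        raise InvalidInputError("empty mask")
    shape = series.spatial_shape
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    valid = np.zeros(shape, dtype=bool)
    time = series.time
    for xyz in np.argwhere(mask):
        x, y, z = xyz
        raw = series.data[x, y, z, :]
        try:
            t0 = detect_baseline(raw, time)
        except NoBolusError:
            continue
        conc = to_concentration(raw, t0)
        base_sd = float(np.std(raw[: t0 + 1], ddof=1))
        peak = float(conc.max())
        if peak < max(3.0 * base_sd, min_peak_hu):
            continue
        fit = fit_voxel(conc, aif, bounds=bounds, max_nfev=max_nfev)
        if not fit.converged:
            continue
        p = fit.params
        maps["cbf"][x, y, z] = p.ft
        maps["mtt"][x, y, z] = p.mtt
        maps["cbv"][x, y, z] = p.mtt * p.ft
        maps["tmax"][x, y, z] = p.t1
        maps["ttp"][x, y, z] = float(time[int(np.argmax(conc))] - time[t0])
        maps["msi"][x, y, z] = msi(conc, time, t0)
        valid[x, y, z] = True
    return ParametricMaps(valid_mask=valid, **maps)
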