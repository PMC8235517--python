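"""Core containers for dynamic CT perfusion series.

A dynamic CT perfusion (CTP) acquisition is a repeated scan of the same
brain volume during contrast-agent passage.  The unit of work throughout
this package is the :class:`DynamicSeries`: a 4D Hounsfield-unit array
(x, y, z, t) together with its time grid, voxel geometry and the
acquisition protocol (tube load in mAs, sampling interval in s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "DynamicSeries",
    "GROUP_PROTOCOLS",
    "InvalidInputError",
]


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Tube load, temporal sampling and frame count of one CTP protocol.

    Parameters
    ----------
    tube_load:
        Tube current-time product in mAs; noise variance scales as 1/mAs.
    sampling_interval:
        Time between dynamic scans, in seconds.
    n_frames:
        Number of dynamic scans (>= 8 so a baseline and a bolus both fit).
    label:
        Free-text protocol name, e.g. ``"group A"``.
    """

    tube_load: float
    sampling_interval: float
    n_frames: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.tube_load > 0:
            raise InvalidInputError(f"tube_load must be > 0, got {self.tube_load}")
        if not self.sampling_interval > 0:
            raise InvalidInputError(
                f"sampling_interval must be > 0, got {self.sampling_interval}"
            )
        if int(self.n_frames) != self.n_frames or self.n_frames < 8:
            raise InvalidInputError(f"n_frames must be an integer >= 8, got {self.n_frames}")

    @property
    def duration(self) -> float:
        """Total scan duration in seconds (first to last frame)."""
        return (self.n_frames - 1) * self.sampling_interval

    def time_vector(self, start: float = 0.0) -> np.ndarray:
        """Uniform acquisition time grid in seconds."""
        return start + np.arange(self.n_frames) * self.sampling_interval


#: Site protocols of the four patient groups studied: (mAs, interval s, frames).
GROUP_PROTOCOLS: dict[str, AcquisitionProtocol] = {
    "A": AcquisitionProtocol(100.0, 1.0, 50, "group A"),
    "B": AcquisitionProtocol(180.0, 1.0, 45, "group B"),
    "C": AcquisitionProtocol(150.0, 1.25, 35, "group C"),
    "D": AcquisitionProtocol(150.0, 1.34, 35, "group D"),
}


@dataclass
class DynamicSeries:
    """A 4D HU volume with time vector, voxel geometry and protocol.

    Invariants (checked on construction): ``len(time) == data.shape[3]``,
    successive time differences equal ``protocol.sampling_interval`` to
    1e-9 s, and all voxel dimensions are positive.
    """

    data: np.ndarray
    time: np.ndarray
    voxel_dims: tuple[float, float, float]
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidInputError(f"data must be 4D (x, y, z, t), got {self.data.ndim}D")
        if self.time.ndim != 1 or len(self.time) != self.data.shape[3]:
            raise InvalidInputError(
                f"time length {self.time.size} != temporal dimension {self.data.shape[3]}"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise InvalidInputError("time vector must be strictly increasing")
        if np.any(np.abs(dt - self.protocol.sampling_interval) > 1e-9):
            raise InvalidInputError(
                "time steps do not match protocol.sampling_interval "
                f"({self.protocol.sampling_interval} s)"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)  # type: ignore[assignment]
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise InvalidInputError(f"voxel_dims must be 3 positive values, got {self.voxel_dims}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        return float(np.prod(self.voxel_dims)) / 1000.0

    def copy(self) -> "DynamicSeries":
        return DynamicSeries(
            self.data.copy(), self.time.copy(), self.voxel_dims, self.protocol
        )

    def with_data(self, data: np.ndarray, **protocol_updates) -> "DynamicSeries":
        """New series sharing geometry, with ``data`` and protocol updates."""
        proto = replace(self.protocol, **protocol_updates) if protocol_updates else self.protocol
        return DynamicSeries(data, self.time.copy(), self.voxel_dims, proto)
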