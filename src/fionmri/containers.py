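"""In-memory containers shared by the simulation and analysis stages.

All image data are plain numpy arrays on one voxel grid; masks are boolean
arrays of the same shape. Grids are index-addressed (0-based), isotropic unless
a voxel size says otherwise, and never resampled by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError


@dataclass
class EchoSeries:
    """Magnitude gradient-echo volumes acquired at a set of echo times.

    ``data`` has shape ``(n_echoes, *grid)``; ``echo_times`` are in ms and must
    be strictly increasing and positive. ``meta`` carries informational
    acquisition parameters (TR, flip angle, FOV, matrix) that no computation
    depends on.
    """

    data: np.ndarray
    echo_times: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.ndim != 1:
            raise ValidationError("echo_times must be a 1-D sequence")
        if self.data.shape[0] != self.echo_times.size:
            raise ValidationError(
                f"{self.data.shape[0]} volumes but {self.echo_times.size} echo times"
            )
        if np.any(self.echo_times <= 0):
            raise ValidationError("echo times must be positive (ms)")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValidationError("echo times must be strictly increasing")
        if np.any(~np.isfinite(self.data)):
            raise ValidationError("echo volumes contain non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("magnitude data must be non-negative")

    @property
    def grid(self) -> tuple:
        return self.data.shape[1:]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    def volume(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class ROISet:
    """Named binary masks (at minimum ``lesion`` and ``muscle``) on one grid.

    Lesion and muscle must be disjoint: the muscle reference must never include
    contrast-carrying voxels.
    """

    masks: dict

    def __post_init__(self):
        masks = {}
        grid = None
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.dtype != bool:
                vals = np.unique(m)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValidationError(
                        f"mask {name!r} is not binary (values {vals[:5]}...)"
                    )
                m = m.astype(bool)
            if grid is None:
                grid = m.shape
            elif m.shape != grid:
                raise GridMismatchError(
                    f"mask {name!r} shape {m.shape} != {grid}"
                )
            masks[name] = m
        self.masks = masks
        if "lesion" in masks and "muscle" in masks:
            if np.any(masks["lesion"] & masks["muscle"]):
                raise ValidationError("lesion and muscle masks overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def grid(self) -> tuple:
        return next(iter(self.masks.values())).shape

    @property
    def lesion(self) -> np.ndarray:
        return self.masks["lesion"]

    @property
    def muscle(self) -> np.ndarray:
        return self.masks["muscle"]


@dataclass
class GroundTruth:
    """Designed truth attached to a simulated volume.

    For phantoms ``t2star_ms`` holds the true per-voxel T2*; for single-echo
    scenes ``hypointense`` flags the voxels carrying labeled-cell signal loss
    and ``designed_fraction_pct`` records the designed hypointense fraction of
    the lesion in percent.
    """

    t2star_ms: np.ndarray | None = None
    hypointense: np.ndarray | None = None
    designed_fraction_pct: float | None = None

    def check_grid(self, grid: tuple) -> None:
        for arr in (self.t2star_ms, self.hypointense):
            if arr is not None and arr.shape != grid:
                raise GridMismatchError(
                    f"ground truth shape {arr.shape} != image grid {grid}"
                )
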