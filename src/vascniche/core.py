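"""Shared containers and error types for the imaging pipeline.

All volumetric data live on a voxel-centered grid in (z, y, x) axis order
with 0-based indices and per-axis physical spacing in micrometres.  The
default spacing (2.0, 0.5, 0.5) um mimics a two-photon z-stack, where the
axial step is coarser than the lateral pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default anisotropic voxel spacing (z, y, x) in um.
DEFAULT_SPACING: tuple[float, float, float] = (2.0, 0.5, 0.5)


class VascnicheError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VascnicheError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateInputError(VascnicheError, ValueError):
    """Input is structurally valid but degenerate (empty mask, constant
    volume for Otsu, empty event table...)."""


class UndefinedRatioError(VascnicheError, ZeroDivisionError):
    """A ratio's denominator is zero; distinct from malformed input."""


class UnreliableEstimateError(VascnicheError, RuntimeError):
    """A Monte-Carlo summary was requested from too few effective samples."""


class InconsistencyError(VascnicheError, ValueError):
    """Two inputs that must agree (shapes, grids, mask membership) do not."""


def _as_spacing(spacing) -> tuple[float, ...]:
    sp = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in sp):
        raise InvalidParameterError(f"spacing must be positive per axis, got {sp}")
    return sp


@dataclass
class ImageVolume:
    """A 3D non-negative scalar field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    spacing : tuple of float
        Voxel spacing in um per axis, (z, y, x) order.
    role : str
        Channel role label, one of ``retained_tracer``, ``leaky_tracer``,
        ``hypoxia``, ``cells``, ``bone`` or a user-defined string.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    role: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("ImageVolume requires a 3D array")
        if np.any(self.values < 0):
            raise InvalidParameterError("ImageVolume values must be non-negative")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def total_intensity(self) -> float:
        return float(self.values.sum())


@dataclass
class BinaryMask:
    """A 3D boolean field on the same grid as its source volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise InvalidParameterError("BinaryMask requires a 3D array")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclass
class LeakinessResult:
    """Dual-tracer vascular-leakiness statistic at one timepoint.

    ``in_sum`` and ``out_sum`` are the summed leaky-tracer intensities
    inside / outside the vascular mask; ``ratio = out_sum / in_sum`` is the
    OUT/IN leakiness.  The ratio is dimensionless and invariant to any
    global rescaling of the tracer intensity.
    """

    in_sum: float
    out_sum: float
    ratio: float
    timepoint: float | None = None


def check_same_grid(a, b, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise InconsistencyError(f"{what} have different shapes: {a.shape} vs {b.shape}")
    if tuple(a.spacing) != tuple(b.spacing):
        raise InconsistencyError(
            f"{what} have different spacings: {a.spacing} vs {b.spacing}"
        )


def rng_from_seed(seed: int) -> np.random.Generator:
    """Deterministic generator; every stochastic operation takes one seed."""
    return np.random.default_rng(int(seed))
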