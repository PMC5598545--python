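"""Synthetic intravital phantoms with exported ground truth.

This module generates everything the downstream quantification stages
consume, with known truth so each stage can be validated without real
microscope data:

* tubular vascular trees rasterized onto an anisotropic voxel grid;
* a vessel-retained tracer channel (Qtracker-like) and a leaky tracer
  channel (dextran-like) that deposits a controllable fraction of its
  mass outside the vessels as a perivascular halo;
* a hypoxia channel that increases monotonically with distance from the
  nearest perfused vessel, ``h(d) = h_max * (1 - exp(-d / lam))``;
* point-like cells in the parenchyma;
* optional PSF blur and Poisson/Gaussian noise;
* multinomial patient-cohort outcome tables and log-normal flow-cytometry
  event tables.

Every generator is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DEFAULT_SPACING,
    BinaryMask,
    ImageVolume,
    InvalidParameterError,
    rng_from_seed,
)

#: Outcome order used everywhere: (persistent & failure, persistent & response,
#: decreased & failure, decreased & response) for NO change x therapy response.
OUTCOME_LABELS = (
    "persistent_failure",
    "persistent_response",
    "decreased_failure",
    "decreased_response",
)


# ---------------------------------------------------------------------------
# Vessel trees


@dataclass
class VesselSegment:
    start: np.ndarray  # um, (z, y, x)
    end: np.ndarray  # um, (z, y, x)
    radius: float  # um

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class VesselTree:
    """A connected branching tube network inside a rectangular field of view."""

    segments: list[VesselSegment]
    depth: int
    extents: tuple[float, float, float]  # um, (z, y, x)

    def __post_init__(self):
        for seg in self.segments:
            if seg.radius <= 0:
                raise InvalidParameterError("all segment radii must be > 0")
            for p in (seg.start, seg.end):
                if np.any(p < 0) or np.any(p > np.asarray(self.extents)):
                    raise InvalidParameterError(
                        "segment endpoint outside the field of view"
                    )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.segments])


def make_vessel_tree(
    extents: tuple[float, float, float],
    depth: int,
    root_radius: float,
    taper: float = 0.8,
    seed: int = 0,
) -> VesselTree:
    """Grow a recursive binary branching tree.

    Each parent segment spawns two children at its distal end; child radius
    equals ``parent radius * taper``.  ``depth = 0`` yields a single straight
    tube.  A tree of depth d has ``2**(d+1) - 1`` segments.

    Parameters
    ----------
    extents : (z, y, x) physical size of the field of view in um.
    depth : number of branching generations (>= 0).
    root_radius : radius of the root tube in um (> 0).
    taper : child/parent radius ratio in (0, 1].
    seed : RNG seed; the same seed reproduces the tree bit-for-bit.
    """
    ext = np.asarray(extents, dtype=float)
    if np.any(ext <= 0):
        raise InvalidParameterError(f"extents must be positive, got {extents}")
    if depth < 0:
        raise InvalidParameterError("depth must be >= 0")
    if root_radius <= 0:
        raise InvalidParameterError("root_radius must be > 0")
    if not (0 < taper <= 1):
        raise InvalidParameterError("taper must be in (0, 1]")

    rng = rng_from_seed(seed)
    margin = min(2.0 * root_radius, 0.2 * float(ext.min()))

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, margin, ext - margin)

    # Root runs from one x-face toward the volume centre.
    start = clamp(np.array([ext[0] / 2.0, ext[1] / 2.0, margin]))
    direction = np.array([0.0, 0.0, 1.0])
    length0 = 0.35 * float(ext.max())

    segments: list[VesselSegment] = []

    def branch_pair(direction: np.ndarray) -> list[np.ndarray]:
        # Two children diverge symmetrically (25-50 degrees off the parent)
        # within a random plane through the parent axis, so sibling tubes
        # separate cleanly instead of overlapping along their length.
        while True:
            u = rng.normal(size=3)
            u -= (u @ direction) * direction
            norm = np.linalg.norm(u)
            if norm > 1e-6:
                u /= norm
                break
        angle = rng.uniform(np.deg2rad(25.0), np.deg2rad(50.0))
        return [
            np.cos(angle) * direction + np.sin(angle) * u,
            np.cos(angle) * direction - np.sin(angle) * u,
        ]

    def grow(p0, direction, radius, length, level):
        p1 = clamp(p0 + direction * length)
        segments.append(VesselSegment(start=p0.copy(), end=p1, radius=radius))
        if level >= depth:
            return
        actual = p1 - p0
        n = np.linalg.norm(actual)
        direction = actual / n if n > 1e-9 else direction
        for child_dir in branch_pair(direction):
            grow(p1, child_dir, radius * taper, length * 0.7, level + 1)

    grow(start, direction, float(root_radius), length0, 0)
    return VesselTree(segments=segments, depth=int(depth), extents=tuple(ext))


# ---------------------------------------------------------------------------
# Rasterization and stacks


@dataclass
class PhantomTruth:
    """Ground truth exported alongside a rendered stack.

    Masses refer to the pre-blur, pre-noise leaky-tracer field, so the mass
    bookkeeping identity ``inside_mass + outside_mass == total_mass`` holds
    exactly.
    """

    vessel_mask: BinaryMask
    leak_fraction: float
    inside_mass: float
    outside_mass: float
    segment_diameters_um: list[float]
    hypoxia_h_max: float
    hypoxia_lambda_um: float
    halo_decay_um: float
    cell_positions_um: np.ndarray  # (n, 3) in (z, y, x)
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.leak_fraction <= 1.0):
            raise InvalidParameterError("leak_fraction must lie in [0, 1]")
        if self.vessel_mask.is_empty():
            raise InvalidParameterError("truth vessel mask must be non-empty")

    @property
    def total_mass(self) -> float:
        return self.inside_mass + self.outside_mass


def rasterize_tree(
    tree: VesselTree,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> BinaryMask:
    """Voxelize tube segments: a voxel is vessel iff its centre lies within
    a segment radius of the segment axis (capsule model)."""
    shape = tuple(int(n) for n in shape)
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise InvalidParameterError("spacing must be positive per axis")
    grid_extent = np.asarray(shape) * sp
    for seg in tree.segments:
        for p in (seg.start, seg.end):
            if np.any(p - seg.radius < -1e-9) or np.any(p + seg.radius > grid_extent + 1e-9):
                raise InvalidParameterError(
                    "grid too small to contain the vessel tree "
                    f"(extent {tuple(grid_extent)} um)"
                )

    mask = np.zeros(shape, dtype=bool)
    for seg in tree.segments:
        a, b, r = seg.start, seg.end, seg.radius
        lo = np.minimum(a, b) - r
        hi = np.maximum(a, b) + r
        i0 = np.maximum(np.floor(lo / sp).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / sp).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        axes = [np.arange(i0[k], i1[k]) * sp[k] for k in range(3)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = ((pts - a) ** 2).sum(axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = ((pts - proj) ** 2).sum(axis=-1)
        sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub |= d2 <= r * r
    return BinaryMask(mask, spacing=tuple(sp))


def _distance_outside(mask: np.ndarray, spacing) -> np.ndarray:
    """Anisotropic Euclidean distance (um) from each voxel to the nearest
    vessel voxel; zero on the vessels themselves."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def render_stack(
    tree: VesselTree,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    leak_fraction: float = 0.0,
    psf_sigma_um: tuple[float, float, float] | None = (1.5, 0.4, 0.4),
    noise: dict | None = None,
    n_cells: int = 30,
    bone_thickness_um: float = 0.0,
    halo_decay_um: float = 10.0,
    hypoxia_h_max: float = 100.0,
    hypoxia_lambda_um: float = 30.0,
    tracer_amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[dict[str, ImageVolume], PhantomTruth]:
    """Render a multi-channel stack from a vessel tree.

    The leaky-tracer channel deposits ``1 - leak_fraction`` of its total
    mass uniformly inside the true vessel mask and ``leak_fraction`` outside
    as a perivascular halo whose density decays as ``exp(-d / halo_decay_um)``
    with distance d from the vessel surface.  The hypoxia channel is
    ``h_max * (1 - exp(-d / lam))``.  PSF blur and noise are applied after
    the truth masses are recorded.

    Parameters
    ----------
    psf_sigma_um : Gaussian PSF sigma per axis in um, or None to disable.
    noise : ``{"photons_per_unit": float, "read_sigma": float}`` or None.
        Poisson shot noise on intensities scaled by ``photons_per_unit``
        plus additive zero-mean Gaussian read noise, clipped at zero.

    Returns
    -------
    (channels, truth) where channels maps role names
    ``{"retained_tracer", "leaky_tracer", "hypoxia", "cells"}`` (plus
    ``"bone"`` when ``bone_thickness_um > 0``) to :class:`ImageVolume`
    and truth is the :class:`PhantomTruth`.
    """
    if not (0.0 <= leak_fraction <= 1.0):
        raise InvalidParameterError("leak_fraction must lie in [0, 1]")
    sp = tuple(float(s) for s in spacing)
    rng = rng_from_seed(seed)

    vmask = rasterize_tree(tree, shape, sp)
    m = vmask.values
    if not m.any():
        raise InvalidParameterError("tree rasterized to an empty mask on this grid")
    n_in = int(m.sum())
    n_out = m.size - n_in
    dist = _distance_outside(m, sp)

    # Retained tracer: lumen only.
    retained = np.where(m, tracer_amplitude, 0.0)

    # Leaky tracer with exact mass bookkeeping on the pre-blur field.
    total_mass = tracer_amplitude * n_in
    inside_mass = (1.0 - leak_fraction) * total_mass
    outside_mass = leak_fraction * total_mass
    leaky = np.zeros(m.shape, dtype=float)
    leaky[m] = inside_mass / n_in
    if outside_mass > 0:
        if n_out == 0:
            raise InvalidParameterError(
                "leak_fraction > 0 but the grid has no extravascular voxels"
            )
        halo = np.where(m, 0.0, np.exp(-dist / float(halo_decay_um)))
        halo_sum = halo.sum()
        leaky += halo * (outside_mass / halo_sum)

    # Hypoxia grows with distance from perfused vessels.
    hypoxia = hypoxia_h_max * (1.0 - np.exp(-dist / float(hypoxia_lambda_um)))

    # Point-like cells in the parenchyma (outside the vessels).
    ext = np.asarray(shape) * np.asarray(sp)
    cells = np.zeros(m.shape, dtype=float)
    positions = []
    attempts = 0
    while len(positions) < n_cells and attempts < 50 * max(n_cells, 1):
        attempts += 1
        p = rng.uniform(low=0.05 * ext, high=0.95 * ext)
        idx = tuple(np.minimum((p / sp).astype(int), np.asarray(shape) - 1))
        if not m[idx]:
            positions.append(np.asarray(idx) * np.asarray(sp))
            cells[idx] += tracer_amplitude
    cell_positions = (
        np.array(positions) if positions else np.zeros((0, 3), dtype=float)
    )

    truth = PhantomTruth(
        vessel_mask=vmask,
        leak_fraction=float(leak_fraction),
        inside_mass=float(inside_mass),
        outside_mass=float(outside_mass),
        segment_diameters_um=[s.diameter for s in tree.segments],
        hypoxia_h_max=float(hypoxia_h_max),
        hypoxia_lambda_um=float(hypoxia_lambda_um),
        halo_decay_um=float(halo_decay_um),
        cell_positions_um=cell_positions,
        seed=int(seed),
    )

    channels = {
        "retained_tracer": retained,
        "leaky_tracer": leaky,
        "hypoxia": hypoxia,
        "cells": cells,
    }

    # Optional SHG-like bone slab across the shallowest z planes, mimicking
    # the calvarial cortex above the marrow cavity.
    if bone_thickness_um > 0:
        n_bone = min(int(np.ceil(bone_thickness_um / sp[0])), shape[0])
        bone = np.zeros(m.shape, dtype=float)
        bone[:n_bone] = tracer_amplitude
        channels["bone"] = bone

    if psf_sigma_um is not None and np.any(np.asarray(psf_sigma_um) > 0):
        sigma_vox = np.asarray(psf_sigma_um, dtype=float) / np.asarray(sp)
        for k in channels:
            channels[k] = ndimage.gaussian_filter(channels[k], sigma=sigma_vox)

    if noise is not None:
        photons = float(noise.get("photons_per_unit", 1.0))
        read_sigma = float(noise.get("read_sigma", 0.0))
        if photons <= 0:
            raise InvalidParameterError("photons_per_unit must be > 0")
        for k in channels:
            v = rng.poisson(channels[k] * photons).astype(float) / photons
            if read_sigma > 0:
                v = v + rng.normal(scale=read_sigma, size=v.shape)
            channels[k] = np.clip(v, 0.0, None)

    volumes = {
        role: ImageVolume(vals, spacing=sp, role=role)
        for role, vals in channels.items()
    }
    return volumes, truth


def leak_fraction_at(permeability: float, t_minutes: float) -> float:
    """Saturating extravasation kinetics, ``f(t) = 1 - exp(-k t)``."""
    if permeability < 0:
        raise InvalidParameterError("permeability must be >= 0")
    if t_minutes < 0:
        raise InvalidParameterError("time must be >= 0")
    return float(1.0 - np.exp(-permeability * t_minutes))


def simulate_timecourse(
    tree: VesselTree,
    shape: tuple[int, int, int],
    permeability: float,
    times: list[float],
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    seed: int = 0,
    **render_kwargs,
) -> list[tuple[dict[str, ImageVolume], PhantomTruth]]:
    """Render one stack per timepoint with leak_fraction(t) = 1 - exp(-k t).

    Vessel geometry is identical across timepoints; only the deposited
    leak fraction (and the per-timepoint noise realization) changes.
    """
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise InvalidParameterError("times must be non-negative")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InvalidParameterError("times must be strictly increasing")
    if permeability < 0:
        raise InvalidParameterError("permeability must be >= 0")

    seeds = np.random.SeedSequence(int(seed)).generate_state(max(len(times), 1))
    out = []
    for t, sub_seed in zip(times, seeds):
        f = leak_fraction_at(permeability, t)
        stack, truth = render_stack(
            tree,
            shape,
            spacing=spacing,
            leak_fraction=f,
            seed=int(sub_seed % (2**31 - 1)),
            **render_kwargs,
        )
        out.append((stack, truth))
    return out


# ---------------------------------------------------------------------------
# Cohort and event tables


@dataclass
class CohortTable:
    """2x2 joint outcome counts for NO change x treatment response.

    ``counts`` follows :data:`OUTCOME_LABELS` order: (persistent & failure,
    persistent & response, decreased & failure, decreased & response).
    """

    counts: tuple[int, int, int, int]

    def __post_init__(self):
        c = tuple(int(x) for x in self.counts)
        if any(x < 0 for x in c):
            raise InvalidParameterError("cohort counts must be non-negative")
        self.counts = c

    @property
    def n_patients(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"outcome": OUTCOME_LABELS, "count": self.counts})


def make_cohort(theta, n_patients: int, seed: int = 0) -> CohortTable:
    """Draw a multinomial cohort with known outcome probabilities."""
    th = np.asarray(theta, dtype=float)
    if th.shape != (4,):
        raise InvalidParameterError("theta must have 4 components")
    if np.any(th < 0):
        raise InvalidParameterError("theta components must be non-negative")
    if abs(th.sum() - 1.0) > 1e-12:
        raise InvalidParameterError("theta must sum to 1 within 1e-12")
    if n_patients < 0:
        raise InvalidParameterError("n_patients must be >= 0")
    rng = rng_from_seed(seed)
    counts = rng.multinomial(int(n_patients), th)
    return CohortTable(counts=tuple(int(c) for c in counts))


def make_events(
    populations: list[tuple[str, dict[str, tuple[float, float]], int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a flow-cytometry-like event table.

    Parameters
    ----------
    populations : list of (label, markers, n) where markers maps a marker
        name to ``(median, sigma_log)`` of a log-normal intensity
        distribution (median > 0, sigma_log >= 0).
    seed : RNG seed.

    Returns
    -------
    DataFrame with one row per cell, one column per marker, plus a
    ``population`` column carrying the hidden truth label.
    """
    rng = rng_from_seed(seed)
    markers: list[str] = []
    for _, mk, _ in populations:
        for name in mk:
            if name not in markers:
                markers.append(name)
    frames = []
    for label, mk, n in populations:
        if n < 0:
            raise InvalidParameterError("population size must be >= 0")
        for name, (median, sigma) in mk.items():
            if median <= 0:
                raise InvalidParameterError(
                    f"log-normal scale (median) for {name!r} must be > 0"
                )
            if sigma < 0:
                raise InvalidParameterError(f"sigma_log for {name!r} must be >= 0")
        data = {}
        for name in markers:
            if name in mk:
                median, sigma = mk[name]
                data[name] = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
            else:
                data[name] = np.zeros(n)
        data["population"] = [label] * n
        frames.append(pd.DataFrame(data))
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=markers + ["population"])
    # Guarantee the header exists even when every population is empty.
    return table[markers + ["population"]] if markers else table
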