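"""3D vessel and hypoxia morphometry.

Implements the geometric quantifications performed on segmented stacks:

* centerline extraction (topology-preserving 3D thinning) and splitting
  into vessel fragments at junctions, with spur pruning;
* per-fragment radii via the anisotropic Euclidean distance transform and
  filament-style mean diameters;
* exact anisotropic distance maps, per-vessel distance-to-hypoxia
  distributions and cell(spot)-to-vessel distances;
* hypoxia signal intensity per voxel;
* microvascular density as skeleton sprout tips per mm^2 of a 2D section,
  expressed as fold over a control density.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .core import (
    BinaryMask,
    DegenerateInputError,
    ImageVolume,
    InconsistencyError,
    InvalidParameterError,
    UndefinedRatioError,
)

#: Spur fragments shorter than this are treated as thinning artifacts.
DEFAULT_PRUNE_UM = 5.0


@dataclass
class VesselFragment:
    """A simple centerline path between junctions (or free ends)."""

    centerline: list[tuple[int, ...]]
    length_um: float
    radii_um: np.ndarray | None = None
    mean_diameter_um: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.centerline)


@dataclass
class DistanceDistribution:
    """Per-object distances (um) with a relative-frequency histogram."""

    distances_um: np.ndarray
    bin_edges_um: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        if np.any(self.distances_um < 0):
            raise InvalidParameterError("distances must be non-negative")
        if len(self.frequencies) and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("relative frequencies must sum to 1")

    @property
    def median_um(self) -> float:
        return float(np.median(self.distances_um))


@dataclass
class HypoxiaDensity:
    total_intensity: float
    voxel_count: int

    @property
    def density(self) -> float:
        return self.total_intensity / self.voxel_count


# ---------------------------------------------------------------------------
# Skeletons and fragments


def skeletonize_vessels(mask: BinaryMask) -> BinaryMask:
    """One-voxel-wide centerline of a vessel mask (3D thinning)."""
    if mask.is_empty():
        raise DegenerateInputError("cannot skeletonize an empty mask")
    skel = skeletonize(mask.values)
    return BinaryMask(skel.astype(bool), spacing=mask.spacing)


def _offsets(ndim: int) -> list[tuple[int, ...]]:
    return [off for off in product((-1, 0, 1), repeat=ndim) if any(off)]


def _skeleton_graph(skel: np.ndarray):
    """Adjacency of skeleton voxels under full (26/8) connectivity."""
    coords = set(map(tuple, np.argwhere(skel)))
    offs = _offsets(skel.ndim)
    adj: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for v in coords:
        adj[v] = [
            tuple(v[k] + o[k] for k in range(len(v)))
            for o in offs
            if tuple(v[k] + o[k] for k in range(len(v))) in coords
        ]
    return adj


def _step_um(a, b, spacing) -> float:
    return float(
        np.sqrt(sum(((ai - bi) * s) ** 2 for ai, bi, s in zip(a, b, spacing)))
    )


def _path_length_um(path, spacing) -> float:
    if len(path) < 2:
        # single-voxel path: nominal length of one voxel
        return float(min(spacing))
    return sum(_step_um(a, b, spacing) for a, b in zip(path, path[1:]))


def _order_path(component: set, adj) -> list:
    """Order a degree-<=2 voxel set into a walkable path."""
    sub = {v: [n for n in adj[v] if n in component] for v in component}
    ends = [v for v, ns in sub.items() if len(ns) <= 1]
    start = min(ends) if ends else min(component)  # cycle: arbitrary start
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [n for n in sub[cur] if n not in seen]
        if not nxt:
            break
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def split_fragments(
    skeleton: BinaryMask,
    prune_um: float = DEFAULT_PRUNE_UM,
) -> list[VesselFragment]:
    """Split a centerline into simple paths at junction voxels.

    Junctions are skeleton voxels with more than two 26-neighbors.  After
    removing them, each connected component of the remainder is one
    fragment.  Spur fragments (free at one or both ends) shorter than
    ``prune_um`` are discarded as thinning artifacts.
    """
    if skeleton.is_empty():
        raise DegenerateInputError("empty skeleton")
    adj = _skeleton_graph(skeleton.values)
    junctions = {v for v, ns in adj.items() if len(ns) > 2}
    remaining = set(adj) - junctions

    fragments: list[VesselFragment] = []
    unvisited = set(remaining)
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for n in adj[v]:
                if n in unvisited:
                    unvisited.discard(n)
                    comp.add(n)
                    frontier.append(n)
        path = _order_path(comp, adj)
        length = _path_length_um(path, skeleton.spacing)
        # A fragment both of whose ends touch junctions is a true bridge and
        # is always kept; short dangling spurs are pruned.
        end_attached = [
            any(n in junctions for n in adj[p]) for p in (path[0], path[-1])
        ]
        is_spur = sum(end_attached) <= 1
        if is_spur and length < prune_um:
            continue
        fragments.append(VesselFragment(centerline=path, length_um=length))
    return fragments


def fragment_diameters(
    fragments: list[VesselFragment],
    mask: BinaryMask,
    spacing=None,
) -> list[VesselFragment]:
    """Attach per-voxel radii and filament-style mean diameters.

    The radius at each centerline voxel is its anisotropic Euclidean
    distance to the nearest background voxel; mean diameter is twice the
    mean radius along the fragment.  Diameters therefore scale exactly
    linearly with voxel spacing.
    """
    sp = tuple(spacing) if spacing is not None else tuple(mask.spacing)
    edt = ndimage.distance_transform_edt(mask.values, sampling=sp)
    for frag in fragments:
        idx = tuple(np.array(frag.centerline).T)
        if not np.all(mask.values[idx]):
            raise InconsistencyError("fragment centerline voxel outside the mask")
        frag.radii_um = edt[idx]
        frag.mean_diameter_um = float(2.0 * frag.radii_um.mean())
    return fragments


def vessel_mean_diameters(
    mask: BinaryMask, prune_um: float = DEFAULT_PRUNE_UM
) -> list[VesselFragment]:
    """Convenience: skeletonize, split and measure in one call."""
    skel = skeletonize_vessels(mask)
    frags = split_fragments(skel, prune_um=prune_um)
    return fragment_diameters(frags, mask)


# ---------------------------------------------------------------------------
# Distance maps and distributions


def distance_map(mask: BinaryMask, spacing=None) -> np.ndarray:
    """Exact anisotropic Euclidean distance (um) to the nearest mask voxel."""
    if mask.is_empty():
        raise DegenerateInputError("distance map of an empty mask is undefined")
    sp = tuple(spacing) if spacing is not None else tuple(mask.spacing)
    return ndimage.distance_transform_edt(~mask.values, sampling=sp)


def _histogram(distances: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    d = np.asarray(distances, dtype=float)
    top = max(float(d.max()), bin_width) if d.size else bin_width
    n_bins = int(np.ceil(top / bin_width + 1e-12))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return edges, freq


def vessel_hypoxia_distances(
    vessel_mask: BinaryMask,
    hypoxia_mask: BinaryMask,
    bin_width: float = 5.0,
) -> DistanceDistribution:
    """Per-vessel distance to the closest hypoxic voxel.

    Each vessel is a 26-connected component of the vessel mask; its
    distance is the minimum, over its voxels, of the distance map of the
    hypoxia mask (i.e. the distance from the vessel to the closest hypoxic
    pixel).  Vessels overlapping hypoxia score zero.
    """
    if vessel_mask.is_empty():
        raise DegenerateInputError("empty vessel mask")
    if hypoxia_mask.is_empty():
        raise DegenerateInputError("empty hypoxia mask")
    if vessel_mask.shape != hypoxia_mask.shape:
        raise InconsistencyError("vessel and hypoxia masks on different grids")
    dm = distance_map(hypoxia_mask)
    labels, n = ndimage.label(vessel_mask.values, structure=np.ones((3, 3, 3), bool))
    dists = ndimage.minimum(dm, labels=labels, index=np.arange(1, n + 1))
    dists = np.atleast_1d(np.asarray(dists, dtype=float))
    edges, freq = _histogram(dists, bin_width)
    return DistanceDistribution(dists, edges, freq)


def hypoxia_density(volume: ImageVolume) -> HypoxiaDensity:
    """Hypoxia reporter signal per voxel over the whole z-stack."""
    n = int(np.prod(volume.shape))
    if n == 0:
        raise DegenerateInputError("empty volume")
    return HypoxiaDensity(total_intensity=float(volume.values.sum()), voxel_count=n)


# ---------------------------------------------------------------------------
# Spot detection (cells)


def detect_spots(
    volume: ImageVolume,
    spot_diameter_um: float = 8.0,
    threshold: float = 0.1,
) -> np.ndarray:
    """Scale-matched blob detection of point-like cells.

    Runs a Laplacian-of-Gaussian filter at sigma = diameter / 2.355 (FWHM
    matching) and keeps local maxima above ``threshold`` times the global
    response maximum, suppressing maxima closer than half the spot
    diameter.  Two blobs closer than that may merge into one detection.

    Returns
    -------
    (n, 3) array of physical coordinates (z, y, x) in um.
    """
    if spot_diameter_um <= 0:
        raise InvalidParameterError("spot_diameter_um must be > 0")
    vals = volume.values
    if not np.any(vals > 0):
        return np.zeros((0, 3), dtype=float)
    sp = np.asarray(volume.spacing, dtype=float)
    sigma_vox = (spot_diameter_um / 2.355) / sp
    response = -ndimage.gaussian_laplace(vals.astype(float), sigma=sigma_vox)
    np.clip(response, 0.0, None, out=response)
    peak = response.max()
    if peak <= 0:
        return np.zeros((0, 3), dtype=float)
    # Ellipsoidal suppression footprint: half a spot diameter per axis.
    semi = np.maximum((spot_diameter_um / 2.0) / sp, 1.0)
    ranges = [np.arange(-int(np.ceil(s)), int(np.ceil(s)) + 1) / s for s in semi]
    zz, yy, xx = np.meshgrid(*ranges, indexing="ij")
    footprint = zz**2 + yy**2 + xx**2 <= 1.0

    from skimage.feature import peak_local_max

    coords = peak_local_max(
        response, footprint=footprint, threshold_abs=threshold * peak
    )
    return coords.astype(float) * sp


def spot_vessel_distances(
    points_um: np.ndarray,
    vessel_mask: BinaryMask,
    bin_width: float = 5.0,
) -> DistanceDistribution:
    """Distance of each detected cell to the closest vascular voxel."""
    if vessel_mask.is_empty():
        raise DegenerateInputError("empty vessel mask")
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.size == 0:
        pts = pts.reshape(0, 3)
    sp = np.asarray(vessel_mask.spacing, dtype=float)
    dm = distance_map(vessel_mask)
    shape = np.asarray(vessel_mask.shape)
    dists = []
    for p in pts:
        idx = np.round(p / sp).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise InvalidParameterError(f"point {tuple(p)} um lies outside the grid")
        dists.append(float(dm[tuple(idx)]))
    dists = np.asarray(dists, dtype=float)
    edges, freq = _histogram(dists, bin_width)
    return DistanceDistribution(dists, edges, freq)


# ---------------------------------------------------------------------------
# Microvascular density (2D histology)


def _prune_skeleton_2d(skel: np.ndarray, spacing, prune_um: float) -> np.ndarray:
    """Remove dangling spur branches shorter than prune_um, iteratively."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        adj = _skeleton_graph(skel)
        junctions = {v for v, ns in adj.items() if len(ns) > 2}
        remaining = set(adj) - junctions
        unvisited = set(remaining)
        while unvisited:
            seed = unvisited.pop()
            comp = {seed}
            frontier = [seed]
            while frontier:
                v = frontier.pop()
                for nb in adj[v]:
                    if nb in unvisited:
                        unvisited.discard(nb)
                        comp.add(nb)
                        frontier.append(nb)
            path = _order_path(comp, adj)
            ends_attached = sum(
                any(nb in junctions for nb in adj[p]) for p in (path[0], path[-1])
            )
            if ends_attached == 1 and _path_length_um(path, spacing) < prune_um:
                for v in comp:
                    skel[v] = False
                changed = True
    return skel


def mvd_sprouts(
    image2d: np.ndarray,
    area_mm2: float,
    control_density: float | None = None,
    pixel_size_um: tuple[float, float] = (0.5, 0.5),
    prune_um: float = DEFAULT_PRUNE_UM,
) -> dict:
    """Microvascular density from a 2D section.

    Sprouts are the endpoints (pixels with exactly one 8-connected skeleton
    neighbour) of the pruned 2D skeleton of the vessel stain.  Density is
    sprouts per mm^2; fold change is density / control_density.

    Parameters
    ----------
    image2d : boolean mask or intensity image (thresholded by Otsu).
    area_mm2 : tissue area covered by the image, in mm^2 (> 0).
    control_density : sprouts/mm^2 of the control group; None skips fold.
    """
    if area_mm2 <= 0:
        raise InvalidParameterError("area_mm2 must be > 0")
    img = np.asarray(image2d)
    if img.ndim != 2:
        raise InvalidParameterError("mvd_sprouts expects a 2D image")
    if img.dtype == bool:
        mask = img
    else:
        if np.ptp(img) == 0:
            raise DegenerateInputError("constant image: cannot threshold")
        mask = img > threshold_otsu(img)
    skel = skeletonize(mask)
    skel = _prune_skeleton_2d(skel, pixel_size_um, prune_um)
    neighbor_count = ndimage.convolve(
        skel.astype(int), np.ones((3, 3), int), mode="constant"
    ) - skel.astype(int)
    endpoints = skel & (neighbor_count == 1)
    n_sprouts = int(endpoints.sum())
    density = n_sprouts / area_mm2
    out = {"n_sprouts": n_sprouts, "density_per_mm2": density}
    if control_density is not None:
        if control_density == 0:
            raise UndefinedRatioError("control density is zero; fold undefined")
        out["fold_over_control"] = density / control_density
    return out
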