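"""Per-grain digital traits.

For every segmented seed the pipeline records the trait set a breeder needs
to reconstruct yield components: voxel count and metric volume, a virtual
weight derived from volume times mean physical absorption, the
absorption-weighted centre of mass, a 3D aspect ratio (radius of the
equal-volume sphere over the radius of the minimum covering sphere — 1 for
a perfect sphere, tending to 0 for a thin rod), the surface-voxel count and
surface-to-volume ratio, and the minimal directional width used by the
virtual 2 mm sieve.

Virtual weights are calibrated against hand-threshed per-ear weights by a
single multiplicative factor fitted through the origin on a small subset of
ears.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import CalibrationError
from .volume import Volume

__all__ = [
    "SeedTraits",
    "CalibrationModel",
    "min_covering_sphere",
    "aspect_ratio",
    "surface_voxel_count",
    "min_diameter",
    "fibonacci_directions",
    "min_feret_width",
    "apply_sieve",
    "uncalibrated_mass_index",
    "fit_calibration",
    "compute_all_traits",
    "traits_frame",
    "TRAIT_COLUMNS",
]

logger = logging.getLogger(__name__)

# Fixed CSV column order of the per-seed trait table.
TRAIT_COLUMNS = [
    "ear_id",
    "seed_label",
    "voxel_count",
    "volume_mm3",
    "virtual_weight_g",
    "com_x_mm",
    "com_y_mm",
    "com_z_mm",
    "mean_attenuation",
    "aspect_ratio",
    "surface_voxels",
    "surface_to_volume",
    "min_diameter_mm",
    "passes_sieve",
    "axial_position_mm",
    "axial_position_norm",
]


@dataclass
class SeedTraits:
    """One row of the per-grain trait table."""

    ear_id: str
    seed_label: int
    voxel_count: int
    volume_mm3: float
    virtual_weight_g: float
    centre_of_mass_mm: np.ndarray  # (z, y, x) world position
    mean_attenuation: float
    aspect_ratio: float
    surface_voxels: int
    surface_to_volume: float
    min_diameter_mm: float
    passes_sieve: bool
    mass_index: float  # volume_mm3 * mean_attenuation, before calibration
    touches_another: bool = False
    axial_position_mm: float = float("nan")
    axial_position_norm: float = float("nan")


@dataclass
class CalibrationModel:
    """Scalar virtual-to-actual weight conversion (g per mm^3 * absorption)."""

    factor_k: float
    n_fit: int
    residual_rms: float

    def __post_init__(self) -> None:
        if not self.factor_k > 0:
            raise CalibrationError("calibration factor must be positive")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        """Uncalibrated output: virtual weight equals the raw mass index."""
        return cls(factor_k=1.0, n_fit=2, residual_rms=0.0)


# ---------------------------------------------------------------------------
# Minimum covering sphere (exact, Welzl's randomized incremental algorithm)
# ---------------------------------------------------------------------------

_EPS = 1e-10


def _sphere_of_boundary(boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest sphere with all boundary points on its surface.

    Handles 0-4 support points; degenerate (collinear/coplanar) sets fall
    back to the minimum sphere over their proper subsets.
    """
    n = len(boundary)
    if n == 0:
        return np.zeros(3), -1.0  # radius -1: contains nothing
    if n == 1:
        return boundary[0].copy(), 0.0
    if n == 2:
        c = 0.5 * (boundary[0] + boundary[1])
        return c, float(np.linalg.norm(boundary[0] - c))
    p0 = boundary[0]
    rel = np.array([p - p0 for p in boundary[1:]])  # (n-1, 3)
    rhs = 0.5 * np.einsum("ij,ij->i", rel, rel)
    # Solve rel @ (c - p0) = rhs restricted to span(rel).
    sol, *_ = np.linalg.lstsq(rel, rhs, rcond=None)
    c = p0 + sol
    if not np.all(np.isfinite(c)):
        return _min_sphere_subsets(boundary)
    r = max(float(np.linalg.norm(p - c)) for p in boundary)
    # Degenerate support (e.g. 4 coplanar points): the lstsq sphere may not
    # have every point on its surface; verify and fall back if needed.
    rmin = min(float(np.linalg.norm(p - c)) for p in boundary)
    if r - rmin > 1e-7 * (1.0 + r):
        return _min_sphere_subsets(boundary)
    return c, r


def _min_sphere_subsets(points: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    """Brute force over proper subsets; only used for degenerate supports."""
    from itertools import combinations

    best: tuple[np.ndarray, float] | None = None
    pts = np.asarray(points)
    for k in range(1, min(4, len(points)) + 1):
        for sub in combinations(range(len(points)), k):
            if k == len(points) and k > 2:
                continue
            c, r = _sphere_of_boundary([pts[i] for i in sub])
            if r < 0:
                continue
            rr = max(r, max(float(np.linalg.norm(p - c)) for p in pts))
            if best is None or rr < best[1]:
                best = (c, rr)
    assert best is not None
    return best


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    order = rng.permutation(len(points))
    pts = [points[i] for i in order]

    def mb(i: int, boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
        # smallest sphere of pts[i:] with `boundary` constrained to its surface
        if i == len(pts) or len(boundary) == 4:
            return _sphere_of_boundary(boundary)
        c, r = mb(i + 1, boundary)
        p = pts[i]
        if r >= 0 and np.linalg.norm(p - c) <= r * (1 + _EPS) + _EPS:
            return c, r
        return mb(i + 1, boundary + [p])

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(pts) * 4 + 100))
    try:
        return mb(0, [])
    finally:
        sys.setrecursionlimit(old_limit)


def min_covering_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing sphere of a 3D point set.

    Parameters
    ----------
    points
        ``(n, 3)`` array, ``n >= 1``.

    Returns
    -------
    centre, radius
        All points satisfy ``|p - centre| <= radius`` and no smaller sphere
        contains them all.  Large inputs are first reduced to their convex
        hull vertices (the minimum covering sphere is determined by them).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("min_covering_sphere needs a non-empty (n, 3) array")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) > 256:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # flat/collinear sets: Welzl handles them directly
    rng = np.random.default_rng(0x5EED)  # fixed: results must be reproducible
    if len(pts) <= 64:
        return _welzl(pts, rng)
    # Violator-driven refinement: run Welzl only on a small active set and
    # grow it with the farthest uncovered point.  On termination the active
    # set's minimum sphere covers all points, and since it is the minimum
    # sphere of a subset it cannot exceed the full minimum — so it is exact.
    active = list(pts[rng.choice(len(pts), size=4, replace=False)])
    for _ in range(len(pts)):
        centre, radius = _welzl(np.asarray(active), rng)
        dists = np.linalg.norm(pts - centre, axis=1)
        worst = int(np.argmax(dists))
        if dists[worst] <= radius * (1 + _EPS) + _EPS:
            return centre, radius
        active.append(pts[worst])
    return _welzl(pts, rng)  # pragma: no cover - refinement always terminates


# ---------------------------------------------------------------------------
# Shape descriptors
# ---------------------------------------------------------------------------


def _region_coords(region) -> np.ndarray:
    coords = np.asarray(region.voxel_coords if hasattr(region, "voxel_coords") else region)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("expected a non-empty (n, 3) voxel coordinate array")
    return coords


def aspect_ratio(region, voxel_size_mm: float) -> float:
    """3D aspect (spherical) ratio in ``(0, 1]``.

    Ratio of the radius of the sphere with the seed's volume to the radius
    of the minimum covering sphere of the seed's voxel centres.  A perfect
    sphere scores 1; an infinitely long thin rod tends to 0.  A single-voxel
    region is sphere-like by convention and scores exactly 1.
    """
    coords = _region_coords(region)
    n = len(coords)
    if n == 1:
        return 1.0
    _, r_mcs = min_covering_sphere(coords * voxel_size_mm)
    if r_mcs <= 0:
        return 1.0
    volume = n * voxel_size_mm**3
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(min(1.0, r_eq / r_mcs))


def surface_voxel_count(region_or_mask) -> int:
    """Number of region voxels face-adjacent (6-connectivity) to background."""
    if isinstance(region_or_mask, np.ndarray) and region_or_mask.dtype == bool:
        mask = region_or_mask
    else:
        coords = _region_coords(region_or_mask)
        lo = coords.min(axis=0)
        shape = coords.max(axis=0) - lo + 1
        mask = np.zeros(shape, dtype=bool)
        mask[tuple((coords - lo).T)] = True
    cross = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return int(np.count_nonzero(mask & ~interior))


def fibonacci_directions(n: int = 256) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([z, rho * np.sin(phi), rho * np.cos(phi)], axis=1)


def min_feret_width(coords: np.ndarray, voxel_size_mm: float, n_directions: int = 256) -> float:
    """Approximate minimal Feret width of a voxel set, in mm.

    The projected centre span plus half the voxel footprint is minimized
    over a fixed Fibonacci-sphere direction set, making the estimate
    deterministic and rotation-robust.  Half a footprint (not a full one)
    because the digitized surface cuts boundary voxels roughly through
    their centres, so the full cube support would overestimate the
    underlying body's width by about one voxel.
    """
    coords = np.asarray(coords, dtype=np.float32)
    dirs = fibonacci_directions(n_directions).astype(np.float32)
    proj = coords @ dirs.T  # (n_voxels, n_directions)
    span = proj.max(axis=0) - proj.min(axis=0)
    footprint = np.abs(dirs).sum(axis=1)  # support width of a unit cube
    widths = (span + 0.5 * footprint) * voxel_size_mm
    return float(widths.min())


def min_diameter(region, voxel_size_mm: float, n_directions: int = 256) -> float:
    """Smallest directional extent of a seed region (virtual sieve input)."""
    return min_feret_width(_region_coords(region), voxel_size_mm, n_directions)


def apply_sieve(seeds: Sequence[SeedTraits], cutoff_mm: float = 2.0) -> tuple[list[SeedTraits], list[SeedTraits]]:
    """Partition seeds by the virtual sieve.

    Seeds whose diameter is below the cutoff in every direction fall
    through; the default 2.0 mm emulates the threshing sieve.  Returns
    ``(retained, omitted)``; counts always sum to the input count.
    """
    retained = [s for s in seeds if s.min_diameter_mm >= cutoff_mm]
    omitted = [s for s in seeds if s.min_diameter_mm < cutoff_mm]
    return retained, omitted


# ---------------------------------------------------------------------------
# Virtual weight
# ---------------------------------------------------------------------------


def uncalibrated_mass_index(region, volume: Volume) -> tuple[float, np.ndarray, float]:
    """Raw density-weighted volume of one seed, before calibration.

    Returns ``(mass_index, centre_of_mass_mm, mean_attenuation)`` where
    ``mass_index`` is the per-voxel absorption sum times the voxel volume
    (algebraically identical to volume x mean attenuation over the same
    mask) and the centre of mass is the absorption-weighted mean world
    position.  Requires the volume's grey-to-absorption scale.
    """
    if not getattr(volume, "grey_per_absorption", 0) > 0:
        raise ValueError(
            "volume lacks a grey_per_absorption scale; raw grey values are "
            "not a measure of absorption"
        )
    coords = _region_coords(region)
    sub = getattr(region, "subvolume", None)
    if sub is not None:
        offset = np.asarray(region.offset)
        grey = sub[tuple((coords - offset).T)].astype(np.float64)
    else:
        grey = volume.grey[tuple(coords.T)].astype(np.float64)
    absorption = grey / volume.grey_per_absorption
    total = absorption.sum()
    mean_att = float(total / len(coords))
    world = (coords + 0.5) * volume.voxel_size_mm
    if total > 0:
        com = (absorption[:, None] * world).sum(axis=0) / total
    else:
        com = world.mean(axis=0)
    mass_index = float(total * volume.voxel_volume_mm3)
    return mass_index, com, mean_att


def fit_calibration(virtual: Sequence[float], actual: Sequence[float]) -> CalibrationModel:
    """Fit the scalar weight-correction factor on paired per-ear sums.

    ``actual ~ k * virtual`` is fitted by least squares through the origin
    (``k = sum(v*a) / sum(v^2)``), mirroring a single correction factor
    determined on a calibration subset of ears.
    """
    v = np.asarray(virtual, dtype=float)
    a = np.asarray(actual, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise CalibrationError("virtual and actual must be 1D and paired")
    if len(v) < 2:
        raise CalibrationError(f"need at least 2 calibration pairs, got {len(v)}")
    if np.any(v <= 0):
        raise CalibrationError("all virtual mass-index sums must be positive")
    k = float((v * a).sum() / (v * v).sum())
    residual_rms = float(np.sqrt(np.mean((a - k * v) ** 2)))
    return CalibrationModel(factor_k=k, n_fit=len(v), residual_rms=residual_rms)


# ---------------------------------------------------------------------------
# Full trait extraction
# ---------------------------------------------------------------------------


def compute_all_traits(
    seeds: Iterable,
    volume: Volume,
    calibration: CalibrationModel | None = None,
    ear_id: str = "ear0",
    sieve_cutoff_mm: float = 2.0,
) -> list[SeedTraits]:
    """Compute the complete trait record for every seed region.

    A failing seed is logged and skipped; the run continues.  Pass
    ``calibration=None`` (identity) for uncalibrated output.
    """
    calibration = calibration or CalibrationModel.identity()
    vox = volume.voxel_size_mm
    out: list[SeedTraits] = []
    for region in seeds:
        try:
            coords = _region_coords(region)
            n = len(coords)
            mass_index, com, mean_att = uncalibrated_mass_index(region, volume)
            surf = surface_voxel_count(region)
            dmin = min_diameter(region, vox)
            out.append(
                SeedTraits(
                    ear_id=ear_id,
                    seed_label=int(getattr(region, "label", len(out) + 1)),
                    voxel_count=n,
                    volume_mm3=n * volume.voxel_volume_mm3,
                    virtual_weight_g=calibration.factor_k * mass_index,
                    centre_of_mass_mm=com,
                    mean_attenuation=mean_att,
                    aspect_ratio=aspect_ratio(region, vox),
                    surface_voxels=surf,
                    surface_to_volume=surf / n,
                    min_diameter_mm=dmin,
                    passes_sieve=dmin >= sieve_cutoff_mm,
                    mass_index=mass_index,
                    touches_another=bool(getattr(region, "touches_another", False)),
                )
            )
        except Exception:  # pragma: no cover - defensive per-seed isolation
            logger.exception(
                "trait extraction failed for seed %s of %s; seed skipped",
                getattr(region, "label", "?"),
                ear_id,
            )
    return out


def recalibrate(seeds: Sequence[SeedTraits], calibration: CalibrationModel) -> list[SeedTraits]:
    """Return seeds with virtual weights rescaled by a fitted calibration."""
    return [replace(s, virtual_weight_g=calibration.factor_k * s.mass_index) for s in seeds]


def traits_frame(seeds: Sequence[SeedTraits]) -> pd.DataFrame:
    """Per-seed trait table in the fixed CSV column order."""
    rows = []
    for s in seeds:
        com = np.asarray(s.centre_of_mass_mm, dtype=float)
        rows.append(
            {
                "ear_id": s.ear_id,
                "seed_label": s.seed_label,
                "voxel_count": s.voxel_count,
                "volume_mm3": s.volume_mm3,
                "virtual_weight_g": s.virtual_weight_g,
                "com_x_mm": com[2],
                "com_y_mm": com[1],
                "com_z_mm": com[0],
                "mean_attenuation": s.mean_attenuation,
                "aspect_ratio": s.aspect_ratio,
                "surface_voxels": s.surface_voxels,
                "surface_to_volume": s.surface_to_volume,
                "min_diameter_mm": s.min_diameter_mm,
                "passes_sieve": s.passes_sieve,
                "axial_position_mm": s.axial_position_mm,
                "axial_position_norm": s.axial_position_norm,
            }
        )
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)
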