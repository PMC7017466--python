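"""Seed segmentation: ears -> grain mask -> individual seed regions.

The stage mirrors what an automated ear-segmentation tool has to do with a
normalized absorption volume:

1. *Ear separation* — coarse foreground analysis on a downsampled volume
   splits a multi-ear scan into per-ear sub-volumes and estimates each
   ear's axis (principal axis of the coarse foreground, oriented bottom to
   top).
2. *Grain/chaff separation* — grain is denser than rachis, glumes and
   awns, so a three-class intensity analysis (air | chaff | grain) yields
   the grain threshold; a morphological opening with a small ball deletes
   residual thin structures.
3. *Touching-seed splitting* — distance-transform maxima separated by at
   least a configurable marker distance seed a watershed that splits fused
   grains; split regions are flagged.

Conventions used throughout: 0-based ``(z, y, x)`` voxel indices with z
vertical, half-open bounding boxes, 26-connectivity for region labelling
(6-connectivity is reserved for the surface operator), world positions at
``(index + 0.5) * voxel size``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import OrientationError, SegmentationError
from .volume import Volume

__all__ = [
    "SegmentationParams",
    "SeedRegion",
    "EarVolume",
    "separate_ears",
    "segment_seeds",
    "orient_seed",
    "max_diameter_cross_section",
]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tunables of the grain segmentation stage (lengths in mm)."""

    grain_threshold: float | None = None  # absorption; None = automatic
    opening_radius_mm: float = 0.3  # ball radius deleting awns/glumes
    marker_min_distance_mm: float = 1.5  # minimum spacing of watershed markers
    min_region_voxels: int = 27  # smaller components are debris
    grain_floor_absorption: float = 0.5  # 1/mm; an intensity class counts as
    # grain only if its mean absorption reaches this floor.  Meaningful
    # because reconstructed volumes are normalized to physical absorption;
    # wheat grain sits near 0.8 and chaff well below 0.5.

    def validate(self) -> None:
        if self.opening_radius_mm < 0 or self.marker_min_distance_mm <= 0:
            raise ValueError("opening radius must be >= 0 and marker distance > 0")
        if self.min_region_voxels < 1:
            raise ValueError("min_region_voxels must be >= 1")


@dataclass
class SeedRegion:
    """One segmented seed: voxel set plus its cropped grey sub-volume."""

    label: int
    voxel_coords: np.ndarray  # (n, 3) int indices into the ear volume
    subvolume: np.ndarray  # grey values, cropped to bbox
    offset: np.ndarray  # (z, y, x) index of subvolume origin
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    touches_another: bool = False


@dataclass
class EarVolume:
    """A single ear cut out of a multi-ear scan, with its axis estimate."""

    volume: Volume
    axis_origin_mm: np.ndarray  # world coordinates within this sub-volume
    axis_direction: np.ndarray  # unit vector, positive vertical component
    ear_index: int
    origin_index: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))


# ---------------------------------------------------------------------------
# Ear separation
# ---------------------------------------------------------------------------


def _block_max(mask: np.ndarray, block: int) -> np.ndarray:
    pad = [(0, (-s) % block) for s in mask.shape]
    m = np.pad(mask, pad)
    nz, ny, nx = (s // block for s in m.shape)
    return m.reshape(nz, block, ny, block, nx, block).max(axis=(1, 3, 5))


def separate_ears(volume: Volume, expected_ears: int, downsample: int = 8) -> list[EarVolume]:
    """Split a scan of several spatially disjoint ears into sub-volumes.

    Coarse Otsu foreground on an ``downsample``-times reduced volume is
    labelled with 26-connectivity; exactly ``expected_ears`` components
    must remain, ordered left to right by centroid.  Each ear gets a
    principal-axis estimate of its coarse foreground, with the sign fixed
    so the axis points bottom to top.
    """
    if expected_ears < 1:
        raise ValueError("expected_ears must be >= 1")
    # float32 sample keeps the multi-Otsu search on a 256-bin histogram
    sample = volume.grey[::4, ::4, ::4].astype(np.float32)
    try:
        # the foreground must include the rachis (it holds an ear
        # together) yet sit well above the air-noise tail, which the
        # lowest split alone does not guarantee: midpoint of the two
        # air | chaff | grain thresholds
        t0, t1 = threshold_multiotsu(sample, classes=3, nbins=256)
        thr = 0.5 * (t0 + t1)
    except ValueError:
        try:
            thr = threshold_otsu(sample)
        except ValueError as exc:
            raise SegmentationError("volume has no contrast; cannot separate ears") from exc
    # block-max pooling: a coarse cell is foreground if any voxel in it is,
    # which bridges the sub-voxel gaps between seeds, glumes and rachis
    fg = _block_max(volume.grey > thr, downsample)
    labels, n_found = ndimage.label(fg, structure=_STRUCT_26)
    if n_found:
        # ignore specks: a real ear covers many coarse voxels
        counts = np.bincount(labels.ravel())
        keep = [lab for lab in range(1, n_found + 1) if counts[lab] >= 8]
    else:
        keep = []
    if len(keep) != expected_ears:
        raise SegmentationError(
            f"expected {expected_ears} ears but found {len(keep)} coarse foreground "
            "components (touching ears or empty slots?)"
        )
    order = np.argsort([ndimage.center_of_mass(labels == lab)[2] for lab in keep])
    ears: list[EarVolume] = []
    for ear_index, pos in enumerate(order):
        lab = keep[pos]
        comp = labels == lab
        coords = np.argwhere(comp)
        lo = np.maximum(coords.min(axis=0) * downsample - downsample, 0)
        hi = np.minimum((coords.max(axis=0) + 1) * downsample + downsample, volume.shape)
        sub = volume.crop(*(slice(l, h) for l, h in zip(lo, hi)))
        world = (coords + 0.5) * (downsample * volume.voxel_size_mm)
        centroid = world.mean(axis=0)
        centred = world - centroid
        if len(coords) > 3:
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            axis = vt[0]
        else:
            axis = np.array([1.0, 0.0, 0.0])
        if axis[0] < 0:
            axis = -axis
        ears.append(
            EarVolume(
                volume=sub,
                axis_origin_mm=centroid - lo * volume.voxel_size_mm,
                axis_direction=axis,
                ear_index=ear_index,
                origin_index=lo,
            )
        )
    return ears


# ---------------------------------------------------------------------------
# Grain mask
# ---------------------------------------------------------------------------


def _grain_threshold(absorption: np.ndarray, params: SegmentationParams) -> float | None:
    """Automatic grain threshold; None if no grain-like class is present.

    A three-class intensity split (air | chaff | grain) is attempted and
    validated against the absolute absorption floor: the class above the
    chosen threshold must average at least ``grain_floor_absorption``.
    This relies on the volumes being normalized to physical absorption
    and is what lets a fully aborted ear (rachis and awns only, all well
    below the floor) come back grain-free instead of mislabelling chaff.
    If both upper classes reach the floor the split landed inside the
    grain mode (chaff-free volume) and the lower threshold is used.
    """
    if params.grain_threshold is not None:
        return params.grain_threshold
    flat = absorption.ravel()
    floor = params.grain_floor_absorption
    try:
        t0, t1 = threshold_multiotsu(flat, classes=3, nbins=256)
    except ValueError:
        try:
            t = float(threshold_otsu(flat))
        except ValueError:
            return None
        above = flat[flat > t]
        return t if above.size and float(above.mean()) >= floor else None
    top = flat[flat > t1]
    if top.size == 0 or float(top.mean()) < floor:
        return None
    mid = flat[(flat > t0) & (flat <= t1)]
    if mid.size and float(mid.mean()) >= floor:
        return float(t0)
    return float(t1)


def _open_component(local: np.ndarray, radius_vox: int) -> np.ndarray:
    """Morphological opening with a ball, via two local distance transforms.

    Erosion thresholds the interior distance map; dilation thresholds the
    distance from the eroded set.  Intersecting with the input guarantees
    opening never adds voxels.  ``local`` must be padded by at least
    ``radius_vox + 1`` so the dilation has room.
    """
    if radius_vox <= 0:
        return local
    eroded = ndimage.distance_transform_edt(local) > radius_vox
    if not eroded.any():
        return np.zeros_like(local)
    return (ndimage.distance_transform_edt(~eroded) <= radius_vox) & local


def segment_seeds(ear: EarVolume, params: SegmentationParams | None = None) -> list[SeedRegion]:
    """Segment all seeds of one ear into disjoint labelled regions.

    Grain voxels are thresholded, each connected component is opened with
    a small ball (deleting residual thin chaff), and fused grains are
    split by a marker watershed on the Euclidean distance transform
    (markers are distance maxima separated by the configured marker
    distance); split regions are flagged.  Returns an empty list (with a
    warning) when no voxel qualifies as grain — a valid outcome for fully
    aborted ears.  Regions below the minimum voxel floor are dropped as
    debris.
    """
    params = params or SegmentationParams()
    params.validate()
    vol = ear.volume
    absorption = vol.absorption()
    vox = vol.voxel_size_mm
    thr = _grain_threshold(absorption, params)
    if thr is None:
        warnings.warn(f"ear {ear.ear_index}: no grain-level voxels found; empty seed list")
        return []
    grain = absorption > thr
    if not grain.any():
        warnings.warn(f"ear {ear.ear_index}: no voxel above grain threshold {thr:.3f}")
        return []
    radius_vox = int(np.ceil(params.opening_radius_mm / vox))

    labels, n_comp = ndimage.label(grain, structure=_STRUCT_26)
    regions: list[SeedRegion] = []
    md = max(3, int(round(params.marker_min_distance_mm / vox)))
    next_label = 1
    pad = radius_vox + 2
    for comp_label, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        psl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, grain.shape)
        )
        local = labels[psl] == comp_label
        if int(local.sum()) < params.min_region_voxels:
            logger.debug("ear %s: dropping %d-voxel debris component", ear.ear_index, int(local.sum()))
            continue
        # the opened mask decides whether this is grain at all and where the
        # watershed markers go; the final region keeps the full thresholded
        # voxel set so measured widths and volumes match the real grain mask
        opened = _open_component(local, radius_vox)
        if not opened.any():
            logger.debug("ear %s: thin component vanished under opening", ear.ear_index)
            continue
        offset = np.array([s.start for s in psl])
        dist = ndimage.distance_transform_edt(local)
        smooth = ndimage.gaussian_filter(dist, 1.0)
        peaks = peak_local_max(
            smooth,
            min_distance=md,
            threshold_abs=2.0,
            labels=opened.astype(np.uint8),
            exclude_border=False,
        )
        if len(peaks) <= 1:
            parts = [local]
        else:
            markers = np.zeros(local.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            ws = watershed(-smooth, markers=markers, mask=local)
            parts = [ws == i for i in range(1, len(peaks) + 1)]
        kept_parts = [p for p in parts if int(p.sum()) >= params.min_region_voxels]
        if len(kept_parts) < len(parts):
            logger.debug("ear %s: dropped %d sub-floor watershed fragments", ear.ear_index, len(parts) - len(kept_parts))
        split = len(kept_parts) > 1
        for part in kept_parts:
            coords = np.argwhere(part) + offset
            lo = coords.min(axis=0)
            hi = coords.max(axis=0) + 1
            regions.append(
                SeedRegion(
                    label=next_label,
                    voxel_coords=coords,
                    subvolume=vol.grey[tuple(slice(l, h) for l, h in zip(lo, hi))],
                    offset=lo,
                    bbox=tuple((int(l), int(h)) for l, h in zip(lo, hi)),
                    touches_another=split,
                )
            )
            next_label += 1
    return regions


# ---------------------------------------------------------------------------
# Orientation and cross-sections
# ---------------------------------------------------------------------------


@dataclass
class OrientedSeed:
    rotation: np.ndarray  # rows = principal axes (descending variance), (z,y,x)
    extents_mm: np.ndarray  # axis-aligned extents in the principal frame
    centroid_mm: np.ndarray  # world position within the ear volume


def orient_seed(region: SeedRegion, voxel_size_mm: float) -> OrientedSeed:
    """Principal-axis orientation of a seed region.

    Eigenvectors of the voxel-coordinate covariance, eigenvalues
    descending; each axis' sign is fixed so its largest-magnitude component
    is positive.  For (near-)isotropic regions such as cubes the axis order
    is an arbitrary permutation of equivalent directions.
    """
    coords = np.asarray(region.voxel_coords, dtype=float)
    if len(coords) < 4:
        raise OrientationError("need at least 4 voxels for orientation")
    world = (coords + 0.5) * voxel_size_mm
    centroid = world.mean(axis=0)
    centred = world - centroid
    if np.linalg.matrix_rank(centred, tol=1e-9) < 3:
        raise OrientationError("voxels are coplanar; covariance is degenerate")
    cov = np.cov(centred.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T
    for i in range(3):
        if axes[i][np.argmax(np.abs(axes[i]))] < 0:
            axes[i] = -axes[i]
    proj = centred @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0) + voxel_size_mm
    return OrientedSeed(rotation=axes, extents_mm=extents, centroid_mm=centroid)


def max_diameter_cross_section(
    region: SeedRegion, voxel_size_mm: float, pad_vox: int = 2
) -> np.ndarray:
    """2D grey-value slice through the seed's two largest principal axes.

    The plane passes through the centroid and is resampled at voxel
    resolution by trilinear interpolation of the cropped sub-volume; this
    is the maximum-diameter section used for visual inspection.
    """
    oriented = orient_seed(region, voxel_size_mm)
    e1, e2 = oriented.rotation[0], oriented.rotation[1]
    centre_idx = oriented.centroid_mm / voxel_size_mm - 0.5 - region.offset
    h1 = int(np.ceil(oriented.extents_mm[0] / (2 * voxel_size_mm))) + pad_vox
    h2 = int(np.ceil(oriented.extents_mm[1] / (2 * voxel_size_mm))) + pad_vox
    s = np.arange(-h1, h1 + 1)[:, None]
    t = np.arange(-h2, h2 + 1)[None, :]
    sample = (
        centre_idx[:, None, None]
        + e1[:, None, None] * s[None, :, :]
        + e2[:, None, None] * t[None, :, :]
    )
    return ndimage.map_coordinates(
        region.subvolume.astype(np.float32), sample, order=1, cval=0.0
    )
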