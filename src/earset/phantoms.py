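"""Synthetic reconstructed ear volumes with exact per-seed ground truth.

The generator emulates what a normalized CT reconstruction of a cereal ear
looks like to the downstream pipeline: a vertical low-density rachis, seeds
attached in alternating spikelets of up to two grains, thin awn rods,
optional crease cavities and germ notches carved into the grain, optional
surface shrivelling, and additive detector noise on the 16-bit grey scale.
Grain is denser than chaff, which is the physical handle the segmentation
stage relies on.

Every generated volume comes with a :class:`PhantomTruth` record holding
per-seed centres, semiaxes, volumes, minimal widths and a voxel-exact label
volume, so segmentation and trait recovery can be scored against known
ground truth without any real scan data.

Seeds are superellipsoids: exponent 2 gives plump ellipsoidal grains,
larger exponents angular ones.  Default seed semiaxes bracket single-grain
volumes of roughly 8-30 mm^3, the range reported for drought- and
drought-plus-heat-stressed wheat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gamma

from .errors import PackingError
from .traits import min_feret_width
from .volume import Volume, write_volume

__all__ = ["PhantomSpec", "SeedTruth", "EarTruth", "PhantomTruth", "generate_ear_volume", "superellipsoid_volume"]

logger = logging.getLogger(__name__)

_GREY_HEADROOM = 60000.0  # peak absorption maps to this grey value
_CLEARANCE_MM = 0.25  # minimum surface-to-surface gap between non-touching seeds
_TOUCH_OVERLAP_MM = 0.12  # aimed interpenetration for deliberately touching pairs


def superellipsoid_volume(a: float, b: float, c: float, p: float) -> float:
    """Closed-form volume of ``(|x|/a)^p + (|y|/b)^p + (|z|/c)^p <= 1``."""
    g1 = gamma(1.0 + 1.0 / p)
    return 8.0 * a * b * c * g1**3 / gamma(1.0 + 3.0 / p)


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic multi-ear scan.

    Ranges may be given as ``(lo, hi)`` tuples for per-seed/per-ear draws.
    ``noise_sd`` is in 16-bit grey counts; the default is 5% of the seed
    grey level (seeds map to 60000 grey).  The default voxel size of
    100 um is the desk-test scale; production scans use finer sampling and
    only change this knob.
    """

    n_ears: int = 1
    seeds_per_ear: int | tuple[int, int] = (20, 60)
    seed_semiaxes_mm: tuple = ((2.2, 3.0), (1.3, 1.7), (1.0, 1.4))
    crease_fraction: float = 0.3
    shrivel_amplitude: float = 0.05
    seed_attenuation: float = 0.80
    chaff_attenuation: float = 0.35
    noise_sd: float = 3000.0
    voxel_size_um: float = 100.0
    rng_seed: int = 0
    # layout and morphology knobs
    touch_fraction: float = 0.0  # fraction of seeds in deliberately touching pairs
    small_seed_fraction: float = 0.15  # seeds scaled below the 2 mm sieve width
    small_seed_scale: tuple = (0.5, 0.7)
    superellipsoid_exponent: float = 2.0
    germ_notch_fraction: float = 0.7
    seed_tilt_deg: float = 35.0
    spikelet_spacing_mm: float = 3.2
    spikelet_fan_deg: float = 60.0
    phyllotaxis_deg: float = 180.0
    rachis_radius_mm: float = 0.8
    awn_fraction: float = 0.5
    awn_length_mm: float = 6.0
    awn_radius_mm: float = 0.15
    true_density_g_per_abs_mm3: float = 1.6e-3
    ear_spacing_mm: float | None = None

    def validate(self) -> None:
        if self.n_ears < 1:
            raise ValueError("n_ears must be >= 1")
        lo, hi = self._seed_count_range()
        if lo < 1 or hi < lo:
            raise ValueError("seeds_per_ear must be a positive count or (lo, hi) range")
        if not 0.0 <= self.crease_fraction <= 1.0:
            raise ValueError("crease_fraction must be in [0, 1]")
        if self.shrivel_amplitude < 0:
            raise ValueError("shrivel_amplitude must be >= 0")
        if not 0 < self.chaff_attenuation < self.seed_attenuation:
            raise ValueError("need 0 < chaff_attenuation < seed_attenuation (grain is denser than chaff)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        for rng_pair in self.seed_semiaxes_mm:
            for v in np.atleast_1d(rng_pair):
                if not v > 0:
                    raise ValueError("seed semiaxes must be strictly positive")
        if not 0.0 <= self.touch_fraction <= 1.0:
            raise ValueError("touch_fraction must be in [0, 1]")
        if self.superellipsoid_exponent < 2.0:
            raise ValueError("superellipsoid_exponent must be >= 2")
        # resolvability: the smallest possible semiaxis must span >= 4 voxels
        vox = self.voxel_size_um / 1000.0
        min_semi = min(float(np.min(np.atleast_1d(ax))) for ax in self.seed_semiaxes_mm)
        if self.small_seed_fraction > 0:
            min_semi *= float(np.min(np.atleast_1d(self.small_seed_scale)))
        if min_semi / vox < 4.0:
            raise ValueError(
                f"voxel size {self.voxel_size_um} um too coarse: smallest semiaxis "
                f"{min_semi:.2f} mm spans {min_semi / vox:.1f} < 4 voxels"
            )

    def _seed_count_range(self) -> tuple[int, int]:
        if isinstance(self.seeds_per_ear, (tuple, list)):
            return int(self.seeds_per_ear[0]), int(self.seeds_per_ear[1])
        return int(self.seeds_per_ear), int(self.seeds_per_ear)


@dataclass
class SeedTruth:
    ear_index: int
    seed_index: int
    label: int
    centre_mm: np.ndarray  # (z, y, x) world coordinates
    semiaxes_mm: tuple[float, float, float]
    exponent: float
    volume_mm3: float
    voxel_count: int
    mean_attenuation: float
    axial_position_mm: float
    min_diameter_mm: float
    has_crease: bool
    has_germ_notch: bool
    is_small: bool
    touch_partner: int  # label of touching partner, 0 if none

    @property
    def true_mass_index(self) -> float:
        return self.volume_mm3 * self.mean_attenuation


@dataclass
class EarTruth:
    ear_index: int
    n_seeds: int
    ear_length_mm: float  # axial span from first to last seed centre
    total_true_volume_mm3: float
    total_true_weight_g: float
    axis_origin_mm: np.ndarray
    axis_direction: np.ndarray


@dataclass
class PhantomTruth:
    """Ground truth for a generated volume (seed table + label volume)."""

    seeds: list[SeedTruth]
    ears: list[EarTruth]
    labels: np.ndarray  # uint16, 0 = background/chaff
    density_g_per_abs_mm3: float

    def seed_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.seeds:
            rows.append(
                {
                    "ear_index": s.ear_index,
                    "seed_index": s.seed_index,
                    "label": s.label,
                    "centre_z_mm": s.centre_mm[0],
                    "centre_y_mm": s.centre_mm[1],
                    "centre_x_mm": s.centre_mm[2],
                    "semi_a_mm": s.semiaxes_mm[0],
                    "semi_b_mm": s.semiaxes_mm[1],
                    "semi_c_mm": s.semiaxes_mm[2],
                    "exponent": s.exponent,
                    "volume_mm3": s.volume_mm3,
                    "voxel_count": s.voxel_count,
                    "mean_attenuation": s.mean_attenuation,
                    "axial_position_mm": s.axial_position_mm,
                    "min_diameter_mm": s.min_diameter_mm,
                    "has_crease": s.has_crease,
                    "has_germ_notch": s.has_germ_notch,
                    "is_small": s.is_small,
                    "touch_partner": s.touch_partner,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.seed_frame().to_csv(out_dir / "truth_seeds.csv", index=False)
        ears = [
            {
                "ear_index": e.ear_index,
                "n_seeds": e.n_seeds,
                "ear_length_mm": e.ear_length_mm,
                "total_true_volume_mm3": e.total_true_volume_mm3,
                "total_true_weight_g": e.total_true_weight_g,
            }
            for e in self.ears
        ]
        (out_dir / "truth_ears.json").write_text(json.dumps(ears, indent=2))


# ---------------------------------------------------------------------------
# Seed planning
# ---------------------------------------------------------------------------


@dataclass
class _SeedPlan:
    index: int
    spikelet: int
    az_deg: float
    z_mm: float
    semiaxes: tuple[float, float, float]
    tilt_deg: float
    exponent: float
    has_crease: bool
    has_germ: bool
    is_small: bool
    has_awn: bool
    shrivel: tuple  # (amplitude, freqs(3), phases(3))
    rho0: float = 0.0
    touch_partner: int = -1  # seed index within the ear
    frame: np.ndarray = field(default=None, repr=False)  # rows u, v, w in (z,y,x)
    centre: np.ndarray = field(default=None, repr=False)  # (z,y,x) mm, ear-local


def _seed_frame(az_deg: float, tilt_deg: float) -> np.ndarray:
    """Orthonormal seed frame (rows u, v, w) in (z, y, x) components.

    u is the grain's long axis, tilted up-and-outward from vertical; v is
    tangential; w is the outward surface normal direction (w points away
    from the rachis, the crease is carved on the -w side).
    """
    az = np.deg2rad(az_deg)
    tilt = np.deg2rad(tilt_deg)
    zhat = np.array([1.0, 0.0, 0.0])
    rhat = np.array([0.0, np.cos(az), np.sin(az)])
    that = np.array([0.0, -np.sin(az), np.cos(az)])
    u = np.cos(tilt) * zhat + np.sin(tilt) * rhat
    v = that
    w = np.cross(u, v)
    if np.dot(w, rhat) < 0:
        w = -w
        v = -v
    return np.stack([u, v, w])


def _support(plan: _SeedPlan, direction: np.ndarray) -> float:
    """Support half-width of the seed's superellipsoid along a unit vector."""
    p = plan.exponent
    q = p / (p - 1.0)
    comps = np.abs(plan.frame @ direction) * np.array(plan.semiaxes)
    return float((comps**q).sum() ** (1.0 / q))


def _pair_gap(p1: _SeedPlan, p2: _SeedPlan) -> float:
    d = p2.centre - p1.centre
    dist = float(np.linalg.norm(d))
    dhat = d / dist
    return dist - _support(p1, dhat) - _support(p2, dhat)


def _place_spikelet(pair: list[_SeedPlan], spec: PhantomSpec, base_az: float, want_touch: bool) -> None:
    """Set azimuths of a 1- or 2-grain spikelet, honouring the touch contract."""
    if len(pair) == 1:
        pair[0].az_deg = base_az
        _update_centre(pair[0], spec)
        return
    lo, hi = 5.0, 110.0
    fan = spec.spikelet_fan_deg
    step = -2.0 if want_touch else 2.0
    target = None
    while lo <= fan <= hi:
        pair[0].az_deg = base_az - fan / 2.0
        pair[1].az_deg = base_az + fan / 2.0
        for p in pair:
            _update_centre(p, spec)
        gap = _pair_gap(pair[0], pair[1])
        if want_touch:
            if gap <= -_TOUCH_OVERLAP_MM:
                target = fan
                break
        elif gap >= _CLEARANCE_MM:
            target = fan
            break
        fan += step
    if target is None:
        raise PackingError(
            f"cannot place grains {pair[0].index} and {pair[1].index}: no fan angle "
            f"in [{lo}, {hi}] deg gives the required {'contact' if want_touch else 'clearance'}"
        )
    if want_touch:
        pair[0].touch_partner = pair[1].index
        pair[1].touch_partner = pair[0].index


def _update_centre(plan: _SeedPlan, spec: PhantomSpec) -> None:
    plan.frame = _seed_frame(plan.az_deg, plan.tilt_deg)
    az = np.deg2rad(plan.az_deg)
    rhat = np.array([0.0, np.cos(az), np.sin(az)])
    plan.rho0 = spec.rachis_radius_mm + 0.2 + _support(plan, rhat)
    plan.centre = plan.z_mm * np.array([1.0, 0.0, 0.0]) + plan.rho0 * rhat


def _plan_ear(spec: PhantomSpec, rng: np.random.Generator, ear_index: int) -> list[_SeedPlan]:
    lo, hi = spec._seed_count_range()
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo

    def draw(ax_range) -> float:
        ax = np.atleast_1d(ax_range).astype(float)
        return float(rng.uniform(ax[0], ax[-1])) if len(ax) > 1 or True else float(ax[0])

    plans: list[_SeedPlan] = []
    for i in range(n):
        semis = sorted((draw(r) for r in spec.seed_semiaxes_mm), reverse=True)
        is_small = rng.random() < spec.small_seed_fraction
        if is_small:
            scale = float(rng.uniform(*np.atleast_1d(spec.small_seed_scale)[[0, -1]]))
            semis = [s * scale for s in semis]
        shrivel = (
            spec.shrivel_amplitude,
            tuple(rng.uniform(3.0, 6.0, size=3)),
            tuple(rng.uniform(0.0, 2 * np.pi, size=3)),
        )
        plans.append(
            _SeedPlan(
                index=i,
                spikelet=i // 2,
                az_deg=0.0,
                z_mm=(i // 2) * spec.spikelet_spacing_mm + float(rng.uniform(-0.15, 0.15)),
                semiaxes=tuple(semis),
                tilt_deg=spec.seed_tilt_deg + float(rng.uniform(-5.0, 5.0)),
                exponent=spec.superellipsoid_exponent,
                has_crease=rng.random() < spec.crease_fraction,
                has_germ=rng.random() < spec.germ_notch_fraction,
                is_small=is_small,
                has_awn=rng.random() < spec.awn_fraction,
                shrivel=shrivel,
            )
        )

    # deliberately touching pairs: whole two-grain spikelets, drawn up front
    full_spikelets = [s for s in range(n // 2) if 2 * s + 1 < n]
    n_touch_pairs = int(round(spec.touch_fraction * n / 2.0))
    touch_spikelets = set(
        rng.choice(full_spikelets, size=min(n_touch_pairs, len(full_spikelets)), replace=False).tolist()
        if n_touch_pairs
        else []
    )

    for s in range(0, (n + 1) // 2):
        pair = [p for p in plans if p.spikelet == s]
        base_az = (s * spec.phyllotaxis_deg + float(rng.uniform(-5.0, 5.0))) % 360.0
        _place_spikelet(pair, spec, base_az, want_touch=s in touch_spikelets)

    # verify clearance between seeds of different spikelets (one nudge retry)
    for i, p1 in enumerate(plans):
        for p2 in plans[i + 1 :]:
            if p2.spikelet == p1.spikelet:
                continue
            if abs(p2.z_mm - p1.z_mm) > 8.0:
                continue
            for attempt in range(4):
                if _pair_gap(p1, p2) >= 0.15:
                    break
                p2.az_deg = (p2.az_deg + 8.0) % 360.0
                _update_centre(p2, spec)
            else:
                raise PackingError(
                    f"ear {ear_index}: seed {p2.index} cannot be placed without "
                    f"touching seed {p1.index} of another spikelet"
                )
    return plans


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _paint_seed(
    absorption: np.ndarray,
    labels: np.ndarray,
    plan: _SeedPlan,
    centre_world: np.ndarray,
    vox: float,
    spec: PhantomSpec,
    label_value: int,
    partner_label: int,
) -> np.ndarray:
    """Rasterize one seed; returns the painted boolean mask slice info."""
    amp = plan.shrivel[0]
    a, b, c = plan.semiaxes
    u, v, w = plan.frame
    half = (1.0 + amp) * (a * np.abs(u) + b * np.abs(v) + c * np.abs(w))  # (z,y,x) mm
    lo_idx = np.floor((centre_world - half) / vox).astype(int) - 2
    hi_idx = np.ceil((centre_world + half) / vox).astype(int) + 3
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(absorption.shape))
    sl = tuple(slice(l, h) for l, h in zip(lo_idx, hi_idx))
    zz = ((np.arange(lo_idx[0], hi_idx[0])[:, None, None] + 0.5) * vox - centre_world[0]).astype(np.float32)
    yy = ((np.arange(lo_idx[1], hi_idx[1])[None, :, None] + 0.5) * vox - centre_world[1]).astype(np.float32)
    xx = ((np.arange(lo_idx[2], hi_idx[2])[None, None, :] + 0.5) * vox - centre_world[2]).astype(np.float32)
    u32, v32, w32 = (vec.astype(np.float32) for vec in (u, v, w))
    U = zz * u32[0] + yy * u32[1] + xx * u32[2]
    V = zz * v32[0] + yy * v32[1] + xx * v32[2]
    W = zz * w32[0] + yy * w32[1] + xx * w32[2]
    p = plan.exponent
    if p == 2.0:
        f = np.square(U / a) + np.square(V / b) + np.square(W / c)
        radial = np.sqrt(f)
    else:
        f = (np.abs(U) / a) ** np.float32(p) + (np.abs(V) / b) ** np.float32(p) + (np.abs(W) / c) ** np.float32(p)
        radial = f ** np.float32(1.0 / p)
    if amp > 0:
        # the perturbation only matters in a thin band around the surface
        inside = radial <= 1.0 - amp
        band = np.abs(radial - 1.0) <= amp
        if np.any(band):
            freqs, phases = plan.shrivel[1], plan.shrivel[2]
            Ub, Vb, Wb = U[band], V[band], W[band]
            g = (
                np.sin(freqs[0] * Ub / a + phases[0])
                + np.sin(freqs[1] * Vb / b + phases[1])
                + np.sin(freqs[2] * Wb / c + phases[2])
            ) / 3.0
            inside[band] = radial[band] <= 1.0 + amp * g
    else:
        inside = radial <= 1.0
    if plan.has_crease:
        crease_r = 0.6 * min(b, c)
        groove = (V**2 + (W + 0.6 * c) ** 2 <= crease_r**2) & (np.abs(U) <= 0.85 * a)
        inside &= ~groove
    if plan.has_germ:
        # germ notch: spherical bite at the basal pole of the long axis
        pole = -0.85 * a if u[0] > 0 else 0.85 * a
        notch = (U - pole) ** 2 + V**2 + W**2 <= (0.4 * c) ** 2
        inside &= ~notch

    lab_bb = labels[sl]
    occupied = lab_bb != 0
    conflict = inside & occupied & (lab_bb != partner_label)
    if np.any(conflict):
        raise PackingError(
            f"seed {plan.index} (label {label_value}) unexpectedly overlaps "
            f"label {int(lab_bb[conflict][0])} by {int(conflict.sum())} voxels"
        )
    paint = inside & ~occupied
    absorption[sl][paint] = spec.seed_attenuation
    lab_bb[paint] = label_value
    return sl, paint


def _paint_awn(absorption: np.ndarray, start: np.ndarray, direction: np.ndarray, length: float, radius: float, vox: float, value: float) -> None:
    end = start + direction * length
    lo = np.floor((np.minimum(start, end) - radius - vox) / vox).astype(int)
    hi = np.ceil((np.maximum(start, end) + radius + vox) / vox).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(absorption.shape))
    if np.any(hi <= lo):
        return
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    zz = (np.arange(lo[0], hi[0])[:, None, None] + 0.5) * vox - start[0]
    yy = (np.arange(lo[1], hi[1])[None, :, None] + 0.5) * vox - start[1]
    xx = (np.arange(lo[2], hi[2])[None, None, :] + 0.5) * vox - start[2]
    t = np.clip(zz * direction[0] + yy * direction[1] + xx * direction[2], 0.0, length)
    d2 = (zz - t * direction[0]) ** 2 + (yy - t * direction[1]) ** 2 + (xx - t * direction[2]) ** 2
    mask = (d2 <= radius**2) & (absorption[sl] == 0)
    absorption[sl][mask] = value


def generate_ear_volume(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate one synthetic scan (possibly several ears) plus ground truth.

    The returned volume is what the reconstruction stage would hand to
    segmentation: a 16-bit grey volume whose sidecar scale converts grey to
    absorption.  Identical specs (including ``rng_seed``) generate
    bit-identical volumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    vox = spec.voxel_size_um / 1000.0

    ear_plans = [_plan_ear(spec, rng, e) for e in range(spec.n_ears)]

    # grid sizing from the planned geometry
    margin = 0.6
    rho_max = 0.0
    z_lo, z_hi = np.inf, -np.inf
    for plans in ear_plans:
        for p in plans:
            zhat = np.array([1.0, 0.0, 0.0])
            h_z = _support(p, zhat) * (1 + p.shrivel[0])
            rho_out = p.rho0 + _support(p, np.array([0.0, np.cos(np.deg2rad(p.az_deg)), np.sin(np.deg2rad(p.az_deg))])) * (1 + p.shrivel[0])
            z_lo = min(z_lo, p.z_mm - h_z)
            top = p.z_mm + h_z
            if p.has_awn:
                top += spec.awn_length_mm
                rho_out += 0.12 * spec.awn_length_mm
            z_hi = max(z_hi, top)
            rho_max = max(rho_max, rho_out)
    half_w = rho_max + margin
    ear_spacing = spec.ear_spacing_mm if spec.ear_spacing_mm is not None else 2 * half_w + 3.0
    nz = int(np.ceil((z_hi - z_lo + 2 * margin) / vox))
    ny = int(np.ceil(2 * half_w / vox))
    nx = int(np.ceil((2 * half_w + (spec.n_ears - 1) * ear_spacing) / vox))

    absorption = np.zeros((nz, ny, nx), dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.uint16)

    z_offset = margin - z_lo  # world z of spikelet 0 plane
    y_centre = half_w
    seeds_truth: list[SeedTruth] = []
    ears_truth: list[EarTruth] = []
    label_value = 0
    for e, plans in enumerate(ear_plans):
        x_centre = half_w + e * ear_spacing
        ear_origin = np.array([0.0, y_centre, x_centre])
        # rachis: vertical cylinder spanning the seed range plus a stub
        if spec.rachis_radius_mm > 0:
            yy = (np.arange(ny)[:, None] + 0.5) * vox - y_centre
            xx = (np.arange(nx)[None, :] + 0.5) * vox - x_centre
            disk = yy**2 + xx**2 <= spec.rachis_radius_mm**2
            z0 = max(0, int((z_offset + min(p.z_mm for p in plans) - 2.0) / vox))
            z1 = min(nz, int((z_offset + max(p.z_mm for p in plans) + 2.0) / vox))
            absorption[z0:z1][:, disk] = spec.chaff_attenuation

        ear_seed_truth: list[SeedTruth] = []
        label_of_index: dict[int, int] = {}
        painted: dict[int, tuple] = {}
        for p in plans:
            label_value += 1
            label_of_index[p.index] = label_value
        for p in plans:
            centre_world = p.centre + np.array([z_offset, y_centre, x_centre])
            partner_label = label_of_index.get(p.touch_partner, 0)
            this_label = label_of_index[p.index]
            sl, paint = _paint_seed(absorption, labels, p, centre_world, vox, spec, this_label, partner_label)
            painted[p.index] = (sl, paint, centre_world)

        for p in plans:
            sl, paint, centre_world = painted[p.index]
            count = int(paint.sum())
            coords = np.argwhere(paint) + np.array([s.start for s in sl])
            modified = p.has_crease or p.has_germ or p.shrivel[0] > 0 or p.touch_partner >= 0
            if modified:
                vol = count * vox**3
            else:
                vol = superellipsoid_volume(*p.semiaxes, p.exponent)
            partner_label = label_of_index.get(p.touch_partner, 0)
            if partner_label:
                # confirm actual voxel contact; pairs that missed are demoted
                psl, ppaint, _ = painted[p.touch_partner]
                touching = _masks_touch(sl, paint, psl, ppaint)
                if not touching:
                    logger.debug("planned touch pair (%d, %d) not in contact after rasterization", p.index, p.touch_partner)
                    partner_label = 0
            ear_seed_truth.append(
                SeedTruth(
                    ear_index=e,
                    seed_index=p.index,
                    label=label_of_index[p.index],
                    centre_mm=centre_world,
                    semiaxes_mm=p.semiaxes,
                    exponent=p.exponent,
                    volume_mm3=vol,
                    voxel_count=count,
                    mean_attenuation=spec.seed_attenuation,
                    axial_position_mm=float(centre_world[0]),
                    min_diameter_mm=min_feret_width(coords, vox),
                    has_crease=p.has_crease,
                    has_germ_notch=p.has_germ,
                    is_small=p.is_small,
                    touch_partner=partner_label,
                )
            )
            if p.has_awn and spec.awn_radius_mm > 0:
                az = np.deg2rad(p.az_deg)
                rhat = np.array([0.0, np.cos(az), np.sin(az)])
                u = p.frame[0] if p.frame[0][0] > 0 else -p.frame[0]
                start = centre_world + u * p.semiaxes[0] * 0.9
                direction = np.array([1.0, 0.0, 0.0]) + 0.12 * rhat
                direction /= np.linalg.norm(direction)
                _paint_awn(absorption, start, direction, spec.awn_length_mm, spec.awn_radius_mm, vox, spec.chaff_attenuation)

        zpos = [s.axial_position_mm for s in ear_seed_truth]
        ears_truth.append(
            EarTruth(
                ear_index=e,
                n_seeds=len(ear_seed_truth),
                ear_length_mm=float(max(zpos) - min(zpos)) if len(zpos) > 1 else 0.0,
                total_true_volume_mm3=float(sum(s.volume_mm3 for s in ear_seed_truth)),
                total_true_weight_g=float(
                    sum(s.true_mass_index * spec.true_density_g_per_abs_mm3 for s in ear_seed_truth)
                ),
                axis_origin_mm=ear_origin,
                axis_direction=np.array([1.0, 0.0, 0.0]),
            )
        )
        seeds_truth.extend(ear_seed_truth)

    scale = _GREY_HEADROOM / spec.seed_attenuation
    grey = absorption * np.float32(scale)
    if spec.noise_sd > 0:
        grey = grey + rng.standard_normal(grey.shape, dtype=np.float32) * np.float32(spec.noise_sd)
    grey = np.clip(np.rint(grey), 0, 65535).astype(np.uint16)
    volume = Volume(
        grey=grey,
        voxel_size_um=spec.voxel_size_um,
        grey_per_absorption=scale,
        extra_metadata={"rng_seed": int(spec.rng_seed)},
    )
    truth = PhantomTruth(
        seeds=seeds_truth,
        ears=ears_truth,
        labels=labels,
        density_g_per_abs_mm3=spec.true_density_g_per_abs_mm3,
    )
    return volume, truth


def _masks_touch(sl1, mask1, sl2, mask2) -> bool:
    """26-connectivity contact test between two bbox-local masks."""
    lo = [min(a.start, b.start) for a, b in zip(sl1, sl2)]
    hi = [max(a.stop, b.stop) for a, b in zip(sl1, sl2)]
    shape = tuple(h - l for l, h in zip(lo, hi))
    m1 = np.zeros(shape, dtype=bool)
    m2 = np.zeros(shape, dtype=bool)
    m1[tuple(slice(a.start - l, a.stop - l) for a, l in zip(sl1, lo))] = mask1
    m2[tuple(slice(a.start - l, a.stop - l) for a, l in zip(sl2, lo))] = mask2
    grown = ndimage.binary_dilation(m1, structure=np.ones((3, 3, 3), dtype=bool))
    return bool(np.any(grown & m2))


def write_phantom(volume: Volume, truth: PhantomTruth, out_dir: str | Path) -> None:
    """Write volume (TIFF + sidecar), truth CSV/JSON and the label volume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(volume, out_dir / "phantom.tif")
    truth.write(out_dir)
    import tifffile

    tifffile.imwrite(out_dir / "truth_labels.tif", truth.labels)
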