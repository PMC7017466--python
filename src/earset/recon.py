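"""Simplified CT stage: parallel-beam projection and normalized FBP.

The production scanner acquires helical cone-beam projections; everything
downstream of reconstruction only depends on a *normalized absorption
volume*, so this module substitutes a desk-verifiable parallel-beam,
slice-stacked geometry.  Two properties of the production reconstruction
are reproduced exactly:

* per-projection normalization by the automatically detected unattenuated
  intensity I0, which makes the reconstructed absorption invariant to
  primary-beam intensity drift, and
* conversion of the absorption range to an unsigned 16-bit grey volume
  with the linear scale stored in the sidecar.

Filtering uses a Hann-windowed ramp at the Nyquist cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .errors import ReconstructionError
from .volume import Volume

__all__ = [
    "ProjectionStack",
    "forward_project",
    "detect_unattenuated_intensity",
    "normalize_stack",
    "fbp_reconstruct",
]

logger = logging.getLogger(__name__)

_GREY_HEADROOM = 60000.0


@dataclass
class ProjectionStack:
    """Parallel-beam projection images on a linear intensity scale.

    ``intensities`` has shape ``(n_angles, n_z, n_u)``: one detector image
    per angle, detector rows stacked along the specimen axis.
    """

    intensities: np.ndarray
    angles_deg: np.ndarray
    detector_pixel_um: float
    i0_estimate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (n_angles, n_z, n_u)")
        if len(self.angles_deg) != len(self.intensities) or len(self.angles_deg) < 2:
            raise ValueError("need one strictly increasing angle per projection, at least 2")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be positive (log transform must be defined)")
        if not self.detector_pixel_um > 0:
            raise ValueError("detector_pixel_um must be positive")


def forward_project(
    phantom_absorption: np.ndarray,
    angles_deg: np.ndarray,
    i0: float | np.ndarray,
    voxel_size_um: float,
) -> ProjectionStack:
    """Beer-Lambert forward projection, computed slice by slice.

    Each detector pixel receives ``i0 * exp(-line integral)`` of the
    absorption (1/mm) along the parallel ray.  ``i0`` may be scalar or
    per-angle (to simulate primary-beam drift).
    """
    absorption = np.asarray(phantom_absorption, dtype=np.float64)
    if not np.all(np.isfinite(absorption)):
        raise ReconstructionError("absorption field contains non-finite values")
    if np.any(absorption < 0):
        raise ReconstructionError("absorption must be non-negative")
    angles = np.asarray(angles_deg, dtype=np.float64)
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=np.float64), (len(angles),))
    if np.any(i0_arr <= 0):
        raise ReconstructionError("i0 must be positive")
    vox_mm = voxel_size_um / 1000.0
    nz, ny, nx = absorption.shape
    if ny != nx:
        raise ReconstructionError("slices must be square for the parallel geometry")
    n_u = nx
    path = np.empty((len(angles), nz, n_u), dtype=np.float64)
    for z in range(nz):
        sino = radon(absorption[z], theta=angles, circle=True) * vox_mm  # (u, angle)
        path[:, z, :] = sino.T
    intensities = i0_arr[:, None, None] * np.exp(-path)
    return ProjectionStack(
        intensities=intensities,
        angles_deg=angles,
        detector_pixel_um=voxel_size_um,
    )


def detect_unattenuated_intensity(
    projection: np.ndarray, border_fraction: float = 0.05, stability_tol: float = 0.02
) -> float:
    """Estimate the unattenuated intensity I0 of one detector image.

    The specimen never fills the detector laterally, so the outermost
    columns see air.  The estimate is the median of the top decile of the
    border-column pixels, which is robust to noise.  If the candidate
    border columns disagree by more than ``stability_tol`` (relative), no
    stable air region exists (specimen covering the border); a warning is
    emitted and the global maximum is used as fallback.
    """
    proj = np.asarray(projection, dtype=np.float64)
    if proj.ndim == 1:
        proj = proj[None, :]
    n_u = proj.shape[1]
    k = max(2, int(round(border_fraction * n_u)))
    border = np.concatenate([proj[:, :k], proj[:, -k:]], axis=1)
    col_medians = np.median(border, axis=0)
    spread = (col_medians.max() - col_medians.min()) / max(col_medians.max(), 1e-300)
    if spread > stability_tol:
        warnings.warn(
            "no stable air region on the detector border; falling back to the "
            "global projection maximum as I0"
        )
        return float(proj.max())
    vals = border.ravel()
    top = np.sort(vals)[int(np.floor(0.9 * len(vals))):]
    return float(np.median(top))


def normalize_stack(stack: ProjectionStack) -> ProjectionStack:
    """Fill ``i0_estimate`` with the per-projection detected I0."""
    stack.i0_estimate = np.array(
        [detect_unattenuated_intensity(img) for img in stack.intensities]
    )
    return stack


def fbp_reconstruct(stack: ProjectionStack, grey_headroom: float = _GREY_HEADROOM) -> Volume:
    """Filtered back projection of a normalized projection stack.

    Per projection the log-normalized attenuation ``-ln(I / I0)`` is
    ramp-filtered (Hann window) and back-projected slice by slice.  The
    absorption field is mapped linearly to 16-bit grey with the scale
    recorded on the volume, so grey values represent physical absorption.
    """
    if stack.i0_estimate is None:
        normalize_stack(stack)
    angles = stack.angles_deg
    span = angles.max() - angles.min()
    if span < 180.0 - 1.01 * np.median(np.diff(angles)):
        raise ReconstructionError(f"angular coverage {span:.1f} deg < 180 deg")
    vox_mm = stack.detector_pixel_um / 1000.0
    n_angles, nz, n_u = stack.intensities.shape
    attenuation = -np.log(stack.intensities / stack.i0_estimate[:, None, None])
    recon = np.empty((nz, n_u, n_u), dtype=np.float64)
    for z in range(nz):
        sino = attenuation[:, z, :].T  # (u, angle)
        recon[z] = iradon(
            sino, theta=angles, filter_name="hann", circle=True, output_size=n_u
        ) / vox_mm
    recon = np.clip(recon, 0.0, None)
    peak = recon.max()
    scale = grey_headroom / peak if peak > 0 else 1.0
    grey = np.clip(np.rint(recon * scale), 0, 65535).astype(np.uint16)
    return Volume(
        grey=grey,
        voxel_size_um=stack.detector_pixel_um,
        grey_per_absorption=scale,
    )
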