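"""Reconstructed grey-value volumes and their on-disk format.

A :class:`Volume` is an unsigned 16-bit grey-value array together with the
two pieces of metadata without which the grey values are meaningless: the
voxel spacing and the linear grey-to-absorption scale.  Volumes are stored
as multi-page TIFF stacks with a JSON sidecar next to them; the sidecar is
mandatory on read — the absorption scale is never guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import SidecarError

__all__ = ["Volume", "read_volume", "write_volume"]

_REQUIRED_SIDECAR_KEYS = ("voxel_size_um", "grey_per_absorption")


@dataclass
class Volume:
    """A reconstructed 3D grey-value volume.

    Parameters
    ----------
    grey
        ``uint16`` array in ``(z, y, x)`` order, ``z`` pointing up along the
        rachis.  Grey values occupy ``[0, 65535]``.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    grey_per_absorption
        Linear scale such that ``absorption = grey / grey_per_absorption``
        (absorption in 1/mm for the beam used).
    """

    grey: np.ndarray
    voxel_size_um: float
    grey_per_absorption: float
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grey = np.asarray(self.grey)
        if self.grey.dtype != np.uint16:
            if self.grey.min() < 0 or self.grey.max() > 65535:
                raise ValueError("grey values must fit the uint16 range")
            self.grey = self.grey.astype(np.uint16)
        if self.grey.ndim != 3:
            raise ValueError("volume must be a 3D (z, y, x) array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.grey_per_absorption > 0:
            raise ValueError("grey_per_absorption must be positive")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grey.shape

    def absorption(self) -> np.ndarray:
        """Grey values converted to absorption (float32, 1/mm)."""
        return self.grey.astype(np.float32) / np.float32(self.grey_per_absorption)

    def crop(self, zs: slice, ys: slice, xs: slice) -> "Volume":
        """Sub-volume view; metadata (including the scale) is preserved."""
        return replace(self, grey=self.grey[zs, ys, xs])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    Returns the sidecar path.  The round trip through
    :func:`read_volume` is lossless for grey values and metadata.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.grey, photometric="minisblack")
    sidecar = {
        "voxel_size_um": float(volume.voxel_size_um),
        "grey_per_absorption": float(volume.grey_per_absorption),
        **volume.extra_metadata,
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=2))
    return sc_path


def read_volume(path: str | Path) -> Volume:
    """Read a TIFF-stack (or raw-block) volume with its JSON sidecar.

    Raw blocks (``.raw``) additionally need ``shape`` and ``dtype`` in the
    sidecar.  A missing sidecar or missing required key is a hard error:
    grey values are never interpreted without their absorption scale.
    """
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar {sc_path} for volume {path}")
    sidecar = json.loads(sc_path.read_text())
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise SidecarError(f"sidecar {sc_path} lacks required key '{key}'")
    if path.suffix.lower() == ".raw":
        for key in ("shape", "dtype"):
            if key not in sidecar:
                raise SidecarError(f"raw volume sidecar lacks required key '{key}'")
        grey = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]))
        grey = grey.reshape(tuple(sidecar["shape"]))
    else:
        grey = tifffile.imread(path)
    extra = {k: v for k, v in sidecar.items() if k not in (*_REQUIRED_SIDECAR_KEYS, "shape", "dtype")}
    return Volume(
        grey=grey,
        voxel_size_um=float(sidecar["voxel_size_um"]),
        grey_per_absorption=float(sidecar["grey_per_absorption"]),
        extra_metadata=extra,
    )
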