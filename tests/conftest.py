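"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from earset.phantoms import PhantomSpec, generate_ear_volume


def small_spec(**overrides) -> PhantomSpec:
    """A compact, quickly-rasterized ear: a handful of mid-sized seeds."""
    defaults = dict(
        n_ears=1,
        seeds_per_ear=8,
        seed_semiaxes_mm=((2.0, 2.4), (1.2, 1.4), (1.0, 1.2)),
        crease_fraction=0.0,
        shrivel_amplitude=0.0,
        small_seed_fraction=0.0,
        germ_notch_fraction=0.0,
        awn_fraction=0.3,
        touch_fraction=0.0,
        noise_sd=1500.0,
        rng_seed=42,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_ear():
    """One clean 8-seed ear with truth; segmentation-friendly."""
    spec = small_spec()
    volume, truth = generate_ear_volume(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def sphere_seed():
    """A single spherical 2 mm-radius seed, noise-free, no chaff structures."""
    spec = PhantomSpec(
        n_ears=1,
        seeds_per_ear=1,
        seed_semiaxes_mm=(2.0, 2.0, 2.0),
        crease_fraction=0.0,
        shrivel_amplitude=0.0,
        small_seed_fraction=0.0,
        germ_notch_fraction=0.0,
        awn_fraction=0.0,
        touch_fraction=0.0,
        noise_sd=0.0,
        rng_seed=7,
    )
    volume, truth = generate_ear_volume(spec)
    return spec, volume, truth


def region_from_mask(mask: np.ndarray, grey_value: int = 60000, label: int = 1):
    """Build a SeedRegion-shaped object from a boolean mask (test helper)."""
    from earset.segment import SeedRegion

    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = np.zeros(tuple(hi - lo), dtype=np.uint16)
    sub[tuple((coords - lo).T)] = grey_value
    return SeedRegion(
        label=label,
        voxel_coords=coords,
        subvolume=sub,
        offset=lo,
        bbox=tuple((int(l), int(h)) for l, h in zip(lo, hi)),
    )
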