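"""Independent brute-force oracles used to validate the implementation."""

from itertools import combinations

import numpy as np


def brute_force_min_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive smallest enclosing sphere via all 1-4 point support sets.

    Independent of the package implementation: every candidate sphere is
    determined directly from its support subset (midpoint for pairs,
    circumcentre solves for triples/quadruples) and checked for coverage.
    Exponential; only for small inputs.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = None

    def covers(c, r):
        return np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9)

    for i in range(n):
        c, r = pts[i], 0.0
        if covers(c, r) and (best is None or r < best[1]):
            best = (c, r)
    for i, j in combinations(range(n), 2):
        c = 0.5 * (pts[i] + pts[j])
        r = np.linalg.norm(pts[i] - c)
        if covers(c, r) and (best is None or r < best[1]):
            best = (c, r)
    for sub in combinations(range(n), 3):
        c = _circumcentre(pts[list(sub)])
        if c is None:
            continue
        r = max(np.linalg.norm(pts[k] - c) for k in sub)
        if covers(c, r) and (best is None or r < best[1]):
            best = (c, r)
    for sub in combinations(range(n), 4):
        c = _circumcentre(pts[list(sub)])
        if c is None:
            continue
        r = max(np.linalg.norm(pts[k] - c) for k in sub)
        if covers(c, r) and (best is None or r < best[1]):
            best = (c, r)
    return best


def _circumcentre(sub: np.ndarray):
    """Centre equidistant from all points of a 3- or 4-point subset."""
    p0 = sub[0]
    rel = sub[1:] - p0
    rhs = 0.5 * np.einsum("ij,ij->i", rel, rel)
    try:
        sol, residual, rank, _ = np.linalg.lstsq(rel, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < len(rel):
        return None
    c = p0 + sol
    d = np.linalg.norm(sub - c, axis=1)
    if d.max() - d.min() > 1e-7 * (1 + d.max()):
        return None
    return c


def brute_force_surface_count(mask: np.ndarray) -> int:
    """Direct 6-neighbour scan counting voxels adjacent to background."""
    padded = np.pad(mask, 1)
    count = 0
    for z, y, x in np.argwhere(padded):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            if not padded[z + dz, y + dy, x + dx]:
                count += 1
                break
    return count


def dense_direction_min_width(coords: np.ndarray, voxel_size: float, n: int = 4096, seed: int = 0) -> float:
    """Minimal projected width over a dense random direction set.

    Same half-footprint width definition as the package estimator, but an
    independent, much denser direction sample.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    proj = np.asarray(coords, dtype=float) @ dirs.T
    span = proj.max(axis=0) - proj.min(axis=0) + 0.5 * np.abs(dirs).sum(axis=1)
    return float(span.min() * voxel_size)


def rasterize_ellipsoid(semiaxes_vox, rotation=None, pad: int = 2) -> np.ndarray:
    """Boolean mask of an (optionally rotated) ellipsoid, voxel units."""
    semiaxes = np.asarray(semiaxes_vox, dtype=float)
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    half = np.ceil(np.abs(R.T * semiaxes).sum(axis=1)).astype(int) + pad
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    local = pts @ R.T
    inside = ((local / semiaxes) ** 2).sum(axis=1) <= 1.0
    return inside.reshape(grids[0].shape)
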