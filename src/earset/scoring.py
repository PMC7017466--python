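"""Scoring segmentation output against phantom ground truth.

A truth seed counts as *correctly recovered* when exactly one predicted
region claims it (by majority voxel overlap) and that region covers at
least half of the seed's true voxels — so both merge failures (one region
claiming two seeds) and spurious splits (two regions on one seed) count
against accuracy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .phantoms import PhantomTruth
from .segment import SeedRegion

__all__ = ["RecoveryScore", "score_seed_recovery"]


@dataclass
class RecoveryScore:
    n_true: int
    n_predicted: int
    n_recovered: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_true if self.n_true else float("nan")


def score_seed_recovery(
    truth: PhantomTruth,
    regions: list[SeedRegion],
    volume_shape: tuple[int, int, int],
    origin_index: np.ndarray | None = None,
) -> RecoveryScore:
    """Match predicted regions to truth labels and count recoveries.

    ``origin_index`` translates region coordinates (which live in an ear
    sub-volume) back into the full phantom frame.
    """
    origin = np.zeros(3, dtype=int) if origin_index is None else np.asarray(origin_index)
    pred = np.zeros(volume_shape, dtype=np.int64)
    for r in regions:
        coords = r.voxel_coords + origin
        pred[tuple(coords.T)] = r.label
    tl = truth.labels.astype(np.int64)
    both = (tl > 0) & (pred > 0)
    t, p = tl[both], pred[both]
    m = int(pred.max()) + 1
    keys, counts = np.unique(t * m + p, return_counts=True)
    best_for_pred: dict[int, tuple[int, int]] = {}
    for key, count in zip(keys, counts):
        tlab, plab = int(key // m), int(key % m)
        if plab not in best_for_pred or count > best_for_pred[plab][1]:
            best_for_pred[plab] = (tlab, int(count))
    claims: dict[int, list[int]] = defaultdict(list)
    for plab, (tlab, count) in best_for_pred.items():
        claims[tlab].append(count)
    true_counts = np.bincount(tl.ravel())
    n_recovered = sum(
        1
        for s in truth.seeds
        if len(claims.get(s.label, [])) == 1 and claims[s.label][0] >= 0.5 * true_counts[s.label]
    )
    return RecoveryScore(n_true=len(truth.seeds), n_predicted=len(regions), n_recovered=n_recovered)
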