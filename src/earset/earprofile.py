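"""Ear-level aggregation: seed ordering, position profiles, evaluation.

Seeds are ordered by the scalar projection of their centre of mass onto
the ear axis; the normalized position maps the first (bottom) seed to 0
and the last (top) seed to 1.  Pooled over ears, the per-bin mean virtual
seed weight against normalized position is the seed-weight profile, which
for stressed wheat shows depressed weights at the ear base and tip.

Virtual totals are evaluated against hand-threshed reference weights and
sieved seed counts with the squared Pearson correlation (r^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .traits import SeedTraits, apply_sieve

__all__ = [
    "EarRecord",
    "EvaluationReport",
    "order_and_normalize",
    "build_ear_record",
    "weight_position_profile",
    "evaluate_against_actual",
    "group_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class EarRecord:
    """Ordered seeds of one ear with aggregate yield components."""

    ear_id: str
    seeds: list[SeedTraits]  # ordered bottom -> top
    total_virtual_weight_g: float
    total_weight_sieved_g: float
    n_seeds_sieved: int
    n_seeds_small: int
    ear_length_seed_span_mm: float
    total_mass_index: float
    group: str | None = None


@dataclass
class EvaluationReport:
    """Per-ear virtual-vs-actual pairs and their r^2."""

    pairs: pd.DataFrame  # ear_id, virtual_weight_g, actual_weight_g, virtual_count, actual_count
    r2_weight: float | None
    r2_count: float | None
    unmatched_ids: list[str]


def order_and_normalize(
    seeds: list[SeedTraits],
    axis_origin_mm: np.ndarray,
    axis_direction: np.ndarray,
) -> list[SeedTraits]:
    """Sort seeds along the ear axis and fill their axial positions.

    The axis direction is used with a positive vertical component, so the
    bottom seed is always normalized position 0 and the top seed 1
    regardless of the sign the caller passes.  A single seed sits at 0.
    """
    if not seeds:
        return []
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if direction[0] < 0:
        direction = -direction
    origin = np.asarray(axis_origin_mm, dtype=float)
    t = np.array([float(np.dot(np.asarray(s.centre_of_mass_mm) - origin, direction)) for s in seeds])
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    span = t_sorted[-1] - t_sorted[0]
    out = []
    for rank, idx in enumerate(order):
        norm = (t_sorted[rank] - t_sorted[0]) / span if span > 0 else 0.0
        out.append(
            replace(
                seeds[idx],
                axial_position_mm=float(t_sorted[rank]),
                axial_position_norm=float(norm),
            )
        )
    return out


def build_ear_record(
    ear_id: str,
    seeds: list[SeedTraits],
    axis_origin_mm: np.ndarray,
    axis_direction: np.ndarray,
    sieve_cutoff_mm: float = 2.0,
    group: str | None = None,
) -> EarRecord:
    """Order seeds and aggregate per-ear yield components."""
    ordered = order_and_normalize(seeds, axis_origin_mm, axis_direction)
    retained, omitted = apply_sieve(ordered, sieve_cutoff_mm)
    span = (
        ordered[-1].axial_position_mm - ordered[0].axial_position_mm if len(ordered) > 1 else 0.0
    )
    return EarRecord(
        ear_id=ear_id,
        seeds=ordered,
        total_virtual_weight_g=float(sum(s.virtual_weight_g for s in ordered)),
        total_weight_sieved_g=float(sum(s.virtual_weight_g for s in retained)),
        n_seeds_sieved=len(retained),
        n_seeds_small=len(omitted),
        ear_length_seed_span_mm=float(span),
        total_mass_index=float(sum(s.mass_index for s in ordered)),
        group=group,
    )


def weight_position_profile(ears: list[EarRecord], n_bins: int = 20) -> pd.DataFrame:
    """Mean seed weight per normalized-position bin, pooled across ears.

    All seeds are included, big and small; empty bins are reported as
    missing (NaN), never as zero.  The last bin is closed so position 1
    belongs to it.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not ears or not any(e.seeds for e in ears):
        raise ValueError("need at least one ear with at least one seed")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ear in ears:
        for s in ear.seeds:
            b = min(int(s.axial_position_norm * n_bins), n_bins - 1)
            sums[b] += s.virtual_weight_g
            counts[b] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) / n_bins
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "mean_seed_weight_g": means,
            "n_seeds": counts,
        }
    )


def _r_squared(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation; None when undefined (constant input)."""
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def evaluate_against_actual(ears: list[EarRecord], actual: pd.DataFrame) -> EvaluationReport:
    """Correlate virtual per-ear totals with reference measurements.

    ``actual`` needs columns ``ear_id``, ``actual_weight_g`` and
    optionally ``actual_count`` (seeds above the sieve).  r^2 is the
    squared Pearson correlation of the matched pairs; a constant actual
    vector makes r^2 undefined and it is reported as missing.
    """
    actual = actual.set_index("ear_id") if "ear_id" in actual.columns else actual
    rows = []
    unmatched = []
    for ear in ears:
        if ear.ear_id in actual.index:
            rec = actual.loc[ear.ear_id]
            rows.append(
                {
                    "ear_id": ear.ear_id,
                    "virtual_weight_g": ear.total_virtual_weight_g,
                    "actual_weight_g": float(rec["actual_weight_g"]),
                    "virtual_count": ear.n_seeds_sieved,
                    "actual_count": float(rec["actual_count"]) if "actual_count" in rec else np.nan,
                }
            )
        else:
            unmatched.append(ear.ear_id)
    if unmatched:
        logger.warning("evaluation: %d ears without reference measurement: %s", len(unmatched), unmatched[:5])
    if len(rows) < 2:
        raise ValueError(f"need >= 2 matched ears for evaluation, got {len(rows)}")
    pairs = pd.DataFrame(rows)
    r2_weight = _r_squared(pairs["virtual_weight_g"].values, pairs["actual_weight_g"].values)
    counts_ok = pairs["actual_count"].notna().all()
    r2_count = (
        _r_squared(pairs["virtual_count"].values.astype(float), pairs["actual_count"].values)
        if counts_ok
        else None
    )
    return EvaluationReport(pairs=pairs, r2_weight=r2_weight, r2_count=r2_count, unmatched_ids=unmatched)


def plot_profile(profile: pd.DataFrame, path) -> None:
    """Write the weight-position profile as a figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    centres = 0.5 * (profile["bin_left"] + profile["bin_right"])
    ax.plot(centres, profile["mean_seed_weight_g"], marker="o")
    ax.set_xlabel("normalized ear position (0 = bottom seed, 1 = top seed)")
    ax.set_ylabel("mean seed weight (g)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_evaluation(report: EvaluationReport, path) -> None:
    """Virtual-vs-actual weight scatter with the r^2 annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(report.pairs["actual_weight_g"], report.pairs["virtual_weight_g"], s=18)
    lim = max(report.pairs["actual_weight_g"].max(), report.pairs["virtual_weight_g"].max())
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    ax.set_xlabel("actual seed weight per ear (g)")
    ax.set_ylabel("virtual seed weight per ear (g)")
    if report.r2_weight is not None:
        ax.set_title(f"$r^2$ = {report.r2_weight:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def group_summary(ears: list[EarRecord]) -> pd.DataFrame:
    """Per-group mean/SD/n of per-ear-averaged seed set characteristics.

    Single-seed traits (weight, volume, spherical ratio, relative surface,
    mean attenuation) are averaged per ear first and only then aggregated
    per group, matching how treatment panels are reported; seed count per
    ear enters directly.  Ears without a group label are excluded with a
    warning.
    """
    rows = []
    for ear in ears:
        if not ear.group:
            logger.warning("group_summary: ear %s has no group label; excluded", ear.ear_id)
            continue
        if not ear.seeds:
            continue
        rows.append(
            {
                "group": ear.group,
                "single_seed_weight_g": np.mean([s.virtual_weight_g for s in ear.seeds]),
                "seed_volume_mm3": np.mean([s.volume_mm3 for s in ear.seeds]),
                "spherical_ratio": np.mean([s.aspect_ratio for s in ear.seeds]),
                "surface_to_volume": np.mean([s.surface_to_volume for s in ear.seeds]),
                "mean_attenuation": np.mean([s.mean_attenuation for s in ear.seeds]),
                "seed_count": len(ear.seeds),
            }
        )
    per_ear = pd.DataFrame(rows)
    if per_ear.empty:
        return per_ear
    return per_ear.groupby("group").agg(["mean", "std", "count"])
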