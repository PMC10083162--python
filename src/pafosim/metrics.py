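"""Outcome metrics: percentage change, muscle force integral, averaging.

The two scalar metrics the analysis reports are

* percentage change between a baseline value V₁ and a comparison value V₂,
  (V₂ − V₁)/|V₁| × 100, and
* the muscle force integral, the trapezoidal integral of |F| over the
  gait-cycle percentage grid — a per-stride force-impulse surrogate with
  units of force × percent.

The overall effect of a device configuration is the mean percentage change
of the muscle force integral across the lower-limb muscles, excluding the
foot-drop-affected dorsiflexors and any muscles tagged for exclusion
(e.g. lower-back muscles in richer muscle sets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EXCLUDED_GROUPS = ("dorsiflexor", "lower_back_excluded")


def percentage_change(v1: float, v2: float) -> float:
    """(V₂ − V₁)/|V₁| × 100; V₁ is the no-device baseline.

    The absolute value in the denominator preserves the sign of the raw
    difference even for negative baselines.  V₁ = 0 is undefined.
    """
    if v1 == 0:
        raise ValueError("percentage change undefined for zero baseline")
    return (v2 - v1) / abs(v1) * 100.0


def muscle_force_integral(force: np.ndarray,
                          percent: np.ndarray | None = None) -> float:
    """Trapezoidal integral of |F| over the gait-cycle percent grid."""
    f = np.abs(np.asarray(force, dtype=float))
    if f.ndim != 1 or f.size < 2:
        raise ValueError("need a 1-D series with at least 2 frames")
    x = np.linspace(0.0, 100.0, f.size) if percent is None \
        else np.asarray(percent, dtype=float)
    return float(np.trapezoid(f, x))


def normalize_to_body_mass(series, body_mass: float):
    """Divide a series (array or moment/force series object) by body mass.

    Series objects carry a ``normalized`` flag; normalizing twice is an
    error.
    """
    if hasattr(series, "normalize_to_body_mass"):
        return series.normalize_to_body_mass(body_mass)
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return np.asarray(series, dtype=float) / body_mass


def average_subjects(values: list):
    """Arithmetic mean across subjects of arrays or series objects.

    All inputs must share their grid; series objects must agree on their
    ``normalized`` state (averaging a mix of normalized and raw subject
    results would be meaningless).
    """
    if not values:
        raise ValueError("need at least one subject")
    first = values[0]
    if hasattr(first, "normalized"):
        states = {bool(v.normalized) for v in values}
        if len(states) > 1:
            raise ValueError("mixed normalization states across subjects")
    if hasattr(first, "moments"):   # JointMomentSeries
        from .inverse_dynamics import JointMomentSeries
        if any(v.n_frames != first.n_frames for v in values):
            raise ValueError("subject grids differ")
        return JointMomentSeries(
            {j: np.mean([v.moments[j] for v in values], axis=0)
             for j in first.moments},
            first.percent.copy(), normalized=first.normalized)
    if hasattr(first, "forces"):    # MuscleForceSeries
        from .static_optimization import MuscleForceSeries
        return MuscleForceSeries(
            list(first.muscle_names),
            np.mean([v.activations for v in values], axis=0),
            np.mean([v.forces for v in values], axis=0),
            np.mean([v.reserve for v in values], axis=0),
            first.percent.copy(),
            np.logical_and.reduce([v.feasible for v in values]),
            np.mean([v.deficit for v in values], axis=0),
            normalized=first.normalized)
    arrs = [np.asarray(v, dtype=float) for v in values]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("subject grids differ")
    return np.mean(arrs, axis=0)


def overall_effect(per_muscle_changes: dict, muscle_tags: dict) -> float:
    """Mean percentage change over the non-excluded muscles.

    ``per_muscle_changes`` maps muscle name → percentage change of its
    force integral; ``muscle_tags`` maps muscle name → group tags.
    Muscles tagged dorsiflexor (foot-drop-affected) or lower-back are
    excluded so the summary reflects the rest of the limb.
    """
    included = [c for name, c in per_muscle_changes.items()
                if not any(g in EXCLUDED_GROUPS
                           for g in muscle_tags.get(name, ()))]
    if not included:
        raise ValueError("no muscles remain after exclusion")
    return float(np.mean(included))


def subject_table_stats(table: pd.DataFrame, decimals: int | None = 2
                        ) -> pd.DataFrame:
    """Mean and sample (n−1) SD of each numeric column of a subject table."""
    if len(table) < 2:
        raise ValueError("need at least 2 subjects")
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("no numeric columns")
    stats = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    if decimals is not None:
        stats = stats.round(decimals)
    return stats
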