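"""Log transforms and the independent cortical-folding components K, I, S.

The universal scaling law of cortical folding, ``A_t * sqrt(T) ∝
A_e^(5/4)``, ties together total pial area ``A_t``, exposed (smoothed
hull) area ``A_e`` and average cortical thickness ``T``.  Writing
``x = log10 A_t``, ``y = log10 T^2``, ``z = log10 A_e``, three mutually
orthogonal linear combinations decompose hemispheric shape:

    K = x + y/4 - 5 z/4      (tension/offset term of the scaling law)
    I = x + y + z            (isometric size)
    S = 3 x/2 - 9 y/4 + 3 z/4  (residual shape/folding complexity)

Isometric rescaling (areas by λ², thickness by λ) shifts I by
``3·log10(λ²)`` and leaves K and S unchanged.  Note that thickness
enters as T² inside the log — the scaling-law variable — while the
input column is plain thickness in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import MorphometryTable

__all__ = ["KIS_COEFFICIENTS", "FoldingComponents", "compute_kis", "log_metrics",
           "folding_components_table"]

#: rows K, I, S; columns (log10 A_t, log10 T^2, log10 A_e)
KIS_COEFFICIENTS = np.array([
    [1.0, 0.25, -1.25],
    [1.0, 1.0, 1.0],
    [1.5, -2.25, 0.75],
])


@dataclass(frozen=True)
class FoldingComponents:
    K: float
    I: float
    S: float


def compute_kis(A_t, A_e, T) -> FoldingComponents:
    """Folding components from total pial area, exposed area, thickness.

    Parameters are in mm² (areas) and mm (thickness) and must be
    strictly positive.  ``A_t < A_e`` (a hemisphere less folded than its
    hull) is physically suspect and triggers a warning, not an error.
    Accepts scalars or aligned arrays.
    """
    A_t = np.asarray(A_t, dtype=float)
    A_e = np.asarray(A_e, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(A_t <= 0) or np.any(A_e <= 0) or np.any(T <= 0):
        raise ValueError("A_t, A_e and T must be strictly positive")
    if np.any(A_t < A_e):
        warnings.warn("total pial area below exposed area: cortex less folded than its hull",
                      stacklevel=2)
    logs = np.stack([np.log10(A_t), np.log10(T ** 2), np.log10(A_e)])
    k, i, s = KIS_COEFFICIENTS @ logs.reshape(3, -1)
    if np.ndim(A_t) == 0:
        return FoldingComponents(float(k[0]), float(i[0]), float(s[0]))
    shape = np.shape(A_t)
    return FoldingComponents(k.reshape(shape), i.reshape(shape), s.reshape(shape))


def folding_components_table(table: MorphometryTable) -> MorphometryTable:
    """Compute per-hemisphere K, I, S records from a folding table.

    Input must contain ``total_pial_area_mm2``, ``exposed_area_mm2`` and
    ``avg_thickness_mm`` at region ``"hemisphere"``; output holds three
    new records (metrics ``K``, ``I``, ``S``) per subject × hemisphere.
    """
    wide = table.select(region="hemisphere").pivot_table(
        index=["subject_id", "hemisphere"], columns="metric", values="value")
    needed = ["total_pial_area_mm2", "exposed_area_mm2", "avg_thickness_mm"]
    missing = [m for m in needed if m not in wide.columns]
    if missing:
        raise ValueError(f"folding metrics missing: {missing}")
    if wide[needed].isna().any().any():
        bad = wide[wide[needed].isna().any(axis=1)].index[:5].tolist()
        raise ValueError(f"incomplete folding measures for: {bad}")
    comp = compute_kis(wide["total_pial_area_mm2"].to_numpy(),
                       wide["exposed_area_mm2"].to_numpy(),
                       wide["avg_thickness_mm"].to_numpy())
    idx = wide.index.to_frame(index=False)
    frames = []
    for name, vals in (("K", comp.K), ("I", comp.I), ("S", comp.S)):
        frames.append(idx.assign(region="hemisphere", metric=name, value=np.asarray(vals)))
    return MorphometryTable(pd.concat(frames, ignore_index=True))


#: K, I and S are already log-scale linear combinations — never re-logged
_LOG_EXEMPT = ("K", "I", "S")


def log_metrics(table: MorphometryTable) -> MorphometryTable:
    """Replace values by log10(value); metric names gain a ``log10_`` prefix.

    K/I/S records pass through unchanged (they are log-derived already).
    Non-positive values are a domain error naming the offending
    subject/region.
    """
    data = table.data.copy()
    loggable = ~data["metric"].isin(_LOG_EXEMPT)
    bad = loggable & (data["value"] <= 0)
    if bad.any():
        row = data[bad].iloc[0]
        raise ValueError(f"non-positive value for subject {row['subject_id']!r}, "
                         f"region {row['region']!r}, metric {row['metric']!r}: {row['value']}")
    data.loc[loggable, "value"] = np.log10(data.loc[loggable, "value"])
    data.loc[loggable, "metric"] = "log10_" + data.loc[loggable, "metric"]
    return MorphometryTable(data)
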