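"""Residual-based outlier flagging and listwise exclusion.

Outliers are flagged per model (region × metric) when the model residual
sits more than ``k`` median absolute deviations from the median
(default k = 5, MAD scaled by the 1.4826 normal-consistency constant).
A subject flagged in *any* model is excluded from *all* models (listwise
deletion), so every normative fit shares one reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MAD_CONSISTENCY", "OutlierReport", "flag_outliers", "listwise_exclude", "qc_cohort"]

#: 1/Phi^-1(3/4): makes MAD a consistent estimator of the normal SD
MAD_CONSISTENCY = 1.4826


def flag_outliers(residuals, k: float = 5.0, consistency: float = MAD_CONSISTENCY) -> np.ndarray:
    """Boolean mask of residuals further than ``k`` (scaled) MADs from the median.

    Pass ``consistency=1.0`` for the raw-MAD reading of the threshold.
    A zero MAD (degenerate scale) flags nothing and warns.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals to estimate a robust scale")
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    if mad == 0:
        warnings.warn("MAD is zero (degenerate residual scale); no outliers flagged", stacklevel=2)
        return np.zeros(r.shape, dtype=bool)
    return np.abs(r - med) / (consistency * mad) > k


@dataclass
class OutlierReport:
    """Per-model outlier flags plus the listwise exclusion they imply."""

    flags: pd.DataFrame  # columns subject_id, region, hemisphere, metric, flagged
    threshold_mads: float = 5.0
    excluded_subjects: list = field(init=False)

    def __post_init__(self):
        f = self.flags
        self.excluded_subjects = sorted(f.loc[f["flagged"], "subject_id"].unique())

    @property
    def n_flagged_records(self) -> int:
        return int(self.flags["flagged"].sum())

    def to_csv(self, path) -> None:
        self.flags.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"QC outlier report (threshold {self.threshold_mads} MADs)",
                 f"records flagged: {self.n_flagged_records}",
                 f"subjects excluded listwise: {len(self.excluded_subjects)}"]
        lines += [f"  - {s}" for s in self.excluded_subjects[:50]]
        return "\n".join(lines)


def listwise_exclude(reports: list[OutlierReport]) -> list[str]:
    """Subjects retained after removing anyone flagged in any model.

    The subject universe is the union over reports; an all-flagged
    universe is a degenerate (empty training set) error.
    """
    universe: set[str] = set()
    flagged: set[str] = set()
    for rep in reports:
        universe |= set(rep.flags["subject_id"].unique())
        flagged |= set(rep.excluded_subjects)
    retained = sorted(universe - flagged)
    if universe and not retained:
        raise ValueError("empty training set: every subject flagged by QC")
    return retained


def qc_cohort(cohort, residual_fn, targets=None, k: float = 5.0,
              consistency: float = MAD_CONSISTENCY) -> OutlierReport:
    """Run MAD flagging over all (region, hemisphere, metric) targets.

    ``residual_fn(cohort, target)`` must return a DataFrame with columns
    ``subject_id`` and ``residual`` for one target; typically a thin
    wrapper around a fitted normative model's residuals.
    """
    targets = targets if targets is not None else cohort.morphometry.targets()
    frames = []
    for target in targets:
        res = residual_fn(cohort, target)
        region, hemisphere, metric = target
        mask = flag_outliers(res["residual"].to_numpy(), k=k, consistency=consistency)
        frames.append(pd.DataFrame({
            "subject_id": res["subject_id"].to_numpy(),
            "region": region, "hemisphere": hemisphere, "metric": metric,
            "flagged": mask,
        }))
    flags = pd.concat(frames, ignore_index=True)
    return OutlierReport(flags=flags, threshold_mads=k)
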