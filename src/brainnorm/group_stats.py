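"""Group-level abnormality summaries and individual lateralisation.

Two summary modes per region × metric:

* ``case_control`` — Cohen's d between patient and control z-scores
  (pooled SD), the classic two-sample comparison;
* ``normative`` — the one-sample standardised mean of patient z-scores
  against the normative reference (mean 0 by construction), usable when
  no matched control group exists.

Lateralisation uses the left-minus-right z difference per subject:
the predicted onset side is the hemisphere that is more abnormal given
the metric's abnormal direction (e.g. atrophy: lower is abnormal), and
subjects are additionally flagged when their difference falls outside
2 SDs of the control difference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["cohens_d", "group_abnormality", "lateralize", "effectsize_correlation",
           "LateralityResult"]


def cohens_d(z_a, z_b) -> float:
    """Two-sample Cohen's d = (mean_a - mean_b) / pooled SD."""
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def _one_sample_d(z) -> float:
    z = np.asarray(z, dtype=float)
    s = z.std(ddof=1)
    if s <= 0:
        if z.mean() == 0:  # all-zero z: no deviation in any direction
            return 0.0
        raise ValueError("zero standard deviation in patient z-scores")
    return float(z.mean() / s)


def group_abnormality(scores: pd.DataFrame, meta: pd.DataFrame,
                      mode: str = "case_control") -> pd.DataFrame:
    """Per-region effect sizes from a score table.

    Parameters
    ----------
    scores : DataFrame
        Tidy score table with subject_id, region, hemisphere, metric, z.
    meta : DataFrame
        Metadata with subject_id and group.
    mode : {"case_control", "normative"}
        case_control: Cohen's d patients vs controls; normative:
        one-sample standardised mean of patient z (reference mean 0).

    Returns one row per (region, hemisphere, metric) with d, group mean
    z's and n's.
    """
    if mode not in ("case_control", "normative"):
        raise ValueError(f"unknown mode {mode!r}")
    merged = scores.merge(meta[["subject_id", "group"]], on="subject_id").dropna(subset=["z"])
    rows = []
    for (region, hemi, metric), g in merged.groupby(["region", "hemisphere", "metric"]):
        pat = g.loc[g["group"] != "control", "z"].to_numpy()
        ctl = g.loc[g["group"] == "control", "z"].to_numpy()
        if len(pat) == 0:
            raise ValueError(f"no patients for ({region}, {hemi}, {metric})")
        if mode == "case_control":
            if len(ctl) == 0:
                raise ValueError("case_control mode requires a control group in the scores")
            d = cohens_d(pat, ctl)
        else:
            d = _one_sample_d(pat)
        rows.append({
            "region": region, "hemisphere": hemi, "metric": metric, "d": d,
            "mean_z_patients": float(pat.mean()),
            "mean_z_controls": float(ctl.mean()) if len(ctl) else np.nan,
            "n_patients": len(pat), "n_controls": len(ctl), "mode": mode,
        })
    return pd.DataFrame(rows)


@dataclass
class LateralityResult:
    """Per-subject laterality calls plus the cohort-level confusion matrix."""

    table: pd.DataFrame  # subject_id, delta_z, predicted_side, exceeds_2sd [, true_side]
    confusion: pd.DataFrame | None
    accuracy: float | None

    def summary(self) -> str:
        lines = [f"laterality: {len(self.table)} subjects, "
                 f"{int(self.table['exceeds_2sd'].sum())} beyond 2 control SDs"]
        if self.confusion is not None:
            lines.append(str(self.confusion))
            lines.append(f"accuracy: {self.accuracy:.3f}")
        return "\n".join(lines)


def lateralize(scores_left: pd.Series, scores_right: pd.Series,
               control_delta, direction: str = "lower_abnormal",
               true_side: pd.Series | None = None) -> LateralityResult:
    """Hemispheric lateralisation from left/right z-scores per subject.

    ``scores_left``/``scores_right`` are z-scores indexed by subject_id;
    ``control_delta`` the left-minus-right differences of controls
    (n >= 10) defining the normal asymmetry band.  ``direction`` states
    which tail is abnormal for this metric ("lower_abnormal" for
    atrophy-like metrics: a more negative hemisphere is the affected
    one).  When ``true_side`` labels ("left"/"right") are supplied, a
    confusion matrix and accuracy over determinate calls are returned.
    """
    if direction not in ("lower_abnormal", "higher_abnormal"):
        raise ValueError(f"unknown direction {direction!r}")
    left = pd.Series(scores_left)
    right = pd.Series(scores_right)
    if not left.index.equals(right.index):
        if set(left.index) != set(right.index):
            raise ValueError("left/right score tables hold different subjects")
        right = right.reindex(left.index)
    ctrl = np.asarray(control_delta, dtype=float)
    if len(ctrl) < 10:
        raise ValueError("need at least 10 control delta-z values")
    delta = left - right  # left - right convention throughout
    if direction == "lower_abnormal":
        side = np.where(delta < 0, "left", np.where(delta > 0, "right", "indeterminate"))
    else:
        side = np.where(delta > 0, "left", np.where(delta < 0, "right", "indeterminate"))
    exceeds = np.abs(delta - ctrl.mean()) > 2.0 * ctrl.std(ddof=1)
    table = pd.DataFrame({"subject_id": left.index, "delta_z": delta.to_numpy(),
                          "predicted_side": side, "exceeds_2sd": exceeds.to_numpy()})
    confusion = accuracy = None
    if true_side is not None:
        truth = pd.Series(true_side).reindex(left.index)
        table["true_side"] = truth.to_numpy()
        det = table[table["predicted_side"] != "indeterminate"]
        confusion = pd.crosstab(det["true_side"], det["predicted_side"],
                                rownames=["true"], colnames=["predicted"])
        accuracy = float((det["predicted_side"] == det["true_side"]).mean()) if len(det) else np.nan
    return LateralityResult(table=table, confusion=confusion, accuracy=accuracy)


def effectsize_correlation(d_1, d_2) -> float:
    """Pearson correlation between two aligned per-region effect-size maps."""
    a = np.asarray(d_1, dtype=float)
    b = np.asarray(d_2, dtype=float)
    if len(a) != len(b):
        raise ValueError("effect-size vectors must be aligned")
    if len(a) < 3:
        raise ValueError("need at least 3 regions")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in effect sizes")
    return float(np.corrcoef(a, b)[0, 1])
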