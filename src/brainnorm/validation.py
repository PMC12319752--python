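"""End-to-end validation experiments on synthetic cohorts.

These routines run the full pipeline — simulate, log-transform, fit,
harmonise, score — against the generator's known ground truth and
return the quantities that certify the method: z-score calibration and
centile coverage on a held-out site, recovery of generating age, sex
and site effects with their standard errors, and recovery of injected
disease effect sizes and lateralisation.  Both the test suite and the
reproduction script drive the pipeline through these entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gamlss_engine import FitConfig, ModelSet, fit_normative
from .group_stats import group_abnormality, lateralize
from .io_tables import Cohort
from .morphometrics import log_metrics
from .scoring import score_cohort
from .synthetic_cohorts import DiseaseSpec, SimConfig, inject_disease, simulate_cohort

__all__ = ["log_cohort", "calibration_experiment", "recovery_experiment",
           "disease_recovery_experiment", "laterality_experiment", "age_slope"]

TARGET = ("precentral", "left", "log10_thickness_mm")


def log_cohort(cohort: Cohort) -> Cohort:
    """Apply the pipeline's log10 transform to a cohort's morphometry."""
    return Cohort(log_metrics(cohort.morphometry), cohort.meta, dict(cohort.join_report))


def _small_config(seed: int, **kw) -> SimConfig:
    base = dict(regions=("precentral",), metrics=("thickness_mm",),
                include_folding=False, seed=seed)
    base.update(kw)
    return SimConfig(**base)


def age_slope(result, age_lo: float = 10.0, age_hi: float = 90.0,
              sex: str = "female") -> tuple[float, float]:
    """Average slope of the fitted mean curve and its standard error.

    The slope is the linear functional (mu(age_hi) - mu(age_lo)) /
    (age_hi - age_lo) at population site effect; its SE comes from the
    mu submodel's posterior covariance.
    """
    sub = result.submodels["mu"]
    male = 1.0 if sex == "male" else 0.0
    X = sub.design(np.array([age_lo, age_hi]), np.array([male, male]),
                   site=None, site_mode="population")
    c = (X[1] - X[0]) / (age_hi - age_lo)
    slope = float(c @ sub.coef)
    se = float(np.sqrt(c @ sub.cov @ c))
    return slope, se


def calibration_experiment(seed: int, n_train: int = 2000, n_heldout: int = 2000,
                           n_train_sites: int = 5) -> dict:
    """Simulate -> fit -> harmonise/score one held-out site.

    One cohort is drawn with ``n_train_sites + 1`` sites; the last site
    is withheld from training and scored as an unseen site (its own
    controls provide the harmonisation offset and SD, mirroring how an
    uploaded dataset is treated).  Returns held-out z mean/SD and the
    empirical coverage of the 5/10/50/90/95 centiles.
    """
    n_total = n_train + n_heldout
    p_held = n_heldout / n_total
    probs = tuple([(1 - p_held) / n_train_sites] * n_train_sites + [p_held])
    cohort, truth = simulate_cohort(_small_config(
        seed, n_subjects=n_total, n_sites=n_train_sites + 1, site_probs=probs))
    cohort = log_cohort(cohort)
    heldout_site = f"{truth.config.site_prefix}{n_train_sites + 1:02d}"
    train = cohort.subset(cohort.meta.loc[cohort.meta["site"] != heldout_site, "subject_id"])
    held = cohort.subset(cohort.meta.loc[cohort.meta["site"] == heldout_site, "subject_id"])

    res = fit_normative(train, TARGET, FitConfig())
    mset = ModelSet(models={ModelSet.key(TARGET): res},
                    training_summary={"targets": [list(TARGET)]})
    scores = score_cohort(mset, held)
    z = scores["z"].to_numpy()
    cent = scores["centile"].to_numpy()
    coverage = {c: float(np.mean(cent <= c)) for c in (5, 10, 50, 90, 95)}
    return {
        "n_heldout": len(z),
        "z_mean": float(z.mean()),
        "z_sd": float(z.std(ddof=1)),
        "centile_coverage": coverage,
        "converged": res.converged,
        "r2": res.r2_train,
    }


LINEAR_SLOPE = -0.002  # generating age slope (log10 units / year)


def recovery_experiment(seed: int, n_reps: int = 50, n: int = 2000,
                        n_sites: int = 5) -> dict:
    """Coverage of generating effects by +-2 SE intervals over replicates.

    Each replicate simulates a cohort with a linear age trend
    (slope -0.002 log10/year), a sex offset and normal site intercepts,
    fits the normative model, and checks whether the fitted age slope,
    sex coefficient and (centred) site effects fall within two standard
    errors of the generating values.  Site effects are compared after
    centring both sides because the intercept absorbs the mean site
    offset.  Returns the per-effect coverage fractions.
    """
    rng = np.random.default_rng(seed)
    linear_points = ((5.0, 0.0), (95.0, LINEAR_SLOPE * 90.0))
    hits = {"age_slope": 0, "sex": 0, "site": 0}
    trials = {"age_slope": 0, "sex": 0, "site": 0}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort, truth = simulate_cohort(_small_config(
            rep_seed, n_subjects=n, n_sites=n_sites,
            age_curve_points=linear_points, age_curve_scale=1.0))
        cohort = log_cohort(cohort)
        res = fit_normative(cohort, TARGET, FitConfig())

        slope, se = age_slope(res)
        trials["age_slope"] += 1
        hits["age_slope"] += int(abs(slope - LINEAR_SLOPE) <= 2 * se)

        sub = res.submodels["mu"]
        names = sub.colnames
        if "sex[male]" in names:
            j = names.index("sex[male]")
            se_sex = float(np.sqrt(sub.cov[j, j]))
            trials["sex"] += 1
            hits["sex"] += int(abs(sub.coef[j] - truth.config.sex_effect) <= 2 * se_sex)

        eff = sub.site_effects()
        b = np.array([eff[s] for s in sub.site_levels])
        true_off = np.array([truth.site_offsets[s] for s in sub.site_levels])
        sl = sub.slices()["site"]
        se_site = np.sqrt(np.diag(sub.cov)[sl])
        b_c = b - b.mean()
        t_c = true_off - true_off.mean()
        trials["site"] += len(b)
        hits["site"] += int(np.sum(np.abs(b_c - t_c) <= 2 * se_site))
    return {k: hits[k] / trials[k] for k in hits} | {"n_reps": n_reps}


def disease_recovery_experiment(seed: int, effect_size: float = -0.8,
                                n_patients: int = 200, n_controls: int = 2000,
                                regions: tuple = ("precentral", "superiorfrontal")) -> dict:
    """Inject a bilateral effect, run the pipeline, recover Cohen's d.

    Patients are carved out of a simulated multi-site cohort, their
    targeted regions shifted by ``effect_size`` control SDs; the models
    are trained on the remaining controls and everyone is scored.
    Returns normative- and case-control-mode d per targeted region.
    """
    cohort, truth = simulate_cohort(SimConfig(
        n_subjects=n_controls + n_patients, n_sites=5, regions=regions,
        metrics=("thickness_mm",), include_folding=False, seed=seed))
    spec = DiseaseSpec(regions=regions, metric="thickness_mm",
                       effect_size=effect_size, laterality="bilateral",
                       n_patients=n_patients, seed=seed + 1)
    cohort, truth = inject_disease(cohort, spec, truth)
    cohort = log_cohort(cohort)

    targets = [(r, h, "log10_thickness_mm") for r in regions for h in ("left", "right")]
    train = cohort.controls()
    mset = ModelSet.fit(train, targets=targets, config=FitConfig())
    scores = score_cohort(mset, cohort, targets=targets)
    norm = group_abnormality(scores[scores["subject_id"].isin(truth.patient_ids)]
                             .assign(), cohort.meta, mode="normative")
    cc = group_abnormality(scores, cohort.meta, mode="case_control")
    return {
        "effect_size": effect_size,
        "d_normative": dict(zip(map(tuple, norm[["region", "hemisphere"]].to_numpy()),
                                norm["d"])),
        "d_case_control": dict(zip(map(tuple, cc[["region", "hemisphere"]].to_numpy()),
                                   cc["d"])),
    }


def laterality_experiment(seed: int, asymmetry_sd: float = -1.5,
                          n_per_side: int = 100, n_controls: int = 2000,
                          region: str = "precentral") -> dict:
    """Left- and right-onset synthetic patients classified by delta-z.

    Injects a one-sided thickness reduction of ``|asymmetry_sd|``
    control SDs into two patient groups (left- and right-lateralised),
    scores everyone, and classifies onset side from the left-minus-right
    z difference (lower = abnormal).  Also reports the 2-control-SD
    exceedance rate among controls themselves (two-tail normal: ~4.6%).
    """
    n_total = n_controls + 2 * n_per_side
    cohort, truth = simulate_cohort(SimConfig(
        n_subjects=n_total, n_sites=5, regions=(region,),
        metrics=("thickness_mm",), include_folding=False, seed=seed))
    left_spec = DiseaseSpec(regions=(region,), metric="thickness_mm",
                            effect_size=asymmetry_sd, laterality="left",
                            n_patients=n_per_side, label="patient_left", seed=seed + 1)
    cohort, truth = inject_disease(cohort, left_spec, truth)
    right_spec = DiseaseSpec(regions=(region,), metric="thickness_mm",
                             effect_size=asymmetry_sd, laterality="right",
                             n_patients=n_per_side, label="patient_right", seed=seed + 2)
    cohort, truth2 = inject_disease(cohort, right_spec, truth)
    cohort = log_cohort(cohort)

    targets = [(region, h, "log10_thickness_mm") for h in ("left", "right")]
    mset = ModelSet.fit(cohort.controls(), targets=targets, config=FitConfig())
    scores = score_cohort(mset, cohort, targets=targets)
    wide = scores.pivot_table(index="subject_id", columns="hemisphere", values="z")
    meta = cohort.meta.set_index("subject_id")
    ctrl_ids = meta.index[meta["group"] == "control"]
    ctrl_delta = (wide.loc[ctrl_ids, "left"] - wide.loc[ctrl_ids, "right"]).to_numpy()

    pat = meta.index[meta["group"] != "control"]
    truth_side = meta.loc[pat, "group"].map(
        {"patient_left": "left", "patient_right": "right"})
    res = lateralize(wide.loc[pat, "left"], wide.loc[pat, "right"], ctrl_delta,
                     direction="lower_abnormal", true_side=truth_side)
    ctrl_res = lateralize(wide.loc[ctrl_ids, "left"], wide.loc[ctrl_ids, "right"],
                          ctrl_delta, direction="lower_abnormal")
    exceed_pat = float(res.table["exceeds_2sd"].mean())
    return {
        "accuracy": res.accuracy,
        "n_patients": len(pat),
        "control_exceed_2sd_rate": float(ctrl_res.table["exceeds_2sd"].mean()),
        "patient_exceed_2sd_rate": exceed_pat,
        "confusion": res.confusion,
    }
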