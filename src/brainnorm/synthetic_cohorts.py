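"""Seeded multi-site morphometry cohort generator with known ground truth.

Emulates the statistical structure the normative models assume: on the
log10 scale each region × hemisphere × metric value is

    y = base + age_curve(age) + sex_effect · 1[male] + site_offset
        + subject_offset + site_scale · noise(sigma, nu, tau)

with uniform ages, balanced sex, equal-probability site assignment, a
normal random site intercept (shared across regions, as a scanner shift
would be), a multiplicative site scale perturbation acting on the
measurement noise, a per-subject biological offset shared across all of
that subject's measures (which makes left/right values of one subject
correlated, as they are in real cohorts), and sinh-arcsinh measurement
noise (Gaussian at nu = 0, tau = 1).  The default age curve is a
monotone-decreasing piecewise cubic with knots at 20 and 65 — steeper
decline in early and late life, the shape typical of cortical thickness
trajectories.  Values are stored as raw metrics (mm/mm²/mm³), i.e.
``10**y``, so the pipeline's own log transform is exercised.

Disease effects are injected afterwards by shifting selected regions by
a stated number of control SDs, optionally lateralised, which emulates
patient cohorts with regional or one-sided atrophy.

The generator can also write the three input dialects (aparcstats2table
morphometry, folding-toolbox hemisphere table, metadata CSV) so the
readers are testable without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io_tables import DK_REGIONS, Cohort, MorphometryTable

__all__ = ["SimConfig", "DiseaseSpec", "GroundTruth", "simulate_cohort",
           "inject_disease", "write_input_files", "AGE_CURVE_POINTS"]

#: (age, log10 offset) control points of the default lifespan trajectory:
#: steep early decline, plateau-ish midlife, steeper late decline
AGE_CURVE_POINTS = ((5.0, 0.012), (20.0, 0.0), (65.0, -0.012), (95.0, -0.045))

#: typical raw magnitudes per metric used for the per-region base levels
_BASE_LOG10 = {
    "thickness_mm": (np.log10(2.5), 0.03),
    "volume_mm3": (np.log10(9000.0), 0.25),
    "area_mm2": (np.log10(2500.0), 0.25),
}

_FOLDING_BASE_LOG10 = {
    "total_pial_area_mm2": np.log10(9.0e4),
    "exposed_area_mm2": np.log10(4.0e4),
    "avg_thickness_mm": np.log10(2.5),
}


@dataclass
class SimConfig:
    """Generating parameters; every field is ground truth for tests.

    Units: all effect sizes and SDs for region values are on the log10
    scale (0.01 log10 units is about 2.3% of the raw value).
    """

    n_subjects: int = 2000
    n_sites: int = 5
    site_offset_sd: float = 0.01
    site_scale_sd: float = 0.10  # SD of log multiplicative scale factor
    age_range: tuple = (5.0, 95.0)
    sex_effect: float = -0.004  # male minus female, log10 units
    age_curve_points: tuple = AGE_CURVE_POINTS
    age_curve_scale: float = 1.0
    sigma: float = 0.015
    subject_offset_sd: float = 0.015  # biological offset shared across measures
    sigma_age_slope: float = 0.0  # optional linear trend of sigma in age
    site_probs: tuple | None = None
    nu: float = 0.0
    tau: float = 1.0
    regions: tuple = DK_REGIONS
    metrics: tuple = ("thickness_mm",)
    include_folding: bool = True
    site_prefix: str = "site"
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("invalid config field n_subjects: must be >= 1")
        if self.n_sites < 1:
            raise ValueError("invalid config field n_sites: must be >= 1")
        for name in ("site_offset_sd", "site_scale_sd", "sigma", "subject_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if self.tau <= 0:
            raise ValueError("invalid config field tau: must be > 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("invalid config field age_range")
        if self.seed is None:
            raise ValueError("invalid config field seed: mandatory")
        if self.site_probs is not None and len(self.site_probs) != self.n_sites:
            raise ValueError("invalid config field site_probs: length must equal n_sites")
        unknown = set(self.regions) - set(DK_REGIONS)
        if unknown:
            raise ValueError(f"invalid config field regions: unknown {sorted(unknown)}")


@dataclass
class DiseaseSpec:
    """Injected disease effect: which regions, how strong, which side."""

    regions: tuple
    metric: str = "thickness_mm"
    effect_size: float = -0.8  # in control-SD units
    laterality: str = "bilateral"  # left | right | bilateral
    n_patients: int = 100
    label: str = "patient"
    control_sd: float | None = None  # log10 units; default: generating sigma
    seed: int = 1

    def validate(self, cohort_regions):
        unknown = set(self.regions) - set(cohort_regions) - {"hemisphere"}
        if unknown:
            raise ValueError(f"disease effect on unknown region(s): {sorted(unknown)}")
        if self.laterality not in ("left", "right", "bilateral"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass
class GroundTruth:
    """Every generating parameter, for oracle-style assertions."""

    config: SimConfig
    site_offsets: dict
    site_scales: dict
    base_log10: dict  # (region, hemisphere, metric) -> base value
    disease: DiseaseSpec | None = None
    patient_ids: list = field(default_factory=list)

    def age_curve(self, age):
        pts = np.asarray(self.config.age_curve_points)
        f = PchipInterpolator(pts[:, 0], pts[:, 1] * self.config.age_curve_scale)
        return f(np.clip(age, pts[0, 0], pts[-1, 0]))

    def sigma_at(self, age):
        return self.config.sigma + self.config.sigma_age_slope * (np.asarray(age, dtype=float)
                                                                  - self.config.age_range[0])

    def control_sd(self, site: str) -> float:
        """Total residual SD (log10) for one site: biological + scaled noise."""
        c = self.config
        return float(np.sqrt(c.subject_offset_sd ** 2
                             + (self.site_scales[site] * c.sigma) ** 2))

    def deterministic_log10(self, age, sex, site, region, hemisphere, metric):
        """Noise-free log10 value for given covariates."""
        male = 1.0 if str(sex).lower() in ("male", "m", "1") else 0.0
        return (self.base_log10[(region, hemisphere, metric)]
                + float(self.age_curve(age))
                + self.config.sex_effect * male
                + self.site_offsets[site])


def _shash_noise(rng, size, nu, tau):
    z = rng.standard_normal(size)
    if nu == 0.0 and tau == 1.0:
        return z
    return np.sinh((np.arcsinh(z) + nu) / tau)


def simulate_cohort(config: SimConfig | None = None, **overrides):
    """Draw a multi-site control cohort.

    Returns ``(cohort, truth)`` where ``truth`` is a :class:`GroundTruth`
    recording every generating parameter.  Keyword overrides are applied
    to a default :class:`SimConfig`.
    """
    config = replace(config or SimConfig(), **overrides) if overrides else (config or SimConfig())
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_subjects
    ids = [f"sub-{i:05d}" for i in range(1, n + 1)]
    age = rng.uniform(*config.age_range, size=n)
    sex = np.where(np.arange(n) % 2 == 0, "female", "male")
    rng.shuffle(sex)
    sites = [f"{config.site_prefix}{j + 1:02d}" for j in range(config.n_sites)]
    site = rng.choice(sites, size=n, p=config.site_probs)

    site_offsets = dict(zip(sites, rng.normal(0.0, config.site_offset_sd, config.n_sites)))
    site_scales = dict(zip(sites, np.exp(rng.normal(0.0, config.site_scale_sd, config.n_sites))))

    meta = pd.DataFrame({
        "subject_id": ids, "age": age, "sex": sex, "group": "control",
        "dataset": "synthetic", "site": site, "session": "ses-01",
    })

    truth = GroundTruth(config=config, site_offsets=site_offsets,
                        site_scales=site_scales, base_log10={})
    curve = truth.age_curve(age)
    male = (sex == "male").astype(float)
    off = np.array([site_offsets[s] for s in site])
    scl = np.array([site_scales[s] for s in site])
    sigma_i = truth.sigma_at(age)
    subj_off = rng.normal(0.0, config.subject_offset_sd, n)

    frames = []
    targets = [(r, h, m) for m in config.metrics for h in ("left", "right")
               for r in config.regions]
    for region, hemi, metric in targets:
        base_mu, base_spread = _BASE_LOG10[metric]
        base = base_mu + rng.normal(0.0, base_spread)
        truth.base_log10[(region, hemi, metric)] = base
        noise = _shash_noise(rng, n, config.nu, config.tau)
        y = base + curve + config.sex_effect * male + off + subj_off + scl * sigma_i * noise
        frames.append(pd.DataFrame({
            "subject_id": ids, "hemisphere": hemi, "region": region,
            "metric": metric, "value": np.power(10.0, y),
        }))

    if config.include_folding:
        for hemi in ("left", "right"):
            for metric, base in _FOLDING_BASE_LOG10.items():
                truth.base_log10[("hemisphere", hemi, metric)] = base
                noise = _shash_noise(rng, n, config.nu, config.tau)
                y = base + curve + config.sex_effect * male + off + subj_off + scl * sigma_i * noise
                frames.append(pd.DataFrame({
                    "subject_id": ids, "hemisphere": hemi, "region": "hemisphere",
                    "metric": metric, "value": np.power(10.0, y),
                }))

    morph = MorphometryTable(pd.concat(frames, ignore_index=True))
    return Cohort(morph, meta), truth


def inject_disease(cohort: Cohort, spec: DiseaseSpec,
                   truth: GroundTruth | None = None):
    """Relabel a patient subgroup and shift their targeted regions.

    The shift is ``effect_size × control_sd`` applied on the log10 scale
    to the targeted region × hemisphere values; ``control_sd`` defaults
    to the generating noise SD when ``truth`` is supplied, else to the
    empirical log10 SD among controls per target.  Returns a new cohort
    (input untouched) and the updated ground truth.
    """
    regions_present = set(cohort.morphometry.data["region"].unique())
    spec.validate(regions_present)
    rng = np.random.default_rng(spec.seed)
    controls = cohort.meta.loc[cohort.meta["group"] == "control", "subject_id"].to_numpy()
    if spec.n_patients > len(controls):
        raise ValueError("n_patients exceeds available control subjects")
    patients = sorted(rng.choice(controls, size=spec.n_patients, replace=False))

    meta = cohort.meta.copy()
    meta.loc[meta["subject_id"].isin(patients), "group"] = spec.label
    data = cohort.morphometry.data.copy()

    site_of = meta.set_index("subject_id")["site"]
    hemis = {"left": ("left",), "right": ("right",), "bilateral": ("left", "right")}[spec.laterality]
    for region in spec.regions:
        for hemi in hemis:
            mask = (data["subject_id"].isin(patients) & (data["region"] == region)
                    & (data["hemisphere"] == hemi) & (data["metric"] == spec.metric))
            if not mask.any():
                raise ValueError(f"no records for ({region}, {hemi}, {spec.metric})")
            if spec.control_sd is not None:
                sd = np.full(int(mask.sum()), spec.control_sd)
            elif truth is not None:
                # control SD of each patient's own site: the scale their z is in
                sd = np.array([truth.control_sd(site_of[s])
                               for s in data.loc[mask, "subject_id"]])
            else:
                ctrl_mask = (~data["subject_id"].isin(patients) & (data["region"] == region)
                             & (data["hemisphere"] == hemi) & (data["metric"] == spec.metric))
                sd = np.full(int(mask.sum()),
                             float(np.log10(data.loc[ctrl_mask, "value"]).std(ddof=1)))
            shift = spec.effect_size * sd
            data.loc[mask, "value"] = np.power(10.0, np.log10(data.loc[mask, "value"]) + shift)

    out = Cohort(MorphometryTable(data), meta)
    if truth is not None:
        truth = replace(truth, disease=spec, patient_ids=list(patients))
    return out, truth


# ---- input-dialect writers -------------------------------------------


def write_input_files(cohort: Cohort, outdir, delimiter: str = ",") -> dict:
    """Write aparc-dialect tables (per hemisphere × metric), the folding
    table and the metadata CSV into ``outdir``; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    sep = delimiter
    data = cohort.morphometry.data
    hemi_code = {"left": "lh", "right": "rh"}
    metric_token = {"thickness_mm": "thickness", "volume_mm3": "volume", "area_mm2": "area"}

    for (hemi, metric), sub in data[data["region"] != "hemisphere"].groupby(["hemisphere", "metric"]):
        token = metric_token.get(metric, metric)
        code = hemi_code[hemi]
        wide = sub.pivot(index="subject_id", columns="region", values="value")
        wide.columns = [f"{code}_{r}_{token}" for r in wide.columns]
        wide.index.name = f"{code}.aparc.{token}"
        path = os.path.join(outdir, f"aparc_{code}_{token}.csv")
        wide.to_csv(path, sep=sep)
        paths[f"aparc_{code}_{token}"] = path

    folding = data[data["region"] == "hemisphere"]
    if not folding.empty:
        wide = folding.pivot_table(index=["subject_id", "hemisphere"],
                                   columns="metric", values="value").reset_index()
        wide = wide.rename(columns={"total_pial_area_mm2": "total_pial_area",
                                    "exposed_area_mm2": "exposed_area",
                                    "avg_thickness_mm": "avg_thickness"})
        path = os.path.join(outdir, "folding.csv")
        wide.to_csv(path, sep=sep, index=False)
        paths["folding"] = path

    meta_path = os.path.join(outdir, "metadata.csv")
    cohort.meta.to_csv(meta_path, sep=sep, index=False)
    paths["metadata"] = meta_path
    return paths
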