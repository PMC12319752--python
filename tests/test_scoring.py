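"""Unseen-site harmonisation, z-scores, centiles and the 30-HC SD rule."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainnorm.io_tables import Cohort, MorphometryTable
from brainnorm.scoring import (HC_SD_THRESHOLD, estimate_site_adjustment,
                               compute_centiles, compute_zscores,
                               sd_rule_probability)
from brainnorm.validation import TARGET


def _new_site_cohort(res, cohort, n, shift=0.0, site="newsite", rng=None,
                     group="control", values=None):
    """Subjects whose values follow the reference-site prediction + shift."""
    rng = rng or np.random.default_rng(0)
    age = rng.uniform(10, 90, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = res.predict_params(age, sex, site_mode="reference")
    if values is None:
        values = p.mu + p.sigma * rng.standard_normal(n) + shift
    ids = [f"new{i:04d}" for i in range(n)]
    region, hemi, metric = TARGET
    morph = MorphometryTable(pd.DataFrame({
        "subject_id": ids, "hemisphere": hemi, "region": region,
        "metric": metric, "value": values}))
    meta = pd.DataFrame({"subject_id": ids, "age": age, "sex": sex,
                         "group": group, "dataset": "new", "site": site,
                         "session": "ses-01"})
    return Cohort(morph, meta)


def test_offset_recovers_known_shift(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=200, shift=0.10)
    adj = estimate_site_adjustment(res, new, TARGET)
    assert adj.offset == pytest.approx(0.10, abs=0.01)
    assert adj.sd_source == "unseen_hc" and adj.n_hc == 200


def test_thirty_hc_rule_boundary(fitted):
    res, cohort, _ = fitted
    adj29 = estimate_site_adjustment(res, _new_site_cohort(res, cohort, 29), TARGET)
    adj30 = estimate_site_adjustment(res, _new_site_cohort(res, cohort, 30), TARGET)
    assert adj29.sd_source == "normative_average"
    assert adj30.sd_source == "unseen_hc"
    # normative average = unweighted mean of per-site training residual SDs
    assert adj29.sd == pytest.approx(np.mean(list(res.per_site_residual_sd.values())))
    assert HC_SD_THRESHOLD == 30


def test_adjustment_requires_controls_from_one_site(fitted):
    res, cohort, _ = fitted
    patients = _new_site_cohort(res, cohort, 20, group="patient_x")
    with pytest.raises(ValueError, match="controls only"):
        estimate_site_adjustment(res, patients, TARGET)
    empty = patients.subset([])
    with pytest.raises(ValueError, match="healthy controls required"):
        estimate_site_adjustment(res, empty, TARGET)


def test_z_is_zero_at_adjusted_mean_and_one_at_plus_sd(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=100, shift=0.05)
    adj = estimate_site_adjustment(res, new, TARGET)
    # craft two subjects exactly at the adjusted mean and mean + sd
    probe = _new_site_cohort(res, cohort, n=2, rng=np.random.default_rng(1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = res.predict_params(probe.meta["age"].to_numpy(),
                               probe.meta["sex"].to_numpy(), site_mode="reference")
    vals = np.array([p.mu[0] + adj.offset, p.mu[1] + adj.offset + adj.sd])
    probe.morphometry.data["value"] = vals
    z = compute_zscores(res, adj, probe, TARGET)["z"].to_numpy()
    assert z[0] == pytest.approx(0.0, abs=1e-10)
    assert z[1] == pytest.approx(1.0, abs=1e-10)


def test_heldout_hc_z_calibrated(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=500, shift=0.03,
                           rng=np.random.default_rng(7))
    adj = estimate_site_adjustment(res, new, TARGET)
    z = compute_zscores(res, adj, new, TARGET)["z"].to_numpy()
    assert abs(z.mean()) < 0.05
    assert abs(z.std(ddof=1) - 1.0) < 0.05


def test_offset_equivariance_and_z_invariance(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=120, rng=np.random.default_rng(3))
    adj = estimate_site_adjustment(res, new, TARGET)
    z = compute_zscores(res, adj, new, TARGET)["z"].to_numpy()
    shifted = Cohort(MorphometryTable(new.morphometry.data.assign(
        value=new.morphometry.data["value"] + 0.25)), new.meta)
    adj2 = estimate_site_adjustment(res, shifted, TARGET)
    z2 = compute_zscores(res, adj2, shifted, TARGET)["z"].to_numpy()
    assert adj2.offset - adj.offset == pytest.approx(0.25, abs=1e-12)
    np.testing.assert_allclose(z2, z, atol=1e-12)


def test_centile_of_z_one_is_8413_for_gaussian_family(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=100, rng=np.random.default_rng(5))
    adj = estimate_site_adjustment(res, new, TARGET)
    # force the symmetric Gaussian reduction for the oracle comparison
    res_g = res
    nu_sub = res_g.submodels["nu"]
    tau_sub = res_g.submodels["tau"]
    saved = (nu_sub.coef.copy(), tau_sub.coef.copy())
    nu_sub.coef[:] = 0.0
    tau_sub.coef[:] = 0.0
    try:
        probe = _new_site_cohort(res, cohort, n=1, rng=np.random.default_rng(2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = res.predict_params(probe.meta["age"].to_numpy(),
                                   probe.meta["sex"].to_numpy(), site_mode="reference")
        probe.morphometry.data["value"] = p.mu + adj.offset + adj.sd
        cent = compute_centiles(res_g, adj, probe, TARGET)["centile"].iloc[0]
        assert cent == pytest.approx(100 * stats.norm.cdf(1.0), abs=1e-6)
    finally:
        nu_sub.coef[:], tau_sub.coef[:] = saved


def test_centile_median_at_adjusted_mean_when_symmetric(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=60, rng=np.random.default_rng(9))
    adj = estimate_site_adjustment(res, new, TARGET)
    saved = res.submodels["nu"].coef.copy()
    res.submodels["nu"].coef[:] = 0.0
    try:
        probe = _new_site_cohort(res, cohort, n=1, rng=np.random.default_rng(4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = res.predict_params(probe.meta["age"].to_numpy(),
                                   probe.meta["sex"].to_numpy(), site_mode="reference")
        probe.morphometry.data["value"] = p.mu + adj.offset
        cent = compute_centiles(res, adj, probe, TARGET)["centile"].iloc[0]
        assert cent == pytest.approx(50.0, abs=1e-6)
    finally:
        res.submodels["nu"].coef[:] = saved


def test_z_and_centile_rank_identically(fitted):
    res, cohort, _ = fitted
    rng = np.random.default_rng(11)
    n = 40
    age = np.full(n, 50.0)
    sex = np.array(["female"] * n)
    ids = [f"p{i:02d}" for i in range(n)]
    region, hemi, metric = TARGET
    vals = 0.36 + rng.uniform(-0.08, 0.08, n)
    morph = MorphometryTable(pd.DataFrame({
        "subject_id": ids, "hemisphere": hemi, "region": region,
        "metric": metric, "value": vals}))
    meta = pd.DataFrame({"subject_id": ids, "age": age, "sex": sex,
                         "group": "control", "dataset": "d", "site": "newsite",
                         "session": "s"})
    subjects = Cohort(morph, meta)
    adj = estimate_site_adjustment(res, subjects, TARGET)
    z = compute_zscores(res, adj, subjects, TARGET).set_index("subject_id")["z"]
    c = compute_centiles(res, adj, subjects, TARGET).set_index("subject_id")["centile"]
    assert list(z.sort_values().index) == list(c.sort_values().index)


def test_extreme_centiles_clipped_and_flagged(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=40, rng=np.random.default_rng(13))
    adj = estimate_site_adjustment(res, new, TARGET)
    probe = _new_site_cohort(res, cohort, n=1, rng=np.random.default_rng(6))
    probe.morphometry.data["value"] = 10.0  # absurdly large log10 value
    out = compute_centiles(res, adj, probe, TARGET)
    assert out["centile"].iloc[0] == 99.99 and bool(out["clipped"].iloc[0])


def test_site_mismatch_rejected(fitted):
    res, cohort, _ = fitted
    new = _new_site_cohort(res, cohort, n=50)
    adj = estimate_site_adjustment(res, new, TARGET)
    other = _new_site_cohort(res, cohort, n=10, site="othersite")
    with pytest.raises(ValueError, match="site"):
        compute_zscores(res, adj, other, TARGET)


def test_sd_rule_matches_chi_square_closed_form():
    for n, acc in [(30, 0.10), (30, 0.25), (10, 0.2), (100, 0.05)]:
        out = sd_rule_probability(n, acc, reps=50_000, seed=3)
        assert abs(out["monte_carlo"] - out["closed_form"]) <= 3 * out["mc_se"]


def test_sd_rule_reference_values_and_certainty():
    p10 = sd_rule_probability(30, 0.10, reps=100_000, seed=0)
    p25 = sd_rule_probability(30, 0.25, reps=100_000, seed=0)
    assert p10["monte_carlo"] == pytest.approx(0.55, abs=0.02)
    assert p25["monte_carlo"] == pytest.approx(0.95, abs=0.02)
    assert sd_rule_probability(30, 10.0, reps=10_000, seed=0)["monte_carlo"] == 1.0


def test_sd_rule_input_validation():
    with pytest.raises(ValueError, match="accuracy"):
        sd_rule_probability(30, -0.1)
    with pytest.raises(ValueError, match="n >= 2"):
        sd_rule_probability(1, 0.1)
    with pytest.raises(ValueError, match="10,000"):
        sd_rule_probability(30, 0.1, reps=100)
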