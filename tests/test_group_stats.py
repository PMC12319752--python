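"""Effect sizes, abnormality summaries and lateralisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from brainnorm.group_stats import (cohens_d, effectsize_correlation,
                                   group_abnormality, lateralize)


def test_hand_computed_cohens_d_is_two():
    # means 2.5 vs 1.5, each group variance 0.25 -> pooled SD 0.5 -> d = 2
    assert cohens_d([2.0, 2.5, 3.0], [1.0, 1.5, 2.0]) == pytest.approx(2.0, abs=1e-12)


def test_identical_groups_give_zero_d():
    x = [0.3, -0.2, 1.1, 0.5]
    assert cohens_d(x, x) == 0.0


def test_unit_shift_with_unit_sd_gives_d_near_one():
    rng = np.random.default_rng(0)
    a = 1.0 + rng.standard_normal(5000)
    b = rng.standard_normal(5000)
    assert cohens_d(a, b) == pytest.approx(1.0, abs=0.06)


@given(st.lists(st.floats(-5, 5), min_size=3, max_size=20),
       st.lists(st.floats(-5, 5), min_size=3, max_size=20))
def test_cohens_d_antisymmetry(a, b):
    if np.std(a, ddof=1) + np.std(b, ddof=1) == 0:
        return
    assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), abs=1e-9)


@given(alpha=st.floats(0.01, 50), beta=st.floats(-100, 100))
def test_cohens_d_affine_invariance(alpha, beta):
    a = np.array([2.0, 2.5, 3.0, 2.2])
    b = np.array([1.0, 1.5, 2.0, 1.2])
    d0 = cohens_d(a, b)
    d1 = cohens_d(alpha * a + beta, alpha * b + beta)
    assert d1 == pytest.approx(d0, rel=1e-6)


def test_degenerate_groups_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        cohens_d([1.0], [0.0, 0.1])
    with pytest.raises(ValueError, match="pooled"):
        cohens_d([1.0, 1.0], [2.0, 2.0])


def _score_table(z_pat, z_ctl=None):
    rows = []
    for i, z in enumerate(z_pat):
        rows.append({"subject_id": f"p{i}", "region": "precentral",
                     "hemisphere": "left", "metric": "m", "z": z})
    for i, z in enumerate(z_ctl if z_ctl is not None else []):
        rows.append({"subject_id": f"c{i}", "region": "precentral",
                     "hemisphere": "left", "metric": "m", "z": z})
    scores = pd.DataFrame(rows)
    meta = pd.DataFrame({
        "subject_id": scores["subject_id"].unique(),
        "group": ["patient" if s.startswith("p") else "control"
                  for s in scores["subject_id"].unique()],
    })
    return scores, meta


def test_zero_patient_z_gives_zero_d_in_both_modes():
    rng = np.random.default_rng(1)
    ctl = rng.standard_normal(30)
    ctl -= ctl.mean()  # a control group centred exactly on the reference
    scores, meta = _score_table([0.0] * 30, ctl)
    for mode in ("case_control", "normative"):
        out = group_abnormality(scores, meta, mode=mode)
        assert out["d"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_normative_mode_is_standardised_patient_mean():
    rng = np.random.default_rng(2)
    z = -0.8 + rng.standard_normal(56)
    scores, meta = _score_table(z)
    out = group_abnormality(scores, meta, mode="normative")
    assert out["d"].iloc[0] == pytest.approx(z.mean() / z.std(ddof=1), abs=1e-12)
    assert out["d"].iloc[0] == pytest.approx(-0.8, abs=0.2)
    assert out["n_patients"].iloc[0] == 56


def test_case_control_mode_matches_small_control_sample():
    rng = np.random.default_rng(3)
    z_pat = -0.8 + rng.standard_normal(56)
    z_ctl = rng.standard_normal(26)
    scores, meta = _score_table(z_pat, z_ctl)
    out = group_abnormality(scores, meta, mode="case_control")
    assert out["d"].iloc[0] == pytest.approx(-0.8, abs=0.35)
    assert out["n_controls"].iloc[0] == 26


def test_missing_group_raises():
    scores, meta = _score_table([0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="control"):
        group_abnormality(scores, meta, mode="case_control")
    with pytest.raises(ValueError, match="unknown mode"):
        group_abnormality(scores, meta, mode="bayes")


def _laterality_inputs(n=100, effect=-1.5, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    truth = np.where(rng.random(n) < 0.5, "left", "right")
    left = rng.standard_normal(n) + np.where(truth == "left", effect, 0.0)
    right = rng.standard_normal(n) + np.where(truth == "right", effect, 0.0)
    ctrl = rng.standard_normal(300) - rng.standard_normal(300)
    return pd.Series(left, idx), pd.Series(right, idx), ctrl, pd.Series(truth, idx)


def test_lateralisation_accuracy_with_strong_asymmetry():
    left, right, ctrl, truth = _laterality_inputs(n=200, effect=-3.0)
    res = lateralize(left, right, ctrl, direction="lower_abnormal", true_side=truth)
    assert res.accuracy > 0.9
    assert set(res.confusion.columns) <= {"left", "right"}


def test_zero_delta_is_indeterminate():
    idx = pd.Index(["a"], name="subject_id")
    res = lateralize(pd.Series([0.5], idx), pd.Series([0.5], idx),
                     np.random.default_rng(0).standard_normal(20))
    assert res.table["predicted_side"].iloc[0] == "indeterminate"


def test_direction_flag_flips_calls():
    idx = pd.Index(["a"], name="subject_id")
    ctrl = np.random.default_rng(0).standard_normal(20)
    low = lateralize(pd.Series([-2.0], idx), pd.Series([0.0], idx), ctrl,
                     direction="lower_abnormal")
    high = lateralize(pd.Series([-2.0], idx), pd.Series([0.0], idx), ctrl,
                      direction="higher_abnormal")
    assert low.table["predicted_side"].iloc[0] == "left"
    assert high.table["predicted_side"].iloc[0] == "right"


def test_controls_exceed_their_own_2sd_band_at_normal_rate():
    rng = np.random.default_rng(4)
    n = 4000
    idx = pd.Index([f"c{i}" for i in range(n)], name="subject_id")
    left = pd.Series(rng.standard_normal(n), idx)
    right = pd.Series(rng.standard_normal(n), idx)
    ctrl = (left - right).to_numpy()
    res = lateralize(left, right, ctrl)
    rate = res.table["exceeds_2sd"].mean()
    expected = 2 * stats.norm.sf(2.0)  # ~4.55%
    assert rate == pytest.approx(expected, abs=0.02)


def test_symmetric_subjects_lateralise_at_chance():
    rng = np.random.default_rng(5)
    n = 2000
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    left = pd.Series(rng.standard_normal(n), idx)
    right = pd.Series(rng.standard_normal(n), idx)
    labels = pd.Series(np.where(rng.random(n) < 0.5, "left", "right"), idx)
    res = lateralize(left, right, rng.standard_normal(50), true_side=labels)
    assert res.accuracy == pytest.approx(0.5, abs=0.05)


def test_misaligned_subjects_rejected():
    ia = pd.Index(["a", "b"], name="subject_id")
    ib = pd.Index(["a", "c"], name="subject_id")
    with pytest.raises(ValueError, match="different subjects"):
        lateralize(pd.Series([1.0, 2.0], ia), pd.Series([1.0, 2.0], ib),
                   np.zeros(10) + np.random.default_rng(0).standard_normal(10))


def test_effectsize_correlation_limits_and_noise():
    rng = np.random.default_rng(6)
    d1 = rng.normal(0, 0.5, 68)
    assert effectsize_correlation(d1, d1) == pytest.approx(1.0)
    assert effectsize_correlation(d1, -d1) == pytest.approx(-1.0)
    d2 = 0.5 * d1 + rng.normal(0, 0.01, 68)
    assert effectsize_correlation(d1, d2) > 0.99
    with pytest.raises(ValueError, match="zero variance"):
        effectsize_correlation(np.ones(10), d1[:10])
    with pytest.raises(ValueError, match="at least 3"):
        effectsize_correlation([0.1, 0.2], [0.3, 0.4])
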