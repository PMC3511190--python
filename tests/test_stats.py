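import numpy as np
import pandas as pd
import pytest

from carotidshift.frames import DisplacementRecord
from carotidshift.stats import (GROUP_A_SUBJECTS, GROUP_B_SUBJECTS, StatsError,
                                build_regressors, fit_all_targets,
                                fit_regression, group_compare,
                                reference_shift_table, round_half_up,
                                round_report, summarize)

# published mean / sample SD / max for the six-subject reference cohort
PUBLISHED_SUMMARY = {
    "C1": (1.02, 0.90, 2.19), "C2": (2.18, 1.81, 4.68), "C3": (4.25, 3.85, 9.83),
    "C4": (5.90, 5.14, 13.38), "mandible": (1.75, 2.76, 7.34),
    "vA": (5.52, 4.12, 12.49), "vB": (4.02, 3.27, 10.04), "vC": (4.39, 2.42, 9.18),
    "vD": (4.48, 1.88, 8.03), "vE": (2.47, 1.32, 4.59),
}


def test_reference_summaries_match_published_values():
    rep = round_report(summarize(reference_shift_table()))
    for col, (mean, sd, mx) in PUBLISHED_SUMMARY.items():
        assert rep.loc[col, "mean"] == mean, col
        assert rep.loc[col, "sd"] == sd, col
        assert rep.loc[col, "max"] == mx, col


def test_summary_is_order_invariant(rng):
    table = reference_shift_table()
    shuffled = table.sample(frac=1.0, random_state=7)
    pd.testing.assert_frame_equal(summarize(table), summarize(shuffled).loc[summarize(table).index])


def test_all_zero_column_summary():
    table = reference_shift_table().copy()
    table["vE"] = 0.0
    s = summarize(table)
    assert tuple(s.loc["vE"]) == (0.0, 0.0, 0.0)


def test_summarize_input_validation():
    with pytest.raises(StatsError):
        summarize(reference_shift_table().iloc[:1])
    bad = reference_shift_table().copy()
    bad.loc[1, "C1"] = -0.1
    with pytest.raises(StatsError):
        summarize(bad)


def test_round_half_up_convention():
    assert round_half_up(1.005) == 1.01
    assert round_half_up(2.675) == 2.68
    assert round_half_up(-1.005) == -1.01  # ties round away from zero


def test_group_comparison_matches_published_means():
    g = group_compare(reference_shift_table(), GROUP_A_SUBJECTS, GROUP_B_SUBJECTS)
    assert round_half_up(g.bone_mean_a) == 1.17
    assert round_half_up(g.bone_mean_b) == 5.51
    assert round_half_up(g.vessel_mean_a) == 2.51
    assert round_half_up(g.vessel_mean_b) == 5.84


def test_group_of_one_constant_subject():
    table = reference_shift_table().copy()
    table.loc[9] = ["L"] + [3.0] * 10
    g = group_compare(table, [9], [1])
    assert g.bone_mean_a == pytest.approx(3.0)
    assert g.vessel_mean_a == pytest.approx(3.0)


def test_group_validation():
    table = reference_shift_table()
    with pytest.raises(StatsError):
        group_compare(table, [1, 2], [2, 3])        # overlap
    with pytest.raises(StatsError):
        group_compare(table, [1], [99])             # unknown id
    with pytest.raises(StatsError):
        group_compare(table, [], [1])


def test_pooled_mean_consistency():
    """With A u B covering all subjects, the pooled vertebral mean equals
    the subject-weighted mean of the two group means."""
    table = reference_shift_table()
    g = group_compare(table, GROUP_A_SUBJECTS, GROUP_B_SUBJECTS)
    pooled = table[["C1", "C2", "C3", "C4"]].values.mean()
    assert pooled == pytest.approx((g.bone_mean_a * 3 + g.bone_mean_b * 3) / 6)


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

def _rec(segment, dx, dy, dz, dalpha, frame="SCS"):
    return DisplacementRecord(segment=segment, frame=frame, dx=dx, dy=dy, dz=dz,
                              dalpha=dalpha, dbeta=0.0, dgamma=0.0)


def test_regressors_are_c4_minus_c2_differences():
    records = {1: {"C2": _rec("C2", 1, 1, 1, 1), "C4": _rec("C4", 2, 1, 3, 4)},
               2: {"C2": _rec("C2", 0.5, 0, 0, 0), "C4": _rec("C4", 0.5, 0, 0, 0)}}
    x = build_regressors(records)
    assert tuple(x.loc[1]) == (1.0, 0.0, 2.0, 3.0)
    assert tuple(x.loc[2]) == (0.0, 0.0, 0.0, 0.0)


def test_regressors_require_scs_records_with_angles():
    with pytest.raises(StatsError, match="C4"):
        build_regressors({1: {"C2": _rec("C2", 0, 0, 0, 0)}})
    with pytest.raises(StatsError, match="SCS"):
        build_regressors({1: {"C2": _rec("C2", 0, 0, 0, 0, frame="PCS"),
                              "C4": _rec("C4", 0, 0, 0, 0, frame="PCS")}})


def test_measured_regressors_match_truth_transforms(analysis, pre_scene, motions):
    """Regressors from the measured pipeline records agree with differences
    computed independently from the injected ground-truth transforms."""
    from carotidshift.frames import euler_decompose, inertia_axes, to_standard
    from carotidshift.pipeline import truth_relative_transforms
    frame = inertia_axes(pre_scene.segments["maxillofacial"], pre_scene.anatomical_hints)
    rel = truth_relative_transforms(motions)
    truth_recs = {}
    for name in ("C2", "C4"):
        c = pre_scene.bone_centroids[name]
        truth_recs[name] = euler_decompose(to_standard(rel[name], frame),
                                           frame.to_scs(c), segment=name, frame="SCS")
    x_meas = build_regressors({1: analysis.records_scs})
    x_true = build_regressors({1: truth_recs})
    assert np.allclose(x_meas.values[:, :3], x_true.values[:, :3], atol=0.5)  # mm
    assert np.allclose(x_meas.values[:, 3], x_true.values[:, 3], atol=0.5)    # deg


# ---------------------------------------------------------------------------
# regression fits
# ---------------------------------------------------------------------------

def test_exact_linear_data_recovered_to_machine_precision(rng):
    x = rng.normal(size=(20, 4))
    b = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
    y = b[0] + x @ b[1:]
    fit = fit_regression(x, y)
    assert np.allclose(fit.params, b, atol=1e-9)
    assert np.abs(fit.residuals).max() < 1e-9
    assert fit.r_squared == pytest.approx(1.0)


def test_constant_response_gives_intercept_only(rng):
    x = rng.normal(size=(12, 4))
    fit = fit_regression(x, np.full(12, 4.2))
    assert fit.params[0] == pytest.approx(4.2)
    assert np.allclose(fit.params[1:], 0.0, atol=1e-9)


def test_saturated_fit_warns_and_interpolates(rng):
    x = rng.normal(size=(5, 4))
    y = rng.normal(size=5)
    with pytest.warns(UserWarning, match="saturated"):
        fit = fit_regression(x, y)
    assert np.abs(fit.residuals).max() < 1e-9


def test_rank_deficient_design_rejected(rng):
    x = rng.normal(size=(10, 4))
    x[:, 3] = 2.0 * x[:, 1]
    with pytest.raises(StatsError, match="rank"):
        fit_regression(x, rng.normal(size=10))


def test_residuals_orthogonal_to_regressors(rng):
    x = rng.normal(size=(30, 4))
    y = x @ [1, -2, 0.5, 1] + rng.normal(size=30)
    fit = fit_regression(x, y)
    scale = np.abs(y).max() * len(y)
    assert abs(fit.residuals.sum()) < 1e-9 * scale
    for k in range(4):
        assert abs(fit.residuals @ x[:, k]) < 1e-9 * scale


def test_ols_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    x = rng.normal(size=(25, 4))
    y = x @ [0.5, 1.5, -1.0, 2.0] + rng.normal(size=25)
    fit = fit_regression(x, y)
    ref = sm.OLS(y, sm.add_constant(x)).fit()
    assert np.allclose(fit.params, ref.params, atol=1e-10)
    assert fit.r_squared == pytest.approx(ref.rsquared)


def test_fit_all_targets_produces_fifteen_fits(rng):
    x = pd.DataFrame(rng.normal(size=(10, 4)), columns=["x1", "x2", "x3", "x4"],
                     index=range(1, 11))
    cols = {f"{lab}_{c}": rng.normal(size=10)
            for lab in ("vA", "vB", "vC", "vD", "vE") for c in ("dx", "dy", "dz")}
    comps = pd.DataFrame(cols, index=x.index)
    fits = fit_all_targets(x, comps)
    assert len(fits) == 15
    assert {t[0] for t in fits} == {"vA", "vB", "vC", "vD", "vE"}
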