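"""Univariable MR estimators against oracles and invariances."""

import numpy as np
import pytest

from protmed import (
    HarmonizedSet,
    ivw_mre,
    leave_one_out,
    mr_egger,
    steiger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from protmed.errors import (
    DegenerateInstrumentError,
    DomainError,
    InsufficientSNPsError,
)
from protmed.uvmr import IVWRandomEffects, MREgger, WeightedMedian, WeightedMode


def hset(bx, by, se_y, se_x=None):
    bx = np.asarray(bx, dtype=float)
    se_x = np.full_like(bx, 1e-6) if se_x is None else np.asarray(se_x)
    return HarmonizedSet(
        [f"rs{i}" for i in range(len(bx))], bx, se_x, by, se_y,
        exposure_id="X", outcome_id="Y",
    )


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_arithmetic():
    est = wald_ratio(hset([0.1], [0.05], [0.02]))
    assert est.estimate == pytest.approx(0.5)
    assert est.se == pytest.approx(0.2)
    assert est.ci_low < 0.5 < est.ci_high


def test_wald_zero_outcome_effect():
    assert wald_ratio(hset([0.1], [0.0], [0.02])).estimate == 0.0


def test_wald_degenerate_instrument():
    with pytest.raises(DegenerateInstrumentError):
        wald_ratio(hset([0.0], [0.1], [0.02]))


def test_wald_scale_equivariance(rng):
    bx = rng.uniform(0.05, 0.3, 10)
    by = rng.standard_normal(10) * 0.05
    se = rng.uniform(0.01, 0.05, 10)
    for i in range(10):
        one = wald_ratio(hset([bx[i]], [by[i]], [se[i]]))
        two = wald_ratio(hset([2 * bx[i]], [by[i]], [se[i]]))
        assert two.estimate == pytest.approx(one.estimate / 2)


# ---------------------------------------------------------------------------
# IVW multiplicative random effects


def test_ivw_hand_example():
    est = ivw_mre(hset([1.0, 1.0], [1.0, 3.0], [1.0, 1.0]))
    assert est.estimate == pytest.approx(2.0)
    assert est.Q == pytest.approx(2.0)
    assert est.se == pytest.approx(1.0)


def test_ivw_constant_ratios_no_heterogeneity():
    est = ivw_mre(hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20],
                       [0.01, 0.02, 0.01]))
    assert est.estimate == pytest.approx(0.5)
    assert est.Q == pytest.approx(0.0, abs=1e-20)


def test_ivw_matches_weighted_regression_oracle(rng):
    import statsmodels.api as sm

    for _ in range(30):
        k = rng.integers(3, 40)
        bx = rng.uniform(-0.3, 0.3, k)
        by = 0.4 * bx + rng.standard_normal(k) * 0.05
        se = rng.uniform(0.01, 0.1, k)
        est = ivw_mre(hset(bx, by, se))
        fit = sm.WLS(by, bx, weights=1 / se ** 2).fit()
        assert est.estimate == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[0], abs=1e-10)


def test_ivw_floor_phi_never_below_fixed_effects():
    h = hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.02, 0.015])
    floored = ivw_mre(h, floor_phi=True)
    w = 1 / h.se_out ** 2
    se_fe = np.sqrt(1 / np.sum(w * h.beta_exp ** 2))
    assert floored.se >= se_fe - 1e-15


def test_ivw_requires_two_variants():
    with pytest.raises(InsufficientSNPsError):
        ivw_mre(hset([0.1], [0.05], [0.01]))


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_orientation_invariance(rng):
    bx = rng.uniform(0.05, 0.3, 20)
    by = 0.3 * bx + rng.standard_normal(20) * 0.02
    se = rng.uniform(0.01, 0.05, 20)
    base = mr_egger(hset(bx, by, se))
    flip = np.ones(20)
    flip[[2, 5, 11]] = -1
    other = mr_egger(hset(bx * flip, by * flip, se))
    assert other.estimate == pytest.approx(base.estimate, abs=1e-12)
    assert other.egger_intercept == pytest.approx(base.egger_intercept,
                                                  abs=1e-12)


def test_egger_recovers_constant_pleiotropy(rng):
    c, slope = 0.05, 0.3
    intercepts = []
    for _ in range(50):
        bx = rng.uniform(0.05, 0.4, 100)
        se = rng.uniform(0.01, 0.03, 100)
        by = c + slope * bx + rng.standard_normal(100) * se
        est = mr_egger(hset(bx, by, se))
        intercepts.append(est.egger_intercept)
    assert np.mean(intercepts) == pytest.approx(c, abs=0.01)


def test_egger_needs_three(rng):
    with pytest.raises(InsufficientSNPsError):
        mr_egger(hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


# ---------------------------------------------------------------------------
# weighted median / mode


def test_weighted_median_percentile_oracle():
    # ratios {0, 1, 100}, weights {0.1, 0.8, 0.1} -> cumulative midpoint 0.5
    bx = np.array([1.0, 1.0, 1.0])
    by = np.array([0.0, 1.0, 100.0])
    se_y = np.sqrt(1.0 / np.array([0.1, 0.8, 0.1]))
    est = weighted_median(hset(bx, by, se_y), boot_reps=0)
    assert est.estimate == pytest.approx(1.0)


def test_weighted_median_equal_ratios():
    est = weighted_median(hset([0.1, 0.2, 0.3], [0.1, 0.2, 0.3],
                               [0.01, 0.01, 0.01]), boot_reps=50, seed=1)
    assert est.estimate == pytest.approx(1.0)
    assert est.se > 0


def test_weighted_median_order_invariance(rng):
    bx = rng.uniform(0.05, 0.3, 9)
    by = 0.4 * bx + rng.standard_normal(9) * 0.02
    se = rng.uniform(0.01, 0.05, 9)
    perm = rng.permutation(9)
    a = weighted_median(hset(bx, by, se), boot_reps=0)
    b = weighted_median(hset(bx[perm], by[perm], se[perm]), boot_reps=0)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


def test_weighted_mode_common_ratio():
    est = weighted_mode(hset([0.1, 0.2, 0.5], [0.07, 0.14, 0.35],
                             [0.01, 0.01, 0.01]), boot_reps=0)
    assert est.estimate == pytest.approx(0.7, abs=1e-9)


def test_weighted_mode_majority_cluster(rng):
    # ~70% of weight near ratio 0.5, 30% near 5.0
    bx = np.concatenate([rng.uniform(0.2, 0.4, 14), rng.uniform(0.2, 0.4, 6)])
    by = np.concatenate([0.5 * bx[:14] + rng.normal(0, 0.002, 14),
                         5.0 * bx[14:] + rng.normal(0, 0.002, 6)])
    se = np.full(20, 0.02)
    est = weighted_mode(hset(bx, by, se), boot_reps=0, grid_size=2048)
    assert abs(est.estimate - 0.5) < 0.1


def test_weighted_mode_order_invariance(rng):
    bx = rng.uniform(0.05, 0.3, 9)
    by = 0.4 * bx + rng.standard_normal(9) * 0.02
    se = rng.uniform(0.01, 0.05, 9)
    perm = rng.permutation(9)
    a = weighted_mode(hset(bx, by, se), boot_reps=0)
    b = weighted_mode(hset(bx[perm], by[perm], se[perm]), boot_reps=0)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


# ---------------------------------------------------------------------------
# cross-estimator invariances


def test_estimators_collapse_to_wald_on_identical_rows():
    h = hset([0.2] * 4, [0.12] * 4, [0.03] * 4)
    wald = wald_ratio(h.subset([0]))
    assert ivw_mre(h).estimate == pytest.approx(wald.estimate)
    assert weighted_median(h, boot_reps=0).estimate == pytest.approx(
        wald.estimate)
    assert weighted_mode(h, boot_reps=0).estimate == pytest.approx(
        wald.estimate)


def test_negating_exposure_negates_all_estimators(rng):
    bx = rng.uniform(0.05, 0.3, 12)
    by = 0.4 * bx + rng.standard_normal(12) * 0.02
    se = rng.uniform(0.01, 0.05, 12)
    h_pos = hset(bx, by, se)
    h_neg = hset(-bx, by, se)
    for fn, kwargs in [
        (ivw_mre, {}),
        (mr_egger, {}),
        (weighted_median, {"boot_reps": 0}),
        (weighted_mode, {"boot_reps": 0}),
    ]:
        a = fn(h_pos, **kwargs).estimate
        b = fn(h_neg, **kwargs).estimate
        assert b == pytest.approx(-a, abs=1e-10), fn.__name__


def test_sklearn_get_set_params_roundtrip():
    for est in (IVWRandomEffects(), MREgger(),
                WeightedMedian(boot_reps=7, seed=3),
                WeightedMode(phi=2.0, boot_reps=5)):
        params = est.get_params()
        est.set_params(**params)
        assert est.get_params() == params


# ---------------------------------------------------------------------------
# leave-one-out


def test_leave_one_out_homogeneous(rng):
    bx = rng.uniform(0.1, 0.3, 6)
    by = 0.5 * bx
    h = hset(bx, by, np.full(6, 0.02))
    loo = leave_one_out(h)
    assert len(loo.results) == 6
    for _, est in loo.results:
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
    assert loo.sign_change_ids == []


def test_leave_one_out_flags_planted_outlier(rng):
    bx = rng.uniform(0.1, 0.3, 10)
    by = 0.3 * bx + rng.standard_normal(10) * 0.001
    by[4] += 0.5  # dominant outlier
    h = hset(bx, by, np.full(10, 0.02))
    loo = leave_one_out(h)
    shifts = {vid: abs(est.estimate - loo.full.estimate)
              for vid, est in loo.results}
    assert max(shifts, key=shifts.get) == "rs4"


# ---------------------------------------------------------------------------
# Steiger directionality


def test_steiger_direction_trivial():
    h = hset([0.3, 0.3], [0.01, 0.01], [0.02, 0.02],
             se_x=[0.02, 0.02])
    res = steiger(h, n_exp=20_000, n_out=20_000, outcome_type="continuous")
    assert res.correct_direction
    assert 0 <= res.r2_exposure <= 2  # sum of per-variant r2


def test_steiger_symmetric_inputs_give_null():
    h = hset([0.2, 0.1], [0.2, 0.1], [0.02, 0.02], se_x=[0.02, 0.02])
    res = steiger(h, n_exp=10_000, n_out=10_000, outcome_type="continuous")
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.pval == pytest.approx(1.0)


def test_steiger_binary_needs_case_fraction():
    h = hset([0.2], [0.1], [0.02], se_x=[0.02])
    with pytest.raises(DomainError):
        steiger(h, 10_000, 10_000, outcome_type="case_control")


def test_steiger_simulation_recovers_direction(rng):
    """Exposure->outcome simulations give correct_direction nearly always."""
    wins = 0
    reps = 100
    for _ in range(reps):
        k, n = 20, 20_000
        bx = rng.uniform(0.03, 0.08, k)
        bx_hat = bx + rng.standard_normal(k) / np.sqrt(n)
        by_hat = 0.3 * bx + rng.standard_normal(k) / np.sqrt(n)
        h = hset(bx_hat, by_hat, np.full(k, 1 / np.sqrt(n)),
                 se_x=np.full(k, 1 / np.sqrt(n)))
        res = steiger(h, n, n, outcome_type="continuous")
        wins += res.correct_direction
    assert wins >= 95
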