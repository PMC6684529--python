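"""Robust scale, pseudo-outlier screen, feasibility functional,
sandwich covariance, gamma selection and the outer fixed-point loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eslreg as E
from eslreg.exceptions import InvalidParameterError, NoFeasibleGammaError
from eslreg.scale import pseudo_outlier_set, residual_scale_sn
from eslreg.tuning import _i1_scalar

from conftest import random_instance


# ---------------------------------------------------------------------------
# S_n and pseudo outliers
# ---------------------------------------------------------------------------


def test_sn_hand_example():
    """(1,2,3,4,100): median 3, |dev| (2,1,0,1,97), MAD 1 -> 1.4826."""
    assert residual_scale_sn([1, 2, 3, 4, 100]) == pytest.approx(1.4826)


def test_sn_constant_residuals_zero():
    assert residual_scale_sn([5.0] * 7) == 0.0


def test_sn_rejects_too_short():
    with pytest.raises(InvalidParameterError):
        residual_scale_sn([1.0])


@settings(derandomize=True, max_examples=50)
@given(
    r=st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    c=st.floats(-10, 10),
)
def test_sn_scale_equivariance(r, c):
    r = np.asarray(r)
    assert residual_scale_sn(c * r) == pytest.approx(
        abs(c) * residual_scale_sn(r), abs=1e-9
    )


def test_pseudo_outlier_hand_example():
    """(1,-1,2,-2,100): S_n = 2.9652, threshold 7.413 -> only the 100."""
    out = pseudo_outlier_set([1.0, -1.0, 2.0, -2.0, 100.0])
    assert out.s_n == pytest.approx(2.9652)
    assert list(out.indices) == [4]
    assert out.m == 1
    assert not out.degenerate_scale


def test_pseudo_outlier_flags_negative_outliers():
    out = pseudo_outlier_set([1.0, -1.0, 2.0, -2.0, -100.0])
    assert list(out.indices) == [4]


def test_pseudo_outlier_degenerate_scale():
    out = pseudo_outlier_set(np.zeros(10))
    assert out.m == 0 and out.degenerate_scale


def test_pseudo_outlier_matches_direct_filter():
    """The rule flags exactly {i: |r_i| >= 2.5 S_n} on random vectors."""
    for seed in range(30):
        rng = np.random.default_rng(seed)
        r = rng.standard_t(2, 200)
        out = pseudo_outlier_set(r)
        direct = np.flatnonzero(np.abs(r) >= 2.5 * residual_scale_sn(r))
        assert np.array_equal(out.indices, direct)


def test_pseudo_outlier_gaussian_rate():
    """Two-sided 2.5 MAD rule flags about 1.2% of Gaussians."""
    rng = np.random.default_rng(123)
    out = pseudo_outlier_set(rng.standard_normal(100_000))
    assert 0.005 < out.m / out.n < 0.025


# ---------------------------------------------------------------------------
# zeta
# ---------------------------------------------------------------------------


def test_zeta_zero_residuals_is_infeasible():
    r = np.zeros(10)
    out = pseudo_outlier_set(r)
    assert E.zeta(1.0, r, out) == 0.0  # outside (0, 1]


def test_zeta_closed_form_two_points():
    r = np.array([1.0, 1.0])
    out = pseudo_outlier_set(r)
    assert out.m == 0
    val = E.zeta(1.0, r, out)
    assert val == pytest.approx(2 * (1 - np.exp(-1)), abs=1e-12)
    assert val > 1.0  # infeasible


def test_zeta_decreasing_in_gamma():
    rng = np.random.default_rng(0)
    r = rng.standard_normal(50)
    out = pseudo_outlier_set(r)
    vals = [E.zeta(g, r, out) for g in (0.1, 0.5, 2.0, 10.0, 100.0)]
    assert np.all(np.diff(vals) < 0)


def test_zeta_bounds():
    """zeta in [2m/n, 2m/n + 2(n-m)/n] for any gamma."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        r = rng.standard_t(1, 80)
        out = pseudo_outlier_set(r)
        lo = 2 * out.m / out.n
        hi = lo + 2 * (out.n - out.m) / out.n
        for g in (1e-4, 0.1, 1.0, 50.0, 1e5):
            z = E.zeta(g, r, out)
            assert lo <= z <= hi


def test_zeta_rejects_bad_gamma():
    r = np.ones(5)
    with pytest.raises(InvalidParameterError):
        E.zeta(-1.0, r, pseudo_outlier_set(r))


# ---------------------------------------------------------------------------
# sandwich covariance
# ---------------------------------------------------------------------------


def test_asymptotic_cov_zero_residuals(exact_fit_data):
    data, beta = exact_fit_data
    ac = E.asymptotic_cov(beta, data, 2.0)
    assert np.allclose(ac.Sigma, 0.0)
    assert np.allclose(ac.V, 0.0)
    assert ac.detV == 0.0
    assert not ac.feasible  # zeta = 0


def test_asymptotic_cov_sigma_psd_and_v_symmetric():
    for seed in range(25):
        data, beta = random_instance(seed, n=20, p=3)
        ac = E.asymptotic_cov(beta, data, 1.0 + 0.2 * seed)
        eig = np.linalg.eigvalsh(ac.Sigma)
        assert eig.min() >= -1e-10
        if np.all(np.isfinite(ac.V)):
            assert np.allclose(ac.V, ac.V.T, atol=1e-10)


def test_i1_scalar_matches_numerical_hessian():
    """For a location model (X = column of ones) the curvature scalar
    is minus the second derivative of the mean objective."""
    rng = np.random.default_rng(8)
    y = rng.standard_normal(20)
    data = E.RegressionData(y, np.ones((20, 1)))
    gamma = 1.3
    b0, h = 0.1, 1e-4

    def f(b):
        return E.esl_objective([b], data, gamma) / data.n

    fd2 = (f(b0 + h) - 2 * f(b0) + f(b0 - h)) / h**2
    a = _i1_scalar(y - b0, gamma)
    assert a == pytest.approx(-fd2, abs=1e-4)


def test_detv_double_entry():
    """detV from the separable I1 equals the independently assembled
    det(Sigma) / det(I1)^2 on 50 random instances."""
    checked = 0
    for seed in range(80):
        data, beta = random_instance(seed, n=25, p=3)
        ac = E.asymptotic_cov(beta, data, 0.5 + 0.1 * seed)
        if not np.all(np.isfinite(ac.V)):
            continue
        det_direct = np.linalg.det(ac.Sigma) / np.linalg.det(ac.I1) ** 2
        assert ac.detV == pytest.approx(det_direct, rel=1e-6, abs=1e-12)
        assert np.linalg.det(ac.V) == pytest.approx(
            ac.detV, rel=1e-6, abs=1e-10
        )
        checked += 1
        if checked >= 50:
            break
    assert checked >= 50


# ---------------------------------------------------------------------------
# gamma selection
# ---------------------------------------------------------------------------


def _contaminated(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    beta = np.array([1.0, 2.0, -1.0])
    eps = rng.standard_normal(n)
    eps[: n // 10] = rng.standard_t(1, n // 10)
    return E.RegressionData(X @ beta + eps, X), beta


def test_select_gamma_singleton_feasible_grid():
    data, beta = _contaminated()
    r = data.y - data.X @ beta
    grid = E.gamma_grid(r)
    # find one feasible candidate, then offer it alone
    chosen = E.select_gamma(beta, data, grid)
    assert E.select_gamma(beta, data, [chosen]) == pytest.approx(chosen)


def test_select_gamma_empty_feasible_set_raises_with_table():
    """Tiny gammas on moderate residuals drive zeta above 1."""
    X = np.ones((6, 1))
    y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    data = E.RegressionData(y, X)
    with pytest.raises(NoFeasibleGammaError) as exc:
        E.select_gamma(np.zeros(1), data, [1e-6, 1e-5])
    table = exc.value.table
    assert set(table.columns) >= {"gamma", "zeta", "detV", "feasible"}
    assert len(table) == 2 and not table["feasible"].any()


def test_select_gamma_rejects_bad_grid():
    data, beta = _contaminated()
    with pytest.raises(InvalidParameterError):
        E.select_gamma(beta, data, [])
    with pytest.raises(InvalidParameterError):
        E.select_gamma(beta, data, [-1.0, 1.0])


def test_clean_data_selected_gamma_tracks_ols():
    """On clean data the tuned fit agrees with least squares."""
    rng = np.random.default_rng(17)
    X = np.column_stack([np.ones(300), rng.standard_normal((300, 4))])
    beta = np.array([1.0, 0.5, -0.5, 2.0, 1.5])
    data = E.RegressionData(X @ beta + rng.standard_normal(300), X)
    fit = E.fit_esl(data, E.FitConfig(mm=E.MMConfig(seed=17)))
    ols = E.fit_ols(data)
    assert np.max(np.abs(fit.beta - ols)) < 0.05


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_fit_esl_exact_fit_one_outer_iteration(exact_fit_data):
    data, beta = exact_fit_data
    fit = E.fit_esl(data, E.FitConfig(mm=E.MMConfig(seed=0)))
    assert np.allclose(fit.beta, beta, atol=1e-8)
    assert fit.converged and fit.n_outer_iters == 1
    assert fit.m == 0


def test_fit_esl_deterministic():
    data, _ = _contaminated(seed=21)
    cfg = E.FitConfig(mm=E.MMConfig(seed=3))
    a = E.fit_esl(data, cfg)
    b = E.fit_esl(data, cfg)
    assert np.array_equal(a.beta, b.beta)
    assert a.gamma == b.gamma and a.m == b.m
    assert a.gamma_trace == b.gamma_trace


def test_fit_esl_outer_loop_always_terminates():
    """max_outer bounds the loop even when forced not to converge."""
    data, _ = _contaminated(seed=4)
    cfg = E.FitConfig(mm=E.MMConfig(seed=0), max_outer=3, outer_tol=1e-300)
    fit = E.fit_esl(data, cfg)
    assert fit.n_outer_iters == 3
    assert not fit.converged
    assert len(fit.outer_trace) == 3 and len(fit.gamma_trace) == 3


def test_fit_esl_converges_at_printed_tolerance():
    """The outer loop stops once ||beta_old - beta_new|| < 1e-2."""
    data, _ = _contaminated(seed=30)
    fit = E.fit_esl(data, E.FitConfig(mm=E.MMConfig(seed=1)))
    assert fit.converged
    assert fit.outer_trace[-1] < 1e-2
    # every earlier step was at or above the tolerance
    assert all(d >= 1e-2 for d in fit.outer_trace[:-1])


def test_fit_esl_weights_final_state():
    data, _ = _contaminated(seed=12)
    fit = E.fit_esl(data, E.FitConfig(mm=E.MMConfig(seed=2)))
    assert np.all(fit.weights > 0) and np.all(fit.weights <= 1)
    assert fit.m == pseudo_outlier_set(fit.residuals).m
    assert fit.gamma > 0
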