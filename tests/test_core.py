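"""Unit and property tests for process definition, simulation and OLS fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from arvarsim import (
    InvalidMatrixError,
    SingularDesignError,
    StationarityError,
    TimeSeries,
    VARModel,
    characteristics,
    estimation_error,
    fit_ar,
    fit_var,
    is_stationary,
    prediction_error,
    simulate_var,
)
from arvarsim.core import (read_matrix_csv, read_series_csv, write_matrix_csv,
                           write_series_csv)


# ---------------------------------------------------------------------------
# stationarity and D-O characteristics

@pytest.mark.parametrize("phi,expected", [
    (np.diag([0.5] * 6), True),            # eigenvalues all 0.5
    (np.eye(6), False),                    # |lambda| = 1 is not strictly < 1
    ([[0.9, 0.9], [0.9, 0.9]], False),     # rank-1 symmetric: eigs 1.8 and 0
    ([[0.0]], True),
])
def test_is_stationary(phi, expected):
    assert is_stationary(phi) is expected


@pytest.mark.parametrize("bad", [np.ones((2, 3)), [[np.inf, 0], [0, 0]], [1, 2]])
def test_is_stationary_rejects_invalid(bad):
    with pytest.raises(InvalidMatrixError):
        is_stationary(bad)


@pytest.mark.parametrize("phi,d,o", [
    (np.eye(6), 1.0, 0.0),
    (np.zeros((6, 6)), 0.0, 0.0),
    ([[0.5, 0.2], [0.1, 0.3]], 0.4, 0.15),
    ([[-0.5, 0.2], [-0.1, 0.3]], 0.4, 0.15),   # absolute values enter
])
def test_characteristics(phi, d, o):
    c = characteristics(phi)
    assert c.D == pytest.approx(d)
    assert c.O == pytest.approx(o)


def test_model_invariants_enforced():
    with pytest.raises(StationarityError):
        VARModel(phi=np.eye(2), noise_vars=np.ones(2))
    with pytest.raises(ValueError):
        VARModel(phi=np.zeros((2, 2)), noise_vars=[1.0, 0.0])


# ---------------------------------------------------------------------------
# simulation

def test_simulate_white_noise_uncorrelated():
    model = VARModel(phi=np.zeros((3, 3)), noise_vars=np.ones(3))
    ts = simulate_var(model, 10_000, burn_in=10, seed=42)
    x = ts.values
    for i in range(3):
        r = np.corrcoef(x[:-1, i], x[1:, i])[0, 1]
        assert abs(r) < 0.05


def test_simulate_deterministic_in_seed():
    model = VARModel(phi=np.diag([0.4, 0.2]), noise_vars=[1.0, 2.0])
    a = simulate_var(model, 300, burn_in=50, seed=7)
    b = simulate_var(model, 300, burn_in=50, seed=7)
    c = simulate_var(model, 300, burn_in=50, seed=8)
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_simulate_univariate_stationary_variance():
    # closed form: Var = sigma^2 / (1 - phi^2) = 4/3 for phi = 0.5
    model = VARModel(phi=[[0.5]], noise_vars=[1.0])
    ts = simulate_var(model, 50_000, burn_in=100, seed=11)
    assert np.var(ts.values) == pytest.approx(4.0 / 3.0, rel=0.05)


def test_simulate_input_validation(ar_truth):
    with pytest.raises(ValueError):
        simulate_var(ar_truth, 1, seed=0)
    with pytest.raises(ValueError):
        simulate_var(ar_truth, 10, burn_in=-1, seed=0)


# ---------------------------------------------------------------------------
# least-squares fits

def _noise_free_series(phi, n, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(phi.shape[0])
    rows = [x]
    for _ in range(n - 1):
        x = phi @ x
        rows.append(x)
    return TimeSeries(np.array(rows))


def test_fit_var_exact_on_noise_free_series():
    phi = np.array([[0.5, 0.2], [0.1, 0.3]])
    ts = _noise_free_series(phi, 6, seed=1)
    fit = fit_var(ts)
    assert fit.model_class == "VAR"
    assert fit.n_used == 6
    np.testing.assert_allclose(fit.phi_hat, phi, atol=1e-10)


def test_fit_ar_exact_on_noise_free_diagonal():
    phi = np.diag([0.6, -0.3, 0.2])
    ts = _noise_free_series(phi, 8, seed=2)
    fit = fit_ar(ts)
    np.testing.assert_allclose(fit.phi_hat, phi, atol=1e-10)


def _generic_ls_phi(values, p):
    """Independent oracle: generic numerical minimizer of the sum of squared
    one-step residuals over the p*p coefficients."""
    X, Y = values[:-1], values[1:]

    def resid(flat):
        return (Y - X @ flat.reshape(p, p).T).ravel()

    sol = optimize.least_squares(resid, np.zeros(p * p), xtol=1e-15,
                                 ftol=1e-15, gtol=1e-15)
    return sol.x.reshape(p, p)


def test_fit_var_matches_generic_minimizer():
    rng = np.random.default_rng(3)
    values = rng.standard_normal((12, 3))
    fit = fit_var(TimeSeries(values))
    oracle = _generic_ls_phi(values, 3)
    np.testing.assert_allclose(fit.phi_hat, oracle, atol=1e-8)


def test_fit_var_consistency_error_shrinks_with_n(var_truth):
    rng = np.random.SeedSequence(99)
    msd_50, msd_500 = [], []
    for child in rng.spawn(100):
        ts = simulate_var(var_truth, 500, burn_in=100, seed=child)
        msd_500.append(estimation_error(fit_var(ts), var_truth))
        msd_50.append(estimation_error(fit_var(ts.head(50)), var_truth))
    assert np.mean(msd_500) < np.mean(msd_50)


def test_fit_ar_structural_zeros():
    rng = np.random.default_rng(4)
    fit = fit_ar(TimeSeries(rng.standard_normal((40, 4))))
    off = fit.phi_hat[~np.eye(4, dtype=bool)]
    assert np.all(off == 0.0)
    assert fit.model_class == "AR"


def test_fit_ar_converges_to_lag1_autocorrelation_not_truth():
    # with strong cross-lags the AR slope estimates the marginal lag-1
    # autocorrelation of each coordinate, which differs from Phi_ii
    phi = np.array([[0.2, 0.6], [0.5, 0.1]])
    model = VARModel(phi=phi, noise_vars=np.ones(2))
    ts = simulate_var(model, 100_000, burn_in=200, seed=5)
    fit = fit_ar(ts)
    x = ts.values
    for i in range(2):
        rho = np.corrcoef(x[:-1, i], x[1:, i])[0, 1]
        assert fit.phi_hat[i, i] == pytest.approx(rho, abs=0.02)
        assert abs(fit.phi_hat[i, i] - phi[i, i]) > 0.05


def test_fit_ar_constant_column_raises():
    vals = np.column_stack([np.ones(20), np.sin(np.arange(20))])
    with pytest.raises(SingularDesignError) as err:
        fit_ar(TimeSeries(vals))
    assert err.value.n_used == 20 and err.value.p == 2


def test_fit_var_singular_design_raises_with_context():
    # two identical columns make the lagged design rank deficient
    rng = np.random.default_rng(6)
    col = rng.standard_normal(15)
    vals = np.column_stack([col, col])
    with pytest.raises(SingularDesignError) as err:
        fit_var(TimeSeries(vals))
    assert err.value.n_used == 15 and err.value.p == 2


def test_fit_var_min_n():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="n >="):
        fit_var(TimeSeries(rng.standard_normal((3, 3))))


def test_fit_with_intercept_recovers_slope_of_shifted_series():
    model = VARModel(phi=np.diag([0.5, 0.3]), noise_vars=[1.0, 1.0])
    ts = simulate_var(model, 20_000, burn_in=100, seed=8)
    shifted = TimeSeries(ts.values + np.array([5.0, -3.0]))
    fit = fit_var(shifted, intercept=True)
    np.testing.assert_allclose(fit.phi_hat, model.phi, atol=0.05)
    fit_ar_ic = fit_ar(shifted, intercept=True)
    np.testing.assert_allclose(np.diag(fit_ar_ic.phi_hat),
                               np.diag(model.phi), atol=0.05)


# ---------------------------------------------------------------------------
# error measures

def test_estimation_error_cases(var_truth):
    exact = fit_var(simulate_var(var_truth, 50, seed=0))
    exact = type(exact)(phi_hat=var_truth.phi, model_class="VAR", n_used=50)
    assert estimation_error(exact, var_truth) == 0.0
    offset = type(exact)(phi_hat=var_truth.phi + 0.1, model_class="VAR", n_used=50)
    assert estimation_error(offset, var_truth) == pytest.approx(0.01)


def test_estimation_error_zero_fit_hand_value():
    truth = VARModel(phi=[[0.5, 0.2], [0.1, 0.3]], noise_vars=[1, 1])
    from arvarsim import FitResult

    zero = FitResult(phi_hat=np.zeros((2, 2)), model_class="VAR", n_used=10)
    # (0.25 + 0.04 + 0.01 + 0.09) / 4
    assert estimation_error(zero, truth) == pytest.approx(0.0975)


def test_estimation_error_dimension_mismatch(ar_truth):
    from arvarsim import FitResult

    fit = FitResult(phi_hat=np.zeros((2, 2)), model_class="VAR", n_used=10)
    with pytest.raises(ValueError, match="mismatch"):
        estimation_error(fit, ar_truth)


def test_prediction_error_perfect_and_zero_fit():
    from arvarsim import FitResult

    phi = np.array([[0.5, 0.2], [0.1, 0.3]])
    ts = _noise_free_series(phi, 30, seed=9)
    perfect = FitResult(phi_hat=phi, model_class="VAR", n_used=30)
    assert prediction_error(perfect, ts) == pytest.approx(0.0, abs=1e-25)
    zero = FitResult(phi_hat=np.zeros((2, 2)), model_class="VAR", n_used=30)
    assert prediction_error(zero, ts) == pytest.approx(np.mean(ts.values[1:] ** 2))


def test_prediction_error_floor_is_mean_noise_variance(var_truth):
    from arvarsim import FitResult

    test = simulate_var(var_truth, 50_000, burn_in=100, seed=10)
    true_fit = FitResult(phi_hat=var_truth.phi, model_class="VAR", n_used=500)
    pe = prediction_error(true_fit, test)
    assert pe == pytest.approx(np.mean(var_truth.noise_vars), rel=0.05)


def test_correct_specification_dominance_light(ar_truth):
    # truth is AR (O = 0): the AR fit cannot lose on average
    ss = np.random.SeedSequence(123)
    ee_ar, ee_var = [], []
    for child in ss.spawn(200):
        ts = simulate_var(ar_truth, 40, burn_in=50, seed=child)
        ee_ar.append(estimation_error(fit_ar(ts), ar_truth))
        ee_var.append(estimation_error(fit_var(ts), ar_truth))
    assert np.mean(ee_ar) <= np.mean(ee_var) + 1e-3


# ---------------------------------------------------------------------------
# property tests

@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_simulation_is_pure_function_of_seed(seed):
    model = VARModel(phi=np.diag([0.3, 0.5]), noise_vars=[1.0, 0.5])
    a = simulate_var(model, 50, burn_in=10, seed=seed)
    b = simulate_var(model, 50, burn_in=10, seed=seed)
    np.testing.assert_array_equal(a.values, b.values)


@given(st.floats(-0.95, 0.95), st.floats(-0.2, 0.2))
@settings(max_examples=30, deadline=None)
def test_characteristics_of_equal_entry_matrix(d, o):
    phi = np.full((4, 4), o)
    np.fill_diagonal(phi, d)
    c = characteristics(phi)
    assert c.D == pytest.approx(abs(d))
    assert c.O == pytest.approx(abs(o))


# ---------------------------------------------------------------------------
# plain-text round trips

def test_matrix_and_series_round_trip(tmp_path, var_truth):
    mpath = tmp_path / "phi.csv"
    write_matrix_csv(mpath, var_truth.phi)
    np.testing.assert_array_equal(read_matrix_csv(mpath), var_truth.phi)

    ts = simulate_var(var_truth, 25, seed=12)
    spath = tmp_path / "series.csv"
    write_series_csv(spath, ts)
    header = spath.read_text().splitlines()[0]
    assert header == ",".join(f"V{i+1}" for i in range(6))
    back = read_series_csv(spath)
    np.testing.assert_allclose(back.values, ts.values, rtol=1e-15)
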