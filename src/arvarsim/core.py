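"""Define, simulate and estimate AR(1)/VAR(1) processes.

A VAR(1) process on p variables evolves as

    x_t = Phi x_{t-1} + eps_t,   eps_t ~ N(0, diag(noise_vars)),

with a p x p lag-1 coefficient matrix Phi whose diagonal entries are the
autoregressive effects and whose off-diagonal entries are the cross-lagged
effects. The AR(1) model is the special case with a diagonal Phi. The
process is stationary iff every eigenvalue of Phi lies strictly inside the
unit circle.

Two scalar characteristics summarise a coefficient matrix:

    D = mean(|Phi_ii|)            (size of autoregressive effects)
    O = mean(|Phi_ij|, i != j)    (size of cross-lagged effects)

Estimation here is per-equation ordinary least squares of x_t on x_{t-1};
series are simulated zero-mean and fitted without an intercept by default
(an ``intercept=True`` switch exists for non-centred data; the intercept is
never part of the estimation error). Estimation error is the mean squared
deviation of the fitted coefficient matrix from the true one over all p^2
entries — for AR fits the structural zeros on the off-diagonal enter as
(0 - Phi_ij)^2. Prediction error is the grand-mean squared one-step-ahead
error on an independent test series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "VARModel", "TimeSeries", "FitResult", "Characteristics",
    "InvalidMatrixError", "StationarityError", "SingularDesignError",
    "is_stationary", "characteristics", "simulate_var",
    "fit_var", "fit_ar", "estimation_error", "prediction_error",
    "read_matrix_csv", "write_matrix_csv",
]

# condition-number threshold above which a lagged design is treated as singular
COND_LIMIT = 1e12


class InvalidMatrixError(ValueError):
    """Input is not a finite square matrix."""


class StationarityError(ValueError):
    """Coefficient matrix has an eigenvalue with modulus >= 1."""


class SingularDesignError(np.linalg.LinAlgError):
    """Lagged design matrix is (numerically) rank deficient."""

    def __init__(self, msg: str, n_used: int | None = None, p: int | None = None):
        super().__init__(msg)
        self.n_used = n_used
        self.p = p


class Characteristics(NamedTuple):
    """D-O summary of a coefficient matrix."""

    D: float
    O: float


def _as_square(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise InvalidMatrixError(f"expected a square matrix, got shape {phi.shape}")
    if not np.all(np.isfinite(phi)):
        raise InvalidMatrixError("matrix contains non-finite entries")
    return phi


def is_stationary(phi) -> bool:
    """True iff the spectral radius of ``phi`` is strictly below 1."""
    phi = _as_square(phi)
    return bool(np.max(np.abs(np.linalg.eigvals(phi))) < 1.0)


def characteristics(phi) -> Characteristics:
    """Mean absolute diagonal (D) and mean absolute off-diagonal (O) of ``phi``."""
    phi = _as_square(phi)
    p = phi.shape[0]
    a = np.abs(phi)
    diag = np.trace(a) / p
    if p == 1:
        return Characteristics(float(diag), 0.0)
    off = (a.sum() - np.trace(a)) / (p * (p - 1))
    return Characteristics(float(diag), float(off))


@dataclass(frozen=True)
class VARModel:
    """True data-generating VAR(1) process.

    Parameters
    ----------
    phi : (p, p) array
        Lag-1 coefficient matrix; must be stationary.
    noise_vars : (p,) array
        Innovation variances (the error covariance is diagonal).
    model_id : str, optional
        Label carried through experiment outputs.
    """

    phi: np.ndarray
    noise_vars: np.ndarray
    model_id: str = ""

    def __post_init__(self):
        phi = _as_square(self.phi)
        nv = np.asarray(self.noise_vars, dtype=float).ravel()
        if nv.shape[0] != phi.shape[0]:
            raise ValueError("noise_vars length must match phi dimension")
        if np.any(nv <= 0) or not np.all(np.isfinite(nv)):
            raise ValueError("noise_vars must be strictly positive and finite")
        if not is_stationary(phi):
            raise StationarityError("phi has an eigenvalue with |lambda| >= 1")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "noise_vars", nv)

    @property
    def p(self) -> int:
        return self.phi.shape[0]

    @property
    def characteristics(self) -> Characteristics:
        return characteristics(self.phi)


@dataclass(frozen=True)
class TimeSeries:
    """Zero-mean multivariate series; row t is time point t."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-d (n, p) array")
        if v.shape[0] < 2:
            raise ValueError(f"need n >= 2 time points, got {v.shape[0]}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def head(self, n: int) -> "TimeSeries":
        """First ``n`` rows (prefix design of the experiment)."""
        return TimeSeries(self.values[:n])

    def to_frame(self):
        import pandas as pd

        cols = [f"V{i + 1}" for i in range(self.p)]
        return pd.DataFrame(self.values, columns=cols)


@dataclass(frozen=True)
class FitResult:
    """Fitted lag-1 coefficient matrix.

    ``model_class`` is "AR" (diagonal fit, off-diagonals structurally zero)
    or "VAR" (full matrix). ``intercept`` is all-zero unless intercept
    fitting was requested.
    """

    phi_hat: np.ndarray
    model_class: str
    n_used: int
    intercept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        phi = _as_square(self.phi_hat)
        object.__setattr__(self, "phi_hat", phi)
        if self.model_class not in ("AR", "VAR"):
            raise ValueError("model_class must be 'AR' or 'VAR'")
        ic = self.intercept
        ic = np.zeros(phi.shape[0]) if ic is None else np.asarray(ic, dtype=float)
        object.__setattr__(self, "intercept", ic)

    @property
    def p(self) -> int:
        return self.phi_hat.shape[0]

    def predict(self, lagged: np.ndarray) -> np.ndarray:
        """One-step-ahead predictions for rows of ``lagged``."""
        return np.asarray(lagged) @ self.phi_hat.T + self.intercept

    def summary(self) -> str:
        lines = [
            f"{self.model_class}(1) least-squares fit",
            f"  variables: {self.p}   observations used: {self.n_used}",
            "  phi_hat:",
        ]
        for row in self.phi_hat:
            lines.append("    " + "  ".join(f"{v: .4f}" for v in row))
        return "\n".join(lines)


def simulate_var(model: VARModel, n: int, burn_in: int = 100, seed=None) -> TimeSeries:
    """Simulate ``n`` observations of a stationary VAR(1) process.

    The recursion starts from the zero state, runs ``burn_in + n`` steps with
    independent Gaussian innovations, and discards the first ``burn_in``
    steps. Identical (model, n, burn_in, seed) give bit-identical output.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a Generator.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rng = np.random.default_rng(seed)
    p = model.p
    total = burn_in + n
    eps = rng.standard_normal((total, p)) * np.sqrt(model.noise_vars)
    out = np.empty((total, p))
    phi = model.phi
    x = np.zeros(p)
    for t in range(total):
        x = phi @ x + eps[t]
        out[t] = x
    return TimeSeries(out[burn_in:])


def _check_min_n(n: int, min_n: int, what: str):
    if n < min_n:
        raise ValueError(f"{what} requires n >= {min_n}, got {n}")


def fit_var(ts: TimeSeries, intercept: bool = False, on_singular: str = "raise") -> FitResult:
    """Per-equation OLS fit of the full VAR(1) coefficient matrix.

    Solves the normal equations of the regression of x_t on x_{t-1}
    (t = 2..n). ``on_singular`` controls behaviour when the lagged design has
    condition number above ``COND_LIMIT``: "raise" (default) raises
    :class:`SingularDesignError`, "pinv" falls back to the pseudo-inverse.
    """
    v = ts.values
    n, p = v.shape
    _check_min_n(n, p + 1, "VAR fit")
    X = v[:-1]
    Y = v[1:]
    if intercept:
        X = np.hstack([np.ones((n - 1, 1)), X])
    G = X.T @ X
    if np.linalg.cond(G) > COND_LIMIT:
        if on_singular == "pinv":
            B = np.linalg.pinv(X) @ Y
        else:
            raise SingularDesignError(
                f"lagged design is numerically singular (n={n}, p={p})",
                n_used=n, p=p,
            )
    else:
        B = np.linalg.solve(G, X.T @ Y)
    if intercept:
        const, coef = B[0], B[1:].T
    else:
        const, coef = np.zeros(p), B.T
    return FitResult(phi_hat=coef, model_class="VAR", n_used=n, intercept=const)


def fit_ar(ts: TimeSeries, intercept: bool = False) -> FitResult:
    """Univariate OLS fit of each diagonal entry; off-diagonals exactly zero."""
    v = ts.values
    n, p = v.shape
    _check_min_n(n, 3, "AR fit")
    x = v[:-1]
    y = v[1:]
    if intercept:
        xm = x.mean(axis=0)
        ym = y.mean(axis=0)
        xc, yc = x - xm, y - ym
    else:
        xm = ym = np.zeros(p)
        xc, yc = x, y
    # a constant lagged column (zero lagged variance) is unidentifiable
    varx = np.var(x, axis=0)
    bad = varx <= COND_LIMIT ** -1 * np.maximum(np.mean(x ** 2, axis=0), 1.0)
    if np.any(bad):
        raise SingularDesignError(
            f"constant lagged column(s) {np.flatnonzero(bad).tolist()} in AR fit",
            n_used=n, p=p,
        )
    sxx = np.einsum("ti,ti->i", xc, xc)
    slope = np.einsum("ti,ti->i", xc, yc) / sxx
    const = ym - slope * xm
    return FitResult(
        phi_hat=np.diag(slope), model_class="AR", n_used=n,
        intercept=const if intercept else np.zeros(p),
    )


def estimation_error(fit: FitResult, truth: VARModel) -> float:
    """Mean squared deviation of phi_hat from the true Phi over all p^2 entries."""
    if fit.p != truth.p:
        raise ValueError(f"dimension mismatch: fit p={fit.p}, truth p={truth.p}")
    return float(np.mean((fit.phi_hat - truth.phi) ** 2))


def prediction_error(fit: FitResult, test: TimeSeries) -> float:
    """Grand-mean squared one-step-ahead error on an independent test series."""
    if fit.p != test.p:
        raise ValueError(f"dimension mismatch: fit p={fit.p}, test p={test.p}")
    resid = test.values[1:] - fit.predict(test.values[:-1])
    return float(np.mean(resid ** 2))


def write_matrix_csv(path, mat) -> None:
    """Write a matrix (or vector) as plain CSV, round-trip exact to 15+ digits."""
    np.savetxt(path, np.atleast_2d(np.asarray(mat, dtype=float)),
               delimiter=",", fmt="%.17g")


def read_matrix_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))


def write_series_csv(path, ts: TimeSeries) -> None:
    """Export a simulated series as CSV with header V1..Vp."""
    header = ",".join(f"V{i + 1}" for i in range(ts.p))
    np.savetxt(path, ts.values, delimiter=",", fmt="%.17g",
               header=header, comments="")


def read_series_csv(path) -> TimeSeries:
    return TimeSeries(np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2))
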