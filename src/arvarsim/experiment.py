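"""Monte-Carlo error curves over sample size and crossover summaries.

For one true VAR model the experiment simulates ``reps`` independent
training series of length max(n_grid) plus one independent test series per
replicate, then fits both the AR(1) and the VAR(1) model on the *prefix* of
the first n observations for every n on the grid (the same series is reused
across n, as in a researcher collecting more data). Four error curves
result, each averaged over replicates with its replicate SD:

    EE_AR(n), EE_VAR(n)   estimation error (MSE of coefficients vs truth)
    PE_AR(n), PE_VAR(n)   prediction error (test-set one-step MSE)

The crossover sample sizes are
    n_e = first n with EE_AR > EE_VAR   (VAR starts to win in estimation)
    n_p = first n with PE_AR > PE_VAR   (VAR starts to win in prediction)
    n_gap = n_e - n_p,
censored when a pair of curves never crosses on the grid.

Implementation note: prefix OLS fits reuse cumulative Gram matrices
(running sums of x_{t-1} x_{t-1}' and x_{t-1} x_t'), so the full n-grid
costs one pass over the series plus a p x p solve per grid point, and
test-set prediction error is evaluated from the test Gram matrices rather
than by forming residuals per grid point. Equivalence with the direct
`fit_var`/`prediction_error` route is covered by tests.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import COND_LIMIT, VARModel, simulate_var

__all__ = [
    "ExperimentConfig", "ErrorCurves", "CrossingSummary",
    "run_model_experiment", "replicate_seeds",
    "crossing_n", "crossing_summary", "summarize_collection",
    "weighted_median", "weighted_quantile",
]

METRICS = ("EE_AR", "EE_VAR", "PE_AR", "PE_VAR")


@dataclass(frozen=True)
class ExperimentConfig:
    """Replication design for one error-curve experiment.

    Defaults follow the full-scale design: n on {8, ..., 500}, 100
    replications, test length 2000, burn-in 100.
    """

    n_grid: tuple = tuple(range(8, 501))
    reps: int = 100
    n_test: int = 2000
    burn_in: int = 100
    master_seed: int = 0
    keep_replicates: bool = False
    persistence: int = 1  # consecutive grid points a crossing must hold

    def __post_init__(self):
        grid = tuple(int(n) for n in self.n_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("n_grid must be non-empty and strictly ascending")
        if grid[0] < 3:
            raise ValueError("n_grid minimum must be >= 3")
        if self.reps < 2:
            raise ValueError("reps must be >= 2 (replicate SD undefined otherwise)")
        if self.n_test < 2:
            raise ValueError("n_test must be >= 2")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        object.__setattr__(self, "n_grid", grid)


@dataclass(frozen=True)
class ErrorCurves:
    """Replicate-averaged error curves for one true model.

    ``mean``/``sd`` map metric name -> array aligned with ``n_grid``; grid
    points where no replicate produced a valid fit are NaN and flagged in
    ``unfittable``. ``n_reps_used`` counts valid replicates per point.
    ``replicates`` (optional) holds the raw reps x len(n_grid) arrays.
    """

    model_id: str
    D: float
    O: float
    n_grid: tuple
    mean: dict
    sd: dict
    n_reps_used: dict
    unfittable: dict
    replicates: Optional[dict] = None

    def to_frame(self):
        """Long-format table: model_id, n, metric, mean, sd, n_reps_used."""
        import pandas as pd

        rows = []
        for metric in METRICS:
            for i, n in enumerate(self.n_grid):
                rows.append({
                    "model_id": self.model_id, "n": n, "metric": metric,
                    "mean": self.mean[metric][i], "sd": self.sd[metric][i],
                    "n_reps_used": int(self.n_reps_used[metric][i]),
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossingSummary:
    """Crossover sample sizes for one model; None marks censoring."""

    model_id: str
    D: float
    O: float
    n_e: Optional[int]
    n_p: Optional[int]

    @property
    def n_gap(self) -> Optional[int]:
        if self.n_e is None or self.n_p is None:
            return None
        return self.n_e - self.n_p


def _model_index(model: VARModel, model_index: Optional[int]) -> int:
    if model_index is not None:
        return int(model_index)
    return zlib.crc32(model.model_id.encode()) & 0x7FFFFFFF


def replicate_seeds(cfg: ExperimentConfig, model_index: int, rep: int):
    """(train, test) seed sequences for one replicate of one model.

    The hierarchy master_seed -> model -> replicate -> (train, test) makes
    every replicate reproducible in isolation and models embarrassingly
    parallel.
    """
    ss = np.random.SeedSequence(
        entropy=cfg.master_seed, spawn_key=(int(model_index), int(rep)))
    return ss.spawn(2)


def _prefix_fits(x: np.ndarray, n_grid, p: int):
    """Cumulative-Gram OLS for every prefix length on the grid.

    Returns (phi_var, phi_ar, ok_var, ok_ar): phi arrays of shape
    (len(n_grid), p, p) with NaN where unfittable.
    """
    T = x.shape[0]
    xs, ys = x[:-1], x[1:]
    outer = np.einsum("ti,tj->tij", xs, xs)
    cross = np.einsum("ti,tj->tij", xs, ys)
    S_xx = np.cumsum(outer, axis=0)
    S_xy = np.cumsum(cross, axis=0)

    m = len(n_grid)
    phi_var = np.full((m, p, p), np.nan)
    phi_ar = np.full((m, p, p), np.nan)
    ok_var = np.zeros(m, dtype=bool)
    ok_ar = np.zeros(m, dtype=bool)
    min_var_n = p + 2  # minimum-n rule: below this the design is too thin
    for i, n in enumerate(n_grid):
        if n > T:
            continue
        G = S_xx[n - 2]
        C = S_xy[n - 2]
        if n >= min_var_n:
            try:
                if np.linalg.cond(G) <= COND_LIMIT:
                    phi_var[i] = np.linalg.solve(G, C).T
                    ok_var[i] = True
            except np.linalg.LinAlgError:
                pass
        if n >= 3:
            d = np.diag(G)
            if np.all(d > 0) and np.max(d) / np.min(d) <= COND_LIMIT:
                phi_ar[i] = np.diag(np.diag(C) / d)
                ok_ar[i] = True
    return phi_var, phi_ar, ok_var, ok_ar


def _pe_from_grams(phi: np.ndarray, Txx: np.ndarray, Txy: np.ndarray,
                   tr_yy: float, denom: float) -> float:
    # ||y - Phi x||^2 summed over test pairs, expanded in Gram matrices
    sse = tr_yy - 2.0 * np.sum(phi * Txy.T) + np.sum((phi @ Txx) * phi)
    return max(sse / denom, 0.0)


def run_model_experiment(model: VARModel, cfg: ExperimentConfig,
                         model_index: Optional[int] = None) -> ErrorCurves:
    """Run the full replication design for one true model.

    Per replicate: simulate one training series of length max(n_grid) and
    one independent test series of length n_test, fit AR and VAR on every
    prefix n of the grid, and record estimation error against ``model`` and
    prediction error on the test series. Fits violating the minimum-n rule
    or with a numerically singular design are flagged unfittable and
    excluded from that grid point's mean.
    """
    idx = _model_index(model, model_index)
    logger = logging.getLogger("arvarsim")
    p = model.p
    grid = cfg.n_grid
    n_max = grid[-1]
    m = len(grid)
    raw = {metric: np.full((cfg.reps, m), np.nan) for metric in METRICS}
    phi_true = model.phi

    log_seeds = logger.isEnabledFor(logging.DEBUG)
    for r in range(cfg.reps):
        train_ss, test_ss = replicate_seeds(cfg, idx, r)
        if log_seeds:
            logger.debug("model %s idx=%d rep=%d train_key=%s test_key=%s",
                         model.model_id, idx, r, train_ss.spawn_key,
                         test_ss.spawn_key)
        train = simulate_var(model, n_max, cfg.burn_in, seed=train_ss)
        test = simulate_var(model, cfg.n_test, cfg.burn_in, seed=test_ss)
        xs, ys = test.values[:-1], test.values[1:]
        Txx = xs.T @ xs
        Txy = xs.T @ ys
        tr_yy = float(np.sum(ys ** 2))
        denom = float(xs.shape[0] * p)

        phi_var, phi_ar, ok_var, ok_ar = _prefix_fits(train.values, grid, p)
        ee_var = np.mean((phi_var - phi_true) ** 2, axis=(1, 2))
        ee_ar = np.mean((phi_ar - phi_true) ** 2, axis=(1, 2))
        raw["EE_VAR"][r, ok_var] = ee_var[ok_var]
        raw["EE_AR"][r, ok_ar] = ee_ar[ok_ar]
        for i in range(m):
            if ok_var[i]:
                raw["PE_VAR"][r, i] = _pe_from_grams(phi_var[i], Txx, Txy, tr_yy, denom)
            if ok_ar[i]:
                raw["PE_AR"][r, i] = _pe_from_grams(phi_ar[i], Txx, Txy, tr_yy, denom)

    mean, sd, used, unfit = {}, {}, {}, {}
    for metric in METRICS:
        a = raw[metric]
        cnt = np.sum(~np.isnan(a), axis=0)
        with warnings.catch_warnings():
            # all-NaN columns are expected below the minimum-n rule
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.where(cnt > 0, np.nanmean(a, axis=0), np.nan)
            s = np.where(cnt > 1, np.nanstd(a, axis=0, ddof=1), np.nan)
        mean[metric] = mu
        sd[metric] = s
        used[metric] = cnt
        unfit[metric] = cnt == 0
    d, o = model.characteristics
    return ErrorCurves(
        model_id=model.model_id, D=d, O=o, n_grid=grid,
        mean=mean, sd=sd, n_reps_used=used, unfittable=unfit,
        replicates=raw if cfg.keep_replicates else None,
    )


def crossing_n(a: Sequence[float], b: Sequence[float], n_grid: Sequence[int],
               persistence: int = 1) -> Optional[int]:
    """Smallest n on the grid where a(n) > b(n) strictly; None if never.

    Grid points where either curve is NaN (unfittable) are skipped. With
    ``persistence`` > 1 the strict inequality must hold at that point and
    the following persistence-1 valid grid points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) != len(n_grid):
        raise ValueError("sequences and n_grid must share one length")
    valid = ~(np.isnan(a) | np.isnan(b))
    idx = np.flatnonzero(valid)
    above = a[idx] > b[idx]
    for j, i in enumerate(idx):
        if all(above[j:j + persistence]) and j + persistence <= len(idx):
            return int(n_grid[i])
    return None


def crossing_summary(curves: ErrorCurves, persistence: int = 1,
                     use_replicates: bool = False) -> CrossingSummary:
    """Locate n_e and n_p for one model's curves.

    Default: crossings of the replicate-averaged curves (the expected-error
    reading). With ``use_replicates=True`` the crossing is located per
    replicate and the median over replicates is reported (requires curves
    built with ``keep_replicates=True``).
    """
    if use_replicates:
        if curves.replicates is None:
            raise ValueError("per-replicate crossings need keep_replicates=True")
        def med_cross(ka, kb):
            vals = [crossing_n(curves.replicates[ka][r], curves.replicates[kb][r],
                               curves.n_grid, persistence)
                    for r in range(curves.replicates[ka].shape[0])]
            vals = [v for v in vals if v is not None]
            return int(np.median(vals)) if vals else None
        n_e = med_cross("EE_AR", "EE_VAR")
        n_p = med_cross("PE_AR", "PE_VAR")
    else:
        n_e = crossing_n(curves.mean["EE_AR"], curves.mean["EE_VAR"],
                         curves.n_grid, persistence)
        n_p = crossing_n(curves.mean["PE_AR"], curves.mean["PE_VAR"],
                         curves.n_grid, persistence)
    return CrossingSummary(model_id=curves.model_id, D=curves.D, O=curves.O,
                           n_e=n_e, n_p=n_p)


def weighted_quantile(values, weights, q: float) -> float:
    """Weighted quantile by lower interpolation on the weighted empirical CDF:
    the smallest value whose cumulative weight reaches q."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    cum /= cum[-1]
    i = int(np.searchsorted(cum, q, side="left"))
    return float(v[order][min(i, v.size - 1)])


def weighted_median(values, weights) -> float:
    return weighted_quantile(values, weights, 0.5)


def _weighted_moments(x, w):
    w = w / np.sum(w)
    mu = float(np.sum(w * x))
    m2 = float(np.sum(w * (x - mu) ** 2))
    m3 = float(np.sum(w * (x - mu) ** 3))
    return mu, m2, m3


def _weighted_corr(x, y, w) -> Optional[float]:
    w = w / np.sum(w)
    mx = np.sum(w * x)
    my = np.sum(w * y)
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return None
    return float(np.sum(w * (x - mx) * (y - my)) / math.sqrt(vx * vy))


def summarize_collection(summaries: Sequence[CrossingSummary], weights=None,
                         gap_bin_width: float = 10.0) -> dict:
    """Weighted distribution report over a collection of crossing summaries.

    Censored entries (missing n_e or n_p) are excluded, with their counts
    reported; weights are renormalized over the relevant non-censored set.
    The n_gap histogram uses bins of ``gap_bin_width`` centred on zero, so
    "mode at zero" is a well-defined statement.
    """
    n = len(summaries)
    if n == 0:
        raise ValueError("empty collection")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)

    has_ne = np.array([s.n_e is not None for s in summaries])
    has_gap = np.array([s.n_gap is not None for s in summaries])
    report = {
        "n_models": n,
        "n_censored_n_e": int(np.sum(~has_ne)),
        "n_censored_n_p": int(sum(s.n_p is None for s in summaries)),
        "n_censored_n_gap": int(np.sum(~has_gap)),
    }
    if not np.any(has_ne):
        raise ValueError("all models censored for n_e")
    ne = np.array([s.n_e for s in summaries if s.n_e is not None], dtype=float)
    wne = w[has_ne]
    report["n_e_median"] = weighted_median(ne, wne)
    report["n_e_q25"] = weighted_quantile(ne, wne, 0.25)
    report["n_e_q75"] = weighted_quantile(ne, wne, 0.75)

    if np.any(has_gap):
        gap = np.array([s.n_gap for s in summaries if s.n_gap is not None], float)
        wg = w[has_gap] / np.sum(w[has_gap])
        mu, m2, m3 = _weighted_moments(gap, wg)
        report["n_gap_mean"] = mu
        report["n_gap_median"] = weighted_median(gap, wg)
        report["n_gap_skewness"] = 0.0 if m2 == 0 else m3 / m2 ** 1.5
        # histogram on width-w bins centred at integer multiples of w,
        # so one bin center sits exactly at 0
        w_bin = float(gap_bin_width)
        k_lo = math.floor(gap.min() / w_bin + 0.5)
        k_hi = math.floor(gap.max() / w_bin + 0.5)
        edges = (np.arange(k_lo, k_hi + 2) - 0.5) * w_bin
        hist, edges = np.histogram(gap, bins=edges, weights=wg)
        imax = int(np.argmax(hist))
        report["n_gap_hist"] = {"edges": edges.tolist(), "mass": hist.tolist()}
        report["n_gap_mode_bin"] = (float(edges[imax]), float(edges[imax + 1]))
        report["n_gap_mode_center"] = float((edges[imax] + edges[imax + 1]) / 2)
        d = np.array([s.D for s in summaries if s.n_gap is not None])
        o = np.array([s.O for s in summaries if s.n_gap is not None])
        ne_g = np.array([s.n_e for s in summaries if s.n_gap is not None], float)
        report["corr_n_gap_D"] = _weighted_corr(gap, d, wg)
        report["corr_n_gap_O"] = _weighted_corr(gap, o, wg)
        report["corr_n_gap_n_e"] = _weighted_corr(gap, ne_g, wg)
    return report
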