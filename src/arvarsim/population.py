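"""Synthetic multilevel population over stationary VAR(1) models.

Real intensive-longitudinal studies fit a mixed (multilevel) VAR model:
every person shares a fixed-effects coefficient matrix and deviates from it
by person-level random effects. This module plays the role of such a fitted
mixed model as a *sampling distribution over true VAR models*: each draw is
one synthetic "person".

A draw perturbs the fixed-effects matrix entrywise with Gaussian random
effects. On top of the entrywise effects, each draw carries two lognormal
person-level scale factors — one for the diagonal (autoregressive) block and
one for the off-diagonal (cross-lagged) block — that multiply the
random-effect standard deviations. The scale mixture makes the random
effects heavy-tailed across persons, which is what spreads the sampled
models over a wide range of the D (mean absolute diagonal) and O (mean
absolute off-diagonal) characteristics; with purely Gaussian entrywise
effects the *mean* of 30 absolute off-diagonal entries concentrates tightly
and the population would collapse onto a sliver of the D-O plane. Setting
``scale_log_sd=(0, 0)`` switches the mixture off.

Draws are rejection-sampled to stationarity (spectral radius < 1), and
innovation variances are lognormal per variable.

For the stratified simulation design the sampled models are binned on a
k x k grid (default 15 x 15) spanning the observed D-O ranges; only cells
that a pilot sample actually reaches are retained, and each retained cell is
filled to a fixed count by continued sampling with overflow discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Characteristics, VARModel, characteristics, is_stationary

__all__ = [
    "MixedVARPopulation", "DOGrid",
    "PopulationInfeasibleError", "PartialFillError",
    "draw_model", "build_grid", "stratified_fill",
    "model_weight", "collection_weights", "cell_weights",
    "default_population",
]


class PopulationInfeasibleError(RuntimeError):
    """Rejection sampling failed to produce a stationary draw."""

    def __init__(self, msg: str, rejects: int):
        super().__init__(msg)
        self.rejects = rejects


class PartialFillError(RuntimeError):
    """Stratified fill ran out of budget before all cells were full."""

    def __init__(self, msg: str, underfilled: dict):
        super().__init__(msg)
        self.underfilled = underfilled


@dataclass(frozen=True)
class MixedVARPopulation:
    """Distribution over stationary VAR(1) models.

    Parameters
    ----------
    fixed_phi : (p, p) array
        Population fixed-effects coefficient matrix; must be stationary.
    re_sd : (p, p) array
        Entrywise random-effect standard deviations (independent entries).
    noise_var_law : (float, float)
        (log-mean, log-sd) of the lognormal innovation-variance law.
    scale_log_sd : (float, float)
        Log-sd of the per-draw lognormal scale factors applied to the
        diagonal-block and off-diagonal-block random effects. (0, 0)
        disables the scale mixture.
    """

    fixed_phi: np.ndarray
    re_sd: np.ndarray
    noise_var_law: tuple = (0.0, 0.3)
    scale_log_sd: tuple = (0.0, 0.0)

    def __post_init__(self):
        fp = np.asarray(self.fixed_phi, dtype=float)
        sd = np.asarray(self.re_sd, dtype=float)
        if fp.shape != sd.shape or fp.ndim != 2 or fp.shape[0] != fp.shape[1]:
            raise ValueError("fixed_phi and re_sd must be square matrices of equal shape")
        if np.any(sd < 0):
            raise ValueError("re_sd entries must be nonnegative")
        # note: fixed_phi is *not* required to be stationary here — draws are
        # rejection-sampled to stationarity, and an infeasible population
        # (e.g. identity fixed effects with zero spread) surfaces as a
        # PopulationInfeasibleError from draw_model.
        if len(self.noise_var_law) != 2 or self.noise_var_law[1] < 0:
            raise ValueError("noise_var_law must be (log-mean, log-sd >= 0)")
        if len(self.scale_log_sd) != 2 or min(self.scale_log_sd) < 0:
            raise ValueError("scale_log_sd must be a pair of nonnegative reals")
        object.__setattr__(self, "fixed_phi", fp)
        object.__setattr__(self, "re_sd", sd)
        object.__setattr__(self, "noise_var_law", (float(self.noise_var_law[0]),
                                                   float(self.noise_var_law[1])))
        object.__setattr__(self, "scale_log_sd", (float(self.scale_log_sd[0]),
                                                  float(self.scale_log_sd[1])))

    @property
    def p(self) -> int:
        return self.fixed_phi.shape[0]


def default_population(p: int = 6) -> MixedVARPopulation:
    """Default synthetic population of person-specific VAR(1) models.

    Calibrated once against the behaviour reported for multilevel VAR fits
    to experience-sampling data: 1000 draws spread over at least D in
    [0.05, 0.5]; cross-lagged size O typically near 0.08 and ranging from
    ~0.05 to above 0.12 (the scale of published person-specific fits);
    and almost no draws with O so small that the AR/VAR estimation-error
    curves would not cross by n = 500. The nonzero fixed-effect
    cross-lags (alternating signs, as positive and negative lagged
    influences mix in affect networks) are what keep O bounded away from
    zero across persons.
    """
    fixed = np.full((p, p), 0.07)
    fixed[1::2, ::2] *= -1.0
    fixed[::2, 1::2] *= -1.0
    np.fill_diagonal(fixed, 0.12)
    sd = np.full((p, p), 0.06)
    np.fill_diagonal(sd, 0.18)
    return MixedVARPopulation(
        fixed_phi=fixed,
        re_sd=sd,
        noise_var_law=(0.0, 0.3),
        scale_log_sd=(0.8, 0.5),
    )


def draw_model(pop: MixedVARPopulation, seed=None, max_rejects: int = 1000,
               model_id: str = "") -> VARModel:
    """Draw one stationary VAR model from the population.

    Rejection-samples coefficient matrices until stationary; after
    ``max_rejects`` consecutive rejections a
    :class:`PopulationInfeasibleError` is raised.
    """
    rng = np.random.default_rng(seed)
    p = pop.p
    off_mask = ~np.eye(p, dtype=bool)
    sd_d, sd_o = pop.scale_log_sd
    for attempt in range(max_rejects):
        s_diag = np.exp(rng.normal(0.0, sd_d)) if sd_d > 0 else 1.0
        s_off = np.exp(rng.normal(0.0, sd_o)) if sd_o > 0 else 1.0
        scale = np.where(off_mask, s_off, s_diag)
        phi = pop.fixed_phi + scale * pop.re_sd * rng.standard_normal((p, p))
        if is_stationary(phi):
            lm, ls = pop.noise_var_law
            noise = np.exp(rng.normal(lm, ls, size=p))
            return VARModel(phi=phi, noise_vars=noise, model_id=model_id)
    raise PopulationInfeasibleError(
        f"no stationary draw in {max_rejects} attempts", rejects=max_rejects)


@dataclass(frozen=True)
class DOGrid:
    """Equal-width binning of the D-O plane with non-empty-cell retention.

    ``d_edges``/``o_edges`` have k+1 entries; intervals are half-open
    [lo, hi) except the last, which is closed. ``retained_cells`` are the
    (d_index, o_index) pairs containing at least one pilot point.
    """

    d_edges: np.ndarray
    o_edges: np.ndarray
    retained_cells: frozenset
    assignments: tuple = ()
    degenerate_axes: tuple = ()

    @property
    def k(self) -> int:
        return len(self.d_edges) - 1

    def cell_of(self, char: Characteristics):
        """Grid cell of a (D, O) point, or None if outside the grid."""
        d_idx = _bin_index(char.D, self.d_edges)
        o_idx = _bin_index(char.O, self.o_edges)
        if d_idx is None or o_idx is None:
            return None
        return (d_idx, o_idx)


def _bin_index(x: float, edges: np.ndarray):
    if x < edges[0] or x > edges[-1]:
        return None
    # half-open [lo, hi) bins, last bin closed
    idx = int(np.searchsorted(edges, x, side="right")) - 1
    return min(idx, len(edges) - 2)


def _axis_edges(values: np.ndarray, k: int):
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        # all points identical on this axis: one degenerate interval
        return np.array([lo, lo]), True
    return np.linspace(lo, hi, k + 1), False


def build_grid(char_list: Sequence[Characteristics], k: int = 15) -> DOGrid:
    """Bin observed (D, O) points into a k x k equal-width grid and retain
    exactly the cells that contain at least one point."""
    if len(char_list) == 0:
        raise ValueError("char_list must be non-empty")
    d = np.array([c.D for c in char_list])
    o = np.array([c.O for c in char_list])
    d_edges, d_degen = _axis_edges(d, k)
    o_edges, o_degen = _axis_edges(o, k)
    degen = tuple(ax for ax, flag in (("D", d_degen), ("O", o_degen)) if flag)
    assignments = []
    retained = set()
    for di, oi in zip(d, o):
        cell = (_bin_index(di, d_edges), _bin_index(oi, o_edges))
        assignments.append(cell)
        retained.add(cell)
    return DOGrid(d_edges=d_edges, o_edges=o_edges,
                  retained_cells=frozenset(retained),
                  assignments=tuple(assignments),
                  degenerate_axes=degen)


def stratified_fill(pop: MixedVARPopulation, grid: DOGrid, per_cell: int = 100,
                    seed=None, budget: int = 2_000_000,
                    on_exhausted: str = "raise") -> list:
    """Sample until every retained grid cell holds exactly ``per_cell`` models.

    Draws landing in already-full or non-retained cells are discarded, so
    every cell contributes the same number of models. If ``budget`` draws
    are exhausted first, the default raises :class:`PartialFillError`
    (listing underfilled cells and their counts);
    ``on_exhausted="drop"`` instead drops every cell that did not fill
    completely — cells a pilot fluke retained but the population all but
    never revisits — and returns the complete cells only.
    """
    if on_exhausted not in ("raise", "drop"):
        raise ValueError("on_exhausted must be 'raise' or 'drop'")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(ss)
    counts = {cell: 0 for cell in grid.retained_cells}
    out = []
    need = len(grid.retained_cells) * per_cell
    for k in range(budget):
        model = draw_model(pop, seed=rng, model_id=f"m{len(out):05d}")
        cell = grid.cell_of(model.characteristics)
        if cell is None or cell not in counts or counts[cell] >= per_cell:
            continue
        counts[cell] += 1
        out.append(model)
        if len(out) == need:
            return out
    under = {cell: c for cell, c in counts.items() if c < per_cell}
    if on_exhausted == "drop":
        import logging

        logging.getLogger("arvarsim").warning(
            "dropping %d underfilled D-O cell(s) after %d draws: %s",
            len(under), budget, sorted(under))
        kept = [m for m in out
                if grid.cell_of(m.characteristics) not in under]
        # re-label so model ids stay dense and deterministic
        return [VARModel(phi=m.phi, noise_vars=m.noise_vars,
                         model_id=f"m{i:05d}") for i, m in enumerate(kept)]
    raise PartialFillError(
        f"budget of {budget} draws exhausted with {len(under)} underfilled cells",
        underfilled=under)


def _log_marginal_density(delta: np.ndarray, sd: np.ndarray, scale_log_sd: float,
                          quad_points: int = 31) -> float:
    """Log density of one block of entrywise deviations under the
    scale-mixture law: entries are N(0, (s * sd)^2) given a shared lognormal
    scale s, integrated out by Gauss-Hermite quadrature."""
    delta = delta.ravel()
    sd = sd.ravel()
    pos = sd > 0
    if np.any(~pos & (np.abs(delta) > 0)):
        return -np.inf  # zero random-effect SD cannot explain a deviation
    delta, sd = delta[pos], sd[pos]
    if delta.size == 0:
        return 0.0
    if scale_log_sd == 0:
        z = delta / sd
        return float(-0.5 * np.sum(z ** 2) - np.sum(np.log(sd))
                     - 0.5 * delta.size * np.log(2 * np.pi))
    nodes, weights = np.polynomial.hermite_e.hermegauss(quad_points)
    # s = exp(scale_log_sd * u) with u ~ N(0,1)
    log_terms = np.empty(quad_points)
    for i, u in enumerate(nodes):
        s = np.exp(scale_log_sd * u)
        z = delta / (s * sd)
        log_terms[i] = (-0.5 * np.sum(z ** 2) - delta.size * np.log(s)
                        - np.sum(np.log(sd))
                        - 0.5 * delta.size * np.log(2 * np.pi)
                        + np.log(weights[i] / np.sqrt(2 * np.pi)))
    m = np.max(log_terms)
    return float(m + np.log(np.sum(np.exp(log_terms - m))))


def model_weight(model: VARModel, pop: MixedVARPopulation,
                 collection: Sequence[VARModel], mode: str = "density") -> float:
    """Population-probability weight of ``model`` within ``collection``.

    In "density" mode the unnormalized weight is the density of the
    coefficient deviations Phi - fixed_phi under the population's
    random-effect law (product over independent entries, with the per-draw
    scale factors integrated out); weights are normalized to sum to 1 over
    the collection. "uniform" mode returns 1/len(collection) for every model.
    """
    if not any(m is model or np.array_equal(m.phi, model.phi) for m in collection):
        raise ValueError("model must be a member of collection")
    if mode == "uniform":
        return 1.0 / len(collection)
    if mode != "density":
        raise ValueError("mode must be 'density' or 'uniform'")
    logw = np.array([_log_weight(m, pop) for m in collection])
    target = _log_weight(model, pop)
    if np.isneginf(target):
        return 0.0
    w = np.exp(logw - np.max(logw[np.isfinite(logw)]))
    w[~np.isfinite(logw)] = 0.0
    return float(np.exp(target - np.max(logw[np.isfinite(logw)])) / np.sum(w))


def _log_weight(model: VARModel, pop: MixedVARPopulation) -> float:
    delta = model.phi - pop.fixed_phi
    p = pop.p
    diag_mask = np.eye(p, dtype=bool)
    ld = _log_marginal_density(delta[diag_mask], pop.re_sd[diag_mask],
                               pop.scale_log_sd[0])
    lo = _log_marginal_density(delta[~diag_mask], pop.re_sd[~diag_mask],
                               pop.scale_log_sd[1])
    return ld + lo


def cell_weights(models: Sequence[VARModel], grid: DOGrid,
                 pilot_chars: Sequence[Characteristics]) -> np.ndarray:
    """Population-probability weights via grid-cell frequencies.

    The stratified design holds every retained D-O cell at the same count,
    deliberately distorting the population; these weights undo that: each
    cell receives the fraction of an (unstratified) pilot sample that lands
    in it, shared equally by the models filling the cell. This is the
    empirical probability, under the mixed population, of the region of
    coefficient space each model represents — and unlike a product of 36
    per-entry densities it does not degenerate onto the single sampled
    model nearest the fixed effects.
    """
    counts: dict = {}
    for c in pilot_chars:
        cell = grid.cell_of(c)
        if cell is not None:
            counts[cell] = counts.get(cell, 0) + 1
    per_cell: dict = {}
    for m in models:
        cell = grid.cell_of(m.characteristics)
        per_cell[cell] = per_cell.get(cell, 0) + 1
    w = np.array([counts.get(grid.cell_of(m.characteristics), 0)
                  / per_cell[grid.cell_of(m.characteristics)]
                  for m in models], dtype=float)
    total = w.sum()
    if total == 0:
        return np.full(len(models), 1.0 / len(models))
    return w / total


def collection_weights(models: Sequence[VARModel], pop: MixedVARPopulation,
                       mode: str = "density") -> np.ndarray:
    """Normalized weights for a whole collection at once."""
    if mode == "uniform":
        return np.full(len(models), 1.0 / len(models))
    logw = np.array([_log_weight(m, pop) for m in models])
    finite = np.isfinite(logw)
    w = np.zeros(len(models))
    if np.any(finite):
        w[finite] = np.exp(logw[finite] - np.max(logw[finite]))
    total = w.sum()
    if total == 0:
        return np.full(len(models), 1.0 / len(models))
    return w / total
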