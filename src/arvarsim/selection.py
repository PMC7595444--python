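"""Model selection between AR(1) and VAR(1): minimum prediction error vs
the 1 Standard Error Rule (1SER).

Given replicate-mean prediction errors PE_AR and PE_VAR at a sample size n,
the two rules are:

* min-PE: take the model with the lower prediction error (AR on an exact
  tie — parsimony tie-break).
* 1SER: take the parsimonious AR model whenever its prediction error is not
  more than one standard error above the VAR model's; otherwise take the
  model with the lower prediction error. The standard error is the
  replicate SD of the VAR prediction error across training sets — the SD of
  a single-training-set PE is itself the standard error the rule needs. An
  alternative mode uses the SD of whichever model currently has the lower
  prediction error (the classic statistical-learning formulation).

The quality of a selection is judged by its estimation-error regret
EE_diff = EE_best - EE_sel <= 0, and the head-to-head score is
EE_comp = EE_diff(1SER) - EE_diff(min-PE): positive means the 1SER picked
the model with the lower estimation error while min-PE did not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .experiment import ErrorCurves

__all__ = [
    "SelectionOutcome", "select_min_pe", "select_1se",
    "ee_diff", "ee_comp", "compare_rules",
]

AR, VAR = "AR", "VAR"


@dataclass(frozen=True)
class SelectionOutcome:
    """Choices and regrets of both rules for one (model, n) case."""

    model_id: str
    n: int
    choice_minpe: str
    choice_1se: str
    ee_diff_minpe: float
    ee_diff_1se: float

    @property
    def ee_comp(self) -> float:
        return self.ee_diff_1se - self.ee_diff_minpe

    @property
    def disagree(self) -> bool:
        return self.choice_minpe != self.choice_1se


def _check_finite(**kwargs):
    for name, v in kwargs.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")


def select_min_pe(pe_ar: float, pe_var: float) -> str:
    """Rule 1: model with the lower prediction error; AR on an exact tie."""
    _check_finite(pe_ar=pe_ar, pe_var=pe_var)
    return AR if pe_ar <= pe_var else VAR


def select_1se(pe_ar: float, pe_var: float, sd_pe_var: float,
               sd_pe_ar: Optional[float] = None, mode: str = "var") -> str:
    """Rule 2 (1SER): AR iff PE_AR <= PE_VAR + SE (boundary inclusive).

    mode="var" (default) takes SE = sd_pe_var. mode="best" takes the SD of
    the model with the lower prediction error (requires ``sd_pe_ar``).
    """
    _check_finite(pe_ar=pe_ar, pe_var=pe_var, sd_pe_var=sd_pe_var)
    if sd_pe_var < 0:
        raise ValueError("sd_pe_var must be nonnegative")
    if mode == "var":
        se = sd_pe_var
    elif mode == "best":
        if sd_pe_ar is None:
            raise ValueError("mode='best' requires sd_pe_ar")
        _check_finite(sd_pe_ar=sd_pe_ar)
        se = sd_pe_ar if pe_ar <= pe_var else sd_pe_var
    else:
        raise ValueError("mode must be 'var' or 'best'")
    return AR if pe_ar <= pe_var + se else VAR


def ee_diff(choice: str, ee_ar: float, ee_var: float) -> float:
    """Estimation-error regret of a choice: min(EE) - EE_chosen, always <= 0."""
    if choice not in (AR, VAR):
        raise ValueError("choice must be 'AR' or 'VAR'")
    chosen = ee_ar if choice == AR else ee_var
    return min(ee_ar, ee_var) - chosen


def ee_comp(pe_ar: float, pe_var: float, sd_pe_var: float,
            ee_ar: float, ee_var: float, mode: str = "var",
            sd_pe_ar: Optional[float] = None) -> float:
    """Regret difference 1SER minus min-PE; > 0 when the 1SER chose better."""
    c1 = select_min_pe(pe_ar, pe_var)
    c2 = select_1se(pe_ar, pe_var, sd_pe_var, sd_pe_ar=sd_pe_ar, mode=mode)
    return ee_diff(c2, ee_ar, ee_var) - ee_diff(c1, ee_ar, ee_var)


def compare_rules(curves: Sequence[ErrorCurves], weights=None,
                  mode: str = "var") -> dict:
    """Head-to-head comparison of the two rules over a model collection.

    For every (model, n) with valid AR and VAR fits, both rules select a
    model from the replicate-mean prediction errors (the 1SER additionally
    uses the replicate SD of PE_VAR), and regrets are computed from the
    replicate-mean estimation errors.

    Returns a dict with:

    * ``outcomes`` — long DataFrame of per-(model, n) selections/regrets;
    * ``prop_1se_better`` — among disagreement cases only, the weighted
      proportion with EE_comp > 0 (each case weighted by its model's
      weight, uniform over n within model); None if the rules never
      disagree;
    * ``ee_comp_by_n`` — DataFrame with the weighted mean EE_comp at each
      n and the Monte-Carlo SD of that weighted mean across models;
    * ``disagreements_per_model`` — model_id -> number of n values where
      the rules disagree.
    """
    import pandas as pd

    if len(curves) == 0:
        raise ValueError("empty curve collection")
    grid = curves[0].n_grid
    for c in curves:
        if c.n_grid != grid:
            raise ValueError("all curves must share one n-grid")
    w = (np.full(len(curves), 1.0 / len(curves)) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / np.sum(w)

    rows = []
    for c, wi in zip(curves, w):
        for i, n in enumerate(grid):
            pe_ar = c.mean["PE_AR"][i]
            pe_var = c.mean["PE_VAR"][i]
            sd_var = c.sd["PE_VAR"][i]
            sd_ar = c.sd["PE_AR"][i]
            ee_ar_v = c.mean["EE_AR"][i]
            ee_var_v = c.mean["EE_VAR"][i]
            vals = (pe_ar, pe_var, sd_var, ee_ar_v, ee_var_v)
            if any(not np.isfinite(v) for v in vals):
                continue
            c1 = select_min_pe(pe_ar, pe_var)
            c2 = select_1se(pe_ar, pe_var, sd_var, sd_pe_ar=sd_ar, mode=mode)
            d1 = ee_diff(c1, ee_ar_v, ee_var_v)
            d2 = ee_diff(c2, ee_ar_v, ee_var_v)
            rows.append({
                "model_id": c.model_id, "n": n,
                "pe_ar": pe_ar, "pe_var": pe_var, "sd_pe_var": sd_var,
                "ee_ar": ee_ar_v, "ee_var": ee_var_v,
                "choice_minpe": c1, "choice_1se": c2,
                "ee_comp": d2 - d1, "weight": wi,
            })
    outcomes = pd.DataFrame(rows)
    report = {"outcomes": outcomes, "mode": mode}

    dis = outcomes[outcomes.choice_minpe != outcomes.choice_1se]
    report["n_disagreement_cases"] = int(len(dis))
    if len(dis):
        wd = dis.weight.to_numpy()
        report["prop_1se_better"] = float(
            np.sum(wd * (dis.ee_comp.to_numpy() > 0)) / np.sum(wd))
    else:
        report["prop_1se_better"] = None

    by_n = []
    for n, grp in outcomes.groupby("n"):
        wn = grp.weight.to_numpy()
        wn = wn / wn.sum()
        x = grp.ee_comp.to_numpy()
        mu = float(np.sum(wn * x))
        mc_sd = float(np.sqrt(np.sum(wn ** 2 * (x - mu) ** 2)))
        by_n.append({"n": int(n), "ee_comp_mean": mu, "ee_comp_mc_sd": mc_sd,
                     "n_models": int(len(grp))})
    report["ee_comp_by_n"] = pd.DataFrame(by_n).sort_values("n", ignore_index=True)

    counts = dis.groupby("model_id").size() if len(dis) else {}
    report["disagreements_per_model"] = {
        c.model_id: int(counts.get(c.model_id, 0)) for c in curves}
    return report
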