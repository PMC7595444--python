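"""End-to-end study orchestration: population -> experiment -> selection.

`Study` is the modelling object for the whole simulation study: it is built
from a `StudyConfig` (or a YAML/JSON config file), and `run()` returns a
`StudyResults` carrying the sampled model collection, the error curves, the
crossover summaries and the selection-rule comparison, with `summary()` and
`save()` for reporting. `run_pipeline` is the file-based entry point used
by the CLI; it writes every table as long-format CSV plus a JSON run
manifest, and can resume any single stage from prior outputs.

The default configuration is a scaled-down study (pilot 2000, two models
per retained cell for roughly 150-190 models, n on {8, 10, ..., 500}, 20
replications) that a single CPU finishes in a few minutes; ``paper_scale_config``
returns the full-scale design (74-ish cells x 100 models, n on {8..500},
100 replications), which takes cluster-style patience.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import VARModel, read_matrix_csv, write_matrix_csv
from .experiment import (ErrorCurves, ExperimentConfig, METRICS,
                         crossing_summary, run_model_experiment,
                         summarize_collection, CrossingSummary)
from .population import (MixedVARPopulation, build_grid, cell_weights,
                         collection_weights, default_population, draw_model,
                         stratified_fill)
from .selection import compare_rules

logger = logging.getLogger("arvarsim")

__all__ = ["StudyConfig", "Study", "StudyResults", "run_pipeline",
           "paper_scale_config", "load_config"]

STAGES = ("sample-models", "run-curves", "crossings", "compare-rules", "report")


@dataclass(frozen=True)
class StudyConfig:
    """Complete, serialisable description of one study run."""

    p: int = 6
    fixed_phi: Optional[list] = None          # defaults to default_population
    re_sd: Optional[list] = None
    noise_var_law: tuple = (0.0, 0.3)
    scale_log_sd: tuple = (0.8, 0.9)
    pilot: int = 2000
    grid_k: int = 15
    per_cell: int = 2
    fill_budget: int = 300_000
    weight_mode: str = "cell"
    n_grid: tuple = tuple(range(8, 501, 2))
    reps: int = 20
    n_test: int = 2000
    burn_in: int = 100
    master_seed: int = 0
    se_mode: str = "var"          # 1SER standard-error reference model
    gap_bin_width: float = 10.0
    persistence: int = 1
    threads: int = 1

    def population(self) -> MixedVARPopulation:
        if self.fixed_phi is None and self.re_sd is None:
            pop = default_population(self.p)
            return MixedVARPopulation(pop.fixed_phi, pop.re_sd,
                                      self.noise_var_law, self.scale_log_sd)
        if self.fixed_phi is None or self.re_sd is None:
            raise ValueError("fixed_phi and re_sd must be given together")
        return MixedVARPopulation(np.asarray(self.fixed_phi),
                                  np.asarray(self.re_sd),
                                  self.noise_var_law, self.scale_log_sd)

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(n_grid=self.n_grid, reps=self.reps,
                                n_test=self.n_test, burn_in=self.burn_in,
                                master_seed=self.master_seed,
                                persistence=self.persistence)

    def validate(self) -> "StudyConfig":
        self.population()
        self.experiment_config()   # raises naming the offending key
        if self.pilot < 1:
            raise ValueError("pilot must be >= 1")
        if self.per_cell < 1:
            raise ValueError("per_cell must be >= 1")
        if self.grid_k < 1:
            raise ValueError("grid_k must be >= 1")
        if self.weight_mode not in ("cell", "density", "uniform"):
            raise ValueError("weight_mode must be 'cell', 'density' or 'uniform'")
        if self.se_mode not in ("var", "best"):
            raise ValueError("se_mode must be 'var' or 'best'")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def paper_scale_config(**overrides) -> StudyConfig:
    """Full-scale design: 15x15 grid filled to 100 models per retained cell,
    n on {8,...,500}, 100 replications, test length 2000."""
    base = dict(pilot=10_000, per_cell=100, n_grid=tuple(range(8, 501)),
                reps=100)
    base.update(overrides)
    return StudyConfig(**base)


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from YAML (or JSON) with schema validation."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    valid_keys = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - valid_keys
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("n_grid", "noise_var_law", "scale_log_sd"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        return StudyConfig(**raw).validate()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


@dataclass
class StudyResults:
    """Everything one study run produced, with reporting helpers."""

    config: StudyConfig
    models: list
    weights: np.ndarray
    cells: dict
    curves: list
    crossings: list
    collection_report: dict
    selection_report: dict

    def summary(self) -> str:
        rep = self.collection_report
        sel = self.selection_report
        lines = [
            "AR(1) vs VAR(1) crossover study",
            "=" * 34,
            f"models: {rep['n_models']}   retained D-O cells: {len(set(self.cells.values()))}",
            f"censored: n_e {rep['n_censored_n_e']}, n_p {rep['n_censored_n_p']}",
            f"n_e weighted median [IQR]: {rep['n_e_median']:.0f} "
            f"[{rep['n_e_q25']:.0f}, {rep['n_e_q75']:.0f}]",
        ]
        if "n_gap_median" in rep:
            lines += [
                f"n_gap weighted median: {rep['n_gap_median']:.0f}   "
                f"skewness: {rep['n_gap_skewness']:.2f}   "
                f"mode bin: {rep['n_gap_mode_bin']}",
            ]
        prop = sel.get("prop_1se_better")
        if prop is not None:
            lines.append(
                f"1SER better in {100 * prop:.1f}% of "
                f"{sel['n_disagreement_cases']} weighted disagreement cases")
        byn = sel["ee_comp_by_n"]
        pos = byn[byn.ee_comp_mean > 0]
        if len(pos):
            lines.append(
                f"mean EE_comp > 0 for n in [{int(pos.n.min())}, {int(pos.n.max())}]")
        return "\n".join(lines)

    # -- tables -----------------------------------------------------------
    def models_frame(self):
        import pandas as pd

        rows = []
        for i, (m, w) in enumerate(zip(self.models, self.weights)):
            d, o = m.characteristics
            cell = self.cells[m.model_id]
            rows.append({"model_id": m.model_id, "model_index": i,
                         "D": d, "O": o, "cell_row": cell[0],
                         "cell_col": cell[1], "weight": w})
        return pd.DataFrame(rows)

    def curves_frame(self):
        import pandas as pd

        return pd.concat([c.to_frame() for c in self.curves],
                         ignore_index=True)

    def crossings_frame(self):
        import pandas as pd

        rows = []
        for s, w in zip(self.crossings, self.weights):
            rows.append({
                "model_id": s.model_id, "D": s.D, "O": s.O,
                "n_e": s.n_e, "n_p": s.n_p, "n_gap": s.n_gap,
                "censored_n_e": s.n_e is None, "censored_n_p": s.n_p is None,
                "weight": w,
            })
        return pd.DataFrame(rows)

    # -- plots ------------------------------------------------------------
    def plot_error_curves(self, model_id: str, ax=None):
        """Diagnostic plot of the four error curves for one model."""
        import matplotlib.pyplot as plt

        curves = next(c for c in self.curves if c.model_id == model_id)
        if ax is None:
            _, ax = plt.subplots()
        n = np.array(curves.n_grid)
        for metric, style in zip(METRICS, ("k-", "r-", "k--", "r--")):
            ax.plot(n, curves.mean[metric], style, label=metric)
        ax.set_xlabel("n")
        ax.set_ylabel("MSE")
        ax.set_title(f"{model_id}: D={curves.D:.2f}, O={curves.O:.2f}")
        ax.legend()
        return ax

    def plot_ee_comp(self, ax=None):
        """Weighted mean EE_comp (with MC-SD band) as a function of n."""
        import matplotlib.pyplot as plt

        byn = self.selection_report["ee_comp_by_n"]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(byn.n, byn.ee_comp_mean, "k-")
        ax.fill_between(byn.n, byn.ee_comp_mean - byn.ee_comp_mc_sd,
                        byn.ee_comp_mean + byn.ee_comp_mc_sd, alpha=0.3)
        ax.axhline(0.0, ls=":", color="grey")
        ax.set_xlabel("n")
        ax.set_ylabel("mean EE_comp")
        return ax

    def save(self, out_dir) -> dict:
        return _write_outputs(Path(out_dir), self)


class Study:
    """The study as a fittable object: configure, then ``run()``."""

    def __init__(self, config: Optional[StudyConfig] = None, **overrides):
        if config is None:
            config = StudyConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        self.config = config.validate()

    @classmethod
    def from_yaml(cls, path) -> "Study":
        return cls(load_config(path))

    def sample_models(self):
        """Stage 1: pilot sample, D-O grid, stratified fill, weights."""
        cfg = self.config
        pop = cfg.population()
        pilot_ss = np.random.SeedSequence(entropy=cfg.master_seed, spawn_key=(0,))
        pilot_rng = np.random.default_rng(pilot_ss)
        pilot = [draw_model(pop, seed=pilot_rng) for _ in range(cfg.pilot)]
        grid = build_grid([m.characteristics for m in pilot], k=cfg.grid_k)
        logger.info("pilot %d draws -> %d retained cells",
                    cfg.pilot, len(grid.retained_cells))
        fill_ss = np.random.SeedSequence(entropy=cfg.master_seed, spawn_key=(1,))
        models = stratified_fill(pop, grid, per_cell=cfg.per_cell,
                                 seed=fill_ss, budget=cfg.fill_budget,
                                 on_exhausted="drop")
        if cfg.weight_mode == "cell":
            weights = cell_weights(models, grid,
                                   [m.characteristics for m in pilot])
        else:
            weights = collection_weights(models, pop, mode=cfg.weight_mode)
        cells = {m.model_id: grid.cell_of(m.characteristics) for m in models}
        return models, weights, cells, grid

    def run_curves(self, models: Sequence[VARModel]) -> list:
        """Stage 2: Monte-Carlo error curves for every model."""
        cfg = self.config
        ecfg = self.config.experiment_config()
        if cfg.threads != 1:
            from joblib import Parallel, delayed

            return Parallel(n_jobs=cfg.threads)(
                delayed(run_model_experiment)(m, ecfg, model_index=i)
                for i, m in enumerate(models))
        out = []
        for i, m in enumerate(models):
            logger.debug("curves for model %s (index %d)", m.model_id, i)
            out.append(run_model_experiment(m, ecfg, model_index=i))
        return out

    def run(self) -> StudyResults:
        cfg = self.config
        t0 = time.time()
        models, weights, cells, _grid = self.sample_models()
        logger.info("sampled %d models (%.1fs)", len(models), time.time() - t0)
        curves = self.run_curves(models)
        logger.info("curves done (%.1fs)", time.time() - t0)
        crossings = [crossing_summary(c, persistence=cfg.persistence)
                     for c in curves]
        collection = summarize_collection(crossings, weights,
                                          gap_bin_width=cfg.gap_bin_width)
        sel = compare_rules(curves, weights, mode=cfg.se_mode)
        logger.info("study complete (%.1fs)", time.time() - t0)
        return StudyResults(config=cfg, models=list(models), weights=weights,
                            cells=cells, curves=list(curves),
                            crossings=crossings, collection_report=collection,
                            selection_report=sel)


# ---------------------------------------------------------------------------
# file-based staged pipeline


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_outputs(out: Path, res: StudyResults) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    for m in res.models:
        write_matrix_csv(mdir / f"{m.model_id}_phi.csv", m.phi)
        write_matrix_csv(mdir / f"{m.model_id}_noise.csv", m.noise_vars)
    mf = res.models_frame()
    mf.to_csv(out / "models.csv", index=False)
    files["models.csv"] = len(mf)

    cf = res.curves_frame()
    cf.to_csv(out / "curves.csv", index=False)
    files["curves.csv"] = len(cf)

    xf = res.crossings_frame()
    xf.to_csv(out / "crossings.csv", index=False)
    files["crossings.csv"] = len(xf)

    with open(out / "collection_summary.json", "w") as fh:
        json.dump(_json_ready(res.collection_report), fh, indent=2)
    files["collection_summary.json"] = 1

    sel = res.selection_report
    sel["outcomes"].to_csv(out / "selection_outcomes.csv", index=False)
    files["selection_outcomes.csv"] = len(sel["outcomes"])
    sel["ee_comp_by_n"].to_csv(out / "ee_comp_by_n.csv", index=False)
    files["ee_comp_by_n.csv"] = len(sel["ee_comp_by_n"])
    small = {k: _json_ready(v) for k, v in sel.items()
             if k not in ("outcomes", "ee_comp_by_n")}
    with open(out / "selection_report.json", "w") as fh:
        json.dump(small, fh, indent=2)
    files["selection_report.json"] = 1
    return files


def _load_models(out: Path):
    import pandas as pd

    mf = pd.read_csv(out / "models.csv", float_precision="round_trip")
    models = []
    for _, row in mf.iterrows():
        phi = read_matrix_csv(out / "models" / f"{row.model_id}_phi.csv")
        noise = read_matrix_csv(out / "models" / f"{row.model_id}_noise.csv").ravel()
        models.append(VARModel(phi=phi, noise_vars=noise, model_id=row.model_id))
    return models, mf


def _load_curves(out: Path, cfg: StudyConfig):
    import pandas as pd

    cf = pd.read_csv(out / "curves.csv", float_precision="round_trip")
    mf = pd.read_csv(out / "models.csv", float_precision="round_trip").set_index("model_id")
    curves = []
    for model_id, grp in cf.groupby("model_id", sort=False):
        grid = tuple(sorted(grp.n.unique()))
        mean, sd, used, unfit = {}, {}, {}, {}
        for metric in METRICS:
            sub = grp[grp.metric == metric].set_index("n")
            mean[metric] = sub["mean"].reindex(grid).to_numpy()
            sd[metric] = sub["sd"].reindex(grid).to_numpy()
            used[metric] = sub["n_reps_used"].reindex(grid).fillna(0).to_numpy()
            unfit[metric] = used[metric] == 0
        row = mf.loc[model_id]
        curves.append(ErrorCurves(model_id=model_id, D=float(row.D),
                                  O=float(row.O), n_grid=grid, mean=mean,
                                  sd=sd, n_reps_used=used, unfittable=unfit))
    order = list(mf.index)
    curves.sort(key=lambda c: order.index(c.model_id))
    return curves, mf.reset_index()


def run_pipeline(config=None, out_dir="study_out", seed: Optional[int] = None,
                 stage: str = "all", threads: Optional[int] = None) -> dict:
    """Run the pipeline (or one stage of it) and write a run manifest.

    ``config`` may be a StudyConfig, a path to a YAML/JSON config, or None
    for the scaled-down defaults. ``seed``/``threads`` override the config.
    Staged runs (stage != "all") read the upstream CSVs from ``out_dir`` and
    fail with a clear error when they are missing.
    """
    if config is None:
        cfg = StudyConfig()
    elif isinstance(config, StudyConfig):
        cfg = config
    else:
        cfg = load_config(config)
    if seed is not None:
        cfg = replace(cfg, master_seed=int(seed))
    if threads is not None:
        cfg = replace(cfg, threads=int(threads))
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    study = Study(cfg)
    files: dict = {}

    def need(name):
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs upstream output {name} in {out}; "
                "run earlier stages first")

    if stage == "all":
        res = study.run()
        files = res.save(out)
    elif stage == "sample-models":
        models, weights, cells, _ = study.sample_models()
        res = StudyResults(cfg, list(models), weights, cells, [], [],
                           {"n_models": len(models)}, {})
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        for m in models:
            write_matrix_csv(mdir / f"{m.model_id}_phi.csv", m.phi)
            write_matrix_csv(mdir / f"{m.model_id}_noise.csv", m.noise_vars)
        mf = res.models_frame()
        mf.to_csv(out / "models.csv", index=False)
        files["models.csv"] = len(mf)
    elif stage == "run-curves":
        need("models.csv")
        models, _mf = _load_models(out)
        curves = study.run_curves(models)
        import pandas as pd

        cf = pd.concat([c.to_frame() for c in curves], ignore_index=True)
        cf.to_csv(out / "curves.csv", index=False)
        files["curves.csv"] = len(cf)
    elif stage == "crossings":
        need("curves.csv")
        curves, mf = _load_curves(out, cfg)
        weights = mf.weight.to_numpy()
        crossings = [crossing_summary(c, persistence=cfg.persistence)
                     for c in curves]
        rows = [{"model_id": s.model_id, "D": s.D, "O": s.O, "n_e": s.n_e,
                 "n_p": s.n_p, "n_gap": s.n_gap,
                 "censored_n_e": s.n_e is None, "censored_n_p": s.n_p is None,
                 "weight": w} for s, w in zip(crossings, weights)]
        import pandas as pd

        xf = pd.DataFrame(rows)
        xf.to_csv(out / "crossings.csv", index=False)
        files["crossings.csv"] = len(xf)
        report = summarize_collection(crossings, weights,
                                      gap_bin_width=cfg.gap_bin_width)
        with open(out / "collection_summary.json", "w") as fh:
            json.dump(_json_ready(report), fh, indent=2)
        files["collection_summary.json"] = 1
    elif stage == "compare-rules":
        need("curves.csv")
        curves, mf = _load_curves(out, cfg)
        sel = compare_rules(curves, mf.weight.to_numpy(), mode=cfg.se_mode)
        sel["outcomes"].to_csv(out / "selection_outcomes.csv", index=False)
        files["selection_outcomes.csv"] = len(sel["outcomes"])
        sel["ee_comp_by_n"].to_csv(out / "ee_comp_by_n.csv", index=False)
        files["ee_comp_by_n.csv"] = len(sel["ee_comp_by_n"])
        small = {k: _json_ready(v) for k, v in sel.items()
                 if k not in ("outcomes", "ee_comp_by_n")}
        with open(out / "selection_report.json", "w") as fh:
            json.dump(small, fh, indent=2)
        files["selection_report.json"] = 1
    elif stage == "report":
        need("collection_summary.json")
        need("selection_report.json")
        with open(out / "collection_summary.json") as fh:
            col = json.load(fh)
        with open(out / "selection_report.json") as fh:
            sel = json.load(fh)
        combined = {"collection": col, "selection": sel}
        with open(out / "summary.json", "w") as fh:
            json.dump(combined, fh, indent=2)
        files["summary.json"] = 1
    else:
        raise ValueError(f"unknown stage '{stage}'; use one of {STAGES + ('all',)}")

    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "master_seed": cfg.master_seed,
        "version": __version__,
        "stage": stage,
        "outputs": {name: {"path": str(out / name), "rows": rows}
                    for name, rows in files.items()},
        "started_unix": t_start,
        "finished_unix": time.time(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
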