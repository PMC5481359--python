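"""Experiment driver: run selector x lambda x mode grids and write result tables.

A run sweeps the configured feature selectors over the encoding and
decoding regularization grids, computes cumulative MRA-vs-M curves under
leave-one-class-out cross-validation, and writes tidy CSV outputs plus a
deterministic run manifest:

* ``curves.csv``        one row per (selector, mode, lam, M, MRA)
* ``summary.csv``       peak MRA and smallest-M-at-peak per selector/mode,
                        maximized over the lambda grid
* ``folds_<...>.csv``   per-fold detail at each selector/mode's peak setting
* ``tally_<...>.csv``   selection counts per metadata bin (when metadata
                        carries a binnable axis such as a frequency center)
* ``manifest.yaml``     config, seed, package/library versions, cell errors
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_attribute_matrix, read_trial_table, write_fold_results
from .regression import lambda_grid, normalize_attribute_rows
from .selection import selection_tally
from .simulate import SyntheticConfig, generate_dataset
from .zeroshot import loco_evaluate, mra_curve

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    output_dir: str = "results"
    seed: int = 0
    # data: either file paths or a simulation preset ("sparse" | "dense")
    attributes_path: str | None = None
    trials_path: str | None = None
    feature_meta_path: str | None = None
    simulate_preset: str | None = "sparse"
    sim_overrides: dict = field(default_factory=dict)
    # grid
    selectors: list = field(default_factory=lambda: ["corr_stability", "attr_feat_corr"])
    modes: list = field(default_factory=lambda: ["encoding", "decoding"])
    m_cap: int = 500
    m_step: int = 10
    lam_en_grid: tuple = (100.0, 1000.0, 5)
    lam_de_grid: tuple = (1.0, 10.0, 5)
    tally_by: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _load_data(cfg: ExperimentConfig):
    if cfg.trials_path is not None:
        if cfg.attributes_path is None:
            raise ValueError("trials_path given without attributes_path")
        A = read_attribute_matrix(cfg.attributes_path)
        table = read_trial_table(cfg.trials_path, cfg.feature_meta_path)
        return normalize_attribute_rows(A), table
    preset = cfg.simulate_preset or "sparse"
    if preset not in ("sparse", "dense"):
        raise ValueError(f"unknown simulation preset {preset!r}")
    sim = SyntheticConfig(seed=cfg.seed, dense_weights=(preset == "dense"),
                          **cfg.sim_overrides)
    A, table, _ = generate_dataset(sim)
    return A, table


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Execute the full grid and write result tables; returns the summary."""
    logging.getLogger("zsdecode").setLevel(cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    A, table = _load_data(cfg)
    lam_en_values = lambda_grid(*cfg.lam_en_grid)
    lam_de_values = lambda_grid(*cfg.lam_de_grid)
    grid = np.arange(cfg.m_step, cfg.m_cap + 1, cfg.m_step)
    grid = np.unique(np.concatenate([[1], grid, [cfg.m_cap]]))

    curve_rows, summary_rows, errors = [], [], []
    for selector in cfg.selectors:
        per_mode_best = {mode: None for mode in cfg.modes}
        lam_pairs = list(zip(lam_en_values, lam_de_values))
        for lam_en, lam_de in lam_pairs:
            try:
                curves = mra_curve(A, table, selector, lam_en=lam_en, lam_de=lam_de,
                                   m_cap=cfg.m_cap, m_grid=grid, modes=tuple(cfg.modes))
            except Exception as e:  # record, keep other cells running
                logger.error("grid cell failed: %s lam=(%g,%g): %s",
                             selector, lam_en, lam_de, e)
                errors.append({"selector": selector, "lam_en": float(lam_en),
                               "lam_de": float(lam_de), "error": str(e)})
                continue
            for mode, curve in curves.items():
                lam = lam_en if mode == "encoding" else lam_de
                for m, v in zip(curve.feature_counts, curve.mra_values):
                    curve_rows.append({"selector": selector, "mode": mode,
                                       "lam": float(lam), "m": int(m), "mra": float(v)})
                best = per_mode_best[mode]
                if best is None or curve.peak_mra > best["peak_mra"]:
                    per_mode_best[mode] = {"selector": selector, "mode": mode,
                                           "lam": float(lam),
                                           "lam_en": float(lam_en), "lam_de": float(lam_de),
                                           "peak_mra": curve.peak_mra,
                                           "m_at_peak": curve.m_at_peak}
        for mode, best in per_mode_best.items():
            if best is None:
                continue
            summary_rows.append({k: best[k] for k in
                                 ("selector", "mode", "lam", "peak_mra", "m_at_peak")})
            # per-fold detail + selection tally at the peak setting
            res, sels = loco_evaluate(A, table, selector, best["m_at_peak"],
                                      lam_en=best["lam_en"], lam_de=best["lam_de"],
                                      modes=(mode,), return_selections=True)
            write_fold_results(res[mode], out / f"folds_{selector}_{mode}.csv")
            if cfg.tally_by and table.feature_meta is not None \
                    and cfg.tally_by in table.feature_meta.columns:
                tally = selection_tally(sels, table.feature_meta, by=cfg.tally_by)
                tally.to_csv(out / f"tally_{selector}_{mode}.csv", index=False)

    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False,
                                    float_format="%.17g")
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.17g")
    manifest = {"config": asdict(cfg), "seed": cfg.seed,
                "versions": {"zsdecode": __version__, "numpy": np.__version__,
                             "pandas": pd.__version__},
                "errors": errors}
    with open(out / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)
    return summary
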