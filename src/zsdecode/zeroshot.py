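"""Zero-shot class ranking, rank accuracy, and leave-one-class-out evaluation.

A fold of leave-one-class-out (LOCO) cross-validation removes every trial of
one stimulus class; feature selection, normalization statistics and ridge
weights are computed from the remaining classes' trials only.  The held-out
class is then identified among all candidate classes by cosine distance:

* encoding mode -- its attribute vector is encoded to a predicted feature
  vector and compared with every class's mean feature template (training
  classes' templates from training trials; the held-out gallery template
  from its own trials, transformed with training statistics);
* decoding mode -- its mean feature vector is decoded to a predicted
  attribute vector and compared with every class's true attribute vector.

Rank accuracy RA = 100 (N - r)/(N - 1) maps the held-out class's rank r to a
percentage (100 = ranked first, 0 = last, 50 = chance), and MRA is the mean
of RA over folds.  Cumulative MRA-vs-M curves re-evaluate the models at
increasing feature budgets in a selector's rank order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .regression import (AttributeMatrix, TrialTable, DEFAULT_LAM_DE, DEFAULT_LAM_EN,
                         fit_decoder, fit_encoder, normalize_attribute_rows,
                         predict_attributes, predict_features, zscore_columns,
                         _trial_design)
from .selection import FeatureRanking, get_selector, select_top_m

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "ZeroShotResult",
    "MRACurve",
    "cosine_distance",
    "class_templates",
    "rank_class",
    "rank_accuracy",
    "loco_evaluate",
    "mra_curve",
]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 2], symmetric, scale-invariant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


def _cosine_distances_to_rows(q: np.ndarray, rows: np.ndarray) -> np.ndarray:
    nq = np.linalg.norm(q)
    nr = np.linalg.norm(rows, axis=1)
    if nq == 0 or (nr == 0).any():
        raise ValueError("cosine distance undefined for zero vector")
    return 1.0 - (rows @ q) / (nr * nq)


def class_templates(table: TrialTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean feature vectors (classes, templates matrix)."""
    classes, idx = np.unique(table.class_ids, return_inverse=True)
    sums = np.zeros((len(classes), table.n_features))
    np.add.at(sums, idx, table.features)
    counts = np.bincount(idx, minlength=len(classes)).astype(float)
    return classes, sums / counts[:, None]


def rank_class(distances, true_class) -> float:
    """Mid-rank of the true class in a candidate distance list.

    r = 1 + #(smaller) + #(tied others)/2.  Mid-ranking ties keeps
    chance-level MRA unbiased at 50.  ``distances`` is a mapping or
    pandas Series from candidate class id to distance.
    """
    if isinstance(distances, pd.Series):
        ids, vals = list(distances.index), distances.to_numpy(dtype=float)
    else:
        ids = list(distances.keys())
        vals = np.array([distances[c] for c in ids], dtype=float)
    try:
        i = ids.index(true_class)
    except ValueError:
        raise KeyError(f"true class {true_class!r} absent from candidates") from None
    d = vals[i]
    smaller = int((vals < d).sum())
    tied_others = int((vals == d).sum()) - 1
    return 1.0 + smaller + tied_others / 2.0


def rank_accuracy(r: float, n_classes: int) -> float:
    """RA = 100 (N - r)/(N - 1): 100 for rank 1, 0 for rank N."""
    if n_classes < 2:
        raise ValueError("need at least 2 candidate classes")
    if not (1 <= r <= n_classes):
        raise ValueError(f"rank {r} outside [1, {n_classes}]")
    return 100.0 * (n_classes - r) / (n_classes - 1)


@dataclass
class FoldResult:
    """One LOCO fold: held-out class, candidate distances, rank and RA."""

    held_out_class: object
    candidate_classes: list
    distances: np.ndarray
    rank: float
    ra: float
    n_train_trials: int = 0


@dataclass
class ZeroShotResult:
    """Per-fold ranks and the mean rank accuracy for one mode/setting."""

    mode: str
    per_fold: list
    mra: float
    settings: dict = field(default_factory=dict)

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"held_out_class": [f.held_out_class for f in self.per_fold],
             "rank": [f.rank for f in self.per_fold],
             "ra": [f.ra for f in self.per_fold]})


@dataclass
class MRACurve:
    """Cumulative MRA as a function of the number of features used."""

    mode: str
    feature_counts: np.ndarray
    mra_values: np.ndarray
    settings: dict = field(default_factory=dict)

    @property
    def peak_mra(self) -> float:
        return float(np.max(self.mra_values))

    @property
    def m_at_peak(self) -> int:
        """Smallest feature count achieving the peak MRA."""
        return int(self.feature_counts[int(np.argmax(self.mra_values))])


def _fold_ingredients(A: AttributeMatrix, table: TrialTable, held, selector_fn,
                      selector_kwargs):
    """Training-side computations of one LOCO fold (no held-out information)."""
    train_mask = table.class_ids != held
    train = table.subset_trials(train_mask)
    train_classes = list(np.unique(train.class_ids))
    A_train = A.restrict(train_classes)
    ranking: FeatureRanking = selector_fn(train, A_train, **selector_kwargs)
    return train, A_train, ranking


def loco_evaluate(A: AttributeMatrix, table: TrialTable, selector, m: int,
                  lam_en: float = DEFAULT_LAM_EN, lam_de: float = DEFAULT_LAM_DE,
                  modes=("encoding", "decoding"), selector_kwargs: dict | None = None,
                  return_selections: bool = False,
                  average_decoder_input: bool = True):
    """Run full leave-one-class-out zero-shot evaluation.

    One fold per class; within each fold, feature selection, z-scoring and
    model fitting see only the training classes' trials.  Returns a dict
    mode -> :class:`ZeroShotResult` (and the per-fold selected feature
    indices if ``return_selections``).

    ``average_decoder_input`` decodes the held-out class's mean feature
    vector (one prediction per fold, the default); with ``False`` each
    held-out trial is decoded and ranked separately and the fold's RA is
    the mean over its trials.
    """
    if m < 1:
        raise ValueError("feature budget M must be >= 1")
    selector_fn = get_selector(selector)
    selector_kwargs = selector_kwargs or {}
    A = normalize_attribute_rows(A)
    all_classes = list(A.class_ids)
    results = {mode: [] for mode in modes}
    selections = []
    for held in all_classes:
        if not np.any(table.class_ids == held):
            raise ValueError(f"class {held!r} has no trials")
        train, A_train, ranking = _fold_ingredients(A, table, held, selector_fn,
                                                    selector_kwargs)
        sel = select_top_m(ranking, m)  # clamps (with a warning) at the pool size
        selections.append(sel)
        train_sel = train.subset_features(sel)
        train_z, stats = zscore_columns(train_sel)
        held_table = table.subset_trials(table.class_ids == held).subset_features(sel)
        held_z, _ = zscore_columns(held_table, stats)
        x_held = A.row(held)
        if "encoding" in modes:
            model = fit_encoder(A_train, train_z, lam_en, stats)
            y_hat = predict_features(model, x_held)
            cls, templ = class_templates(train_z)
            ids = list(cls) + [held]
            rows = np.vstack([templ, held_z.features.mean(axis=0)])
            d = _cosine_distances_to_rows(y_hat, rows)
            r = rank_class(pd.Series(d, index=ids), held)
            results["encoding"].append(FoldResult(held, ids, d, r,
                                                  rank_accuracy(r, len(ids)),
                                                  train.n_trials))
        if "decoding" in modes:
            model = fit_decoder(train_z, A_train, lam_de, stats)
            if average_decoder_input:
                inputs = held_z.features.mean(axis=0)[None, :]
            else:
                inputs = held_z.features
            ranks, dists = [], []
            for y_in in inputs:
                x_hat = predict_attributes(model, y_in)
                d = _cosine_distances_to_rows(x_hat, A.values)
                dists.append(d)
                ranks.append(rank_class(pd.Series(d, index=all_classes), held))
            r = float(np.mean(ranks))
            ra = float(np.mean([rank_accuracy(rk, len(all_classes)) for rk in ranks]))
            results["decoding"].append(FoldResult(held, all_classes,
                                                  np.mean(dists, axis=0), r, ra,
                                                  train.n_trials))
    out = {}
    for mode in modes:
        folds = results[mode]
        mra = float(np.mean([f.ra for f in folds]))
        out[mode] = ZeroShotResult(mode, folds, mra,
                                   {"selector": getattr(selector_fn, "__name__", str(selector)),
                                    "m": m, "lam_en": lam_en, "lam_de": lam_de})
    if return_selections:
        return out, selections
    return out


def default_m_grid(m_cap: int, step: int = 10) -> np.ndarray:
    """Feature budgets 1, step, 2*step, ... up to (and including) ``m_cap``."""
    grid = np.arange(step, m_cap + 1, step)
    grid = np.unique(np.concatenate([[1], grid, [m_cap]]))
    return grid


def mra_curve(A: AttributeMatrix, table: TrialTable, selector,
              lam_en: float = DEFAULT_LAM_EN, lam_de: float = DEFAULT_LAM_DE,
              m_cap: int = 500, m_grid=None, modes=("encoding", "decoding"),
              selector_kwargs: dict | None = None) -> dict:
    """Cumulative MRA as features are added in a selector's rank order.

    Returns a dict mode -> :class:`MRACurve`.  The grid is trimmed at the
    smallest candidate pool over folds, so for the attribute/feature
    correlation selector the curve ends at M' <= P (every reported budget is
    fully realized in every fold).
    """
    selector_fn = get_selector(selector)
    selector_kwargs = selector_kwargs or {}
    A = normalize_attribute_rows(A)
    all_classes = list(A.class_ids)
    # pass 1: rankings per fold, which also fix the realizable feature cap
    fold_rankings = []
    for held in all_classes:
        _, _, ranking = _fold_ingredients(A, table, held, selector_fn, selector_kwargs)
        fold_rankings.append(ranking)
    m_cap = min(m_cap, table.n_features,
                min(r.pool_size for r in fold_rankings))
    grid = np.asarray(m_grid) if m_grid is not None else default_m_grid(m_cap)
    grid = np.unique(np.concatenate([grid[grid < m_cap], [m_cap]]))
    ra = {mode: np.zeros((len(all_classes), len(grid))) for mode in modes}
    for fi, held in enumerate(all_classes):
        ranking = fold_rankings[fi]
        train = table.subset_trials(table.class_ids != held)
        A_train = A.restrict(list(np.unique(train.class_ids)))
        cap = int(m_cap)
        sel = ranking.order[:cap]
        train_sel = train.subset_features(sel)
        train_z, stats = zscore_columns(train_sel)
        held_table = table.subset_trials(table.class_ids == held).subset_features(sel)
        held_z, _ = zscore_columns(held_table, stats)
        x_held = A.row(held)
        Xtr = _trial_design(A_train, train_z)  # (T, P)
        Y = train_z.features
        cls, templ = class_templates(train_z)
        held_templ = held_z.features.mean(axis=0)
        if "encoding" in modes:
            # encoder weights for the full cap; any prefix M is a column slice
            W_full = scipy.linalg.solve(Xtr.T @ Xtr + lam_en * np.eye(Xtr.shape[1]),
                                        Xtr.T @ Y, assume_a="pos")
            ids = list(cls) + [held]
            rows_full = np.vstack([templ, held_templ])
            y_hat_full = x_held @ W_full
            for gi, m in enumerate(grid):
                mm = min(int(m), cap)
                r = rank_class(pd.Series(_cosine_distances_to_rows(
                    y_hat_full[:mm], rows_full[:, :mm]), index=ids), held)
                ra["encoding"][fi, gi] = rank_accuracy(r, len(ids))
        if "decoding" in modes:
            # decoder targets: trial-level attribute columns, unit-normalized
            Xt = Xtr.copy()
            norms = np.linalg.norm(Xt, axis=0)
            nz = norms > 0
            Xt[:, nz] /= norms[nz]
            G = Y.T @ Y
            B = Y.T @ Xt
            prev_mm = -1
            for gi, m in enumerate(grid):
                mm = min(int(m), cap)
                if mm != prev_mm:
                    W = scipy.linalg.solve(G[:mm, :mm] + lam_de * np.eye(mm),
                                           B[:mm], assume_a="pos")
                    x_hat = held_templ[:mm] @ W
                    prev_mm = mm
                r = rank_class(pd.Series(_cosine_distances_to_rows(x_hat, A.values),
                                         index=all_classes), held)
                ra["decoding"][fi, gi] = rank_accuracy(r, len(all_classes))
    settings = {"selector": getattr(selector_fn, "__name__", str(selector)),
                "lam_en": lam_en, "lam_de": lam_de, "m_cap": m_cap}
    return {mode: MRACurve(mode, grid.copy(), ra[mode].mean(axis=0), dict(settings))
            for mode in modes}
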