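"""Delimited-text readers/writers and model serialization.

Dialects
--------
* Attribute matrix: CSV, header row of attribute names, first column
  ``class_id``.
* Trial table: CSV with columns ``class_id``, ``block_id``, then one column
  per feature; optional sidecar feature-metadata CSV (``feature_id`` plus
  electrode/voxel id, time/frequency centers, ...).
* Rankings: CSV with ``feature_index``, ``method``, ``score``, ``rank``,
  ``in_pool``.
* Results: tidy CSVs, one row per fold or per (mode, selector, lam, M, MRA).
* Ridge models: a single ``.npz`` archive with weights, lam, train stats and
  selected-feature indices.
* Raw recordings: an HDF5 container with ``signals``, ``sample_rate``,
  channel tables and an events table.

Floats are written with 17 significant digits so write -> read round-trips
are exact and reruns are byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ecog import EcogRecording
from .regression import AttributeMatrix, RidgeModel, TrainStats, TrialTable
from .selection import FeatureRanking
from .zeroshot import ZeroShotResult

__all__ = [
    "read_attribute_matrix", "write_attribute_matrix",
    "read_trial_table", "write_trial_table",
    "read_ranking", "write_ranking",
    "write_fold_results",
    "save_model", "load_model",
    "read_recording", "write_recording",
]

FLOAT_FMT = "%.17g"


def _check_numeric(df: pd.DataFrame, cols, path):
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = converted
    return df


def write_attribute_matrix(A: AttributeMatrix, path):
    names = A.attribute_names or [f"attr{j:03d}" for j in range(A.P)]
    df = pd.DataFrame(A.values, columns=names)
    df.insert(0, "class_id", A.class_ids)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_attribute_matrix(path) -> AttributeMatrix:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "class_id":
        raise ValueError(f"{path}: first column must be 'class_id', got {df.columns[0]!r}")
    attr_cols = list(df.columns[1:])
    if not attr_cols:
        raise ValueError(f"{path}: no attribute columns found")
    df = _check_numeric(df, attr_cols, path)
    return AttributeMatrix(df[attr_cols].to_numpy(float), list(df["class_id"]), attr_cols)


def write_trial_table(table: TrialTable, path, meta_path=None):
    cols = (list(table.feature_meta["feature_id"])
            if table.feature_meta is not None and "feature_id" in table.feature_meta
            else [f"f{j:04d}" for j in range(table.n_features)])
    df = pd.DataFrame(table.features, columns=[str(c) for c in cols])
    df.insert(0, "block_id", table.block_ids)
    df.insert(0, "class_id", table.class_ids)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    if meta_path is not None and table.feature_meta is not None:
        table.feature_meta.to_csv(meta_path, index=False, float_format=FLOAT_FMT)


def read_trial_table(path, meta_path=None) -> TrialTable:
    df = pd.read_csv(path, dtype={"class_id": str})
    for required in ("class_id", "block_id"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    feat_cols = [c for c in df.columns if c not in ("class_id", "block_id")]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns found")
    df = _check_numeric(df, feat_cols, path)
    meta = pd.read_csv(meta_path) if meta_path is not None else None
    return TrialTable(df[feat_cols].to_numpy(float), df["class_id"].to_numpy(),
                      df["block_id"].to_numpy(int), meta)


def write_ranking(ranking: FeatureRanking, path):
    m = len(ranking.scores)
    rank = np.full(m, -1)
    rank[ranking.order] = np.arange(1, ranking.pool_size + 1)
    in_pool = np.zeros(m, dtype=bool)
    in_pool[ranking.order] = True
    pd.DataFrame({"feature_index": np.arange(m), "method": ranking.method,
                  "score": ranking.scores, "rank": rank, "in_pool": in_pool}
                 ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_ranking(path) -> FeatureRanking:
    df = pd.read_csv(path)
    scores = df["score"].to_numpy(float)
    in_pool = df["in_pool"].to_numpy(bool)
    ranked = df.loc[in_pool].sort_values("rank")
    order = ranked["feature_index"].to_numpy(int)
    return FeatureRanking(str(df["method"].iloc[0]), scores, order, len(order))


def write_fold_results(result: ZeroShotResult, path):
    df = result.fold_table()
    for k, v in result.settings.items():
        df[k] = v
    df.insert(0, "mode", result.mode)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def save_model(model: RidgeModel, path):
    extra = {}
    if model.train_stats is not None:
        extra["train_mean"] = model.train_stats.mean
        extra["train_sd"] = model.train_stats.sd
    if model.feature_indices is not None:
        extra["feature_indices"] = model.feature_indices
    if model.target_norms is not None:
        extra["target_norms"] = model.target_norms
    np.savez(path, direction=model.direction, weights=model.weights,
             lam=model.lam, **extra)


def load_model(path) -> RidgeModel:
    with np.load(path, allow_pickle=False) as z:
        stats = None
        if "train_mean" in z:
            stats = TrainStats(z["train_mean"], z["train_sd"])
        return RidgeModel(direction=str(z["direction"]), weights=z["weights"],
                          lam=float(z["lam"]), train_stats=stats,
                          feature_indices=z["feature_indices"] if "feature_indices" in z else None,
                          target_norms=z["target_norms"] if "target_norms" in z else None)


def write_recording(rec: EcogRecording, path):
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals)
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["t_stim"] = rec.t_stim
        f.attrs["t_fix"] = list(rec.t_fix)
        f.create_dataset("channel_ids", data=np.array(rec.channel_ids, dtype="S"))
        f.create_dataset("channel_groups", data=np.array(rec.channel_groups, dtype="S"))
        ev = f.create_group("events")
        ev.create_dataset("onset_sample", data=rec.events["onset_sample"].to_numpy(int))
        ev.create_dataset("class_id", data=rec.events["class_id"].astype(str).to_numpy(dtype="S"))
        ev.create_dataset("block_id", data=rec.events["block_id"].to_numpy(int))


def read_recording(path) -> EcogRecording:
    import h5py
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({
            "onset_sample": f["events/onset_sample"][:],
            "class_id": [s.decode() for s in f["events/class_id"][:]],
            "block_id": f["events/block_id"][:]})
        return EcogRecording(
            signals=f["signals"][:], sample_rate=float(f.attrs["sample_rate"]),
            channel_ids=[s.decode() for s in f["channel_ids"][:]],
            channel_groups=[s.decode() for s in f["channel_groups"][:]],
            events=events, t_stim=float(f.attrs["t_stim"]),
            t_fix=tuple(f.attrs["t_fix"]))
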