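"""Ridge-regression encoding and decoding between semantic attributes and neural features.

The encoding model predicts each neural feature ``y_m`` from a stimulus's
semantic attribute vector ``x`` (one independent ridge regression per
feature); the decoding model predicts each semantic attribute ``x_p`` from
the vector of neural features.  Both use the closed-form ridge solution

    W_en = (X'X + lam I)^-1 X' Y        (attributes -> features)
    W_de = (Y'Y + lam I)^-1 Y' X        (features  -> attributes)

with the field's normalization conventions: attribute rows are scaled to
unit Euclidean length, neural feature columns are z-scored on the training
trials, and decoder target columns are scaled to unit length over the
training trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "AttributeMatrix",
    "TrialTable",
    "TrainStats",
    "RidgeModel",
    "normalize_attribute_rows",
    "zscore_columns",
    "fit_encoder",
    "fit_decoder",
    "predict_features",
    "predict_attributes",
    "lambda_grid",
]


@dataclass
class AttributeMatrix:
    """Class-by-attribute semantic matrix (one row per stimulus class).

    ``values`` has shape ``(n_classes, P)``; in the canonical design P = 218
    crowd-sourced property questions, rescaled from the ordinal 1..5 answers
    to [-1, 1] and (after :func:`normalize_attribute_rows`) unit-normalized
    per row.
    """

    values: np.ndarray
    class_ids: list
    attribute_names: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("attribute matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribute matrix contains non-finite entries")
        self.class_ids = list(self.class_ids)
        if len(self.class_ids) != self.values.shape[0]:
            raise ValueError("class_ids length does not match number of rows")
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ValueError("duplicate class ids in attribute matrix")
        if self.attribute_names is not None:
            self.attribute_names = list(self.attribute_names)
            if len(self.attribute_names) != self.values.shape[1]:
                raise ValueError("attribute_names length does not match P")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def P(self) -> int:
        return self.values.shape[1]

    def row(self, class_id) -> np.ndarray:
        """Attribute vector of one class."""
        try:
            i = self.class_ids.index(class_id)
        except ValueError:
            raise KeyError(f"class {class_id!r} not in attribute matrix") from None
        return self.values[i]

    def restrict(self, class_ids) -> "AttributeMatrix":
        """Sub-matrix containing only ``class_ids`` (in the given order)."""
        rows = np.stack([self.row(c) for c in class_ids])
        return AttributeMatrix(rows, list(class_ids), self.attribute_names)


@dataclass
class TrialTable:
    """Trial-by-feature neural data with class and block labels.

    ``features`` is ``(T, M)``; ``class_ids`` and ``block_ids`` label each
    trial.  A balanced design has every class exactly once per block (the
    60-class x 6-block object-naming design gives T = 360).  ``feature_meta``
    is an optional per-feature annotation table (electrode / voxel id, time
    window center, frequency band center) indexed 0..M-1.
    """

    features: np.ndarray
    class_ids: np.ndarray
    block_ids: np.ndarray
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.class_ids = np.asarray(self.class_ids)
        self.block_ids = np.asarray(self.block_ids)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (trials x features)")
        t = self.features.shape[0]
        if len(self.class_ids) != t or len(self.block_ids) != t:
            raise ValueError("label length does not match number of trials")
        if pd.isna(self.class_ids).any() or pd.isna(self.block_ids).any():
            raise ValueError("class_id / block_id labels must be complete")
        if self.feature_meta is not None and len(self.feature_meta) != self.features.shape[1]:
            raise ValueError("feature_meta length does not match feature count")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.class_ids)

    @property
    def blocks(self) -> np.ndarray:
        return np.unique(self.block_ids)

    def validate_balanced(self):
        """Raise unless every class appears the same number of times in every block."""
        tab = pd.crosstab(pd.Series(self.class_ids), pd.Series(self.block_ids))
        if tab.shape != (len(self.classes), len(self.blocks)) or tab.to_numpy().min() < 1:
            raise ValueError("design not complete: some class missing from some block")
        if tab.to_numpy().std() != 0:
            raise ValueError("design not balanced across blocks")

    def subset_trials(self, mask) -> "TrialTable":
        mask = np.asarray(mask)
        return TrialTable(self.features[mask], self.class_ids[mask],
                          self.block_ids[mask], self.feature_meta)

    def subset_features(self, idx) -> "TrialTable":
        idx = np.asarray(idx)
        meta = self.feature_meta.iloc[idx].reset_index(drop=True) if self.feature_meta is not None else None
        return TrialTable(self.features[:, idx], self.class_ids, self.block_ids, meta)


@dataclass
class TrainStats:
    """Per-feature mean and sample standard deviation from the training trials.

    Retained on the model so held-out trials are transformed with *training*
    statistics only.  ``sd`` entries of 0 mark zero-variance columns, which
    z-score to all-zero.
    """

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class RidgeModel:
    """Fitted ridge encoder (P x M weights) or decoder (M x P weights)."""

    direction: str  # "encoder" | "decoder"
    weights: np.ndarray
    lam: float
    train_stats: TrainStats | None = None
    feature_indices: np.ndarray | None = None
    target_norms: np.ndarray | None = field(default=None)  # decoder target column norms


def normalize_attribute_rows(A: AttributeMatrix) -> AttributeMatrix:
    """Scale every class's attribute row to unit Euclidean length."""
    norms = np.linalg.norm(A.values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = [A.class_ids[i] for i in zero]
        raise ValueError(f"cannot normalize all-zero attribute row(s) for class(es): {bad}")
    return AttributeMatrix(A.values / norms[:, None], A.class_ids, A.attribute_names)


def zscore_columns(table: TrialTable, stats: TrainStats | None = None
                   ) -> tuple[TrialTable, TrainStats]:
    """Z-score each feature column (sample sd, n-1 denominator).

    Without ``stats``, means/sds are computed from ``table`` (training-time)
    and returned; with ``stats``, those training statistics are applied
    (test-time).  Zero-variance columns are set to all-zero and logged, so
    feature indexing stays stable across folds.
    """
    y = table.features
    if stats is None:
        mean = y.mean(axis=0)
        sd = y.std(axis=0, ddof=1) if y.shape[0] > 1 else np.zeros(y.shape[1])
        sd = np.where(np.isfinite(sd), sd, 0.0)
        stats = TrainStats(mean=mean, sd=sd)
    else:
        if stats.mean.shape[0] != y.shape[1]:
            raise ValueError("train statistics dimension does not match feature count")
    nz = stats.sd > 0
    n_zero = int((~nz).sum())
    if n_zero:
        logger.warning("zscore_columns: %d zero-variance feature column(s) set to 0", n_zero)
    z = np.zeros_like(y)
    z[:, nz] = (y[:, nz] - stats.mean[nz]) / stats.sd[nz]
    return TrialTable(z, table.class_ids, table.block_ids, table.feature_meta), stats


def _trial_design(A: AttributeMatrix, table: TrialTable) -> np.ndarray:
    """Trial-level design matrix: each trial's row is its class's attribute vector."""
    index = {c: i for i, c in enumerate(A.class_ids)}
    try:
        rows = np.array([index[c] for c in table.class_ids])
    except KeyError as e:
        raise KeyError(f"trial class {e.args[0]!r} missing from attribute matrix") from None
    return A.values[rows]


def _ridge_solve(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G + lam I) w = b with G symmetric PSD."""
    n = G.shape[0]
    lhs = G + lam * np.eye(n)
    if lam > 0:
        return scipy.linalg.solve(lhs, b, assume_a="pos")
    try:
        return scipy.linalg.solve(lhs, b, assume_a="sym")
    except scipy.linalg.LinAlgError:
        raise ValueError("singular normal equations with lam=0; use a positive lam") from None


def _check_lam(lam: float):
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"ridge penalty must be a finite value >= 0, got {lam!r}")


def fit_encoder(A: AttributeMatrix, table: TrialTable, lam: float,
                train_stats: TrainStats | None = None) -> RidgeModel:
    """Fit the encoding model (attributes -> every neural feature at once).

    ``A`` holds the unit-normalized attribute rows of the *training* classes;
    ``table`` the z-scored training trials.  The design matrix replicates each
    class's attribute row once per trial of that class (T rows).
    """
    _check_lam(lam)
    X = _trial_design(A, table)  # (T, P)
    Y = table.features
    G = X.T @ X
    W = _ridge_solve(G, X.T @ Y, lam)  # (P, M)
    if lam == 0:
        # guard against a silently garbage solve on rank-deficient designs
        resid = G @ W - X.T @ Y
        if not np.allclose(resid, 0, atol=1e-6 * max(1.0, float(np.abs(X.T @ Y).max()))):
            raise ValueError("singular normal equations with lam=0; use a positive lam")
    return RidgeModel("encoder", W, float(lam), train_stats)


def fit_decoder(table: TrialTable, A: AttributeMatrix, lam: float,
                train_stats: TrainStats | None = None,
                normalize_targets: bool = True) -> RidgeModel:
    """Fit the decoding model (neural features -> every attribute at once).

    ``table`` holds z-scored training trials; targets are the trial-level
    attribute columns, each scaled to unit length over the training trials
    (the convention the encoding/decoding framework states for x_p).  When
    the selected feature count exceeds the trial count the equivalent dual
    (kernel) form is solved; results match the primal closed form.
    """
    _check_lam(lam)
    Y = table.features  # (T, M)
    Xt = _trial_design(A, table).copy()  # (T, P)
    norms = None
    if normalize_targets:
        norms = np.linalg.norm(Xt, axis=0)
        zero = norms == 0
        if zero.any():
            logger.warning("fit_decoder: %d constant-zero attribute target(s) left at 0",
                           int(zero.sum()))
        Xt[:, ~zero] /= norms[~zero]
    t, m = Y.shape
    if lam == 0 or t >= m:
        G = Y.T @ Y
        W = _ridge_solve(G, Y.T @ Xt, lam)
        if lam == 0:
            resid = G @ W - Y.T @ Xt
            if not np.allclose(resid, 0, atol=1e-6 * max(1.0, float(np.abs(Y.T @ Xt).max()))):
                raise ValueError("singular normal equations with lam=0; use a positive lam")
    else:
        # dual route: (Y'Y + lam I)^-1 Y' = Y'(YY' + lam I)^-1
        K = Y @ Y.T
        W = Y.T @ scipy.linalg.solve(K + lam * np.eye(t), Xt, assume_a="pos")
    return RidgeModel("decoder", W, float(lam), train_stats, target_norms=norms)


def predict_features(model: RidgeModel, x: np.ndarray) -> np.ndarray:
    """Encode: predicted neural feature vector y_hat = x . W_en."""
    if model.direction != "encoder":
        raise ValueError("predict_features requires an encoder model")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.shape[0]:
        raise ValueError(f"attribute vector length {x.shape[-1]} != model P "
                         f"{model.weights.shape[0]}")
    return x @ model.weights


def predict_attributes(model: RidgeModel, y: np.ndarray) -> np.ndarray:
    """Decode: predicted attribute vector x_hat = y . W_de."""
    if model.direction != "decoder":
        raise ValueError("predict_attributes requires a decoder model")
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != model.weights.shape[0]:
        raise ValueError(f"feature vector length {y.shape[-1]} != model M "
                         f"{model.weights.shape[0]}")
    return y @ model.weights


def lambda_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """``n`` logarithmically spaced ridge penalties from ``lo`` to ``hi`` inclusive.

    The canonical sweeps are 5 values in [100, 1000] for encoding and
    5 values in [1, 10] for decoding.
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo!r}, hi={hi!r}")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.geomspace(lo, hi, int(n))


#: default regularization sweeps
ENCODER_LAMBDA_GRID = (100.0, 1000.0, 5)
DECODER_LAMBDA_GRID = (1.0, 10.0, 5)

#: geometric midpoints of the default sweeps, used where a single lambda is needed
DEFAULT_LAM_EN = float(np.sqrt(100.0 * 1000.0))
DEFAULT_LAM_DE = float(np.sqrt(1.0 * 10.0))
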