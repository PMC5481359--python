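"""Feature-ranking (selection) methods for zero-shot encoding/decoding.

Five rankers are provided, all operating strictly on the training trials of
a cross-validation fold:

* ``correlation_stability`` -- average Pearson correlation of a feature's
  per-class response profile across all pairs of repetition blocks.
* ``mutual_info_stability`` -- the same block-pair scheme scored with the
  Gaussian mutual information I = -1/2 log(1 - rho^2).
* ``attribute_feature_correlation`` -- the two-stage attribute-driven
  selector: per attribute keep the single best-|r|-correlated feature over
  all training trials, then rank the pooled winners by correlation
  stability.  The pool size M' never exceeds the attribute count P.
* ``fisher_score`` -- ratio of between-class to pooled within-class spread.
* ``ridge_wrapper`` -- an inner leave-one-class-out sweep of the ridge
  encoder; features are ranked by the correlation between their predicted
  and true class-average responses across inner folds.

Scores are sorted descending; ties break by ascending feature index so
rankings are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import (AttributeMatrix, TrialTable, DEFAULT_LAM_EN,
                         fit_encoder, normalize_attribute_rows, predict_features,
                         zscore_columns, _trial_design)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRanking",
    "correlation_stability",
    "mutual_info_stability",
    "attribute_feature_correlation",
    "fisher_score",
    "ridge_wrapper",
    "select_top_m",
    "selection_tally",
    "get_selector",
    "SELECTORS",
]

#: cap on rho^2 in the Gaussian MI when a block pair is numerically degenerate
_RHO2_CAP = 1.0 - 1e-12


@dataclass
class FeatureRanking:
    """Per-feature scores and the ranked index list from one selector.

    ``scores`` has one entry per feature in the source table; entries are NaN
    for features outside the selector's candidate pool (only the
    attribute/feature correlation method has a restricted pool).  ``order``
    lists pool features by descending score.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray
    pool_size: int

    def __post_init__(self):
        if len(self.order) != self.pool_size:
            raise ValueError("order length must equal pool_size")


def _rank_descending(scores: np.ndarray, pool: np.ndarray | None = None) -> np.ndarray:
    """Indices sorted by descending score, ties broken by ascending index."""
    if pool is None:
        pool = np.arange(len(scores))
    pool = np.asarray(pool)
    s = scores[pool]
    # stable sort on -s keeps ascending-index order within ties; -inf sorts last
    return pool[np.argsort(-s, kind="stable")]


def _block_class_profiles(table: TrialTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block per-class mean responses, shape (B, C, M).

    With one trial per class per block this is a reindexing; with replicates
    it is the within-block class mean.
    """
    classes, cls_idx = np.unique(table.class_ids, return_inverse=True)
    blocks, blk_idx = np.unique(table.block_ids, return_inverse=True)
    b, c, m = len(blocks), len(classes), table.n_features
    flat = blk_idx * c + cls_idx
    counts = np.bincount(flat, minlength=b * c).astype(float)
    if (counts == 0).any():
        missing = np.argwhere(counts.reshape(b, c) == 0)
        raise ValueError(f"class missing from block (block,class index pairs {missing.tolist()[:3]}...)")
    sums = np.zeros((b * c, m))
    np.add.at(sums, flat, table.features)
    return sums / counts[:, None], blocks, classes


def _block_pair_correlations(table: TrialTable) -> np.ndarray:
    """Pearson r per feature for every block pair, shape (n_pairs, M).

    The correlation for one pair is computed over the classes' per-block mean
    responses.  A zero-variance block vector contributes r = 0 (logged).
    """
    prof_flat, blocks, classes = _block_class_profiles(table)
    b, c, m = len(blocks), len(classes), table.n_features
    if b < 2:
        raise ValueError("need at least 2 blocks for stability ranking")
    prof = prof_flat.reshape(b, c, m)
    centered = prof - prof.mean(axis=1, keepdims=True)
    ss = (centered ** 2).sum(axis=1)  # (B, M)
    pairs = [(i, j) for i in range(b) for j in range(i + 1, b)]
    out = np.empty((len(pairs), m))
    n_degenerate = 0
    for k, (i, j) in enumerate(pairs):
        num = (centered[i] * centered[j]).sum(axis=0)
        den = np.sqrt(ss[i] * ss[j])
        ok = den > 0
        n_degenerate += int((~ok).sum())
        r = np.zeros(m)
        r[ok] = num[ok] / den[ok]
        out[k] = r
    if n_degenerate:
        logger.warning("stability: %d zero-variance block vector(s) contributed r=0",
                       n_degenerate)
    return out


def correlation_stability(table: TrialTable,
                          attributes: AttributeMatrix | None = None) -> FeatureRanking:
    """Rank features by mean block-pair Pearson correlation of class profiles."""
    r = _block_pair_correlations(table)
    scores = r.mean(axis=0)
    return FeatureRanking("corr_stability", scores, _rank_descending(scores),
                          table.n_features)


def gaussian_mutual_information(rho: np.ndarray) -> np.ndarray:
    """MI (nats) of a bivariate Gaussian with correlation ``rho``.

    Algebraic reduction of 1/2 log(sigma1^2 sigma2^2 / |Sigma|): with
    |Sigma| = sigma1^2 sigma2^2 (1 - rho^2) this is -1/2 log(1 - rho^2).
    rho^2 is capped just below 1 for numerically degenerate (identical
    profile) pairs.
    """
    rho2 = np.square(rho)
    capped = rho2 >= _RHO2_CAP
    if np.any(capped):
        logger.warning("gaussian MI: %d block pair(s) at |rho|~1, score capped",
                       int(np.sum(capped)))
        rho2 = np.minimum(rho2, _RHO2_CAP)
    return -0.5 * np.log1p(-rho2)


def mutual_info_stability(table: TrialTable,
                          attributes: AttributeMatrix | None = None) -> FeatureRanking:
    """Rank features by mean block-pair Gaussian mutual information.

    Marginal/joint moments are the maximum-likelihood (Gaussian) estimates,
    so the per-pair MI reduces to -1/2 log(1 - rho^2) with rho the Pearson
    correlation of the pair's class profiles.
    """
    r = _block_pair_correlations(table)
    scores = gaussian_mutual_information(r).mean(axis=0)
    return FeatureRanking("mi_stability", scores, _rank_descending(scores),
                          table.n_features)


def attribute_feature_correlation(table: TrialTable,
                                  attributes: AttributeMatrix) -> FeatureRanking:
    """Two-stage attribute-driven selector.

    Stage 1: for each attribute, find the feature with the largest |Pearson r|
    to it over all training trials (attribute values expanded to trial level
    by class lookup).  Stage 2: pool the unique winners (M' <= P; fewer when
    one feature wins several attributes, or when an attribute is constant
    over the training trials).  Stage 3: rank the pool by correlation
    stability; features outside the pool are unranked (NaN score).
    """
    if attributes is None:
        raise ValueError("attribute_feature_correlation requires an attribute matrix")
    Xt = _trial_design(attributes, table)  # (T, P)
    F = table.features
    xc = Xt - Xt.mean(axis=0)
    fc = F - F.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sf = np.sqrt((fc ** 2).sum(axis=0))
    valid_attr = sx > 0
    if not valid_attr.all():
        logger.warning("attr/feat correlation: %d constant attribute(s) contribute no winner",
                       int((~valid_attr).sum()))
    valid_feat = sf > 0
    denom = np.outer(sx[valid_attr], np.where(valid_feat, sf, 1.0))
    corr = np.abs(xc[:, valid_attr].T @ fc) / denom
    corr[:, ~valid_feat] = -np.inf  # constant features can win nothing
    winners = np.unique(corr.argmax(axis=1))
    stability = correlation_stability(table).scores
    scores = np.full(table.n_features, np.nan)
    scores[winners] = stability[winners]
    order = _rank_descending(stability, pool=winners)
    return FeatureRanking("attr_feat_corr", scores, order, len(winners))


def _class_conditional_stats(table: TrialTable):
    """Class trial counts, means and sample variances per feature."""
    classes, idx = np.unique(table.class_ids, return_inverse=True)
    c, m = len(classes), table.n_features
    n_i = np.bincount(idx, minlength=c).astype(float)
    sums = np.zeros((c, m))
    np.add.at(sums, idx, table.features)
    means = sums / n_i[:, None]
    sq = np.zeros((c, m))
    np.add.at(sq, idx, (table.features - means[idx]) ** 2)
    with np.errstate(invalid="ignore"):
        svar = np.where(n_i[:, None] > 1, sq / np.maximum(n_i[:, None] - 1, 1), np.nan)
    return classes, n_i, means, svar


def fisher_score(table: TrialTable,
                 attributes: AttributeMatrix | None = None) -> FeatureRanking:
    """Rank features by the Fisher criterion.

    S_F = sum_i n_i (mu_i - mu)^2 / sum_i n_i sigma_i^2, with class sample
    means/variances: features that cluster tightly around distinct per-class
    means score high.  Zero within-class variance with nonzero between-class
    spread scores +inf (ranked first); a feature constant everywhere scores 0.
    """
    classes, n_i, means, svar = _class_conditional_stats(table)
    if np.isnan(svar).any():
        raise ValueError("fisher_score needs >= 2 trials per class for sample variances")
    grand = (n_i[:, None] * means).sum(axis=0) / n_i.sum()
    num = (n_i[:, None] * (means - grand) ** 2).sum(axis=0)
    den = (n_i[:, None] * svar).sum(axis=0)
    scores = np.empty(table.n_features)
    zero_den = den <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(zero_den, np.where(num > 0, np.inf, 0.0), num / np.maximum(den, 1e-300))
    n_inf = int(np.isinf(scores).sum())
    if n_inf:
        logger.warning("fisher_score: %d feature(s) with zero within-class variance scored +inf",
                       n_inf)
    return FeatureRanking("fisher", scores, _rank_descending(scores), table.n_features)


def ridge_wrapper(table: TrialTable, attributes: AttributeMatrix,
                  lam_en: float = DEFAULT_LAM_EN) -> FeatureRanking:
    """Wrapper ranking via an inner leave-one-class-out encoder sweep.

    For each inner fold one training class is held out, the ridge encoder is
    fit on the remaining classes' trials, and the held-out class's features
    are predicted from its attribute vector.  After all folds, each feature
    is scored by the Pearson correlation between its inner-fold predictions
    and the true class-average responses (one pair per inner fold).  In the
    full design this is 59 inner folds with 58-class encoders.
    """
    if attributes is None:
        raise ValueError("ridge_wrapper requires an attribute matrix")
    A = normalize_attribute_rows(attributes.restrict(list(np.unique(table.class_ids))))
    classes = A.class_ids
    if len(classes) < 3:
        raise ValueError("ridge_wrapper needs at least 3 training classes")
    m = table.n_features
    preds = np.empty((len(classes), m))
    truths = np.empty((len(classes), m))
    for k, held in enumerate(classes):
        inner = table.subset_trials(table.class_ids != held)
        inner_z, stats = zscore_columns(inner)
        model = fit_encoder(A.restrict([c for c in classes if c != held]), inner_z, lam_en)
        preds[k] = predict_features(model, A.row(held))
        held_mean = table.features[table.class_ids == held].mean(axis=0)
        with np.errstate(invalid="ignore"):
            truths[k] = np.where(stats.sd > 0, (held_mean - stats.mean) / np.where(stats.sd > 0, stats.sd, 1.0), 0.0)
    pc = preds - preds.mean(axis=0)
    tc = truths - truths.mean(axis=0)
    sp = np.sqrt((pc ** 2).sum(axis=0))
    st = np.sqrt((tc ** 2).sum(axis=0))
    ok = (sp > 0) & (st > 0)
    scores = np.full(m, -np.inf)
    scores[ok] = (pc[:, ok] * tc[:, ok]).sum(axis=0) / (sp[ok] * st[ok])
    if (~ok).any():
        logger.warning("ridge_wrapper: %d feature(s) with degenerate correlation ranked last",
                       int((~ok).sum()))
    return FeatureRanking("ridge_wrapper", scores, _rank_descending(scores), m)


def select_top_m(ranking: FeatureRanking, m: int) -> np.ndarray:
    """First min(m, pool_size) feature indices of a ranking."""
    if m < 1:
        raise ValueError("feature budget M must be >= 1")
    if m > ranking.pool_size:
        logger.warning("select_top_m: budget %d clamped to pool size %d", m, ranking.pool_size)
    return ranking.order[: min(m, ranking.pool_size)]


def selection_tally(per_fold_selections, feature_meta: pd.DataFrame,
                    by: str = "freq_center_hz") -> pd.DataFrame:
    """Tally how often each metadata bin was selected across CV folds.

    Returns one row per unique value of ``feature_meta[by]`` with the total
    selection count over folds and the per-fold average.
    """
    if feature_meta is None:
        raise ValueError("selection_tally requires feature metadata")
    if by not in feature_meta.columns:
        raise KeyError(f"feature metadata has no column {by!r}")
    n_folds = len(per_fold_selections)
    if n_folds == 0:
        raise ValueError("no fold selections given")
    counts = {}
    for sel in per_fold_selections:
        for v in feature_meta[by].iloc[np.asarray(sel)]:
            counts[v] = counts.get(v, 0) + 1
    out = pd.DataFrame({by: sorted(counts), "count": [counts[v] for v in sorted(counts)]})
    out["mean_per_fold"] = out["count"] / n_folds
    return out


SELECTORS = {
    "corr_stability": correlation_stability,
    "mi_stability": mutual_info_stability,
    "attr_feat_corr": attribute_feature_correlation,
    "fisher": fisher_score,
    "ridge_wrapper": ridge_wrapper,
}


def get_selector(name_or_fn):
    """Resolve a selector by registry name, or pass a callable through."""
    if callable(name_or_fn):
        return name_or_fn
    try:
        return SELECTORS[name_or_fn]
    except KeyError:
        raise KeyError(f"unknown selector {name_or_fn!r}; choose from {sorted(SELECTORS)}") from None
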