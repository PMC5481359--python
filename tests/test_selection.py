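"""Unit tests for the five feature-ranking methods and selection utilities."""

import numpy as np
import pandas as pd
import pytest

from zsdecode import (AttributeMatrix, TrialTable, attribute_feature_correlation,
                      correlation_stability, fisher_score, mutual_info_stability,
                      normalize_attribute_rows, ridge_wrapper, select_top_m,
                      selection_tally, SELECTORS)
from zsdecode.selection import gaussian_mutual_information, _block_pair_correlations


def blocked_table(profiles_per_block, n_extra_noise=0, rng=None):
    """Build a table from explicit per-block class profiles (B, C, M)."""
    prof = np.asarray(profiles_per_block, float)
    b, c, m = prof.shape
    feats = prof.reshape(b * c, m)
    if n_extra_noise:
        feats = np.hstack([feats, rng.normal(size=(b * c, n_extra_noise))])
    cls = np.tile([f"c{i}" for i in range(c)], b)
    blk = np.repeat(np.arange(1, b + 1), c)
    return TrialTable(feats, cls, blk)


class TestCorrelationStability:
    def test_identical_profiles_score_one(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(1, 59, 1))
        t = blocked_table(np.repeat(p, 6, axis=0))
        assert correlation_stability(t).scores[0] == pytest.approx(1.0)

    def test_negated_profile_scores_minus_one(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(59, 1))
        t = blocked_table(np.stack([p, -p]))
        assert correlation_stability(t).scores[0] == pytest.approx(-1.0)

    def test_noise_features_near_zero(self):
        rng = np.random.default_rng(2)
        t = blocked_table(rng.normal(size=(6, 59, 100)))
        scores = correlation_stability(t).scores
        assert abs(scores.mean()) < 0.05

    def test_zero_variance_block_contributes_zero(self, caplog):
        prof = np.zeros((2, 4, 1))
        prof[0, :, 0] = [1, 2, 3, 4]  # block 2 constant
        with caplog.at_level("WARNING", logger="zsdecode.selection"):
            s = correlation_stability(blocked_table(prof)).scores
        assert s[0] == 0.0

    def test_additive_block_drift_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(59, 1))
        drifted = np.stack([p, p + 5.0, p - 2.0])
        s = correlation_stability(blocked_table(drifted)).scores
        assert s[0] == pytest.approx(1.0)


class TestMutualInfoStability:
    def test_uncorrelated_profiles_zero(self):
        # exactly orthogonal centered profiles -> rho = 0 -> MI = 0
        p1 = np.array([1.0, -1.0, 1.0, -1.0])
        p2 = np.array([1.0, 1.0, -1.0, -1.0])
        t = blocked_table(np.stack([p1, p2])[:, :, None])
        assert mutual_info_stability(t).scores[0] == pytest.approx(0.0)

    def test_known_rho(self):
        assert gaussian_mutual_information(np.array([0.5]))[0] == pytest.approx(
            -0.5 * np.log(0.75), abs=1e-12)

    def test_identical_profiles_capped(self, caplog):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(1, 10, 1))
        t = blocked_table(np.repeat(p, 2, axis=0))
        with caplog.at_level("WARNING", logger="zsdecode.selection"):
            s = mutual_info_stability(t).scores
        assert s[0] == pytest.approx(0.5 * np.log(1e12), rel=1e-6)

    def test_identity_with_covariance_form(self):
        """-1/2 log(1-rho^2) equals 1/2 log(s1^2 s2^2 / |Sigma|) computed from
        the ML covariance of the block profiles (dual-route check)."""
        rng = np.random.default_rng(5)
        t = blocked_table(rng.normal(size=(2, 30, 4)))
        scores = mutual_info_stability(t).scores
        prof = t.features.reshape(2, 30, 4)
        for f in range(4):
            y1, y2 = prof[0, :, f], prof[1, :, f]
            cov = np.cov(np.stack([y1, y2]), ddof=0)
            direct = 0.5 * np.log(cov[0, 0] * cov[1, 1] / np.linalg.det(cov))
            assert scores[f] == pytest.approx(direct, abs=1e-10)


class TestAttributeFeatureCorrelation:
    def _attrs(self, values, n_classes):
        ids = [f"c{i}" for i in range(n_classes)]
        return normalize_attribute_rows(AttributeMatrix(values, ids))

    def test_distinct_perfect_matches(self):
        rng = np.random.default_rng(6)
        c, p = 10, 4
        raw = rng.normal(size=(c, p))
        A = self._attrs(raw, c)
        # features 0..3 copy attributes 0..3 exactly; feature 4 is noise
        prof = np.concatenate([A.values, rng.normal(size=(c, 1))], axis=1)
        t = blocked_table(np.stack([prof, prof + rng.normal(0, 0.01, prof.shape)]))
        r = attribute_feature_correlation(t, A)
        assert sorted(r.order) == [0, 1, 2, 3]
        assert r.pool_size == 4

    def test_shared_winner_shrinks_pool(self):
        rng = np.random.default_rng(7)
        c = 12
        raw = rng.normal(size=(c, 1))
        A = self._attrs(np.hstack([raw, raw * 2]), c)  # two collinear attributes
        prof = np.hstack([A.values[:, :1], rng.normal(size=(c, 3)) * 0.01])
        t = blocked_table(np.stack([prof, prof]))
        r = attribute_feature_correlation(t, A)
        assert r.pool_size == 1
        assert r.order[0] == 0

    def test_pool_never_exceeds_p(self, small_data):
        A, table, _ = small_data
        r = attribute_feature_correlation(table, A)
        assert r.pool_size <= A.P
        assert np.isnan(r.scores[~np.isin(np.arange(table.n_features), r.order)]).all()

    def test_constant_attribute_skipped(self, caplog):
        rng = np.random.default_rng(8)
        c = 8
        vals = np.hstack([np.full((c, 1), 0.5), rng.normal(size=(c, 2))])
        A = AttributeMatrix(vals, [f"c{i}" for i in range(c)])
        # constant attribute stays constant at trial level -> no winner from it
        prof = rng.normal(size=(2, c, 5))
        t = blocked_table(prof)
        with caplog.at_level("WARNING", logger="zsdecode.selection"):
            r = attribute_feature_correlation(t, A)
        assert r.pool_size <= 2


class TestFisherScore:
    def test_hand_example(self):
        # classes {0,2} and {2,4}: between = 2*1+2*1 = 4, within = 2*2+2*2 = 8
        t = TrialTable([[0.0], [2.0], [2.0], [4.0]], ["a", "a", "b", "b"], [1, 2, 1, 2])
        assert fisher_score(t).scores[0] == pytest.approx(0.5)

    def test_constant_feature_zero(self):
        t = TrialTable([[1.0], [1.0], [1.0], [1.0]], ["a", "a", "b", "b"], [1, 2, 1, 2])
        assert fisher_score(t).scores[0] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(12, 3))
        cls = np.repeat(["a", "b", "c"], 4)
        blk = np.tile([1, 2, 3, 4], 3)
        s1 = fisher_score(TrialTable(f, cls, blk)).scores
        s2 = fisher_score(TrialTable(f + 7.5, cls, blk)).scores
        np.testing.assert_allclose(s1, s2, rtol=1e-9)

    def test_zero_within_variance_ranked_first(self, caplog):
        feats = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        t = TrialTable(feats, ["a", "a", "b", "b"], [1, 2, 1, 2])
        with caplog.at_level("WARNING", logger="zsdecode.selection"):
            r = fisher_score(t)
        assert np.isinf(r.scores[0])
        assert r.order[0] == 0


class TestRidgeWrapper:
    def test_linear_feature_outranks_noise(self):
        from zsdecode import SyntheticConfig, generate_dataset
        cfg = SyntheticConfig(n_classes=20, n_blocks=3, p_attributes=20, m_total=80,
                              n_informative=15, snr=3.0, block_drift_sd=0.2, seed=7)
        A, table, truth = generate_dataset(cfg)
        r = ridge_wrapper(table, A)
        informative = set(truth.informative_idx)
        top = set(r.order[: len(informative)])
        assert len(top & informative) >= len(informative) * 0.6

    def test_inner_fold_count_and_scores_bounded(self, small_data):
        A, table, _ = small_data
        r = ridge_wrapper(table, A)
        finite = np.isfinite(r.scores)
        assert (np.abs(r.scores[finite]) <= 1 + 1e-9).all()

    def test_constant_feature_ranked_last(self, small_data):
        A, table, _ = small_data
        feats = table.features.copy()
        feats[:, 0] = 3.14  # constant -> degenerate truth vector
        t = TrialTable(feats, table.class_ids, table.block_ids)
        r = ridge_wrapper(t, A)
        assert r.order[-1] == 0
        assert r.scores[0] == -np.inf


class TestSelectTopM:
    def test_single_best_and_clamp(self, small_data):
        A, table, _ = small_data
        r = correlation_stability(table)
        assert select_top_m(r, 1)[0] == r.order[0]
        assert len(select_top_m(r, 10_000)) == r.pool_size
        np.testing.assert_array_equal(select_top_m(r, 5), select_top_m(r, 5))

    def test_invalid_budget(self, small_data):
        _, table, _ = small_data
        with pytest.raises(ValueError):
            select_top_m(correlation_stability(table), 0)


class TestSelectionTally:
    def test_single_fold_single_bin(self):
        meta = pd.DataFrame({"freq_center_hz": [10.0, 10.0, 80.0]})
        out = selection_tally([[0, 1]], meta)
        assert out.loc[out.freq_center_hz == 10.0, "count"].item() == 2
        assert 80.0 not in out.freq_center_hz.values

    def test_identical_selections_accumulate(self):
        meta = pd.DataFrame({"freq_center_hz": [10.0, 80.0]})
        out = selection_tally([[0]] * 60, meta)
        assert out["count"].item() == 60
        assert out["mean_per_fold"].item() == 1.0

    def test_missing_metadata_column(self):
        with pytest.raises(KeyError):
            selection_tally([[0]], pd.DataFrame({"x": [1]}), by="freq_center_hz")


class TestSelectorInvariances:
    @pytest.mark.parametrize("name", sorted(SELECTORS))
    def test_feature_permutation_equivariance(self, name, small_data):
        """Scores follow the feature under column permutation."""
        A, table, _ = small_data
        rng = np.random.default_rng(10)
        perm = rng.permutation(table.n_features)
        permuted = TrialTable(table.features[:, perm], table.class_ids,
                              table.block_ids)
        s0 = SELECTORS[name](table, A).scores
        s1 = SELECTORS[name](permuted, A).scores
        np.testing.assert_allclose(s1, s0[perm], atol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("fn", [correlation_stability, fisher_score])
    def test_affine_invariance_of_single_feature(self, fn, small_data):
        A, table, _ = small_data
        scaled = table.features.copy()
        scaled[:, 0] = 3.0 * scaled[:, 0] + 11.0
        t2 = TrialTable(scaled, table.class_ids, table.block_ids)
        assert fn(t2).scores[0] == pytest.approx(fn(table).scores[0], rel=1e-9)

    def test_tie_break_by_ascending_index(self):
        t = TrialTable(np.tile([[1.0, 1.0], [2.0, 2.0], [1.1, 1.1], [2.2, 2.2]], 1),
                       ["a", "b", "a", "b"], [1, 1, 2, 2])
        r = correlation_stability(t)
        assert list(r.order) == [0, 1]  # equal scores -> ascending index
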