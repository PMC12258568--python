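"""Group statistics: coding tests, corrections, regressions, nulls, ANOVAs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import seqrsa as sq
from seqrsa.rsa import SimilarityMatrix
from seqrsa.stats import (behavior_metrics, category_contrast,
                          category_contrast_test, correct_pvalues,
                          delta_similarity, diag_vs_offdiag_test, lag_anova,
                          offdiag_pattern_correlation, one_sample_delta_test,
                          split_half_reliability, stepwise_attribution,
                          surrogate_null)


def _sm(values, labels=None, kind="RD_POS"):
    n = values.shape[0]
    labels = labels or list(range(1, n + 1))
    return SimilarityMatrix(kind=kind, values=np.asarray(values, dtype=float),
                            row_labels=list(labels), col_labels=list(labels),
                            n_iterations=1)


class TestDeltaSimilarity:
    def test_identity_like_matrix(self):
        assert delta_similarity(np.eye(4)).delta == pytest.approx(1.0)

    def test_constant_matrix(self):
        assert delta_similarity(np.full((5, 5), 0.3)).delta == pytest.approx(0.0)

    def test_hand_matrix_oracle(self):
        m = np.array([[2.0, 1.0, 0.0],
                      [3.0, 4.0, 1.0],
                      [0.0, 2.0, 3.0]])
        d = delta_similarity(m)
        assert d.diag_mean == pytest.approx((2 + 4 + 3) / 3)
        assert d.offdiag_mean == pytest.approx((1 + 0 + 3 + 1 + 0 + 2) / 6)
        assert d.delta == pytest.approx(d.diag_mean - d.offdiag_mean)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            delta_similarity(np.zeros((2, 3)))


class TestCodingTests:
    def test_identical_vectors_give_t_zero_p_half(self, rng):
        v = rng.standard_normal(10)
        res = diag_vs_offdiag_test(v, v.copy())
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.5)

    def test_df_convention_thirty_subjects(self, rng):
        diag = rng.standard_normal(30) + 0.5
        res = diag_vs_offdiag_test(diag, rng.standard_normal(30))
        assert res.df == 29

    def test_hand_vectors_match_paired_formula(self):
        diag = np.array([0.9, 0.7, 0.8, 0.6])
        off = np.array([0.2, 0.3, 0.1, 0.4])
        res = diag_vs_offdiag_test(diag, off, n_comparisons=5)
        d = diag - off
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1))
        assert res.p_corrected == pytest.approx(min(1, res.p * 5))

    def test_one_sample_zero_deltas(self):
        res = one_sample_delta_test(np.zeros(8))
        assert res.statistic == 0.0 and res.p == pytest.approx(0.5)

    def test_one_sample_constant_positive_flagged(self):
        res = one_sample_delta_test(np.full(8, 0.4))
        assert res.note is not None and "sign-test" in res.note
        assert res.p == pytest.approx(0.5 ** 8)

    def test_one_sample_matches_scipy(self, rng):
        x = rng.standard_normal(12) + 0.3
        res = one_sample_delta_test(x)
        ref = sps.ttest_1samp(x, 0, alternative="greater")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            diag_vs_offdiag_test(np.ones(2), np.zeros(2))


class TestCorrections:
    def test_bonferroni_examples(self):
        assert correct_pvalues([0.01], m=5)[0] == pytest.approx(0.05)
        assert correct_pvalues([0.3], m=5)[0] == 1.0

    def test_bonferroni_never_decreases(self, rng):
        p = rng.random(20)
        assert (correct_pvalues(p, m=5) >= p).all()

    def test_bh_matches_brute_force_on_permutations(self):
        """BH output equals a hand step-up on every ordering of 5 p-values."""
        base = np.array([0.01, 0.02, 0.03, 0.04, 0.05])

        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, p[i] * m / rank)
                adj[i] = val
                prev = val
            return adj

        for perm in itertools.permutations(range(5)):
            p = base[list(perm)]
            np.testing.assert_allclose(
                correct_pvalues(p, method="fdr_bh"), bh_oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalues([1.2])


class TestStepwise:
    def test_dv_equals_predictor(self, rng):
        x = rng.standard_normal(20)
        res = stepwise_attribution(x, pd.DataFrame({"key": x, "pos": rng.standard_normal(20)}))
        assert res.steps[0].predictor == "key"
        assert res.steps[0].r2 == pytest.approx(1.0)
        assert res.steps[0].delta_r2 == pytest.approx(1.0)

    def test_df2_convention_thirty_subjects(self, rng):
        y = rng.standard_normal(30)
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        res = stepwise_attribution(y, X)
        assert res.steps[0].df2 == 28

    def test_delta_r2_matches_hierarchical_oracle(self, rng):
        """Step gains equal direct R^2 differences of nested OLS fits."""
        n = 30
        X = pd.DataFrame({"a": rng.standard_normal(n),
                          "b": rng.standard_normal(n),
                          "c": rng.standard_normal(n)})
        y = 0.9 * X["a"] + 0.5 * X["b"] + 0.2 * rng.standard_normal(n)
        res = stepwise_attribution(y.to_numpy(), X)

        def r2_of(cols):
            Z = np.column_stack([np.ones(n), X[cols].to_numpy()])
            yhat = Z @ np.linalg.lstsq(Z, y.to_numpy(), rcond=None)[0]
            ss_res = ((y - yhat) ** 2).sum()
            return 1 - ss_res / ((y - y.mean()) ** 2).sum()

        entered = []
        r2_prev = 0.0
        for s in res.steps:
            entered.append(s.predictor)
            r2 = r2_of(entered)
            assert s.delta_r2 == pytest.approx(r2 - r2_prev, abs=1e-10)
            # F for the gain, recomputed independently
            df2 = n - len(entered) - 1
            f = (r2 - r2_prev) / ((1 - r2) / df2)
            assert s.f == pytest.approx(f, abs=1e-8)
            r2_prev = r2
        assert res.r2_total == pytest.approx(r2_prev, abs=1e-12)

    def test_full_model_f_df(self, rng):
        y = rng.standard_normal(30)
        X = pd.DataFrame({"a": rng.standard_normal(30),
                          "b": rng.standard_normal(30)})
        res = stepwise_attribution(y, X)
        assert res.full_model_df1 == 2 and res.full_model_df2 == 27

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            stepwise_attribution(np.ones(4), pd.DataFrame(
                {"a": np.arange(4.0), "b": np.arange(4.0) ** 2}))


class TestSurrogate:
    @pytest.mark.parametrize("n", [3, 4])
    def test_exhaustive_surrogate_delta_exactly_zero(self, rng, n):
        m = rng.standard_normal((n, n))
        surr, corr = surrogate_null(m, exhaustive=True)
        assert abs(delta_similarity(surr).delta) < 1e-12
        # each surrogate row is constant: the row mean
        np.testing.assert_allclose(surr, np.tile(m.mean(axis=1)[:, None], n),
                                   atol=1e-12)
        np.testing.assert_allclose(corr, m - surr, atol=1e-12)

    def test_identity_permutation_equals_observed(self, rng):
        m = rng.standard_normal((5, 5))
        surr, corr = surrogate_null(m, perms=[list(range(5))])
        np.testing.assert_allclose(surr, m)
        np.testing.assert_allclose(corr, 0.0, atol=1e-15)

    def test_default_n_perm_is_1000(self):
        import inspect
        assert inspect.signature(surrogate_null).parameters["n_perm"].default == 1000

    def test_similarity_matrix_type_preserved(self, all_matrices):
        surr, corr = surrogate_null(all_matrices["RD_KEY"], n_perm=50, seed=1)
        assert isinstance(surr, SimilarityMatrix)
        assert surr.kind == "RD_KEY"

    def test_bad_n_perm(self, rng):
        with pytest.raises(ValueError):
            surrogate_null(rng.standard_normal((4, 4)), n_perm=0)


class TestReliability:
    def test_duplicated_noiseless_data_r_one(self):
        rng = np.random.default_rng(5)
        patterns = rng.standard_normal((8, 30))
        data = {}
        for run in range(1, 9):
            for s in ("position", "key", "object"):
                for cond in ("SQ_MOT", "SQ_OBJ", "RD"):
                    for l in range(1, 9):
                        data[(run, s, cond, l)] = patterns[l - 1]
        tm = sq.TMapSet(data=data, n_voxels=30, normalized=True)
        r = split_half_reliability(tm, "RD_KEY", n_partitions=3, seed=0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_low_reliability(self, subject_protocol, small_bank):
        amps = sq.CodingAmplitudes().null()
        tm = sq.normalize_tmaps(
            sq.simulate_tmaps(subject_protocol, small_bank, amps, seed=2))
        r = split_half_reliability(tm, "RD_KEY", n_partitions=10, seed=0)
        assert abs(r) < 0.35

    def test_reliability_monotone_in_snr(self, subject_protocol, small_bank):
        rs = []
        for noise in (3.0, 1.0, 0.2):
            amps = sq.CodingAmplitudes(a_key=1.0, a_obj=0, a_pos=0,
                                       a_itempos=0, a_boundary=0,
                                       noise_sigma=noise, subject_sigma=0)
            tm = sq.normalize_tmaps(
                sq.simulate_tmaps(subject_protocol, small_bank, amps, seed=2))
            rs.append(split_half_reliability(tm, "RD_KEY", n_partitions=10,
                                             seed=0))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.9

    def test_too_few_runs(self):
        data = {(r, "key", c, l): np.zeros(5) for r in (1, 2)
                for c in ("RD",) for l in range(1, 9)}
        tm = sq.TMapSet(data=data, n_voxels=5, normalized=True)
        with pytest.raises(ValueError, match="4 runs"):
            split_half_reliability(tm, "RD_KEY")


class TestLagAnova:
    def test_identical_profiles_f_zero(self):
        profiles = pd.DataFrame(np.tile(np.arange(6.0)[:, None], 8))
        res, _ = lag_anova(profiles)
        assert res.statistic == 0.0

    def test_two_levels_f_equals_t_squared(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((9, 2)),
                                columns=["lag0", "lag1"])
        res, _ = lag_anova(profiles)
        t = sps.ttest_rel(profiles["lag0"], profiles["lag1"]).statistic
        assert res.statistic == pytest.approx(t ** 2, rel=1e-10)

    def test_df_convention_eight_lags_thirty_subjects(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((30, 8)))
        res, pairwise = lag_anova(profiles)
        assert res.df == 7
        assert "(7, 203)" in res.note
        assert len(pairwise) == 28

    def test_missing_lag_rejected(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((5, 4)))
        profiles.iloc[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            lag_anova(profiles)


class TestOffdiagCorrelation:
    def test_self_correlation_is_one(self, rng):
        mats = [rng.standard_normal((8, 8)) for _ in range(5)]
        rs, test = offdiag_pattern_correlation(mats, mats)
        np.testing.assert_allclose(rs, 1.0)

    def test_independent_matrices_mean_near_zero(self, rng):
        a = [rng.standard_normal((8, 8)) for _ in range(40)]
        b = [rng.standard_normal((8, 8)) for _ in range(40)]
        rs, test = offdiag_pattern_correlation(a, b)
        assert abs(rs.mean()) < 3 * rs.std(ddof=1) / np.sqrt(len(rs))

    def test_seven_lags_enter(self, rng):
        """Only lags 1-7 drive the correlation: diagonal changes are inert."""
        a = rng.standard_normal((8, 8))
        b = a.copy()
        b[np.diag_indices(8)] += 100.0
        rs, _ = offdiag_pattern_correlation([a], [b])
        assert rs[0] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            offdiag_pattern_correlation([rng.standard_normal((8, 8))],
                                        [rng.standard_normal((6, 6))])


class TestCategoryContrast:
    def test_constant_matrix_zero_contrast(self):
        m = _sm(np.full((8, 8), 0.5), labels=list(sq.CANONICAL_OBJECT_SEQUENCE),
                kind="RD_OBJ")
        c = category_contrast(m)
        assert c.contrast == pytest.approx(0.0)

    def test_same_category_cell_count(self):
        labels = list(sq.CANONICAL_OBJECT_SEQUENCE)
        values = np.zeros((8, 8))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j and sq.OBJECT_CATEGORIES[a] == sq.OBJECT_CATEGORIES[b]:
                    values[i, j] = 1.0
        assert values.sum() == 8  # 4 unordered pairs = 8 ordered cells
        c = category_contrast(_sm(values, labels=labels))
        assert c.same_mean == pytest.approx(1.0)
        assert c.different_mean == pytest.approx(0.0)

    def test_block_matrix_oracle(self):
        labels = list(sq.CANONICAL_OBJECT_SEQUENCE)
        rng = np.random.default_rng(3)
        values = rng.standard_normal((8, 8))
        c = category_contrast(_sm(values, labels=labels))
        same, diff = [], []
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                (same if sq.OBJECT_CATEGORIES[a] == sq.OBJECT_CATEGORIES[b]
                 else diff).append(values[i, j])
        assert c.same_mean == pytest.approx(np.mean(same))
        assert c.different_mean == pytest.approx(np.mean(diff))
        assert set(c.per_category) == {"fruit", "vehicle", "animal", "tool"}

    def test_bad_category_map_rejected(self):
        m = _sm(np.zeros((8, 8)), labels=list(sq.CANONICAL_OBJECT_SEQUENCE))
        bad = dict(sq.OBJECT_CATEGORIES)
        bad["axe"] = "fruit"
        with pytest.raises(ValueError):
            category_contrast(m, bad)

    def test_group_paired_test(self, rng):
        labels = list(sq.CANONICAL_OBJECT_SEQUENCE)
        mats = [_sm(rng.standard_normal((8, 8)), labels=labels)
                for _ in range(6)]
        df, test = category_contrast_test(mats)
        assert len(df) == 6
        assert test.tails == "two-tailed"


class TestBehaviorMetrics:
    @staticmethod
    def _table(rng, n_sub=6, advantage=0.0):
        rows = []
        for s in range(n_sub):
            for cond in ("SQ_MOT", "RD"):
                for block in (1, 2):
                    for _ in range(10):
                        rt = 0.8 - advantage * (cond == "SQ_MOT") \
                            + 0.05 * rng.standard_normal()
                        rows.append({"subject": s, "condition": cond,
                                     "block": block, "rt_s": rt,
                                     "correct": True})
        return pd.DataFrame(rows)

    def test_constant_rt_all_correct(self, rng):
        df = self._table(rng)
        df["rt_s"] = 0.5
        metrics, _ = behavior_metrics(df)
        assert (metrics["mean_rt_s"] == 0.5).all()
        assert (metrics["pct_correct"] == 100.0).all()

    def test_metrics_values(self):
        df = pd.DataFrame({
            "subject": [1] * 4, "condition": ["RD"] * 4, "block": [1] * 4,
            "rt_s": [0.5, 0.7, 0.6, 10.0],
            "correct": [True, True, True, False],
        })
        responses = df
        grp = responses.assign(
            _rt=responses["rt_s"].where(responses["correct"]))
        # accuracy denominator is all trials of the block
        assert 100 * responses["correct"].mean() == 75.0
        assert grp["_rt"].mean() == pytest.approx(0.6)

    def test_two_by_two_anova_matches_paired_t(self, rng):
        df = self._table(rng, advantage=0.1)
        metrics, aovs = behavior_metrics(df)
        aov = aovs["mean_rt_s"]
        cond = aov[aov["Source"] == "condition"].iloc[0]
        # with 2 levels, the main-effect F is the square of the paired t
        cell = metrics.groupby(["subject", "condition"])["mean_rt_s"].mean().unstack()
        t = sps.ttest_rel(cell["SQ_MOT"], cell["RD"]).statistic
        assert cond["F"] == pytest.approx(t ** 2, rel=1e-8)
        assert 0 <= cond["np2"] <= 1

    def test_zero_correct_block_warns(self, rng):
        df = self._table(rng)
        df.loc[(df["subject"] == 0) & (df["block"] == 1)
               & (df["condition"] == "RD"), "correct"] = False
        with pytest.warns(RuntimeWarning, match="zero correct"):
            metrics, _ = behavior_metrics(df)
        bad = metrics.query("subject == 0 and block == 1 and condition == 'RD'")
        assert bad["mean_rt_s"].isna().all()
        assert bad["pct_correct"].iloc[0] == 0.0

    def test_uncrossed_design_rejected(self, rng):
        df = self._table(rng)
        df = df[~((df["condition"] == "RD") & (df["block"] == 2))]
        with pytest.raises(ValueError, match="crossed"):
            behavior_metrics(df)
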