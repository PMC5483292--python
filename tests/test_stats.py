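"""PCA reduction and Wilks-lambda MANOVA against independent oracles."""

import numpy as np
import pytest

from thermoface.core import FeatureMatrix
from thermoface.schedule import ALL_BLOCKS, EmotionType
from thermoface.stats import (
    StatsError,
    analyze_cohort,
    manova_wilks,
    pca_reduce,
    table2_analysis,
)

from _oracles import hotelling_t2_f, pooled_t_squared
from conftest import two_group_data


def block(X, y, roi="forehead", emotion="LVHA"):
    return FeatureMatrix(X, y, roi, emotion)


class TestPca:
    def test_scores_shape_35x9(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(35, 48)), np.array(["moderate"] * 18 + ["marked"] * 17)
        model, reduced = pca_reduce(block(X, y), k=9)
        assert reduced.values.shape == (35, 9)
        assert model.components.shape == (9, 48)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        # orthonormal loadings
        assert np.allclose(model.components @ model.components.T, np.eye(9), atol=1e-10)

    def test_zero_variance_matrix(self):
        X = np.full((10, 5), 3.0)
        y = np.array(["moderate"] * 5 + ["marked"] * 5)
        model, reduced = pca_reduce(block(X, y), k=2)
        assert np.all(reduced.values == 0.0)
        assert np.all(model.explained_variance_ratio == 0.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(12, 8)), np.array(["moderate"] * 6 + ["marked"] * 6)
        model, reduced = pca_reduce(block(X, y), k=8)
        recon = reduced.values @ model.components + model.mean
        assert np.abs(recon - X).max() < 1e-8

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(6, 10)), np.array(["moderate"] * 3 + ["marked"] * 3)
        with pytest.raises(StatsError):
            pca_reduce(block(X, y), k=6)

    def test_scores_invariant_under_row_reordering(self):
        rng = np.random.default_rng(3)
        X, y = two_group_data(rng, 10, 10, k=6)
        perm = rng.permutation(20)
        _, r1 = pca_reduce(block(X, y), k=4)
        _, r2 = pca_reduce(block(X[perm], y[perm]), k=4)
        assert np.allclose(r1.values[perm], r2.values, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        X, y = two_group_data(rng, 10, 10, k=6)
        model, _ = pca_reduce(block(X, y), k=4)
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0


class TestWilksManova:
    def test_no_between_group_variation(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(10, 3))
        X = np.vstack([base, base])  # identical rows duplicated across groups
        y = np.array(["moderate"] * 10 + ["marked"] * 10)
        res = manova_wilks(block(X, y))
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.f_value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_univariate_case_equals_squared_pooled_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        x[15:] += 0.8
        y = np.array(["moderate"] * 15 + ["marked"] * 15)
        res = manova_wilks(block(x[:, None], y))
        assert res.df1 == 1 and res.df2 == 28
        assert res.f_value == pytest.approx(pooled_t_squared(x, y), rel=1e-12)

    def test_agrees_with_hotelling_oracle_100_instances(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            X, y = two_group_data(rng, 18, 17, k=9, gap=rng.uniform(0, 1))
            res = manova_wilks(block(X, y))
            _, f_oracle, df = hotelling_t2_f(X, y)
            worst = max(worst, abs(res.f_value - f_oracle))
            assert (res.df1, res.df2) == df == (9, 25)
        assert worst < 1e-10

    def test_agrees_with_statsmodels(self):
        """Independent library cross-check of the Wilks statistic itself."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(8)
        X, y = two_group_data(rng, 18, 17, k=4, gap=0.7)
        res = manova_wilks(block(X, y))
        sm = MANOVA(endog=X, exog=np.column_stack([np.ones(35), y == "marked"]))
        tab = sm.mv_test().results["x1"]["stat"]
        assert res.wilks_lambda == pytest.approx(tab.loc["Wilks' lambda", "Value"], abs=1e-10)
        assert res.f_value == pytest.approx(tab.loc["Wilks' lambda", "F Value"], abs=1e-8)
        assert res.p_value == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], abs=1e-10)

    def test_p_decreases_as_gap_grows(self):
        rng = np.random.default_rng(9)
        noise = rng.normal(size=(30, 5))
        y = np.array(["moderate"] * 15 + ["marked"] * 15)
        last_p = 1.1
        for gap in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = noise.copy()
            X[15:, 0] += gap
            p = manova_wilks(block(X, y)).p_value
            assert p <= last_p + 1e-12
            last_p = p

    def test_lambda_always_in_unit_interval(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            X, y = two_group_data(rng, 6, 6, k=3, gap=rng.uniform(0, 3))
            lam = manova_wilks(block(X, y)).wilks_lambda
            assert 0.0 < lam <= 1.0

    def test_singular_within_sscp_rejected(self):
        X = np.zeros((8, 4))
        X[:, 0] = np.arange(8)
        y = np.array(["moderate"] * 4 + ["marked"] * 4)
        with pytest.raises(StatsError):
            manova_wilks(block(X, y))

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 2))
        y = np.array(["moderate"] * 4 + ["marked"])
        with pytest.raises(StatsError):
            manova_wilks(block(X, y))

    def test_summary_mentions_statistic(self):
        rng = np.random.default_rng(12)
        X, y = two_group_data(rng, 10, 10, k=3, gap=1.0)
        text = manova_wilks(block(X, y)).summary()
        assert "Wilks" in text and "F(3, 16)" in text


class TestTable:
    def _blocks(self, rng, reduce_to=None):
        blocks = {}
        for roi in ("forehead", "nose", "mouth", "left_cheek", "right_cheek"):
            for emo in ALL_BLOCKS:
                X, y = two_group_data(rng, 10, 10, k=12)
                fm = FeatureMatrix(X, y, roi, emo.value)
                if reduce_to:
                    _, fm = pca_reduce(fm, k=reduce_to)
                blocks[(roi, emo)] = fm
        return blocks

    def test_full_grid_shape_and_stars(self):
        rng = np.random.default_rng(13)
        tab = table2_analysis(self._blocks(rng, reduce_to=3))
        assert len(tab) == 20
        assert set(tab["emotion"]) == {"HVLA", "LVLA", "LVHA", "REST"}
        assert set(tab["stars"]) <= {"", "*", "**", "***"}

    def test_missing_cell_named(self):
        rng = np.random.default_rng(14)
        blocks = self._blocks(rng, reduce_to=3)
        del blocks[("nose", EmotionType.LVLA)]
        with pytest.raises(StatsError, match="nose.*LVLA"):
            table2_analysis(blocks)

    def test_identical_blocks_identical_statistics(self):
        rng = np.random.default_rng(15)
        X, y = two_group_data(rng, 10, 10, k=3, gap=0.5)
        blocks = {
            (roi, emo): FeatureMatrix(X, y, roi, emo.value)
            for roi in ("forehead", "nose", "mouth", "left_cheek", "right_cheek")
            for emo in ALL_BLOCKS
        }
        tab = table2_analysis(blocks)
        assert tab["F"].nunique() == 1 and tab["p"].nunique() == 1

    def test_analyze_cohort_records_singular_cells(self):
        rng = np.random.default_rng(16)
        blocks = {
            (roi, emo): FeatureMatrix(
                rng.normal(size=(4, 6)), np.array(["moderate"] * 2 + ["marked"] * 2),
                roi, emo.value,
            )
            for roi in ("forehead", "nose", "mouth", "left_cheek", "right_cheek")
            for emo in ALL_BLOCKS
        }
        tab = analyze_cohort(blocks, k=3, on_error="record")
        assert len(tab) == 20
        assert (tab["error"] != "").all()  # N - k - 1 = 0: every cell degenerate
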