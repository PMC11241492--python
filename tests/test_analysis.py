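"""Descriptive sensory analytics: correlations, box stats, shared features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactosense.analysis import (
    boxplot_stats,
    overlap_correlation_trend,
    shared_feature_counts,
    spearman_matrix,
)
from lactosense.pipeline import PipelineParams, fit_pipeline
from lactosense.simulate import simulate_genotypes, simulate_phenotypes, trend_design


class TestSpearman:
    def test_unit_diagonal_and_symmetry(self, rng):
        P = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        rho = spearman_matrix(P)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)
        assert (rho.to_numpy() <= 1).all() and (rho.to_numpy() >= -1).all()

    def test_perfect_inverse_monotone(self):
        x = np.arange(10.0)
        P = pd.DataFrame({"x": x, "y": np.exp(-x)})
        assert spearman_matrix(P).loc["x", "y"] == pytest.approx(-1.0)

    def test_midrank_tie_handling_hand_computed(self):
        # mid-ranks: x=(1,2,2,4) -> (1, 2.5, 2.5, 4); y identical ranks -> rho 1
        P = pd.DataFrame({"x": [1, 2, 2, 4], "y": [1, 3, 3, 5]})
        assert spearman_matrix(P).loc["x", "y"] == pytest.approx(1.0)

    def test_constant_column_rejected_by_name(self):
        P = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            spearman_matrix(P)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        P = pd.DataFrame(rng.random((12, 3)), columns=list("abc"))
        Q = P.copy()
        Q["b"] = np.exp(3 * Q["b"])  # strictly monotone transform
        pd.testing.assert_frame_equal(spearman_matrix(P), spearman_matrix(Q))


class TestBoxplotStats:
    def test_identical_values_degenerate(self):
        P = pd.DataFrame({"a": [3.0] * 8})
        row = boxplot_stats(P).loc["a"]
        assert row["q1"] == row["median"] == row["q3"] == 3.0
        assert row["outliers"] == []

    def test_far_point_flagged_outlier(self):
        P = pd.DataFrame({"a": list(range(1, 10)) + [100]}, index=[f"s{i}" for i in range(10)])
        row = boxplot_stats(P).loc["a"]
        q1, q3 = np.percentile(P["a"], [25, 75])
        assert row["q1"] == pytest.approx(q1) and row["q3"] == pytest.approx(q3)
        assert row["outliers"] == ["s9"]
        assert row["whisker_hi"] == 9

    def test_translation_equivariance(self, rng):
        x = rng.random(30)
        P = pd.DataFrame({"a": x})
        Q = pd.DataFrame({"a": x + 7.5})
        a, b = boxplot_stats(P).loc["a"], boxplot_stats(Q).loc["a"]
        for stat in ("q1", "median", "q3", "whisker_lo", "whisker_hi"):
            assert b[stat] == pytest.approx(a[stat] + 7.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5"):
            boxplot_stats(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSharedFeatures:
    def test_set_arithmetic(self):
        sfm = shared_feature_counts({"p": ["A", "B", "C"], "q": ["B", "C", "D"]})
        assert sfm.loc["p", "q"] == 2
        assert sfm.loc["p", "p"] == 3 and sfm.loc["q", "q"] == 3

    def test_identical_and_disjoint_masks(self):
        sfm = shared_feature_counts({"a": ["x", "y"], "b": ["x", "y"], "c": ["z"]})
        assert sfm.loc["a", "b"] == sfm.loc["a", "a"] == 2
        assert sfm.loc["a", "c"] == 0

    def test_matrix_invariants(self, rng):
        masks = {f"p{i}": rng.choice(50, size=rng.integers(5, 20), replace=False).tolist() for i in range(4)}
        sfm = shared_feature_counts(masks)
        M = sfm.to_numpy()
        assert (M == M.T).all() and (M >= 0).all()
        for i in range(4):
            for j in range(4):
                assert M[i, j] <= min(M[i, i], M[j, j])

    def test_id_space_mismatch_rejected(self):
        with pytest.raises(ValueError, match="id space"):
            shared_feature_counts({"p": ["A", "ZZZ"]}, universe=["A", "B"])


class TestPlotting:
    def test_plot_functions_render_without_display(self, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from lactosense.analysis import plot_boxplots, plot_heatmap, plot_importance
        from lactosense.importance import ImportanceVector

        P = pd.DataFrame(rng.random((20, 3)), columns=["Umami", "Richness", "W1C"])
        ax1 = plot_boxplots(P)
        ax2 = plot_heatmap(spearman_matrix(P), title="corr")
        iv = ImportanceVector(np.array(["SNP_1", "GENE_2"], dtype=object), np.array([1.0, -2.0]))
        ax3 = plot_importance(iv, k=2)
        for ax in (ax1, ax2, ax3):
            ax.figure.savefig(tmp_path / f"{id(ax)}.png", dpi=40)
            plt.close(ax.figure)


class TestOverlapTrend:
    def corr_and_counts(self, counts_by_pair):
        names = ["a", "b", "c"]
        corr = pd.DataFrame(np.eye(3), index=names, columns=names)
        sfm = pd.DataFrame(np.zeros((3, 3), dtype=int), index=names, columns=names)
        for (i, j), (c, s) in counts_by_pair.items():
            corr.iloc[i, j] = corr.iloc[j, i] = c
            sfm.iloc[i, j] = sfm.iloc[j, i] = s
        return corr, sfm

    def test_perfect_monotone_gives_rho_one(self):
        corr, sfm = self.corr_and_counts({(0, 1): (0.9, 30), (0, 2): (0.5, 10), (1, 2): (0.1, 1)})
        assert overlap_correlation_trend(corr, sfm).rho == pytest.approx(1.0)

    def test_constant_counts_undefined(self):
        corr, sfm = self.corr_and_counts({(0, 1): (0.9, 5), (0, 2): (0.5, 5), (1, 2): (0.1, 5)})
        result = overlap_correlation_trend(corr, sfm)
        assert not result.defined and "undefined" in result.note

    def test_too_few_phenotypes_rejected(self):
        names = ["a", "b"]
        m = pd.DataFrame(np.eye(2), index=names, columns=names)
        with pytest.raises(ValueError, match="3"):
            overlap_correlation_trend(m, m.astype(int))

    def test_planted_overlaps_recovered_from_pipeline_masks(self):
        # end-to-end direction check: pairs with more planted causal overlap
        # should show both higher |correlation| and more shared survivors
        positives = []
        for seed in range(5):
            design = trend_design(
                n_samples=120, n_features_per_class=(250, 150, 100), n_causal=40, seed=seed
            )
            G = simulate_genotypes(design)
            P = simulate_phenotypes(G, design)
            X = G.to_numpy(dtype=float)
            params = PipelineParams(0.0, 40, 5, 60, "r2", 20)
            masks = {}
            for name in P.columns:
                fp = fit_pipeline(params, X, P[name].to_numpy(), feature_ids=G.columns.to_numpy(object), seed=seed)
                masks[name] = fp.selected_feature_ids
            corr = spearman_matrix(P)
            sfm = shared_feature_counts(masks, universe=G.columns)
            positives.append(overlap_correlation_trend(corr, sfm).rho > 0)
        assert sum(positives) >= 4
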