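"""Synthetic genotype/phenotype generator: contracts and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lactosense.simulate import (
    PhenotypeSpec,
    SimDesign,
    block_overlap_design,
    design_from_dict,
    design_to_dict,
    planted_overlap_design,
    simulate_genotypes,
    simulate_phenotypes,
    trend_design,
)


def small_design(**kw):
    defaults = dict(n_samples=10, n_features_per_class=(5, 3, 2), seed=1)
    defaults.update(kw)
    return SimDesign(**defaults)


class TestGenotypes:
    def test_shape_and_class_prefixed_ids(self):
        G = simulate_genotypes(small_design())
        assert G.shape == (10, 10)
        prefixes = [c.split("_")[0] for c in G.columns]
        assert prefixes == ["SNP"] * 5 + ["GENE"] * 3 + ["IGR"] * 2
        assert set(np.unique(G.to_numpy())) <= {0, 1}

    def test_same_seed_bitwise_identical(self):
        d = small_design(n_samples=50)
        a, b = simulate_genotypes(d), simulate_genotypes(d)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_genotypes(small_design(n_samples=50))
        b = simulate_genotypes(small_design(n_samples=50, seed=2))
        assert not a.equals(b)

    def test_bernoulli_mean_at_half(self):
        d = small_design(n_samples=4000, presence_prob_range=(0.5, 0.5))
        G = simulate_genotypes(d)
        means = G.to_numpy().mean(axis=0)
        assert np.all(np.abs(means - 0.5) < 4 / np.sqrt(4000))

    def test_feature_variance_converges_to_p_times_one_minus_p(self):
        # population variance of Bernoulli(p) is p(1-p)
        d = small_design(n_samples=100_000, n_features_per_class=(3, 2, 1))
        G = simulate_genotypes(d)
        means = G.to_numpy().mean(axis=0)
        variances = G.to_numpy(dtype=float).var(axis=0)
        assert np.all(np.abs(variances - means * (1 - means)) < 0.01)

    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(n_samples=0), "n_samples"),
            (dict(n_features_per_class=(5, 0, 2)), "GENE"),
            (dict(presence_prob_range=(0.0, 0.5)), "presence_prob_range"),
            (dict(presence_prob_range=(0.5, 1.0)), "presence_prob_range"),
        ],
    )
    def test_invalid_design_rejected_naming_field(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_genotypes(small_design(**kw))


class TestPhenotypes:
    def test_zero_noise_single_causal_is_identity(self):
        spec = PhenotypeSpec("y", causal_indices=(3,), effect_sizes=(1.0,), noise_sd=0.0)
        d = small_design(phenotype_specs=(spec,))
        G = simulate_genotypes(d)
        P = simulate_phenotypes(G, d)
        np.testing.assert_array_equal(P["y"].to_numpy(), G.iloc[:, 3].to_numpy(dtype=float))

    def test_identical_causal_sets_give_perfect_spearman(self):
        specs = tuple(
            PhenotypeSpec(n, causal_indices=(0, 4, 7), effect_sizes=(1.0, -2.0, 0.5), noise_sd=0.0)
            for n in ("a", "b")
        )
        d = small_design(n_samples=60, phenotype_specs=specs)
        P = simulate_phenotypes(simulate_genotypes(d), d)
        rho = stats.spearmanr(P["a"], P["b"]).statistic
        assert rho == pytest.approx(1.0)

    def test_causal_id_absent_rejected(self):
        spec = PhenotypeSpec("y", causal_indices=(99,), effect_sizes=(1.0,), noise_sd=0.0)
        d = small_design(phenotype_specs=(spec,))
        with pytest.raises(ValueError, match="causal index"):
            simulate_phenotypes(simulate_genotypes(small_design()), d)

    def test_full_overlap_pairs_more_correlated_than_disjoint(self):
        # Monte-Carlo oracle on the generator: run both designs over 20 seeds
        wins = []
        for seed in range(20):
            full = planted_overlap_design(
                n_samples=100, n_features_per_class=(40, 30, 30), names=("a", "b"),
                n_causal=10, overlaps={(0, 1): 10}, signal_fraction=0.7, seed=seed,
            )
            none = planted_overlap_design(
                n_samples=100, n_features_per_class=(40, 30, 30), names=("a", "b"),
                n_causal=10, overlaps={}, signal_fraction=0.7, seed=seed,
            )
            rhos = {}
            for tag, d in (("full", full), ("none", none)):
                P = simulate_phenotypes(simulate_genotypes(d), d)
                rhos[tag] = abs(stats.spearmanr(P["a"], P["b"]).statistic)
            wins.append(rhos["full"] > rhos["none"])
        assert np.mean(wins) > 0.9

    def test_planted_signal_supports_ols_r2(self):
        # with signal fraction 0.9 an OLS on the true causal columns reaches
        # high in-sample R² at the default panel size
        r2s = []
        for seed in range(7):
            d = planted_overlap_design(
                n_samples=194, n_features_per_class=(200, 100, 100), names=("y",),
                n_causal=20, signal_fraction=0.9, seed=seed,
            )
            G = simulate_genotypes(d)
            P = simulate_phenotypes(G, d)
            idx = np.asarray(d.phenotype_specs[0].causal_indices)
            A = np.column_stack([G.to_numpy(dtype=float)[:, idx], np.ones(194)])
            y = P["y"].to_numpy()
            resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            r2s.append(1 - resid.var() / y.var())
        assert np.median(r2s) >= 0.85


class TestOverlapDesigns:
    def test_planted_overlaps_are_exact(self):
        d = trend_design(n_samples=20, n_features_per_class=(100, 60, 40), seed=3)
        om = d.overlap_matrix()
        assert om.loc["P1", "P2"] == 30
        assert om.loc["P3", "P4"] == 10
        assert om.loc["P1", "P3"] == om.loc["P1", "P4"] == om.loc["P2", "P4"] == 0
        assert (np.diag(om) == 40).all()

    def test_block_design_gradient(self):
        d = block_overlap_design(
            n_samples=20, n_features_per_class=(300, 200, 100), n_causal=20, seed=0
        )
        om = d.overlap_matrix()
        names = list(om.columns)
        assert om.loc[names[0], names[1]] == 15  # 75 %
        assert om.loc[names[2], names[3]] == 5  # 25 %
        assert om.loc[names[4], names[5]] == 0

    def test_overlap_exceeding_causal_size_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            planted_overlap_design(
                n_samples=10, n_features_per_class=(50, 30, 20), names=("a", "b"),
                n_causal=5, overlaps={(0, 1): 9}, seed=0,
            )

    def test_design_roundtrips_through_dict(self):
        d = trend_design(n_samples=15, n_features_per_class=(100, 60, 40), seed=9)
        assert design_from_dict(design_to_dict(d)) == d
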