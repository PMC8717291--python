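"""Synthetic survey generator: pool, traits, communities, geography, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kipuka import (
    SyntheticConfig,
    ValidationError,
    generate_dataset,
    generate_kipuka_survey,
    generate_regional_pool,
    simulate_traits,
    synthesize_support_table,
    write_dataset,
)


def small_config(**kw):
    base = dict(
        n_regional=50,
        lam=1.0,
        mu=0.0,
        n_communities=6,
        richness_range=(5, 10),
        seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestRegionalPool:
    def test_pool_shape_and_ultrametricity(self):
        cfg = small_config(n_regional=10)
        tree, traits = generate_regional_pool(cfg)
        assert tree.n_tips == 10
        td = tree.tip_depths()
        assert np.ptp(td) <= 1e-9 * max(1.0, td.max())
        assert len(traits) == 10
        assert list(traits.index) == tree.tip_labels

    def test_bm_tip_variance_on_star_tree(self, star_tree_factory):
        """Monte-Carlo check of Var[x_tip] = sigma2 * T under BM."""
        T = 2.5
        star = star_tree_factory(10, T)
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [simulate_traits(star, rng, model="BM", sigma2=1.0) for _ in range(500)]
        )
        assert np.var(draws) == pytest.approx(T, rel=0.05)

    def test_ou_alpha_zero_matches_bm(self, star_tree_factory):
        star = star_tree_factory(4, 1.5)
        rng = np.random.default_rng(1)
        bm = np.concatenate(
            [simulate_traits(star, rng, model="BM", sigma2=1.0) for _ in range(500)]
        )
        ou = np.concatenate(
            [
                simulate_traits(star, rng, model="OU", sigma2=1.0, alpha=0.0, theta=0.0)
                for _ in range(500)
            ]
        )
        assert stats.ks_2samp(bm, ou).pvalue > 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            small_config(n_regional=1)
        with pytest.raises(ValidationError):
            small_config(mu=2.0)  # mu >= lambda
        with pytest.raises(ValidationError):
            small_config(richness_range=(5, 60))  # exceeds pool
        with pytest.raises(ValidationError):
            small_config(tau=0.0)


class TestSurvey:
    def test_survey_shape(self):
        cfg = SyntheticConfig(
            n_regional=100, n_communities=19, richness_range=(9, 20), seed=4
        )
        ds = generate_dataset(cfg)
        assert len(ds.communities) == 19
        sizes = [len(m) for m in ds.communities.values()]
        assert all(9 <= s <= 20 for s in sizes)
        tips = set(ds.regional_tree.tip_labels)
        for members in ds.communities.values():
            assert len(set(members)) == len(members)
            assert set(members) <= tips
        assert set(ds.traits.index) == tips

    def test_geography_ranges(self):
        ds = generate_dataset(small_config())
        g = ds.geography
        assert g["area_m2"].between(700, 114_100).all()
        assert g["isolation_m"].between(17.65, 2_137).all()
        assert g["elevation_m"].between(1_358, 1_678).all()
        assert (g["richness"] == [len(ds.communities[c]) for c in g["community_id"]]).all()

    def test_no_planted_effect_means_constant_tau(self):
        ds = generate_dataset(small_config(geography_effects=None))
        assert ds.community_tau.nunique() == 1

    def test_planted_effect_links_tau_to_covariate(self):
        ds = generate_dataset(
            small_config(assembly_model="filtering", geography_effects={"elevation": 5.0})
        )
        r = np.corrcoef(ds.geography["elevation_m"], ds.community_tau)[0, 1]
        assert r > 0.99  # tau is a linear function of elevation alone

    def test_richness_above_pool_rejected(self):
        cfg = small_config()
        tree, traits = generate_regional_pool(small_config(n_regional=8, richness_range=(2, 5)))
        with pytest.raises(ValidationError):
            generate_kipuka_survey((tree, traits), small_config(richness_range=(9, 20)))

    def test_neutral_inclusion_frequencies_binomial(self):
        """Neutral assembly: every pool species included at rate richness/pool."""
        cfg = SyntheticConfig(
            n_regional=50,
            n_communities=40,
            richness_range=(8, 8),
            assembly_model="neutral",
            seed=0,
        )
        tree, traits = generate_regional_pool(cfg)
        counts = np.zeros(50)
        reps = 50
        for s in range(reps):
            c2 = SyntheticConfig(**{**cfg.__dict__, "seed": s})
            ds = generate_kipuka_survey((tree, traits), c2)
            for members in ds.communities.values():
                for m in members:
                    counts[tree.tip_index[m]] += 1
        n_draws = reps * 40
        p = 8 / 50
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 5 * se)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        for name in ("regional_tree.nwk", "traits.csv", "communities.csv", "geography.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestSupportSynthesis:
    def test_rows_sum_to_one(self, rng):
        geo = generate_dataset(small_config()).geography
        sup = synthesize_support_table(geo, seed=0)
        totals = sup[["p_neutral", "p_filtering", "p_competition"]].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)

    def test_planted_effect_shifts_support(self):
        geo = generate_dataset(small_config(n_communities=19)).geography
        sup = synthesize_support_table(
            geo, effects={("p_filtering", "elevation"): -3.0}, noise_sd=0.1, seed=1
        )
        r = np.corrcoef(geo["elevation_m"], sup["p_filtering"])[0, 1]
        assert r < -0.5
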