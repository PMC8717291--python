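"""BM/OU likelihoods against dense multivariate-normal oracles; fitting; α profiling."""

import numpy as np
import pytest
from scipy import stats

from kipuka import (
    Phylogeny,
    ValidationError,
    bm_loglik,
    fit_model,
    ou_loglik,
    profile_alpha,
    simulate_birth_death_tree,
    simulate_traits,
)
from kipuka.trait_models import select_plateau


def dense_bm_oracle(tree, x, sigma2, z0):
    """Independent route: explicit covariance + scipy's multivariate normal."""
    C = sigma2 * tree.mrca_depth_matrix()
    return stats.multivariate_normal.logpdf(x, mean=np.full(len(x), z0), cov=C)


def dense_ou_oracle(tree, x, sigma2, alpha, theta, z0):
    td = tree.tip_depths()
    s = tree.mrca_depth_matrix()
    V = (
        sigma2
        / (2 * alpha)
        * np.exp(-alpha * (td[:, None] + td[None, :] - 2 * s))
        * (1 - np.exp(-2 * alpha * s))
    )
    np.fill_diagonal(V, sigma2 / (2 * alpha) * (1 - np.exp(-2 * alpha * td)))
    mean = z0 * np.exp(-alpha * td) + theta * (1 - np.exp(-alpha * td))
    return stats.multivariate_normal.logpdf(x, mean=mean, cov=V)


class TestLikelihoods:
    def test_two_tip_closed_form(self, star_tree_factory):
        """Two unit branches from the root: independent unit normals."""
        t = star_tree_factory(2, 1.0)
        ll = bm_loglik(t, np.array([0.0, 2.0]), sigma2=1.0, z0=0.0)
        assert ll == pytest.approx(-np.log(2 * np.pi) - 2.0, abs=1e-9)

    def test_bm_scale_invariance(self, rng):
        t = simulate_birth_death_tree(15, 1.0, 0.2, rng)
        x = rng.normal(size=15)
        ll = bm_loglik(t, x, sigma2=0.7, z0=0.1)
        c = 3.7
        labels: list = [None] * t.n_nodes
        for v in t.tip_nodes:
            labels[v] = t.tip_labels[t.tip_index_of_node(int(v))]
        scaled = Phylogeny(t.parent, t.blen * c, labels)
        assert bm_loglik(scaled, x, sigma2=0.7 / c, z0=0.1) == pytest.approx(ll, abs=1e-8)

    def test_bm_matches_dense_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 12))
            t = simulate_birth_death_tree(n, 1.0, 0.3, rng)
            x = rng.normal(size=n)
            s2 = float(rng.uniform(0.3, 2.0))
            z0 = float(rng.normal())
            assert bm_loglik(t, x, s2, z0) == pytest.approx(
                dense_bm_oracle(t, x, s2, z0), abs=1e-8
            )

    def test_ou_matches_dense_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 12))
            t = simulate_birth_death_tree(n, 1.0, 0.2, rng)
            x = rng.normal(size=n)
            s2, a = float(rng.uniform(0.3, 2.0)), float(rng.uniform(0.05, 2.0))
            th, z0 = float(rng.normal()), float(rng.normal())
            assert ou_loglik(t, x, s2, a, th, z0) == pytest.approx(
                dense_ou_oracle(t, x, s2, a, th, z0), abs=1e-8
            )

    def test_ou_degenerates_to_bm(self, rng):
        for _ in range(5):
            t = simulate_birth_death_tree(10, 1.0, 0.0, rng)
            x = rng.normal(size=10)
            assert ou_loglik(t, x, 1.0, 1e-10, 0.0, 0.0) == pytest.approx(
                bm_loglik(t, x, 1.0, 0.0), abs=1e-6
            )

    def test_ou_stationary_limit(self, rng):
        """Huge alpha: tips are iid N(theta, sigma2/2alpha)."""
        t = simulate_birth_death_tree(10, 1.0, 0.0, rng)
        x = rng.normal(size=10)
        alpha = 300.0
        ll = ou_loglik(t, x, 1.0, alpha, 0.3, 0.3)
        iid = stats.norm.logpdf(x, loc=0.3, scale=np.sqrt(1.0 / (2 * alpha))).sum()
        assert ll == pytest.approx(iid, abs=1e-4)

    def test_tip_order_permutation_invariance(self, rng):
        import pandas as pd

        t = simulate_birth_death_tree(10, 1.0, 0.0, rng)
        s = pd.Series(rng.normal(size=10), index=t.tip_labels)
        shuffled = s.sample(frac=1, random_state=1)
        assert bm_loglik(t, s, 1.0, 0.0) == pytest.approx(bm_loglik(t, shuffled, 1.0, 0.0))


class TestFitting:
    def test_ou_fit_at_least_as_good_as_bm(self, rng):
        t = simulate_birth_death_tree(40, 1.0, 0.0, rng)
        x = simulate_traits(t, rng, model="BM", sigma2=1.0)
        bm = fit_model(t, x, "BM")
        ou = fit_model(t, x, "OU", alpha_bound=1.0, n_starts=3)
        assert ou.loglik >= bm.loglik - 1e-6
        assert bm.aic == pytest.approx(4 - 2 * bm.loglik)
        assert ou.aic == pytest.approx(8 - 2 * ou.loglik)

    def test_bm_rate_recovery(self, rng):
        t = simulate_birth_death_tree(128, 1.0, 0.0, rng)
        est = []
        for _ in range(60):
            x = simulate_traits(t, rng, model="BM", sigma2=1.0)
            est.append(fit_model(t, x, "BM").sigma2)
        assert 0.85 <= float(np.median(est)) <= 1.15

    def test_bm_wins_aic_on_bm_data(self, rng):
        t = simulate_birth_death_tree(64, 1.0, 0.0, rng)
        wins = 0
        n = 40
        for _ in range(n):
            x = simulate_traits(t, rng, model="BM", sigma2=1.0)
            bm = fit_model(t, x, "BM")
            ou = fit_model(t, x, "OU", alpha_bound=1.0, n_starts=2)
            wins += bm.aic < ou.aic
        assert wins / n >= 0.70

    def test_invalid_model_rejected(self, three_tip_tree):
        with pytest.raises(ValidationError):
            fit_model(three_tip_tree, np.array([0.0, 1.0, 2.0]), "EB")


class TestProfileAlpha:
    def test_plateau_rule_synthetic(self):
        # gains (10, 10, 1, 0.1): third grid point selected at threshold 2
        lls = np.array([0.0, 10.0, 20.0, 21.0, 21.1])
        idx, saturated = select_plateau(lls, 2.0)
        assert idx == 2 and not saturated

    def test_plateau_all_flat_picks_first(self):
        idx, saturated = select_plateau(np.array([5.0, 5.1, 5.2, 5.15]), 2.0)
        assert idx == 0 and not saturated

    def test_plateau_saturated_picks_last(self):
        idx, saturated = select_plateau(np.array([0.0, 10.0, 20.0, 30.0]), 2.0)
        assert idx == 3 and saturated

    def test_bm_data_plateaus_early(self, rng):
        t = simulate_birth_death_tree(48, 1.0, 0.0, rng)
        x = simulate_traits(t, rng, model="BM", sigma2=1.0)
        s2, a, profile = profile_alpha(
            t, x, bound_grid=np.array([0.01, 0.05, 0.2, 1.0]), n_starts=2
        )
        assert len(profile) == 4
        sel = profile.loc[profile["selected"]].index[0]
        assert sel <= 1  # no meaningful gain from larger alpha bounds
        assert s2 > 0 and 0 <= a <= profile.loc[sel, "bound"] + 1e-9

    def test_bad_grid_rejected(self, three_tip_tree, rng):
        with pytest.raises(ValidationError):
            profile_alpha(three_tip_tree, np.array([0.0, 1.0, 2.0]), bound_grid=np.array([0.5, 0.1]))
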