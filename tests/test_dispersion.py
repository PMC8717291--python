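"""MPD/MNTD, richness-preserving null tests, and Blomberg's K."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kipuka import (
    DataError,
    DistanceMatrix,
    Phylogeny,
    ValidationError,
    blomberg_k,
    dispersion_report,
    mntd,
    mpd,
    patristic_matrix,
    ses_null_test,
    simulate_birth_death_tree,
    simulate_traits,
    trait_distance_matrix,
)


def brute_mpd(comm, dist):
    pairs = list(itertools.combinations(comm, 2))
    return float(np.mean([dist.values[dist.index[a], dist.index[b]] for a, b in pairs]))


def brute_mntd(comm, dist):
    out = []
    for a in comm:
        out.append(min(dist.values[dist.index[a], dist.index[b]] for b in comm if b != a))
    return float(np.mean(out))


class TestDistanceMatrices:
    def test_patristic_hand_example(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        get = lambda a, b: d.values[d.index[a], d.index[b]]
        assert get("A", "B") == pytest.approx(2.0)
        assert get("A", "C") == pytest.approx(4.0)
        assert get("B", "C") == pytest.approx(4.0)

    def test_patristic_matches_dendropy_oracle(self, rng):
        """Independent path-length oracle: dendropy's phylogenetic distance matrix."""
        import dendropy

        for _ in range(10):
            t = simulate_birth_death_tree(20, 1.0, 0.3, rng)
            D = t.patristic_matrix()
            dtree = dendropy.Tree.get(data=t.to_newick(), schema="newick")
            pdm = dtree.phylogenetic_distance_matrix()
            taxa = {x.label.replace(" ", "_"): x for x in dtree.taxon_namespace}
            for i, a in enumerate(t.tip_labels):
                for j, b in enumerate(t.tip_labels):
                    if i < j:
                        assert D[i, j] == pytest.approx(
                            pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9
                        )

    def test_ultrametric_cross_root_distance(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        # pairs spanning the root sit at 2 x height
        assert d.values[d.index["A"], d.index["C"]] == pytest.approx(2 * three_tip_tree.height)

    def test_trait_distance_values(self):
        d = trait_distance_matrix(pd.Series({"a": 0.0, "b": 1.0, "c": 3.0}))
        assert d.values[d.index["a"], d.index["b"]] == 1.0
        assert d.values[d.index["a"], d.index["c"]] == 3.0
        assert d.values[d.index["b"], d.index["c"]] == 2.0

    def test_trait_distance_missing_named(self):
        with pytest.raises(DataError, match="bad_sp"):
            trait_distance_matrix(pd.Series({"ok_sp": 1.0, "bad_sp": np.nan}))

    def test_trait_distance_metric_properties(self, rng):
        x = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        d = trait_distance_matrix(x).values
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        # triangle inequality for |xi - xj|
        for _ in range(200):
            i, j, k = rng.integers(30, size=3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestMpdMntd:
    def test_hand_example(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        assert mpd(["A", "B", "C"], d) == pytest.approx(10 / 3)
        assert mntd(["A", "B", "C"], d) == pytest.approx(8 / 3)

    def test_matches_brute_force_on_random_communities(self, rng):
        t = simulate_birth_death_tree(40, 1.0, 0.2, rng)
        d = patristic_matrix(t)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            comm = list(rng.choice(t.tip_labels, size=k, replace=False))
            assert mpd(comm, d) == pytest.approx(brute_mpd(comm, d), abs=1e-9)
            assert mntd(comm, d) == pytest.approx(brute_mntd(comm, d), abs=1e-9)
            assert mntd(comm, d) <= mpd(comm, d) + 1e-12

    def test_two_species_community(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        assert mpd(["A", "C"], d) == pytest.approx(4.0)
        assert mntd(["A", "C"], d) == pytest.approx(mpd(["A", "C"], d))

    def test_order_invariance(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        assert mpd(["C", "A", "B"], d) == mpd(["A", "B", "C"], d)

    def test_too_small_community(self, three_tip_tree):
        d = patristic_matrix(three_tip_tree)
        with pytest.raises(ValidationError):
            mpd(["A"], d)


class TestSesNullTest:
    def _line_matrix(self, n=50):
        # species on a line: community of adjacent species is clustered
        labels = [f"s{i:02d}" for i in range(n)]
        x = np.arange(n, dtype=float)
        return DistanceMatrix(np.abs(x[:, None] - x[None, :]), labels)

    def test_clustered_community_detected(self):
        d = self._line_matrix()
        res = ses_null_test(["s00", "s01", "s02"], d.labels, d, "MPD", n_reps=500, seed=1)
        assert res.verdict == "clustered"
        assert res.p < 0.025
        assert res.ses < 0

    def test_overdispersed_community_detected(self):
        d = self._line_matrix()
        res = ses_null_test(["s00", "s25", "s49"], d.labels, d, "MNTD", n_reps=500, seed=1)
        assert res.verdict == "overdispersed"
        assert res.p > 0.975

    def test_rank_p_convention(self):
        """p = rank/n_reps, so rank 10 of 1000 reads as p = .01 and clustering."""
        d = self._line_matrix()
        res = ses_null_test(["s10", "s20", "s30"], d.labels, d, "MPD", n_reps=1000, seed=7)
        assert res.p == pytest.approx(res.rank / 1000)
        assert 0 <= res.rank <= 1000

    def test_community_equal_to_pool_is_neutral(self):
        d = self._line_matrix(12)
        with pytest.warns(UserWarning, match="zero spread"):
            res = ses_null_test(d.labels, d.labels, d, "MPD", n_reps=50, seed=3)
        assert res.verdict == "neutral"
        assert np.isnan(res.ses)

    def test_ses_sign_matches_deviation(self):
        d = self._line_matrix()
        rng = np.random.default_rng(11)
        for _ in range(20):
            comm = list(rng.choice(d.labels, size=6, replace=False))
            res = ses_null_test(comm, d.labels, d, "MPD", n_reps=200, seed=5)
            if res.null_sd > 0 and res.observed != res.null_mean:
                assert np.sign(res.ses) == np.sign(res.observed - res.null_mean)

    def test_community_not_subset_rejected(self):
        d = self._line_matrix(10)
        with pytest.raises(ValidationError):
            ses_null_test(["s00", "zz"], d.labels, d, "MPD")

    def test_null_p_values_roughly_uniform(self, rng):
        """Under neutral sampling the rank distribution must be near-uniform."""
        t = simulate_birth_death_tree(80, 1.0, 0.2, rng)
        d = patristic_matrix(t)
        ps = []
        for _ in range(400):
            comm = list(rng.choice(t.tip_labels, size=10, replace=False))
            res = ses_null_test(comm, t.tip_labels, d, "MPD", n_reps=199, seed=int(rng.integers(2**31)))
            ps.append(res.p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBlombergK:
    def test_bm_simulations_center_on_one(self, rng):
        t = simulate_birth_death_tree(64, 1.0, 0.0, rng)
        ks = []
        for _ in range(300):
            x = simulate_traits(t, rng, model="BM", sigma2=1.0)
            ks.append(blomberg_k(t, x))
        assert np.mean(ks) == pytest.approx(1.0, abs=0.07)

    def test_permutation_destroys_signal(self, rng):
        t = simulate_birth_death_tree(64, 1.0, 0.0, rng)
        k_perm = []
        for _ in range(100):
            x = simulate_traits(t, rng, model="BM", sigma2=1.0)
            k_perm.append(blomberg_k(t, rng.permutation(x)))
        assert np.mean(k_perm) < 0.7

    def test_constant_trait_rejected(self, three_tip_tree):
        with pytest.raises(DataError):
            blomberg_k(three_tip_tree, np.ones(3))

    def test_accepts_series_by_label(self, three_tip_tree):
        s = pd.Series({"A": 0.1, "B": 0.4, "C": 2.0})
        assert blomberg_k(three_tip_tree, s) > 0


class TestDispersionReport:
    def test_report_shape_and_verdicts(self, rng):
        t = simulate_birth_death_tree(30, 1.0, 0.0, rng)
        traits = pd.Series(rng.normal(size=30), index=t.tip_labels)
        comms = {
            "K1": list(rng.choice(t.tip_labels, 5, replace=False)),
            "K2": list(rng.choice(t.tip_labels, 8, replace=False)),
        }
        rep = dispersion_report(t, comms, traits=traits, n_reps=99, seed=0)
        # 2 communities x 2 metrics x 2 bases
        assert len(rep) == 8
        assert set(rep["verdict"]) <= {"clustered", "neutral", "overdispersed"}
        assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()
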