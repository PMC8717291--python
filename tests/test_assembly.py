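"""Assembly kernels, local-community sampling, and the reference table."""

import numpy as np
import pytest
from scipy import stats

from kipuka import (
    AssemblyParams,
    SimulationError,
    ValidationError,
    assemble_local,
    assembly_weight,
    simulate_birth_death_tree,
    simulate_reference_table,
    simulate_traits,
)
from kipuka.assembly import WEIGHT_FLOOR
from kipuka.summary_stats import STAT_NAMES


class TestAssemblyWeight:
    def test_filtering_at_optimum_is_one(self):
        assert assembly_weight(1.5, "filtering", tau=3.0, x_opt=1.5) == 1.0

    def test_filtering_monotone_in_tau(self):
        w_strong = assembly_weight(2.0, "filtering", tau=1.0, x_opt=0.0)
        w_weak = assembly_weight(2.0, "filtering", tau=60.0, x_opt=0.0)
        assert w_strong < w_weak  # small tau = strong filter

    def test_competition_identical_trait_floored(self):
        w = assembly_weight(1.0, "competition", tau=5.0, resident_traits=[1.0])
        assert w == WEIGHT_FLOOR

    def test_competition_empty_residents(self):
        assert assembly_weight(1.0, "competition", tau=5.0, resident_traits=[]) == 1.0

    def test_neutral_always_one(self):
        assert assembly_weight(123.0, "neutral", tau=2.0) == 1.0

    def test_invalid_tau(self):
        with pytest.raises(ValidationError):
            assembly_weight(0.0, "filtering", tau=0.0)


@pytest.fixture(scope="module")
def small_pool():
    rng = np.random.default_rng(5)
    tree = simulate_birth_death_tree(40, 1.0, 0.0, rng)
    traits = simulate_traits(tree, rng, model="OU", sigma2=0.92, alpha=0.2, theta=0.0)
    return tree, traits


class TestAssembleLocal:
    def test_neutral_inclusion_uniform(self, small_pool):
        tree, traits = small_pool
        rng = np.random.default_rng(0)
        counts = np.zeros(tree.n_tips)
        reps = 3000
        for _ in range(reps):
            comm = assemble_local(
                (tree, traits), AssemblyParams(model="neutral", n_local=8, n_regional=40), rng
            )
            counts[comm.member_idx] += 1
        expected = reps * 8 / 40
        assert stats.chisquare(counts, f_exp=np.full(40, expected)).pvalue > 0.01

    def test_filtering_pulls_toward_optimum(self, small_pool):
        tree, traits = small_pool
        rng = np.random.default_rng(1)
        x_opt = float(np.mean(traits))
        pool_dev = np.abs(traits - x_opt).mean()
        closer = 0
        reps = 200
        for _ in range(reps):
            comm = assemble_local(
                (tree, traits),
                AssemblyParams(model="filtering", tau=1.0, n_local=8, n_regional=40),
                rng,
            )
            closer += np.abs(traits[comm.member_idx] - x_opt).mean() < pool_dev
        assert closer / reps >= 0.99

    def test_competition_spreads_traits(self, small_pool):
        tree, traits = small_pool
        rng = np.random.default_rng(2)
        var_comp, var_neut = [], []
        for _ in range(300):
            c1 = assemble_local(
                (tree, traits),
                AssemblyParams(model="competition", tau=1.0, n_local=8, n_regional=40),
                rng,
            )
            c2 = assemble_local(
                (tree, traits), AssemblyParams(model="neutral", n_local=8, n_regional=40), rng
            )
            var_comp.append(np.var(traits[c1.member_idx]))
            var_neut.append(np.var(traits[c2.member_idx]))
        assert np.mean(var_comp) > np.mean(var_neut)

    def test_huge_tau_filtering_is_neutral_like(self, small_pool):
        """tau -> infinity: inclusion frequencies indistinguishable from uniform."""
        tree, traits = small_pool
        rng = np.random.default_rng(3)
        counts = np.zeros(tree.n_tips)
        reps = 2500
        for _ in range(reps):
            comm = assemble_local(
                (tree, traits),
                AssemblyParams(model="filtering", tau=1e9, n_local=8, n_regional=40),
                rng,
            )
            counts[comm.member_idx] += 1
        expected = np.full(40, reps * 8 / 40)
        assert stats.chisquare(counts, f_exp=expected).pvalue > 0.01

    def test_oversized_community_rejected(self, small_pool):
        tree, traits = small_pool
        with pytest.raises(ValidationError):
            AssemblyParams(model="neutral", n_local=50, n_regional=40)

    def test_members_are_unique_pool_species(self, small_pool):
        tree, traits = small_pool
        comm = assemble_local(
            (tree, traits),
            AssemblyParams(model="competition", tau=2.0, n_local=12, n_regional=40),
            np.random.default_rng(4),
        )
        assert len(set(comm.members)) == 12
        assert set(comm.members) <= set(tree.tip_labels)


class TestBirthDeath:
    def test_tip_count_and_ultrametric(self, rng):
        for mu_frac in (0.0, 0.5):
            t = simulate_birth_death_tree(25, 1.0, mu_frac, rng)
            assert t.n_tips == 25
            td = t.tip_depths()
            assert np.ptp(td) < 1e-9 * max(1.0, td.max())

    def test_invalid_rates(self, rng):
        with pytest.raises(ValidationError):
            simulate_birth_death_tree(10, 0.5, 0.6, rng)

    def test_restart_exhaustion_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationError):
            # mu nearly equal to lambda and a single restart: extinction almost certain
            simulate_birth_death_tree(200, 1.0, 0.999, rng, max_restarts=1)


class TestReferenceTable:
    def test_bookkeeping_and_prior_support(self):
        ref = simulate_reference_table(
            10, data_conditions={"n_regional": 50, "n_local_values": [5, 8]}, seed=9
        )
        assert len(ref) == 30
        assert ref["model"].value_counts().to_dict() == {
            "neutral": 10,
            "filtering": 10,
            "competition": 10,
        }
        assert ref["tau"].between(1, 60).all()
        assert ref["n_local"].isin([5, 8]).all()
        assert all(c in ref.columns for c in STAT_NAMES)
        assert np.isfinite(ref[STAT_NAMES].to_numpy()).all()

    def test_bitwise_reproducible(self):
        cond = {"n_regional": 40, "n_local_values": [6]}
        a = simulate_reference_table(5, data_conditions=cond, seed=123)
        b = simulate_reference_table(5, data_conditions=cond, seed=123)
        assert a.equals(b)

    def test_filtering_shrinks_trait_variance_ratio(self):
        """Label-conditional mean variance ratio is lowest under filtering."""
        ref = simulate_reference_table(
            60, data_conditions={"n_regional": 60, "n_local_values": [10]}, seed=77
        )
        means = ref.groupby("model")["trait_var_ratio"].mean()
        assert means["filtering"] == means.min()
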