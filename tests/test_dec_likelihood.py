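import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import decophylo as dp
from decophylo.errors import DataError, ParameterError
from decophylo.reference import brute_force_loglik

from conftest import random_instance


class TestRateMatrix:
    def test_single_area_limit(self):
        space = dp.build_state_space(["A"], 1)
        Q = dp.build_rate_matrix(space, dp.DECParams(d=0.3, e=0.25))
        a = space.index_of(("A",))
        assert Q[a, 0] == pytest.approx(0.25)
        assert Q[a, a] == pytest.approx(-0.25)
        assert np.all(Q[0] == 0.0)  # empty range is absorbing

    def test_two_area_rates(self, two_area_space):
        Q = dp.build_rate_matrix(two_area_space, dp.DECParams(d=0.4, e=0.1))
        sp = two_area_space
        a, ab = sp.index_of(("A",)), sp.index_of(("A", "B"))
        assert Q[a, ab] == pytest.approx(0.4)
        assert Q[ab, a] == pytest.approx(0.1)

    def test_zero_multiplier_bars_dispersal(self, two_area_space):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        epochs = dp.EpochConfig([0.0], [m])
        Q = dp.build_rate_matrix(two_area_space, dp.DECParams(d=0.4, e=0.1, epochs=epochs))
        sp = two_area_space
        assert Q[sp.index_of(("A",)), sp.index_of(("A", "B"))] == 0.0

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            _, _, space, params = random_instance(rng)
            Q = dp.build_rate_matrix(space, params)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12
            off = Q - np.diag(np.diag(Q))
            assert off.min() >= 0.0


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, two_area_space):
        Q = dp.build_rate_matrix(two_area_space, dp.DECParams(d=0.2, e=0.1))
        assert np.allclose(dp.transition_matrix(Q, 0.0), np.eye(two_area_space.n_states))

    def test_single_area_survival_closed_form(self):
        space = dp.build_state_space(["A"], 1)
        Q = dp.build_rate_matrix(space, dp.DECParams(d=0.0, e=0.1))
        P = dp.transition_matrix(Q, 1.0)
        a = space.index_of(("A",))
        assert P[a, a] == pytest.approx(np.exp(-0.1), abs=1e-12)

    def test_symmetric_areas_give_symmetric_transitions(self, two_area_space):
        Q = dp.build_rate_matrix(two_area_space, dp.DECParams(d=0.3, e=0.2))
        P = dp.transition_matrix(Q, 2.0)
        sp = two_area_space
        a, b = sp.index_of(("A",)), sp.index_of(("B",))
        assert abs(P[a, b] - P[b, a]) < 1e-10

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_rows_are_stochastic(self, t):
        rng = np.random.default_rng(11)
        for _ in range(5):
            _, _, space, params = random_instance(rng)
            Q = dp.build_rate_matrix(space, params)
            P = dp.transition_matrix(Q, t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9
            assert P.min() >= 0.0

    def test_negative_time_rejected(self, two_area_space):
        Q = dp.build_rate_matrix(two_area_space, dp.DECParams(d=0.2, e=0.1))
        with pytest.raises(ParameterError):
            dp.transition_matrix(Q, -1.0)


class TestLikelihoodClosedForms:
    def test_two_tip_single_area(self):
        # sympatric copy at the root, independent survival on both branches
        tree = dp.DatedTree.from_newick("(x:1,y:1);")
        space = dp.build_state_space(["A"], 1)
        ll = dp.tree_likelihood(
            tree, {"x": ("A",), "y": ("A",)}, space, dp.DECParams(d=0.0, e=0.1)
        )
        assert ll == pytest.approx(-0.2, abs=1e-12)

    def test_loglik_is_nonpositive(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree, tips, space, params = random_instance(rng)
            assert dp.tree_likelihood(tree, tips, space, params) <= 0.0

    def test_tip_range_not_in_space_names_tip(self, three_tip_tree):
        space = dp.build_state_space(["A", "B"], 2)
        with pytest.raises(DataError, match="z"):
            dp.tree_likelihood(
                three_tip_tree,
                {"x": ("A",), "y": ("A",), "z": ("C",)},
                space,
                dp.DECParams(d=0.1, e=0.1),
            )


class TestPruningAgainstEnumeration:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(5):
            tree, tips, space, params = random_instance(rng)
            a = dp.tree_likelihood(tree, tips, space, params)
            b = brute_force_loglik(tree, tips, space, params)
            assert a == pytest.approx(b, rel=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        tree, tips, space, params = random_instance(rng)
        a = dp.tree_likelihood(tree, tips, space, params)
        b = brute_force_loglik(tree, tips, space, params)
        assert a == pytest.approx(b, rel=1e-10)


class TestInvariances:
    def test_stratification_with_unit_multipliers_is_noop(self):
        rng = np.random.default_rng(21)
        tree, tips, space, _ = random_instance(rng)
        n = space.n_areas
        flat = dp.DECParams(d=0.2, e=0.05)
        strat = dp.DECParams(
            d=0.2,
            e=0.05,
            epochs=dp.EpochConfig(
                [tree.root_age * 0.6, tree.root_age * 0.2, 0.0],
                [np.ones((n, n))] * 3,
            ),
        )
        a = dp.tree_likelihood(tree, tips, space, flat)
        b = dp.tree_likelihood(tree, tips, space, strat)
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_to_consistent_area_permutation(self):
        tree = dp.DatedTree.from_newick("((x:1,y:1):1,(z:1.5,w:1.5):0.5);")
        tips = {"x": ("A",), "y": ("B",), "z": ("A", "C"), "w": ("C",)}
        params = dp.DECParams(d=0.15, e=0.07)
        space1 = dp.build_state_space(["A", "B", "C"], 2)
        perm = {"A": "C", "B": "A", "C": "B"}
        space2 = dp.build_state_space(["A", "B", "C"], 2)
        tips2 = {k: tuple(sorted(perm[a] for a in v)) for k, v in tips.items()}
        a = dp.tree_likelihood(tree, tips, space1, params)
        b = dp.tree_likelihood(tree, tips2, space2, params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_extinction_rate_monotonicity_for_full_range_tips(self):
        # every tip retains the root's full range: raising e only hurts
        tree = dp.DatedTree.from_newick("((x:1,y:1):1,z:2);")
        space = dp.build_state_space(["A", "B"], 2)
        tips = {t: ("A", "B") for t in "xyz"}
        lls = [
            dp.tree_likelihood(tree, tips, space, dp.DECParams(d=0.2, e=e))
            for e in (0.01, 0.05, 0.1, 0.5, 1.0)
        ]
        assert all(a >= b for a, b in zip(lls, lls[1:]))
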