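import numpy as np
import pytest

import decophylo as dp


def _clades(tree, relabel=None):
    """Set of tip-label clades, optionally relabelled."""
    out = set()
    labels = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            lab = tree.label(node)
            labels[node] = frozenset([relabel[lab] if relabel else lab])
        else:
            labels[node] = frozenset().union(*(labels[c] for c in tree.children(node)))
            out.add(labels[node])
    return out


class TestYuleTrees:
    def test_two_tips_single_split(self):
        tree = dp.simulate_host_tree(1.0, 2, 0)
        assert tree.n_tips == 2
        assert tree.root_age > 0

    def test_mean_root_age_matches_yule_expectation(self):
        rng = np.random.default_rng(42)
        ages = [dp.simulate_host_tree(1.0, 8, rng).root_age for _ in range(1000)]
        expected = sum(1.0 / k for k in range(2, 9))
        se = np.std(ages) / np.sqrt(len(ages))
        assert abs(np.mean(ages) - expected) < 3 * se

    def test_same_seed_same_newick(self):
        assert (
            dp.simulate_host_tree(1.2, 9, 123).newick()
            == dp.simulate_host_tree(1.2, 9, 123).newick()
        )

    def test_output_passes_tree_validation(self):
        # construction goes through DatedTree, so re-reading must succeed
        tree = dp.simulate_host_tree(0.7, 15, 5)
        back = dp.DatedTree.from_newick(tree.newick())
        assert back.n_tips == 15


class TestCophyloSimulation:
    def test_pure_cospeciation_mirrors_host_tree(self):
        host = dp.simulate_host_tree(1.0, 9, 2)
        sim = dp.simulate_cophylo(host, 1.0, 0.0, 0.0, 0.0, 3)
        assert not sim.empty
        assert sim.parasite_tree.n_tips == host.n_tips
        cosp = [e for e in sim.events if e.type == "cospeciation"]
        assert len(cosp) == host.n_tips - 1
        assert all(e.type == "cospeciation" for e in sim.events)
        # identical topology under the tip association relabelling
        assert _clades(sim.parasite_tree, sim.associations) == _clades(host)

    def test_heavy_loss_flags_empty(self):
        host = dp.simulate_host_tree(1.0, 8, 4)
        sim = dp.simulate_cophylo(host, 1.0, 0.0, 0.0, 500.0, 5)
        assert sim.empty
        assert sim.parasite_tree is None

    def test_switch_rate_scaling_per_lineage_time(self):
        # host switches are a Poisson process per lineage: the rate estimate
        # (events / total lineage time) tracks the nominal rate, and doubling
        # the nominal rate doubles the estimate
        rng = np.random.default_rng(3)
        est = {}
        for lam in (0.5, 1.0):
            count = time = 0.0
            for _ in range(250):
                host = dp.simulate_host_tree(1.0, 8, rng)
                sim = dp.simulate_cophylo(host, 1.0, lam, 0.0, 0.0, rng)
                count += sum(e.type == "host-switch" for e in sim.events)
                time += sim.total_lineage_time
            est[lam] = count / time
        assert 1.8 <= est[1.0] / est[0.5] <= 2.2
        assert est[0.5] == pytest.approx(0.5, rel=0.15)

    def test_event_ages_within_tree_span(self):
        host = dp.simulate_host_tree(1.0, 10, 7)
        sim = dp.simulate_cophylo(host, 0.7, 0.4, 0.1, 0.1, 8)
        for ev in sim.events:
            assert 0.0 <= ev.age <= host.root_age + 1e-12

    def test_same_seed_reproducible(self):
        host = dp.simulate_host_tree(1.0, 10, 9)
        a = dp.simulate_cophylo(host, 0.7, 0.4, 0.1, 0.1, 10)
        b = dp.simulate_cophylo(host, 0.7, 0.4, 0.1, 0.1, 10)
        assert [(e.type, e.age) for e in a.events] == [(e.type, e.age) for e in b.events]
        if not a.empty:
            assert a.parasite_tree.newick() == b.parasite_tree.newick()

    def test_every_extant_parasite_on_extant_host(self):
        host = dp.simulate_host_tree(1.0, 10, 13)
        sim = dp.simulate_cophylo(host, 0.8, 0.5, 0.1, 0.2, 14)
        host_tips = set(host.tip_labels)
        for p, h in sim.associations.items():
            assert h in host_tips


class TestDecForwardSimulation:
    def test_no_rates_no_events(self):
        tree = dp.simulate_host_tree(1.0, 6, 1)
        space = dp.build_state_space(["A", "B"], 2)
        sim = dp.simulate_dec_history(tree, space, dp.DECParams(d=0.0, e=0.0), ("A",), 2)
        assert sim.events == []
        assert all(r == ("A",) for r in sim.tip_ranges.values())
        assert sim.extinct_tips == set()

    def test_single_branch_law_matches_transition_matrix(self):
        # a two-tip tree whose root copies {A} to both daughters: each tip's
        # range is one draw from the CTMC over the branch length
        t = 1.5
        tree = dp.DatedTree.from_newick(f"(x:{t},y:{t});")
        space = dp.build_state_space(["A", "B"], 2)
        params = dp.DECParams(d=0.4, e=0.3)
        Q = dp.build_rate_matrix(space, params)
        expected = dp.transition_matrix(Q, t)[space.index_of(("A",))]
        rng = np.random.default_rng(6)
        counts = np.zeros(space.n_states)
        reps = 10_000
        for _ in range(reps):
            sim = dp.simulate_dec_history(tree, space, params, ("A",), rng)
            rng_x = sim.tip_ranges["x"]
            counts[space.index_of(rng_x)] += 1
        tv = 0.5 * np.abs(counts / reps - expected).sum()
        assert tv < 0.02

    def test_extinct_lineages_flagged(self):
        tree = dp.simulate_host_tree(1.0, 8, 3)
        space = dp.build_state_space(["A"], 1)
        sim = dp.simulate_dec_history(tree, space, dp.DECParams(d=0.0, e=3.0), ("A",), 4)
        assert sim.extinct_tips  # with e=3 over a deep tree someone dies
        for tip in sim.extinct_tips:
            assert sim.tip_ranges[tip] == ()

    def test_same_seed_identical_history(self):
        tree = dp.simulate_host_tree(1.0, 8, 3)
        space = dp.build_state_space(["A", "B", "C"], 2)
        params = dp.DECParams(d=0.3, e=0.1)
        a = dp.simulate_dec_history(tree, space, params, ("A", "B"), 9)
        b = dp.simulate_dec_history(tree, space, params, ("A", "B"), 9)
        assert a.tip_ranges == b.tip_ranges
        assert [(e.type, e.age, e.subject) for e in a.events] == [
            (e.type, e.age, e.subject) for e in b.events
        ]

    def test_epoch_multiplier_shapes_dispersal(self):
        # barring all dispersal in the recent epoch freezes ranges there
        tree = dp.DatedTree.from_newick("(x:1,y:1);")
        space = dp.build_state_space(["A", "B"], 2)
        n = 2
        epochs = dp.EpochConfig([0.5, 0.0], [np.ones((n, n)), np.zeros((n, n))])
        params = dp.DECParams(d=5.0, e=0.0, epochs=epochs)
        rng = np.random.default_rng(11)
        for _ in range(50):
            sim = dp.simulate_dec_history(tree, space, params, ("A",), rng)
            for ev in sim.events:
                if ev.type == "dispersal/host-switch":
                    assert ev.age >= 0.5 - 1e-12
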