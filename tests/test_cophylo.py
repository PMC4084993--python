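import numpy as np
import pytest

import decophylo as dp
from decophylo.errors import DataError


def _scen(node, age, range_, left, right, kind):
    return dp.NodeScenario(
        node=node, age=age, range_=tuple(range_), left=tuple(left),
        right=tuple(right), kind=kind, relative_probability=1.0,
    )


class TestHostEncoding:
    def test_terminal_repertoires_from_fixture(self, margotrema):
        space, tip_ranges = dp.encode_hosts_as_areas(margotrema)
        assert space.state_space.n_areas == 15
        assert space.max_repertoire_size == 2
        assert tip_ranges[dp.terminal_label("Margotrema bravoae Lineage II", "B")] == ("i",)
        assert tip_ranges[dp.terminal_label("Margotrema bravoae Lineage III", "D")] == ("f", "n")

    def test_empty_table_rejected(self, margotrema):
        import pandas as pd

        empty = margotrema.records.iloc[0:0]
        with pytest.raises(Exception):
            dp.encode_hosts_as_areas(dp.AssociationTable(empty))

    def test_cooccurrence_gate_limits_switches(self, margotrema):
        space, _ = dp.encode_hosts_as_areas(margotrema, cooccurrence_gate=True)
        hosts = space.hosts
        adj = space.adjacency
        i_f, i_n = hosts.index("f"), hosts.index("n")  # share Zacapu Lake
        i_m = hosts.index("m")  # Cuzalapa only, shares no area
        assert adj[i_f, i_n] == 1
        assert adj[i_m, i_f] == 0
        # repertoires observed in the table must remain admissible states
        _, tip_ranges = dp.encode_hosts_as_areas(margotrema, cooccurrence_gate=True)
        for rep in tip_ranges.values():
            space.state_space.index_of(rep)


class TestNodeEventClassification:
    def test_vicariance_maps_to_cospeciation(self):
        events = dp.classify_node_events(
            {0: _scen(0, 1.04, ("i", "n"), ("i",), ("n",), "vicariance")}
        )
        assert [e.type for e in events] == ["cospeciation"]

    def test_singleton_copy_maps_to_duplication(self):
        events = dp.classify_node_events(
            {0: _scen(0, 2.0, ("g",), ("g",), ("g",), "sympatric-copy")}
        )
        assert [e.type for e in events] == ["duplication"]

    def test_peripheral_isolate_maps_to_duplication_plus_sharing(self):
        events = dp.classify_node_events(
            {0: _scen(0, 0.5, ("g", "i"), ("g",), ("g", "i"), "peripheral-isolate")}
        )
        assert [e.type for e in events] == ["duplication", "sharing"]
        assert events[1].subject == "g+i"

    def test_unknown_kind_rejected(self):
        with pytest.raises(DataError):
            dp.classify_node_events(
                {0: _scen(0, 1.0, ("a",), ("a",), ("a",), "founder-event")}
            )


class TestBranchEventClassification:
    @pytest.fixture
    def tree(self):
        return dp.DatedTree.from_newick("((x:1,y:1):1,z:2);")

    def test_gain_is_host_switch_with_donor(self, tree):
        inner = tree.mrca(["x", "y"])
        scen = {
            tree.root: _scen(tree.root, 2.0, ("n",), ("n",), ("n",), "sympatric-copy"),
            inner: _scen(inner, 1.0, ("n", "d"), ("n",), ("d",), "vicariance"),
        }
        tips = {"x": ("n",), "y": ("d",), "z": ("n",)}
        events = dp.classify_branch_events(tree, scen, tips)
        switches = [e for e in events if e.type == "host-switch"]
        assert len(switches) == 1
        assert switches[0].donor == "n" and switches[0].recipient == "d"
        assert (switches[0].age, switches[0].age_end) == (2.0, 1.0)

    def test_loss_is_lineage_loss(self, tree):
        inner = tree.mrca(["x", "y"])
        scen = {
            tree.root: _scen(tree.root, 2.0, ("i", "h"), ("i", "h"), ("i",), "peripheral-isolate"),
            inner: _scen(inner, 1.0, ("h",), ("h",), ("h",), "sympatric-copy"),
        }
        tips = {"x": ("h",), "y": ("h",), "z": ("i",)}
        events = dp.classify_branch_events(tree, scen, tips)
        losses = [e for e in events if e.type == "lineage-loss"]
        assert [e.subject for e in losses] == ["i"]

    def test_identical_end_states_give_no_event(self, tree):
        inner = tree.mrca(["x", "y"])
        scen = {
            tree.root: _scen(tree.root, 2.0, ("a",), ("a",), ("a",), "sympatric-copy"),
            inner: _scen(inner, 1.0, ("a",), ("a",), ("a",), "sympatric-copy"),
        }
        tips = {t: ("a",) for t in "xyz"}
        assert dp.classify_branch_events(tree, scen, tips) == []

    def test_set_difference_conservation(self):
        # every gained host appears in exactly one switch, every lost host in
        # exactly one loss, for arbitrary scenario chains
        rng = np.random.default_rng(4)
        tree = dp.simulate_host_tree(1.0, 10, rng)
        space = dp.build_state_space(["a", "b", "c"], 2)
        sim = dp.simulate_dec_history(
            tree, space, dp.DECParams(d=0.6, e=0.3), ("a", "b"), rng
        )
        scen = {}
        for node, labels in sim.node_states.items():
            if not labels:
                continue
            c1, c2 = tree.children(node)
            left = sim.node_states.get(c1) or sim.tip_ranges.get(tree.label(c1))
            right = sim.node_states.get(c2) or sim.tip_ranges.get(tree.label(c2))
            scen[node] = _scen(node, tree.age(node), labels, labels, labels, "sympatric-copy")
        tips = {k: v for k, v in sim.tip_ranges.items() if v}
        if len(scen) == len(tree.internal_nodes()) and len(tips) == tree.n_tips:
            events = dp.classify_branch_events(tree, scen, tips)
            for node in tree.postorder():
                if node == tree.root or not tree.is_tip(node):
                    continue
                parent_state = set(scen[tree.parent(node)].range_)
                child_state = set(tips[tree.label(node)])
                anchored = [e for e in events if e.anchor == tree.label(node)]
                gains = {e.recipient for e in anchored if e.type == "host-switch"}
                losses = {e.subject for e in anchored if e.type == "lineage-loss"}
                assert gains == child_state - parent_state
                assert losses == parent_state - child_state

    def test_label_permutation_permutes_events(self, tree):
        inner = tree.mrca(["x", "y"])

        def run(perm):
            scen = {
                tree.root: _scen(tree.root, 2.0, (perm["n"],), (perm["n"],), (perm["n"],), "sympatric-copy"),
                inner: _scen(inner, 1.0, tuple(sorted((perm["n"], perm["d"]))),
                             (perm["n"],), (perm["d"],), "vicariance"),
            }
            tips = {"x": (perm["n"],), "y": (perm["d"],), "z": (perm["n"],)}
            return dp.classify_branch_events(tree, scen, tips)

        base = run({"n": "n", "d": "d"})
        swapped = run({"n": "q", "d": "r"})
        mapping = {"n": "q", "d": "r"}
        assert [(e.type, mapping[e.recipient or e.subject]) for e in base] == [
            (e.type, e.recipient or e.subject) for e in swapped
        ]


class TestCodivergenceLevels:
    def test_fixture_levels_match_published_assignments(self, margotrema):
        levels = {lv.lineage: lv for lv in dp.assign_codivergence_levels(margotrema)}
        assert len(levels) == 4
        assert levels["Margotrema resolanae"].level == "Species-Species"
        assert levels["Margotrema bravoae Lineage II"].level == "Species-Lineage"
        assert levels["Margotrema bravoae Lineage I"].level == "Tribe-Lineage"
        assert levels["Margotrema bravoae Lineage III"].level == "Tribe-Lineage"
        assert {lv.level for lv in levels.values()} == {
            "Species-Species", "Species-Lineage", "Tribe-Lineage"
        }

    def test_focal_tribes_and_exceptions(self, margotrema):
        levels = {lv.lineage: lv for lv in dp.assign_codivergence_levels(margotrema)}
        l1 = levels["Margotrema bravoae Lineage I"]
        assert l1.tribes == ("Ilyodontini",)
        assert "h" in l1.exceptions  # the cyprinid C. ornata never defines the tribe
        l3 = levels["Margotrema bravoae Lineage III"]
        assert set(l3.tribes) == {"Chapalichthyini", "Girardinichthyini"}
        assert l3.exceptions == ()

    def test_missing_tribe_rejected(self, margotrema):
        with pytest.raises(DataError):
            dp.assign_codivergence_levels(margotrema, tribes={"m": "Ilyodontini"})
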