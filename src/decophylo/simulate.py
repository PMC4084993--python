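"""Synthetic data with known ground truth.

Three generators provide the controlled conditions under which the inference
machinery is validated:

* :func:`simulate_host_tree` — a Yule (pure-birth) tree conditioned on a tip
  count, with the final inter-speciation interval included so the expected
  root age is ``sum_{k=2..n} 1/(k*lambda)``;
* :func:`simulate_cophylo` — a parasite lineage diversifying on the host
  tree: at each host speciation a resident parasite cospeciates with
  probability ``p_c`` (otherwise it follows one daughter uniformly), and
  along branches host switches, duplications and losses occur as independent
  Poisson processes;
* :func:`simulate_dec_history` — a forward DEC history: the anagenetic CTMC
  simulated exactly (Gillespie, with epoch-boundary handling) along each
  branch and cladogenetic scenarios drawn uniformly at nodes.

Every event is logged; the log *is* the ground truth that downstream
inference is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dec import (
    DECParams,
    EpochConfig,
    NodeScenario,
    build_rate_matrix,
    cladogenesis_table,
    scenario_kind,
    SYMPATRIC_COPY,
    VICARIANCE,
    PERIPHERAL_ISOLATE,
)
from .errors import DataError, ParameterError
from .events import Event
from .statespace import RangeStateSpace
from .trees import DatedTree

__all__ = [
    "simulate_host_tree",
    "simulate_cophylo",
    "simulate_dec_history",
    "SimResult",
    "DECSimResult",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Yule host trees
# ---------------------------------------------------------------------------


def simulate_host_tree(
    birth_rate: float, n_tips: int, seed: int | np.random.Generator
) -> DatedTree:
    """Yule tree with exactly ``n_tips`` tips, branch lengths in Ma."""
    if n_tips < 2:
        raise ParameterError("need at least two tips")
    if birth_rate <= 0:
        raise ParameterError("birth rate must be positive")
    rng = _rng(seed)
    t = 0.0
    root = {"time": 0.0, "children": None}
    active = []
    for _ in range(2):
        child = {"time": 0.0, "children": None}
        active.append(child)
    root["children"] = list(active)
    for k in range(2, n_tips + 1):
        t += rng.exponential(1.0 / (k * birth_rate))
        if k < n_tips:
            idx = rng.integers(len(active))
            node = active.pop(idx)
            node["split"] = t
            kids = [{"time": t, "children": None}, {"time": t, "children": None}]
            node["children"] = kids
            active.extend(kids)
    total = t
    counter = [0]

    def convert(node: dict) -> dict:
        if node["children"] is None:
            counter[0] += 1
            return {"age": 0.0, "label": f"t{counter[0]}", "children": []}
        split = node.get("split", 0.0)
        return {
            "age": total - split,
            "label": None,
            "children": [convert(c) for c in node["children"]],
        }

    nested = {
        "age": total,
        "label": None,
        "children": [convert(c) for c in root["children"]],
    }
    return DatedTree.from_structure(nested)


# ---------------------------------------------------------------------------
# codiversification on a host tree
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Ground truth of one codiversification simulation."""

    host_tree: DatedTree
    parasite_tree: DatedTree | None
    associations: dict[str, str]
    events: list[Event]
    true_node_scenarios: dict[int, NodeScenario]
    true_tip_ranges: dict[str, tuple[str, ...]]
    empty: bool
    total_lineage_time: float = 0.0
    params: dict = field(default_factory=dict)


class _Lineage:
    __slots__ = ("host", "parent_node")

    def __init__(self, host: int, parent_node: dict | None):
        self.host = host
        self.parent_node = parent_node


def simulate_cophylo(
    host: DatedTree,
    p_c: float,
    switch_rate: float = 0.0,
    dup_rate: float = 0.0,
    loss_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SimResult:
    """Simulate a parasite tree on a host tree with a full event log.

    The parasite starts on the host root lineage.  At each host speciation a
    resident parasite cospeciates with probability ``p_c`` (else it follows
    one uniformly chosen daughter).  Along branches, host switches (to a
    uniformly chosen co-extant host branch), duplications and losses are
    Poisson processes at the given per-lineage rates.  If no parasite lineage
    survives to the present (or only one does, so no tree exists) the result
    is flagged empty rather than raising.
    """
    if not (0.0 <= p_c <= 1.0):
        raise ParameterError("p_c must lie in [0, 1]")
    for r in (switch_rate, dup_rate, loss_rate):
        if r < 0:
            raise ParameterError("rates must be >= 0")
    rng = _rng(seed)

    def host_name(b: int) -> str:
        return host.label(b) or f"h{b}"

    events: list[Event] = []
    new_node_scen: dict[int, tuple] = {}  # id(pnode) -> scenario payload

    def speciation_node(age: float, lineage: _Lineage, scen: tuple) -> dict:
        pnode: dict = {"age": age, "label": None, "children": []}
        if lineage.parent_node is not None:
            lineage.parent_node["children"].append(pnode)
        pnode["scen"] = scen
        return pnode

    living: list[_Lineage] = [_Lineage(host=host.root, parent_node=None)]
    root_pnodes: list[dict] = []

    def attach_root(pnode: dict, lineage: _Lineage) -> None:
        if lineage.parent_node is None:
            root_pnodes.append(pnode)

    total_rate = switch_rate + dup_rate + loss_rate

    lineage_time = [0.0]  # integral of living-lineage count over age

    def anagenetic(interval_lineages, a_hi, a_lo, live_branches):
        """Evolve lineages over [a_lo, a_hi]; returns surviving lineages."""
        survivors = []
        stack = [(lin, a_hi) for lin in interval_lineages]
        while stack:
            lin, tau = stack.pop()
            alive = True
            if total_rate <= 0:
                lineage_time[0] += tau - a_lo
            while total_rate > 0:
                nxt = tau - rng.exponential(1.0 / total_rate)
                if nxt <= a_lo:
                    lineage_time[0] += tau - a_lo
                    break
                lineage_time[0] += tau - nxt
                tau = nxt
                u = rng.uniform(0, total_rate)
                if u < loss_rate:
                    events.append(
                        Event(
                            type="lineage-loss",
                            anchor=host_name(lin.host),
                            subject=host_name(lin.host),
                            age=tau,
                        )
                    )
                    alive = False
                    break
                elif u < loss_rate + dup_rate:
                    h = host_name(lin.host)
                    pnode = speciation_node(
                        tau, lin, ((h,), (h,), (h,), SYMPATRIC_COPY)
                    )
                    attach_root(pnode, lin)
                    events.append(
                        Event(type="duplication", anchor=h, subject=h, age=tau)
                    )
                    d1 = _Lineage(lin.host, pnode)
                    d2 = _Lineage(lin.host, pnode)
                    stack.append((d2, tau))
                    lin = d1
                else:
                    recipients = [b for b in live_branches if b != lin.host]
                    if recipients:
                        r = recipients[rng.integers(len(recipients))]
                        hd, hr = host_name(lin.host), host_name(r)
                        scen = (
                            tuple(sorted((hd, hr))),
                            (hd,),
                            (hr,),
                            VICARIANCE,
                        )
                        pnode = speciation_node(tau, lin, scen)
                        attach_root(pnode, lin)
                        events.append(
                            Event(
                                type="host-switch",
                                anchor=hd,
                                donor=hd,
                                recipient=hr,
                                subject=hr,
                                age=tau,
                            )
                        )
                        d1 = _Lineage(lin.host, pnode)
                        d2 = _Lineage(r, pnode)
                        stack.append((d2, tau))
                        lin = d1
            if alive:
                survivors.append(lin)
        return survivors

    host_events = sorted(host.internal_nodes(), key=lambda n: -host.age(n))
    live_branches: set[int] = {host.root}
    t = host.root_age
    for h in host_events + [None]:
        a_next = host.age(h) if h is not None else 0.0
        if t > a_next:
            living = anagenetic(living, t, a_next, sorted(live_branches))
        t = a_next
        if h is None:
            break
        live_branches.discard(h)
        c1, c2 = host.children(h)
        live_branches.update((c1, c2))
        next_living = []
        for lin in living:
            if lin.host != h:
                next_living.append(lin)
                continue
            if rng.uniform() < p_c:
                n1, n2 = host_name(c1), host_name(c2)
                scen = (tuple(sorted((n1, n2))), (n1,), (n2,), VICARIANCE)
                pnode = speciation_node(t, lin, scen)
                attach_root(pnode, lin)
                events.append(
                    Event(
                        type="cospeciation",
                        anchor=host_name(h),
                        child_left=n1,
                        child_right=n2,
                        age=t,
                    )
                )
                next_living.append(_Lineage(c1, pnode))
                next_living.append(_Lineage(c2, pnode))
            else:
                lin.host = c1 if rng.uniform() < 0.5 else c2
                next_living.append(lin)
        living = next_living

    # attach extant tips
    associations: dict[str, str] = {}
    true_tip_ranges: dict[str, tuple[str, ...]] = {}
    single_survivor = None
    for k, lin in enumerate(living, start=1):
        label = f"p{k}"
        tip = {"age": 0.0, "label": label, "children": []}
        if lin.parent_node is None:
            single_survivor = label
        else:
            lin.parent_node["children"].append(tip)
        associations[label] = host_name(lin.host)
        true_tip_ranges[label] = (host_name(lin.host),)

    params_echo = dict(
        p_c=p_c, switch_rate=switch_rate, dup_rate=dup_rate, loss_rate=loss_rate
    )

    def clean(node: dict) -> dict | None:
        if node["label"] is not None:
            return node
        kids = [c for c in (clean(k) for k in node["children"]) if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node["children"] = kids
        return node

    root = clean(root_pnodes[0]) if root_pnodes else None
    if root is None or root["label"] is not None or single_survivor is not None:
        return SimResult(
            host_tree=host,
            parasite_tree=None,
            associations=associations,
            events=events,
            true_node_scenarios={},
            true_tip_ranges=true_tip_ranges,
            empty=True,
            total_lineage_time=lineage_time[0],
            params=params_echo,
        )
    tree = DatedTree.from_structure(root)
    # recover node ids: from_structure assigns ids in the same preorder as a
    # depth-first walk of the nested structure
    scen_by_node: dict[int, NodeScenario] = {}
    counter = [0]

    def walk(node: dict) -> None:
        i = counter[0]
        counter[0] += 1
        scen = node.get("scen")
        if scen is not None:
            rng_, left, right, kind = scen
            scen_by_node[i] = NodeScenario(
                node=i,
                age=node["age"],
                range_=rng_,
                left=left,
                right=right,
                kind=kind,
                relative_probability=1.0,
            )
        for c in node["children"]:
            walk(c)

    walk(root)
    return SimResult(
        host_tree=host,
        parasite_tree=tree,
        associations=associations,
        events=events,
        true_node_scenarios=scen_by_node,
        true_tip_ranges=true_tip_ranges,
        empty=False,
        total_lineage_time=lineage_time[0],
        params=params_echo,
    )


# ---------------------------------------------------------------------------
# forward DEC histories
# ---------------------------------------------------------------------------


@dataclass
class DECSimResult:
    """Ground truth of one forward DEC simulation."""

    tip_ranges: dict[str, tuple[str, ...]]
    events: list[Event]
    node_states: dict[int, tuple[str, ...]]
    extinct_tips: set[str]


def simulate_dec_history(
    tree: DatedTree,
    space: RangeStateSpace,
    params: DECParams,
    root_range: Sequence[str],
    seed: int | np.random.Generator = 0,
) -> DECSimResult:
    """Forward-simulate ranges along a dated tree under the DEC model.

    The anagenetic chain is simulated exactly (exponential waiting times,
    restarted at epoch boundaries by memorylessness); cladogenetic scenarios
    are drawn uniformly from the allowed set at each node.  Lineages whose
    range hits the empty set are extinct; their tips are flagged and carry an
    empty range.
    """
    rng = _rng(seed)
    epochs = params.epochs or EpochConfig.uniform(space.n_areas)
    if not root_range:
        raise DataError("root range must be non-empty")
    s_root = space.index_of(root_range)
    Qs = [build_rate_matrix(space, params, k) for k in range(epochs.n_epochs)]
    clado = cladogenesis_table(space)
    events: list[Event] = []
    node_states: dict[int, tuple[str, ...]] = {}
    tip_ranges: dict[str, tuple[str, ...]] = {}
    extinct: set[str] = set()

    def anchor_of(node: int) -> str:
        return tree.label(node) or str(node)

    def evolve(s: int, a_hi: float, a_lo: float, anchor: str) -> int:
        tau = a_hi
        while tau > a_lo and s != 0:
            below = [b for b in epochs.boundaries if b < tau]
            seg_end = max(max(below, default=0.0), a_lo)
            k = epochs.epoch_at(tau)
            total = -Qs[k][s, s]
            if total <= 0:
                tau = seg_end
                continue
            step = rng.exponential(1.0 / total)
            if tau - step <= seg_end:
                tau = seg_end
                continue
            tau -= step
            row = Qs[k][s].copy()
            row[s] = 0.0
            target = rng.choice(len(row), p=row / row.sum())
            old, new = set(space.labels(s)), set(space.labels(int(target)))
            gained = new - old
            lost = old - new
            if gained:
                events.append(
                    Event(
                        type="dispersal/host-switch",
                        anchor=anchor,
                        subject=gained.pop(),
                        age=tau,
                    )
                )
            elif lost:
                events.append(
                    Event(
                        type="extinction/loss",
                        anchor=anchor,
                        subject=lost.pop(),
                        age=tau,
                    )
                )
            s = int(target)
        return s

    # preorder walk carrying the state at the top of each branch
    state_at_top: dict[int, int] = {tree.root: s_root}
    for node in tree.preorder():
        s = state_at_top[node]
        if node != tree.root:
            s = evolve(s, tree.age(tree.parent(node)), tree.age(node), anchor_of(node))
        if tree.is_tip(node):
            tip_ranges[tree.label(node)] = space.labels(s)
            if s == 0:
                extinct.add(tree.label(node))
            continue
        node_states[node] = space.labels(s)
        c1, c2 = tree.children(node)
        if s == 0:
            state_at_top[c1] = state_at_top[c2] = 0
            continue
        pairs = clado[s]
        l, r = pairs[rng.integers(len(pairs))]
        kind = scenario_kind(space, s, l, r)
        common = dict(
            anchor=anchor_of(node),
            child_left="+".join(space.labels(l)),
            child_right="+".join(space.labels(r)),
            age=tree.age(node),
        )
        if kind == VICARIANCE:
            events.append(Event(type="vicariance/cospeciation", **common))
        elif kind == SYMPATRIC_COPY:
            pass  # both daughters copy the singleton range: nothing changes
        else:  # peripheral isolate: duplication with retention
            events.append(
                Event(type="duplication", subject="+".join(space.labels(s)), **common)
            )
            events.append(
                Event(type="sharing", subject="+".join(space.labels(s)), **common)
            )
        state_at_top[c1], state_at_top[c2] = l, r
    return DECSimResult(
        tip_ranges=tip_ranges,
        events=events,
        node_states=node_states,
        extinct_tips=extinct,
    )
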