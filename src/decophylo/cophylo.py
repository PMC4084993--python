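"""Host repertoires as DEC ranges and event-based cophylogenetics.

Historical biogeography and cophylogenetics share one formal structure: an
area plays the role of a host, dispersal the role of a host switch,
vicariance the role of cospeciation, within-area (sympatric) speciation the
role of parasite duplication, and local extinction the role of parasite
lineage loss.  This module encodes observed host repertoires (capped at two
hosts per terminal) as DEC "ranges" so the likelihood machinery in
:mod:`decophylo.dec` applies unchanged, translates reconstructed scenarios
back into cophylogenetic events, and classifies each parasite lineage into
one of three hierarchical codivergence levels:

* Species-Species — a parasite species tied to a single host species;
* Species-Lineage — an intraspecific parasite lineage tied to a single host
  species;
* Tribe-Lineage  — a parasite lineage ranging over several hosts of one or
  two host tribes, with out-of-tribe hosts flagged as exceptions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .associations import GOODEINE_TRIBES, AssociationTable
from .dec import (
    PERIPHERAL_ISOLATE,
    SYMPATRIC_COPY,
    VICARIANCE,
    NodeScenario,
)
from .errors import DataError
from .events import Event
from .statespace import RangeStateSpace
from .trees import DatedTree

__all__ = [
    "HostSpace",
    "CodivergenceLevel",
    "encode_hosts_as_areas",
    "classify_node_events",
    "classify_branch_events",
    "assign_codivergence_levels",
    "terminal_label",
]

MAX_REPERTOIRE = 2


@dataclass
class HostSpace:
    """The set of host species treated as DEC 'areas'."""

    hosts: list[str]
    tribes: dict[str, str]
    adjacency: np.ndarray
    max_repertoire_size: int = MAX_REPERTOIRE
    state_space: RangeStateSpace = field(init=False)

    def __post_init__(self) -> None:
        missing = [h for h in self.hosts if h not in self.tribes]
        if missing:
            raise DataError(f"hosts without a tribe label: {missing}")
        self.state_space = RangeStateSpace(
            self.hosts, self.max_repertoire_size, self.adjacency
        )


def terminal_label(lineage: str, area_code: str) -> str:
    """Label of a per-area parasite terminal, e.g. ``'...Lineage III@D'``."""
    return f"{lineage}@{area_code}"


def encode_hosts_as_areas(
    table: AssociationTable,
    cooccurrence_gate: bool = False,
) -> tuple[HostSpace, dict[str, tuple[str, ...]]]:
    """Host repertoires per terminal, ready for the DEC machinery.

    Each (parasite lineage, area) terminal receives its observed host set as
    a DEC range.  With ``cooccurrence_gate`` the host 'adjacency' only allows
    switches between hosts sharing at least one area in the table; by default
    any switch is possible.
    """
    if table.n_records == 0:
        raise DataError("association table is empty")
    hosts = table.host_codes
    n = len(hosts)
    if cooccurrence_gate:
        adjacency = np.eye(n, dtype=int)
        for i, h1 in enumerate(hosts):
            a1 = table.areas_of_host(h1)
            for j, h2 in enumerate(hosts):
                if i < j and a1 & table.areas_of_host(h2):
                    adjacency[i, j] = adjacency[j, i] = 1
    else:
        adjacency = np.ones((n, n), dtype=int)
    space = HostSpace(hosts=hosts, tribes=table.host_to_tribe(), adjacency=adjacency)
    tip_ranges: dict[str, tuple[str, ...]] = {}
    for (lineage, area), repertoire in table.terminals().items():
        if len(repertoire) > MAX_REPERTOIRE:
            raise DataError(
                f"terminal {terminal_label(lineage, area)!r} has "
                f"{len(repertoire)} hosts; split the terminal so each carries "
                f"at most {MAX_REPERTOIRE}"
            )
        tip_ranges[terminal_label(lineage, area)] = repertoire
    return space, tip_ranges


# ---------------------------------------------------------------------------
# event translation
# ---------------------------------------------------------------------------


def _one_per_node(
    scenarios: Mapping[int, NodeScenario | Sequence[NodeScenario]],
) -> dict[int, NodeScenario]:
    out = {}
    for node, sc in scenarios.items():
        out[node] = sc[0] if isinstance(sc, (list, tuple)) else sc
    return out


def classify_node_events(
    scenarios: Mapping[int, NodeScenario | Sequence[NodeScenario]],
) -> list[Event]:
    """Cophylogenetic events implied by one scenario per internal node.

    Vicariance maps to cospeciation; a sympatric copy on a single host maps
    to duplication; a peripheral-isolate split is a duplication in which one
    daughter retains the full repertoire, reported as duplication plus a
    sharing record.
    """
    out: list[Event] = []
    for node, sc in sorted(_one_per_node(scenarios).items()):
        common = dict(
            anchor=str(node),
            child_left="+".join(sc.left),
            child_right="+".join(sc.right),
            age=sc.age,
        )
        if sc.kind == VICARIANCE:
            out.append(Event(type="cospeciation", **common))
        elif sc.kind == SYMPATRIC_COPY:
            out.append(Event(type="duplication", subject="+".join(sc.range_), **common))
        elif sc.kind == PERIPHERAL_ISOLATE:
            out.append(Event(type="duplication", subject="+".join(sc.range_), **common))
            retained = sc.left if len(sc.left) > len(sc.right) else sc.right
            out.append(Event(type="sharing", subject="+".join(retained), **common))
        else:
            raise DataError(f"unknown scenario kind {sc.kind!r} at node {node}")
    return out


def classify_branch_events(
    tree: DatedTree,
    scenarios: Mapping[int, NodeScenario | Sequence[NodeScenario]],
    tip_ranges: Mapping[str, Sequence[str]],
) -> list[Event]:
    """Host switches and lineage losses implied along each branch.

    A host present at the child end but absent from the parent-side daughter
    range was gained on the branch (host switch, donor = first retained host
    in sorted order); a host absent at the child end was lost (lineage loss).
    Events are ordered oldest first.
    """
    top = _one_per_node(scenarios)
    out: list[Event] = []
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent = tree.parent(node)
        if parent not in top:
            raise DataError(f"no scenario supplied for internal node {parent}")
        psc = top[parent]
        c1, c2 = tree.children(parent)
        side = psc.left if node == c1 else psc.right
        if tree.is_tip(node):
            label = tree.label(node)
            if label not in tip_ranges:
                raise DataError(f"tip {label!r} has no observed range")
            child_range = tuple(tip_ranges[label])
            anchor = label
        else:
            child_range = top[node].range_
            anchor = str(node)
        gained = sorted(set(child_range) - set(side))
        lost = sorted(set(side) - set(child_range))
        retained = sorted(set(side) & set(child_range))
        a_hi, a_lo = tree.age(parent), tree.age(node)
        for g in gained:
            out.append(
                Event(
                    type="host-switch",
                    anchor=anchor,
                    donor=retained[0] if retained else None,
                    recipient=g,
                    subject=g,
                    age=a_hi,
                    age_end=a_lo,
                )
            )
        for l in lost:
            out.append(
                Event(
                    type="lineage-loss",
                    anchor=anchor,
                    subject=l,
                    age=a_hi,
                    age_end=a_lo,
                )
            )
    out.sort(key=lambda ev: (-(ev.age if ev.age is not None else 0.0), ev.anchor))
    return out


# ---------------------------------------------------------------------------
# codivergence levels
# ---------------------------------------------------------------------------

SPECIES_SPECIES = "Species-Species"
SPECIES_LINEAGE = "Species-Lineage"
TRIBE_LINEAGE = "Tribe-Lineage"


@dataclass
class CodivergenceLevel:
    """Codivergence classification of one parasite lineage."""

    lineage: str
    level: str
    hosts: tuple[str, ...]
    tribes: tuple[str, ...]
    exceptions: tuple[str, ...]


def assign_codivergence_levels(
    table: AssociationTable,
    tribes: Mapping[str, str] | None = None,
) -> list[CodivergenceLevel]:
    """Classify each parasite lineage into one of the three levels.

    A single-host lineage is Species-Species (parasite ranked as a species)
    or Species-Lineage (intraspecific lineage).  A multi-host lineage is
    Tribe-Lineage: its focal tribes are the host tribes carrying at least two
    of its hosts (falling back to the plurality tribe), restricted to proper
    goodeine tribes; remaining hosts — minority-tribe or non-goodeid — are
    listed as exceptions.
    """
    tribe_of = dict(tribes) if tribes is not None else table.host_to_tribe()
    ranks = table.lineage_rank()
    out: list[CodivergenceLevel] = []
    for lineage, hosts in sorted(table.lineage_hosts().items()):
        missing = [h for h in hosts if h not in tribe_of]
        if missing:
            raise DataError(f"hosts without tribe label: {missing}")
        if len(hosts) == 1:
            level = SPECIES_SPECIES if ranks[lineage] == "species" else SPECIES_LINEAGE
            out.append(
                CodivergenceLevel(
                    lineage=lineage,
                    level=level,
                    hosts=hosts,
                    tribes=(tribe_of[hosts[0]],),
                    exceptions=(),
                )
            )
            continue
        counts = Counter(
            tribe_of[h] for h in hosts if tribe_of[h] in GOODEINE_TRIBES
        )
        focal = sorted(t for t, c in counts.items() if c >= 2)
        if not focal and counts:
            best = max(counts.values())
            focal = sorted(t for t, c in counts.items() if c == best)
        exceptions = tuple(sorted(h for h in hosts if tribe_of[h] not in focal))
        out.append(
            CodivergenceLevel(
                lineage=lineage,
                level=TRIBE_LINEAGE,
                hosts=hosts,
                tribes=tuple(focal),
                exceptions=exceptions,
            )
        )
    return out
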