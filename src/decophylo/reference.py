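"""Exhaustive reference likelihood by enumeration.

``brute_force_loglik`` sums the joint probability over every assignment of a
cladogenetic scenario to every internal node — no pruning recursion, no
partial-likelihood bookkeeping — and exists solely as an independent check of
the production likelihood in :mod:`decophylo.dec`.  It is exponential in the
number of internal nodes and only usable on toy instances (a handful of tips
and states).
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .dec import DECParams, EpochConfig, build_rate_matrix, cladogenesis_table
from .statespace import RangeStateSpace
from .trees import DatedTree

__all__ = ["brute_force_loglik"]


def brute_force_loglik(
    tree: DatedTree,
    tip_ranges: Mapping[str, Sequence[str]],
    space: RangeStateSpace,
    params: DECParams,
    fix: Mapping[int, tuple[int, int, int]] | None = None,
) -> float:
    """Log-likelihood by explicit enumeration of all scenario assignments.

    ``fix`` optionally pins the (state, left, right) scenario of chosen
    internal nodes, yielding the constrained likelihood used to cross-check
    relative scenario probabilities.
    """
    epochs = params.epochs or EpochConfig.uniform(space.n_areas)
    Qs = [build_rate_matrix(space, params, k) for k in range(epochs.n_epochs)]
    clado = cladogenesis_table(space)

    def branch_P(node: int, child: int) -> np.ndarray:
        P = np.eye(space.n_states)
        for k, dt in epochs.segments(tree.age(node), tree.age(child)):
            P = P @ scipy.linalg.expm(Qs[k] * dt)
        return P

    P_of = {}
    for node in tree.postorder():
        if node != tree.root:
            P_of[node] = branch_P(tree.parent(node), node)

    internals = tree.internal_nodes()
    fix = fix or {}
    choices = [
        [fix[node]]
        if node in fix
        else [(s, l, r) for s in range(1, space.n_states) for (l, r) in clado[s]]
        for node in internals
    ]
    tip_state = {
        tip: space.index_of(tip_ranges[tree.label(tip)]) for tip in tree.tips()
    }
    root_prior = 1.0 / (space.n_states - 1)
    total = 0.0
    for assignment in product(*choices):
        by_node = dict(zip(internals, assignment))
        prob = root_prior
        for node, (s, l, r) in by_node.items():
            prob /= len(clado[s])
            c1, c2 = tree.children(node)
            for child, side in ((c1, l), (c2, r)):
                target = (
                    by_node[child][0] if not tree.is_tip(child) else tip_state[child]
                )
                prob *= P_of[child][side, target]
            if prob == 0.0:
                break
        total += prob
    return -np.inf if total <= 0 else float(np.log(total))
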