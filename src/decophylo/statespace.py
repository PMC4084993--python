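"""Enumeration of allowed geographic ranges (area subsets).

The DEC state space is the set of subsets of areas that a lineage may occupy:
the empty range, all singletons, and every multi-area subset up to a maximum
size whose areas form a connected patch under the adjacency matrix.  States
are represented internally as bitmasks over the ordered area list, and the
ordering (by size, then lexicographically by area indices) is deterministic so
that likelihoods and tie-breaks are reproducible.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParameterError

__all__ = ["RangeStateSpace", "build_state_space"]


class RangeStateSpace:
    """All admissible ranges over a fixed ordered set of areas.

    Parameters
    ----------
    areas:
        Ordered area labels (e.g. ``["A", "B", "C"]``).
    max_range_size:
        Largest number of areas a single lineage may occupy.
    adjacency:
        Symmetric 0/1 matrix; a multi-area range is admissible only if its
        areas induce a connected subgraph.  ``None`` means complete adjacency.
    """

    def __init__(
        self,
        areas: Sequence[str],
        max_range_size: int,
        adjacency: np.ndarray | None = None,
    ):
        self.areas = [str(a) for a in areas]
        if len(set(self.areas)) != len(self.areas):
            raise ParameterError("area labels must be unique")
        n = len(self.areas)
        if n < 1:
            raise ParameterError("at least one area required")
        if not (1 <= max_range_size <= n):
            raise ParameterError(
                f"max_range_size must be in [1, {n}], got {max_range_size}"
            )
        self.max_range_size = int(max_range_size)
        if adjacency is None:
            adjacency = np.ones((n, n), dtype=int)
        adjacency = np.asarray(adjacency)
        if adjacency.shape != (n, n):
            raise ParameterError("adjacency matrix has wrong shape")
        if not np.array_equal(adjacency, adjacency.T):
            raise ParameterError("adjacency matrix must be symmetric")
        self.adjacency = (adjacency != 0).astype(int)
        np.fill_diagonal(self.adjacency, 1)

        self._area_index = {a: i for i, a in enumerate(self.areas)}
        self.states: list[int] = [0]  # bitmasks; state 0 is the empty range
        for size in range(1, self.max_range_size + 1):
            for combo in combinations(range(n), size):
                if size == 1 or self._connected(combo):
                    mask = 0
                    for i in combo:
                        mask |= 1 << i
                    self.states.append(mask)
        self._state_index = {m: k for k, m in enumerate(self.states)}

    def _connected(self, members: tuple[int, ...]) -> bool:
        members_set = set(members)
        frontier = {members[0]}
        seen = {members[0]}
        while frontier:
            nxt = set()
            for i in frontier:
                for j in members_set - seen:
                    if self.adjacency[i, j]:
                        nxt.add(j)
            seen |= nxt
            frontier = nxt
        return seen == members_set

    # -- lookups ------------------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, range_areas: Iterable[str]) -> int:
        """State index of a range given as an iterable of area labels."""
        mask = 0
        for a in range_areas:
            try:
                mask |= 1 << self._area_index[a]
            except KeyError:
                raise DataError(f"unknown area label {a!r}") from None
        try:
            return self._state_index[mask]
        except KeyError:
            raise DataError(
                f"range {sorted(range_areas)} is not an admissible state "
                f"(max size {self.max_range_size}, adjacency constraints)"
            ) from None

    def index_of_mask(self, mask: int) -> int:
        return self._state_index[mask]

    def contains_mask(self, mask: int) -> bool:
        return mask in self._state_index

    def members(self, state: int) -> tuple[int, ...]:
        """Area indices of a state (by state index)."""
        mask = self.states[state]
        return tuple(i for i in range(self.n_areas) if mask >> i & 1)

    def labels(self, state: int) -> tuple[str, ...]:
        return tuple(self.areas[i] for i in self.members(state))

    def size(self, state: int) -> int:
        return len(self.members(state))

    def state_name(self, state: int) -> str:
        labs = self.labels(state)
        return "+".join(labs) if labs else "0"

    def nonempty(self) -> list[int]:
        return list(range(1, self.n_states))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RangeStateSpace {self.n_areas} areas, max {self.max_range_size}, "
            f"{self.n_states} states>"
        )


def build_state_space(
    areas: Sequence[str],
    max_range_size: int,
    adjacency: np.ndarray | None = None,
) -> RangeStateSpace:
    """Convenience constructor mirroring :class:`RangeStateSpace`."""
    return RangeStateSpace(areas, max_range_size, adjacency)
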