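"""Rooted, dated, ultrametric trees.

Trees are the substrate for every likelihood in this package: node ages are in
absolute time (Ma before present, tips at age 0), every internal node —
including the root — has exactly two children, and all root-to-tip path
lengths agree within a tolerance.  Newick parsing and writing is delegated to
dendropy; this module adds age computation and the structural validation that
downstream code relies on.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy

from .errors import FormatError, ValidationError

__all__ = ["DatedTree", "read_newick", "write_newick"]

DEFAULT_AGE_TOLERANCE = 1e-6


class DatedTree:
    """A strictly bifurcating ultrametric tree with node ages in Ma.

    Nodes are integer ids ``0 .. n_nodes-1``; tips carry unique string labels.
    The class is immutable after construction.
    """

    def __init__(
        self,
        parent: Sequence[int | None],
        children: Sequence[Sequence[int]],
        age: Sequence[float],
        label: Sequence[str | None],
        root: int,
        age_tolerance: float = DEFAULT_AGE_TOLERANCE,
    ):
        self._parent = [None if p is None else int(p) for p in parent]
        self._children = [tuple(int(c) for c in cs) for cs in children]
        self._age = [float(a) for a in age]
        self._label = list(label)
        self.root = int(root)
        self.age_tolerance = float(age_tolerance)
        self._validate()
        self._postorder = self._compute_postorder()
        self._tips = [i for i in range(self.n_nodes) if not self._children[i]]
        self._tip_index = {self._label[i]: i for i in self._tips}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, age_tolerance: float = DEFAULT_AGE_TOLERANCE) -> "DatedTree":
        """Parse a Newick string (branch lengths required) into a dated tree."""
        try:
            dtree = dendropy.Tree.get(
                data=source, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"could not parse Newick input: {exc}") from exc
        return cls._from_dendropy(dtree, age_tolerance)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree, age_tolerance: float) -> "DatedTree":
        dnodes = list(dtree.preorder_node_iter())
        if len(dnodes) < 3:
            raise ValidationError("tree must have at least two tips")
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        parent: list[int | None] = [None] * len(dnodes)
        children: list[list[int]] = [[] for _ in dnodes]
        depth = [0.0] * len(dnodes)
        label: list[str | None] = [None] * len(dnodes)
        for nd in dnodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                label[i] = nd.taxon.label
            elif nd.label:
                label[i] = nd.label
            for ch in nd.child_nodes():
                j = index[id(ch)]
                parent[j] = i
                children[i].append(j)
                if ch.edge.length is None:
                    raise FormatError("Newick input is missing a branch length")
                depth[j] = depth[i] + float(ch.edge.length)
        root = index[id(dtree.seed_node)]
        tips = [i for i in range(len(dnodes)) if not children[i]]
        for i in tips:
            if label[i] is None:
                raise FormatError("unlabelled tip in Newick input")
        # ultrametricity: all tip depths equal the reference depth within tol
        ref = depth[tips[0]]
        for i in tips:
            if abs(depth[i] - ref) > age_tolerance:
                raise ValidationError(
                    f"tree is not ultrametric: tip {label[i]!r} has root-to-tip "
                    f"length {depth[i]:.9g}, expected {ref:.9g} "
                    f"(tolerance {age_tolerance:g})"
                )
        height = max(depth[i] for i in tips)
        age = [height - d for d in depth]
        for i in tips:
            age[i] = 0.0
        return cls(parent, children, age, label, root, age_tolerance)

    @classmethod
    def from_structure(cls, root_node: dict, age_tolerance: float = DEFAULT_AGE_TOLERANCE) -> "DatedTree":
        """Build from nested dicts ``{"age": float, "label": str|None, "children": [...]}``.

        Used by the simulators, where exact node ages are known and should not
        round-trip through a Newick string.
        """
        parent: list[int | None] = []
        children: list[list[int]] = []
        age: list[float] = []
        label: list[str | None] = []

        def visit(node: dict, par: int | None) -> int:
            i = len(parent)
            parent.append(par)
            children.append([])
            age.append(float(node["age"]))
            label.append(node.get("label"))
            for ch in node.get("children", ()):
                j = visit(ch, i)
                children[i].append(j)
            return i

        root = visit(root_node, None)
        return cls(parent, children, age, label, root, age_tolerance)

    def _validate(self) -> None:
        n = self.n_nodes
        if not (0 <= self.root < n) or self._parent[self.root] is not None:
            raise ValidationError("invalid root")
        seen_labels: set[str] = set()
        for i in range(n):
            cs = self._children[i]
            if cs and len(cs) != 2:
                raise ValidationError(
                    f"node {i} has {len(cs)} children; the tree must be strictly bifurcating"
                )
            if not cs:
                if not self._label[i]:
                    raise ValidationError(f"tip {i} has no label")
                if self._label[i] in seen_labels:
                    raise ValidationError(f"duplicate tip label {self._label[i]!r}")
                seen_labels.add(self._label[i])
                if abs(self._age[i]) > self.age_tolerance:
                    raise ValidationError(f"tip {self._label[i]!r} has nonzero age")
            for c in cs:
                if self._parent[c] != i:
                    raise ValidationError("parent/child arrays inconsistent")
                if self._age[c] > self._age[i] + self.age_tolerance:
                    raise ValidationError(
                        f"ages must decrease from root to tips (node {i} -> {c})"
                    )

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or not self._children[node]:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self._children[node]):
                    stack.append((c, False))
        return order

    # -- accessors ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._parent)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self._label[i] for i in self._tips]

    def tips(self) -> list[int]:
        return list(self._tips)

    def tip_id(self, label: str) -> int:
        return self._tip_index[label]

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def children(self, node: int) -> tuple[int, ...]:
        return self._children[node]

    def parent(self, node: int) -> int | None:
        return self._parent[node]

    def age(self, node: int) -> float:
        return self._age[node]

    def label(self, node: int) -> str | None:
        return self._label[node]

    def branch_length(self, node: int) -> float:
        p = self._parent[node]
        return 0.0 if p is None else self._age[p] - self._age[node]

    @property
    def root_age(self) -> float:
        return self._age[self.root]

    def postorder(self) -> list[int]:
        return list(self._postorder)

    def preorder(self) -> list[int]:
        return list(reversed(self._postorder))

    def internal_nodes(self) -> list[int]:
        return [i for i in self._postorder if self._children[i]]

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        ids = [self._tip_index[l] for l in labels]
        if not ids:
            raise ValueError("mrca of empty set")
        paths = []
        for i in ids:
            path = []
            cur: int | None = i
            while cur is not None:
                path.append(cur)
                cur = self._parent[cur]
            paths.append(list(reversed(path)))
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    # -- output -------------------------------------------------------------

    def newick(self) -> str:
        """Newick string with branch lengths derived from node ages."""
        out = io.StringIO()

        def write(node: int) -> None:
            cs = self._children[node]
            if cs:
                out.write("(")
                for k, c in enumerate(cs):
                    if k:
                        out.write(",")
                    write(c)
                out.write(")")
                if self._label[node]:
                    out.write(_quote(self._label[node]))
            else:
                out.write(_quote(self._label[node]))
            p = self._parent[node]
            if p is not None:
                out.write(":%.17g" % (self._age[p] - self._age[node]))

        write(self.root)
        out.write(";")
        return out.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def pruned(self, keep_labels: Iterable[str]) -> "DatedTree":
        """Restriction of the tree to a subset of tips (unifurcations suppressed)."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValidationError("a pruned tree needs at least two tips")

        def build(node: int):
            cs = self._children[node]
            if not cs:
                if self._label[node] in keep:
                    return {"age": 0.0, "label": self._label[node], "children": []}
                return None
            sub = [s for s in (build(c) for c in cs) if s is not None]
            if not sub:
                return None
            if len(sub) == 1:
                return sub[0]
            return {"age": self._age[node], "label": self._label[node], "children": sub}

        root = build(self.root)
        return DatedTree.from_structure(root, self.age_tolerance)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<DatedTree {self.n_tips} tips, root age {self.root_age:.4g} Ma>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path, age_tolerance: float = DEFAULT_AGE_TOLERANCE) -> DatedTree:
    """Read a dated ultrametric tree from a Newick file."""
    with open(path) as fh:
        return DatedTree.from_newick(fh.read(), age_tolerance)


def write_newick(tree: DatedTree, path) -> None:
    tree.write(path)
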