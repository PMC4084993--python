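"""Dispersal-extinction-cladogenesis (DEC) model: likelihood, fitting, ancestors.

The model is a continuous-time Markov chain on area subsets ("ranges").
Along a branch a lineage gains an adjacent area ``j`` at rate
``d * sum_{i in S} m_ij`` (dispersal, scaled by a per-epoch multiplier matrix
``m``) and loses any occupied area at rate ``e`` (local extinction); the empty
range is absorbing.  At a speciation node the ancestral range is partitioned
by one of the classical cladogenetic scenarios:

* sympatric copy      — a single-area range is inherited by both daughters;
* vicariance          — one daughter receives one area, the other the rest;
* peripheral isolate  — one daughter receives one area, the other keeps the
  whole ancestral range.

All scenarios allowed for a given ancestral range are equally weighted
(probability ``1/n`` each, counting left/right assignments as distinct), and
the root range is averaged uniformly over non-empty states, so the total
likelihood is a proper probability.  Time stratification is supported by
splitting branches at epoch boundaries and chaining the per-epoch transition
matrices in time order.

Relative probabilities of node scenarios are computed exactly with an
inside-outside pass: the probability of a scenario is the fraction of the
total likelihood obtained when that node's split is fixed to the scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import Bounds, minimize

from .errors import DataError, ParameterError
from .statespace import RangeStateSpace
from .trees import DatedTree

__all__ = [
    "EpochConfig",
    "DECParams",
    "NodeScenario",
    "DECFit",
    "CombinedNode",
    "build_rate_matrix",
    "transition_matrix",
    "tree_likelihood",
    "fit_dec",
    "ancestral_scenarios",
    "combine_runs",
    "DECModel",
    "write_scenarios",
    "read_scenarios",
]

SYMPATRIC_COPY = "sympatric-copy"
VICARIANCE = "vicariance"
PERIPHERAL_ISOLATE = "peripheral-isolate"


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


class EpochConfig:
    """Time stratification of dispersal multipliers.

    ``boundaries`` are epoch end ages in Ma, strictly decreasing and ending at
    0; epoch ``k`` covers ages ``(boundaries[k], boundaries[k-1]]`` with the
    oldest epoch extending to infinity.  ``multipliers[k]`` scales the pairwise
    dispersal rate ``d`` within epoch ``k``.
    """

    def __init__(self, boundaries: Sequence[float], multipliers: Sequence[np.ndarray]):
        self.boundaries = [float(b) for b in boundaries]
        if not self.boundaries or self.boundaries[-1] != 0.0:
            raise ParameterError("epoch boundaries must end at 0")
        if any(a <= b for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise ParameterError("epoch boundaries must be strictly decreasing")
        self.multipliers = [np.asarray(m, dtype=float) for m in multipliers]
        if len(self.multipliers) != len(self.boundaries):
            raise ParameterError("need one multiplier matrix per epoch")
        shape = self.multipliers[0].shape
        for m in self.multipliers:
            if m.shape != shape or m.shape[0] != m.shape[1]:
                raise ParameterError("multiplier matrices must be square and same size")
            if np.any(m < 0):
                raise ParameterError("dispersal multipliers must be >= 0")

    @classmethod
    def uniform(cls, n_areas: int) -> "EpochConfig":
        """A single epoch with all multipliers equal to one."""
        return cls([0.0], [np.ones((n_areas, n_areas))])

    @property
    def n_epochs(self) -> int:
        return len(self.boundaries)

    @property
    def n_areas(self) -> int:
        return self.multipliers[0].shape[0]

    def epoch_at(self, age: float) -> int:
        """Index of the epoch containing the instant ``age``."""
        for k, b in enumerate(self.boundaries):
            if age > b:
                return k
        return self.n_epochs - 1

    def segments(self, age_top: float, age_bottom: float) -> list[tuple[int, float]]:
        """Split the interval [age_bottom, age_top] at epoch boundaries.

        Returns ``(epoch index, duration)`` pairs in time order (oldest
        first).  Zero-length segments are dropped.
        """
        if age_bottom > age_top:
            raise ParameterError("age_top must be >= age_bottom")
        cuts = [b for b in self.boundaries if age_bottom < b < age_top]
        edges = [age_top] + cuts + [age_bottom]
        out = []
        for hi, lo in zip(edges, edges[1:]):
            if hi > lo:
                out.append((self.epoch_at(0.5 * (hi + lo)), hi - lo))
        return out or [(self.epoch_at(age_bottom), 0.0)]


@dataclass
class DECParams:
    """Anagenetic DEC rates plus the stratification they act under."""

    d: float
    e: float
    epochs: EpochConfig | None = None
    adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.d) or self.d < 0:
            raise ParameterError("dispersal rate d must be finite and >= 0")
        if not np.isfinite(self.e) or self.e < 0:
            raise ParameterError("extinction rate e must be finite and >= 0")


# ---------------------------------------------------------------------------
# cladogenesis scenarios
# ---------------------------------------------------------------------------


def cladogenesis_table(space: RangeStateSpace) -> list[list[tuple[int, int]]]:
    """Allowed (left, right) daughter-state pairs per ancestral state.

    Cached on the state space: the table depends only on the space.
    """
    cached = getattr(space, "_clado_table", None)
    if cached is not None:
        return cached
    table: list[list[tuple[int, int]]] = [[]]  # empty range: no scenarios
    for s in range(1, space.n_states):
        members = space.members(s)
        if len(members) == 1:
            pairs = {(s, s)}
        else:
            pairs = set()
            mask = space.states[s]
            for i in members:
                single = space.index_of_mask(1 << i)
                rest_mask = mask & ~(1 << i)
                if space.contains_mask(rest_mask):
                    rest = space.index_of_mask(rest_mask)
                    pairs.add((single, rest))
                    pairs.add((rest, single))
                pairs.add((single, s))
                pairs.add((s, single))
        table.append(sorted(pairs))
    space._clado_table = table  # type: ignore[attr-defined]
    return table


def scenario_kind(space: RangeStateSpace, s: int, left: int, right: int) -> str:
    if space.size(s) == 1:
        return SYMPATRIC_COPY
    if left == s or right == s:
        return PERIPHERAL_ISOLATE
    return VICARIANCE


# ---------------------------------------------------------------------------
# rate and transition matrices
# ---------------------------------------------------------------------------


def build_rate_matrix(
    space: RangeStateSpace, params: DECParams, epoch: int = 0
) -> np.ndarray:
    """Anagenetic generator over the state space for one epoch.

    Range expansion ``S -> S + {j}`` at rate ``d * sum_{i in S, i~j} m_ij``;
    range contraction ``S -> S - {i}`` at rate ``e``; the empty range is
    absorbing.  Transitions out of the state space are disallowed.
    """
    n = space.n_states
    adjacency = params.adjacency if params.adjacency is not None else space.adjacency
    adjacency = np.asarray(adjacency)
    epochs = params.epochs or EpochConfig.uniform(space.n_areas)
    if epochs.n_areas != space.n_areas:
        raise ParameterError("epoch multiplier dimension does not match areas")
    m = epochs.multipliers[epoch]
    Q = np.zeros((n, n))
    for s in range(1, n):
        members = space.members(s)
        mask = space.states[s]
        occupied = set(members)
        for j in range(space.n_areas):
            if j in occupied:
                continue
            target_mask = mask | (1 << j)
            if not space.contains_mask(target_mask):
                continue
            rate = params.d * sum(
                m[i, j] for i in members if adjacency[i, j]
            )
            if rate > 0:
                Q[s, space.index_of_mask(target_mask)] += rate
        for i in members:
            target_mask = mask & ~(1 << i)
            if space.contains_mask(target_mask):
                Q[s, space.index_of_mask(target_mask)] += params.e
        Q[s, s] = -Q[s].sum()
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """Matrix exponential ``exp(Q t)`` with tiny negative entries clamped."""
    if t < 0:
        raise ParameterError("elapsed time must be >= 0")
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * t)
    P[(P < 0) & (P > -1e-12)] = 0.0
    return P


class _Propagator:
    """Fast ``exp(Q t) @ v`` via eigendecomposition, with an expm fallback.

    DEC generators are small and generically diagonalizable; when the
    eigenbasis is ill-conditioned we fall back to scipy's Pade expm.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self._use_eig = False
        try:
            w, V = np.linalg.eig(self.Q)
            W = np.linalg.inv(V)
            recon = (V * w) @ W
            scale = max(1.0, np.abs(self.Q).max())
            if np.abs(recon - self.Q).max() < 1e-10 * scale:
                self.w, self.V, self.W = w, V, W
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def matrix(self, t: float) -> np.ndarray:
        if self._use_eig:
            P = (self.V * np.exp(self.w * t)) @ self.W
            P = np.real(P)
        else:
            P = scipy.linalg.expm(self.Q * t)
        np.maximum(P, 0.0, out=P)
        return P

    def apply(self, t: float, v: np.ndarray) -> np.ndarray:
        """Column action: ``exp(Qt) @ v``."""
        if self._use_eig:
            out = np.real(self.V @ (np.exp(self.w * t) * (self.W @ v)))
        else:
            out = scipy.linalg.expm(self.Q * t) @ v
        return np.maximum(out, 0.0)

    def apply_left(self, t: float, v: np.ndarray) -> np.ndarray:
        """Row action: ``v @ exp(Qt)``."""
        if self._use_eig:
            out = np.real(((v @ self.V) * np.exp(self.w * t)) @ self.W)
        else:
            out = v @ scipy.linalg.expm(self.Q * t)
        return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


class _Engine:
    """Shared machinery for likelihood and ancestral-state passes."""

    def __init__(
        self,
        tree: DatedTree,
        tip_ranges: Mapping[str, Sequence[str]],
        space: RangeStateSpace,
        params: DECParams,
    ):
        self.tree = tree
        self.space = space
        self.params = params
        self.epochs = params.epochs or EpochConfig.uniform(space.n_areas)
        self.clado = cladogenesis_table(space)
        self.tip_state: dict[int, int] = {}
        for tip in tree.tips():
            label = tree.label(tip)
            if label not in tip_ranges:
                raise DataError(f"tip {label!r} has no observed range")
            rng = tip_ranges[label]
            if not rng:
                raise DataError(f"tip {label!r} has an empty observed range")
            try:
                self.tip_state[tip] = space.index_of(rng)
            except DataError as exc:
                raise DataError(f"tip {label!r}: {exc}") from None
        self._props = {
            k: _Propagator(build_rate_matrix(space, params, k))
            for k in range(self.epochs.n_epochs)
        }

    def branch_down(self, node: int, child: int, v: np.ndarray) -> np.ndarray:
        """Propagate a conditional likelihood from child up to the node."""
        segs = self.epochs.segments(self.tree.age(node), self.tree.age(child))
        for k, dt in reversed(segs):  # youngest segment applied first
            v = self._props[k].apply(dt, v)
        return v

    def branch_up(self, node: int, child: int, v: np.ndarray) -> np.ndarray:
        """Propagate an outside (row) vector from the node down to the child."""
        segs = self.epochs.segments(self.tree.age(node), self.tree.age(child))
        for k, dt in segs:  # oldest segment applied first
            v = self._props[k].apply_left(dt, v)
        return v

    def inside(self):
        """Postorder pass: per-node scaled partials and per-branch D arrays."""
        n = self.space.n_states
        partial: dict[int, np.ndarray] = {}
        branch_D: dict[int, np.ndarray] = {}  # keyed by child node
        log_scale = 0.0
        for node in self.tree.postorder():
            if self.tree.is_tip(node):
                v = np.zeros(n)
                v[self.tip_state[node]] = 1.0
                partial[node] = v
                continue
            c1, c2 = self.tree.children(node)
            D1 = self.branch_down(node, c1, partial[c1])
            D2 = self.branch_down(node, c2, partial[c2])
            branch_D[c1], branch_D[c2] = D1, D2
            v = np.zeros(n)
            for s in range(1, n):
                pairs = self.clado[s]
                if not pairs:
                    continue
                acc = 0.0
                for l, r in pairs:
                    acc += D1[l] * D2[r]
                v[s] = acc / len(pairs)
            top = v.max()
            if top <= 0.0:
                return partial, branch_D, -np.inf
            v /= top
            log_scale += np.log(top)
            partial[node] = v
        root_prior = 1.0 / (n - 1)
        L = partial[self.tree.root][1:].sum() * root_prior
        loglik = -np.inf if L <= 0 else np.log(L) + log_scale
        self._root_prior = root_prior
        return partial, branch_D, loglik


def tree_likelihood(
    tree: DatedTree,
    tip_ranges: Mapping[str, Sequence[str]],
    space: RangeStateSpace,
    params: DECParams,
) -> float:
    """Log-likelihood of observed tip ranges under the DEC model."""
    _, _, loglik = _Engine(tree, tip_ranges, space, params).inside()
    return loglik


# ---------------------------------------------------------------------------
# ancestral scenarios
# ---------------------------------------------------------------------------


@dataclass
class NodeScenario:
    """One cladogenetic outcome at an internal node with its support."""

    node: int
    age: float
    range_: tuple[str, ...]
    left: tuple[str, ...]
    right: tuple[str, ...]
    kind: str
    relative_probability: float

    def key(self) -> tuple:
        return (self.range_, self.left, self.right)


def ancestral_scenarios(
    tree: DatedTree,
    tip_ranges: Mapping[str, Sequence[str]],
    space: RangeStateSpace,
    params: DECParams,
) -> dict[int, list[NodeScenario]]:
    """Relative probability of every allowed scenario at every internal node.

    The relative probability of scenario ``(S -> S_L, S_R)`` at node ``v`` is
    the likelihood with the split at ``v`` fixed to that scenario divided by
    the sum over all scenarios at ``v`` (which equals the total likelihood).
    Scenarios are returned sorted by decreasing probability, ties broken by
    state-space order.
    """
    eng = _Engine(tree, tip_ranges, space, params)
    partial, branch_D, loglik = eng.inside()
    if not np.isfinite(loglik):
        raise DataError("data have zero likelihood under the supplied parameters")
    n = space.n_states
    clado = eng.clado
    outside: dict[int, np.ndarray] = {}
    F_root = np.zeros(n)
    F_root[1:] = 1.0 / (n - 1)
    outside[tree.root] = F_root
    result: dict[int, list[NodeScenario]] = {}
    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        c1, c2 = tree.children(node)
        F = outside[node]
        D1, D2 = branch_D[c1], branch_D[c2]
        weights = []
        H1 = np.zeros(n)
        H2 = np.zeros(n)
        for s in range(1, n):
            pairs = clado[s]
            if not pairs or F[s] == 0.0:
                continue
            base = F[s] / len(pairs)
            for l, r in pairs:
                w = base * D1[l] * D2[r]
                weights.append((w, s, l, r))
                H1[l] += base * D2[r]
                H2[r] += base * D1[l]
        total = sum(w for w, *_ in weights)
        if total <= 0:
            raise DataError(f"node {node}: zero total scenario weight")
        scen = [
            NodeScenario(
                node=node,
                age=tree.age(node),
                range_=space.labels(s),
                left=space.labels(l),
                right=space.labels(r),
                kind=scenario_kind(space, s, l, r),
                relative_probability=w / total,
            )
            for w, s, l, r in weights
        ]
        order = {id(sc): (sc.relative_probability, idx) for idx, sc in enumerate(scen)}
        scen.sort(key=lambda sc: (-order[id(sc)][0], order[id(sc)][1]))
        result[node] = scen
        for child, H in ((c1, H1), (c2, H2)):
            if not tree.is_tip(child):
                Fc = eng.branch_up(node, child, H)
                top = Fc.max()
                if top > 0:
                    Fc = Fc / top
                outside[child] = Fc
    return result


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class DECFit:
    """Result of a maximum-likelihood DEC fit."""

    d: float
    e: float
    log_likelihood: float
    converged: bool
    n_starts: int
    start_values: list[tuple[float, float]] = field(default_factory=list)


def fit_dec(
    tree: DatedTree,
    tip_ranges: Mapping[str, Sequence[str]],
    space: RangeStateSpace,
    epochs: EpochConfig | None = None,
    bounds: tuple[float, float] = (1e-9, 10.0),
    n_starts: int = 5,
    seed: int = 0,
    adjacency: np.ndarray | None = None,
) -> DECFit:
    """Maximise the DEC likelihood over (d, e) by bounded derivative-free search.

    The search runs in log10 space with Nelder-Mead from ``n_starts`` starting
    points drawn log-uniformly in [1e-3, 1] from a seeded generator, so the
    fit is reproducible.  Returns the best optimum over all starts.
    """
    if tree.n_tips < 2:
        raise ParameterError("need at least two tips to fit")
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ParameterError("bounds must satisfy 0 < lo < hi")
    log_lo, log_hi = np.log10(lo), np.log10(hi)

    def objective(x: np.ndarray) -> float:
        d, e = 10.0 ** x
        params = DECParams(d=d, e=e, epochs=epochs, adjacency=adjacency)
        ll = tree_likelihood(tree, tip_ranges, space, params)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = rng.uniform(-3.0, 0.0, size=(n_starts, 2))
    best = None
    any_converged = False
    start_values = []
    for x0 in starts:
        start_values.append(tuple(10.0 ** x0))
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=Bounds([log_lo] * 2, [log_hi] * 2),
            options={"fatol": 1e-8, "xatol": 1e-7, "maxiter": 1000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn(
            "DEC optimiser did not report convergence from any start; "
            "returning best point found",
            RuntimeWarning,
        )
    d, e = 10.0 ** best.x
    return DECFit(
        d=float(d),
        e=float(e),
        log_likelihood=float(-best.fun),
        converged=any_converged,
        n_starts=n_starts,
        start_values=start_values,
    )


class DECModel:
    """Object-style front end bundling a state space and stratification.

    ``fit`` populates ``d_``, ``e_`` and ``log_likelihood_``; ``scenarios``
    computes per-node relative probabilities at the fitted (or supplied)
    rates.
    """

    def __init__(
        self,
        space: RangeStateSpace,
        epochs: EpochConfig | None = None,
        bounds: tuple[float, float] = (1e-9, 10.0),
        n_starts: int = 5,
        seed: int = 0,
    ):
        self.space = space
        self.epochs = epochs
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed

    def log_likelihood(self, tree: DatedTree, tip_ranges, d: float, e: float) -> float:
        params = DECParams(d=d, e=e, epochs=self.epochs)
        return tree_likelihood(tree, tip_ranges, self.space, params)

    def fit(self, tree: DatedTree, tip_ranges) -> "DECModel":
        res = fit_dec(
            tree,
            tip_ranges,
            self.space,
            epochs=self.epochs,
            bounds=self.bounds,
            n_starts=self.n_starts,
            seed=self.seed,
        )
        self.d_, self.e_ = res.d, res.e
        self.log_likelihood_ = res.log_likelihood
        self.converged_ = res.converged
        self._tree, self._tip_ranges = tree, tip_ranges
        return self

    def scenarios(
        self, tree: DatedTree | None = None, tip_ranges=None
    ) -> dict[int, list[NodeScenario]]:
        tree = tree if tree is not None else self._tree
        tip_ranges = tip_ranges if tip_ranges is not None else self._tip_ranges
        params = DECParams(d=self.d_, e=self.e_, epochs=self.epochs)
        return ancestral_scenarios(tree, tip_ranges, self.space, params)


# ---------------------------------------------------------------------------
# combining model runs
# ---------------------------------------------------------------------------


@dataclass
class CombinedNode:
    """Across-run consensus at one node under the accept/moderate rule."""

    node: int
    area: str | None
    area_support: dict
    area_tier: str  # "accepted" | "moderate" | "equivocal"
    scenario: tuple | None
    scenario_support: float
    scenario_tier: str


def _area_supports(scenarios: list[NodeScenario]) -> dict[str, float]:
    sup: dict[str, float] = {}
    for sc in scenarios:
        for a in sc.range_:
            sup[a] = sup.get(a, 0.0) + sc.relative_probability
    return sup


def combine_runs(
    runs: Sequence[Mapping[int, list[NodeScenario]]],
    threshold: float = 0.7,
    moderate_threshold: float = 0.5,
) -> dict[int, CombinedNode]:
    """Consensus of several model runs over the same tree.

    An ancestral area at a node is *accepted* when the across-run mean of the
    summed relative probabilities of scenarios containing it exceeds
    ``threshold`` and it is the top-ranked area in every run; it falls in the
    *moderate* tier when the same agreement holds above
    ``moderate_threshold``.  Otherwise the node is *equivocal*.  The same rule
    is applied to whole scenarios.
    """
    if len(runs) < 2:
        raise ParameterError("need at least two runs to combine")
    node_sets = [set(r) for r in runs]
    if any(ns != node_sets[0] for ns in node_sets[1:]):
        raise ParameterError("runs cover different node sets (different trees?)")
    out: dict[int, CombinedNode] = {}
    for node in sorted(node_sets[0]):
        per_run_sup = [_area_supports(r[node]) for r in runs]
        tops = [max(sorted(sup), key=lambda a: sup[a]) for sup in per_run_sup]
        all_areas = sorted({a for sup in per_run_sup for a in sup})
        mean_sup = {
            a: float(np.mean([sup.get(a, 0.0) for sup in per_run_sup]))
            for a in all_areas
        }
        agree = len(set(tops)) == 1
        area, tier = None, "equivocal"
        if agree:
            top = tops[0]
            if mean_sup[top] > threshold:
                area, tier = top, "accepted"
            elif mean_sup[top] > moderate_threshold:
                area, tier = top, "moderate"
        # scenario-level consensus
        scen_tops = []
        scen_mean: dict[tuple, float] = {}
        for r in runs:
            scen_tops.append(r[node][0].key())
            for sc in r[node]:
                scen_mean[sc.key()] = scen_mean.get(sc.key(), 0.0) + (
                    sc.relative_probability / len(runs)
                )
        s_agree = len(set(scen_tops)) == 1
        scenario, s_sup, s_tier = None, 0.0, "equivocal"
        if s_agree:
            s_sup = scen_mean[scen_tops[0]]
            if s_sup > threshold:
                scenario, s_tier = scen_tops[0], "accepted"
            elif s_sup > moderate_threshold:
                scenario, s_tier = scen_tops[0], "moderate"
        out[node] = CombinedNode(
            node=node,
            area=area,
            area_support=mean_sup,
            area_tier=tier,
            scenario=scenario,
            scenario_support=float(s_sup),
            scenario_tier=s_tier,
        )
    return out


# ---------------------------------------------------------------------------
# scenario (de)serialisation
# ---------------------------------------------------------------------------

_SCEN_HEADER = [
    "node",
    "age_ma",
    "range",
    "left",
    "right",
    "kind",
    "relative_probability",
]


def write_scenarios(
    scenarios: Mapping[int, list[NodeScenario]], path, comment: str | None = None
) -> None:
    """Write per-node scenarios as a TSV (one row per scenario)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_SCEN_HEADER) + "\n")
        for node in sorted(scenarios):
            for sc in scenarios[node]:
                fh.write(
                    "\t".join(
                        [
                            str(sc.node),
                            "%.10g" % sc.age,
                            "+".join(sc.range_),
                            "+".join(sc.left),
                            "+".join(sc.right),
                            sc.kind,
                            "%.12g" % sc.relative_probability,
                        ]
                    )
                    + "\n"
                )


def read_scenarios(path) -> dict[int, list[NodeScenario]]:
    out: dict[int, list[NodeScenario]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\n").split("\t")
            break
        if header != _SCEN_HEADER:
            raise DataError(f"unexpected scenario file header: {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            node, age, rng, left, right, kind, prob = line.rstrip("\n").split("\t")
            out.setdefault(int(node), []).append(
                NodeScenario(
                    node=int(node),
                    age=float(age),
                    range_=tuple(rng.split("+")) if rng else (),
                    left=tuple(left.split("+")) if left else (),
                    right=tuple(right.split("+")) if right else (),
                    kind=kind,
                    relative_probability=float(prob),
                )
            )
    return out
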