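"""Dynamics of Boolean networks under synchronous and asynchronous schemes.

Three update schemes are supported:

* ``synchronous`` — all nodes update simultaneously each time step;
* ``random_order_asynchronous`` (ROA) — each round applies a fresh random
  permutation of the nodes, updating sequentially with the latest values;
* ``general_asynchronous`` (GA) — a single uniformly random node updates per
  step, making the dynamics a Markov chain on the 2^N state space.

Attractors of the stochastic schemes are the terminal strongly connected
components of the scheme's state transition graph; for GA they can
equivalently be read off the transition matrix T (T_ij = probability of
moving from state i to state j in one update) by examining T^m for large m.
Steady states (fixed points of every node's rule) are scheme-independent.

State indices encode the bit vector as an integer with the first canonical
node as the most significant bit; graph nodes are state strings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .network import BooleanNetwork, NetworkState

SYNCHRONOUS = "synchronous"
ROA = "random_order_asynchronous"
GA = "general_asynchronous"
SCHEMES = (SYNCHRONOUS, ROA, GA)

DEFAULT_SYNC_CAP = 20
DEFAULT_ASYNC_CAP = 16


class StateSpaceTooLarge(ValueError):
    """Raised when an exhaustive state-space operation exceeds its cap."""


@dataclass(frozen=True)
class UpdateScheme:
    kind: str = SYNCHRONOUS
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in SCHEMES:
            raise ValueError(f"unknown update scheme {self.kind!r}")


@dataclass(frozen=True)
class Attractor:
    """A steady state, synchronous limit cycle, or complex attractor.

    ``states`` are distinct; for synchronous limit cycles they are in cyclic
    successor order.  For complex attractors (terminal SCCs of a stochastic
    scheme) the order carries no dynamical meaning.
    """

    kind: str  # steady_state | limit_cycle | complex
    states: tuple[NetworkState, ...]
    scheme: str = SYNCHRONOUS

    def __len__(self) -> int:
        return len(self.states)

    @property
    def state_strings(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.states)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "scheme": self.scheme,
            "states": list(self.state_strings),
        }


@dataclass
class TransitionMatrix:
    """Row-stochastic one-step transition matrix of the GA Markov chain."""

    matrix: sp.csr_matrix
    n_nodes: int
    scheme: str = GA

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def power(self, m: int) -> sp.csr_matrix:
        """T^m by repeated squaring."""
        result = None
        base = self.matrix.copy()
        e = m
        while e:
            if e & 1:
                result = base if result is None else result @ base
            e >>= 1
            if e:
                base = base @ base
        return result


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _step_int(compiled, x: int, n: int) -> int:
    """Synchronous successor of integer-encoded state ``x``."""
    y = 0
    for regs, table in compiled:
        idx = 0
        for r in regs:
            idx = (idx << 1) | ((x >> (n - 1 - r)) & 1)
        y = (y << 1) | table[idx]
    return y


def _update_one_int(compiled, x: int, n: int, i: int) -> int:
    """State after updating only node ``i``."""
    regs, table = compiled[i]
    idx = 0
    for r in regs:
        idx = (idx << 1) | ((x >> (n - 1 - r)) & 1)
    bit = table[idx]
    mask = 1 << (n - 1 - i)
    return (x | mask) if bit else (x & ~mask)


def synchronous_step(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """All nodes update simultaneously from ``state``."""
    if len(state) != net.n:
        raise ValueError("state length does not match network size")
    x = _step_int(net.compiled(), state.to_int(), net.n)
    return NetworkState.from_int(x, net.n)


def find_synchronous_attractor(net: BooleanNetwork, s0: NetworkState) -> Attractor:
    """Iterate the synchronous map from ``s0`` until a state repeats.

    Returns the cycle portion of the trajectory (``steady_state`` if its
    length is 1), starting from the first revisited state.
    """
    comp = net.compiled()
    n = net.n
    seen: dict[int, int] = {}
    traj: list[int] = []
    x = s0.to_int()
    while x not in seen:
        seen[x] = len(traj)
        traj.append(x)
        x = _step_int(comp, x, n)
    cycle = traj[seen[x]:]
    kind = "steady_state" if len(cycle) == 1 else "limit_cycle"
    return Attractor(
        kind, tuple(NetworkState.from_int(v, n) for v in cycle), SYNCHRONOUS
    )


# ---------------------------------------------------------------------------
# State transition graphs
# ---------------------------------------------------------------------------

def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise StateSpaceTooLarge(
            f"network has {n} nodes; exhaustive state-space analysis capped at "
            f"{cap} (pass a larger cap explicitly to override)"
        )


def build_state_transition_graph(
    net: BooleanNetwork,
    scheme: str = SYNCHRONOUS,
    *,
    cap: int | None = None,
    seed: int | None = None,
    max_permutations: int = 100_000,
) -> nx.DiGraph:
    """Directed graph over all 2^N states under the given update scheme.

    Synchronous graphs have exactly one out-edge per state; GA graphs one
    edge per distinct single-node update outcome.  ROA edges are exhaustive
    over all N! permutations for N <= 7, otherwise sampled (``10 * N!``
    capped at ``max_permutations``, seeded) and the graph is flagged
    ``approximate``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown update scheme {scheme!r}")
    n = net.n
    _check_cap(n, cap if cap is not None else
               (DEFAULT_SYNC_CAP if scheme == SYNCHRONOUS else DEFAULT_ASYNC_CAP))
    comp = net.compiled()
    g = nx.DiGraph(scheme=scheme, approximate=False)
    states = [NetworkState.from_int(x, n) for x in range(1 << n)]
    labels = [str(s) for s in states]
    g.add_nodes_from(labels)

    if scheme == SYNCHRONOUS:
        for x in range(1 << n):
            g.add_edge(labels[x], labels[_step_int(comp, x, n)])
    elif scheme == GA:
        for x in range(1 << n):
            for i in range(n):
                g.add_edge(labels[x], labels[_update_one_int(comp, x, n, i)])
    else:  # ROA
        if n <= 7:
            perms: Iterable[tuple[int, ...]] = itertools.permutations(range(n))
        else:
            rng = np.random.default_rng(seed)
            n_perms = min(10 * math.factorial(n), max_permutations)
            perms = [tuple(rng.permutation(n)) for _ in range(n_perms)]
            g.graph["approximate"] = True
            g.graph["n_sampled_permutations"] = n_perms
            g.graph["seed"] = seed
        perms = list(perms)
        for x in range(1 << n):
            targets = set()
            for perm in perms:
                y = x
                for i in perm:
                    y = _update_one_int(comp, y, n, i)
                targets.add(y)
            for y in targets:
                g.add_edge(labels[x], labels[y])
    return g


def ga_transition_matrix(
    net: BooleanNetwork, *, cap: int | None = None
) -> TransitionMatrix:
    """One-step GA transition matrix: T_ij = (#nodes taking i to j) / N."""
    n = net.n
    _check_cap(n, cap if cap is not None else DEFAULT_ASYNC_CAP)
    comp = net.compiled()
    size = 1 << n
    rows, cols, vals = [], [], []
    w = 1.0 / n
    for x in range(size):
        counts: dict[int, int] = {}
        for i in range(n):
            y = _update_one_int(comp, x, n, i)
            counts[y] = counts.get(y, 0) + 1
        for y, c in counts.items():
            rows.append(x)
            cols.append(y)
            vals.append(c * w)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(size, size))
    return TransitionMatrix(m, n_nodes=n)


# ---------------------------------------------------------------------------
# Attractors and basins
# ---------------------------------------------------------------------------

@dataclass
class BasinAnalysis:
    """Attractors plus, per state, the set of reachable attractors."""

    attractors: list[Attractor]
    basins: dict[str, frozenset[int]]  # state string -> attractor indices

    def exclusive_count(self, attractor_index: int) -> int:
        return sum(
            1 for s in self.basins.values() if s == frozenset({attractor_index})
        )

    def shared_count(self) -> int:
        return sum(1 for s in self.basins.values() if len(s) > 1)

    def find_attractor(self, state_string: str) -> int:
        for i, a in enumerate(self.attractors):
            if state_string in a.state_strings:
                return i
        raise KeyError(state_string)


def _terminal_sccs_sparse(adj: sp.csr_matrix) -> tuple[np.ndarray, list[int]]:
    """(component label per state, labels of terminal components)."""
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # terminal components have no out-edges leaving them
    coo = adj.tocoo()
    has_out = np.zeros(n_comp, dtype=bool)
    for u, v in zip(labels[coo.row], labels[coo.col]):
        if u != v:
            has_out[u] = True
    return labels, [c for c in range(n_comp) if not has_out[c]]


def _reachable_sets(adj: sp.csr_matrix, labels: np.ndarray,
                    terminal: list[int]) -> list[frozenset[int]]:
    """Per component, the set of reachable terminal components (by index)."""
    n_comp = labels.max() + 1
    comp_edges: list[set[int]] = [set() for _ in range(n_comp)]
    coo = adj.tocoo()
    for u, v in zip(labels[coo.row], labels[coo.col]):
        if u != v:
            comp_edges[u].add(v)
    term_index = {c: i for i, c in enumerate(terminal)}
    memo: list[frozenset[int] | None] = [None] * n_comp

    order = list(nx.topological_sort(
        nx.DiGraph((u, v) for u in range(n_comp) for v in comp_edges[u])
    )) if any(comp_edges) else []
    covered = set(order)
    order.extend(c for c in range(n_comp) if c not in covered)
    for c in reversed(order):
        acc: set[int] = set()
        if c in term_index:
            acc.add(term_index[c])
        for d in comp_edges[c]:
            acc |= memo[d]  # type: ignore[operator]
        memo[c] = frozenset(acc)
    return memo  # type: ignore[return-value]


def _attractor_from_states(strings: list[str], scheme: str) -> Attractor:
    states = tuple(NetworkState.from_string(s) for s in sorted(strings))
    kind = "steady_state" if len(states) == 1 else "complex"
    return Attractor(kind, states, scheme)


def attractors_and_basins(
    matrix_or_graph: TransitionMatrix | nx.DiGraph,
    m: int = 1024,
    tol: float = 1e-5,
) -> BasinAnalysis:
    """Attractors (terminal SCCs) and per-state reachable-attractor sets.

    For a :class:`TransitionMatrix` the SCC decomposition is cross-checked
    against the matrix-power criterion: states carrying probability mass in
    any column of T^m (entries > ``tol``, ``m`` > 10^3 by default) must be
    exactly the attractor states, and the basin labeling from T^m row masses
    must agree with graph reachability.
    """
    if isinstance(matrix_or_graph, TransitionMatrix):
        tm = matrix_or_graph
        mat = tm.matrix
        rowsum = np.asarray(mat.sum(axis=1)).ravel()
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("transition matrix is not row-stochastic")
        n = tm.n_nodes
        adj = (mat > 0).astype(np.int8).tocsr()
        labels, terminal = _terminal_sccs_sparse(adj)
        reach = _reachable_sets(adj, labels, terminal)
        attractors = []
        for c in terminal:
            idxs = np.nonzero(labels == c)[0]
            attractors.append(
                _attractor_from_states(
                    [str(NetworkState.from_int(int(x), n)) for x in idxs], tm.scheme
                )
            )
        basins = {
            str(NetworkState.from_int(x, n)): reach[labels[x]]
            for x in range(mat.shape[0])
        }
        _crosscheck_matrix_power(tm, m, tol, labels, terminal, basins, n)
        return BasinAnalysis(attractors, basins)

    g = matrix_or_graph
    scheme = g.graph.get("scheme", "unknown")
    comp = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=comp)
    terminal = [c for c in cond.nodes if cond.out_degree(c) == 0]
    term_index = {c: i for i, c in enumerate(terminal)}
    attractors = []
    for c in terminal:
        members = sorted(cond.nodes[c]["members"])
        if len(members) == 1:
            kind = "steady_state"
        elif scheme == SYNCHRONOUS:
            kind = "limit_cycle"
            # order the cycle by following successors
            cur = members[0]
            ordered = [cur]
            while (nxt := next(iter(g.successors(cur)))) != ordered[0]:
                ordered.append(nxt)
                cur = nxt
            members = ordered
        else:
            kind = "complex"
        attractors.append(
            Attractor(kind, tuple(NetworkState.from_string(s) for s in members),
                      scheme)
        )
    memo: dict[int, frozenset[int]] = {}
    for c in reversed(list(nx.topological_sort(cond))):
        acc: set[int] = set()
        if c in term_index:
            acc.add(term_index[c])
        for d in cond.successors(c):
            acc |= memo[d]
        memo[c] = frozenset(acc)
    mapping = {}
    for c in cond.nodes:
        for s in cond.nodes[c]["members"]:
            mapping[s] = memo[c]
    return BasinAnalysis(attractors, mapping)


def _crosscheck_matrix_power(tm, m, tol, labels, terminal, basins, n):
    pm = tm.power(m)
    col_mass = np.asarray(np.abs(pm).max(axis=0).todense()).ravel()
    power_states = set(np.nonzero(col_mass > tol)[0].tolist())
    scc_states = {
        int(x) for c in terminal for x in np.nonzero(labels == c)[0]
    }
    if power_states != scc_states:
        raise RuntimeError(
            "matrix-power attractor states disagree with terminal SCCs"
        )
    term_members = [np.nonzero(labels == c)[0] for c in terminal]
    pm_csr = pm.tocsr()
    for x in range(pm.shape[0]):
        row = pm_csr.getrow(x).toarray().ravel()
        reached = frozenset(
            i for i, members in enumerate(term_members)
            if row[members].sum() > tol
        )
        if reached != basins[str(NetworkState.from_int(x, n))]:
            raise RuntimeError(
                "matrix-power basin labeling disagrees with SCC reachability"
            )


def synchronous_attractors(
    net: BooleanNetwork, *, cap: int | None = None
) -> list[Attractor]:
    """All synchronous attractors, by exhaustive sweep over 2^N states."""
    n = net.n
    _check_cap(n, cap if cap is not None else DEFAULT_SYNC_CAP)
    comp = net.compiled()
    assignment: dict[int, int] = {}
    attractors: list[Attractor] = []
    for start in range(1 << n):
        if start in assignment:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        x = start
        while x not in assignment and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = _step_int(comp, x, n)
        if x in assignment:
            aid = assignment[x]
        else:
            cycle = path[pos[x]:]
            aid = len(attractors)
            kind = "steady_state" if len(cycle) == 1 else "limit_cycle"
            attractors.append(Attractor(
                kind, tuple(NetworkState.from_int(v, n) for v in cycle),
                SYNCHRONOUS,
            ))
        for v in path:
            assignment[v] = aid
    return attractors


def export_edge_list(g: nx.DiGraph, path: str) -> None:
    nx.write_edgelist(g, path, data=False)


def export_graphml(g: nx.DiGraph, path: str) -> None:
    nx.write_graphml(g, path)


def export_matrix_market(tm: TransitionMatrix, path: str) -> None:
    from scipy.io import mmwrite

    mmwrite(path, tm.matrix)
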