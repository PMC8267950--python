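"""Minimal-event copy-number phylogenies over FISH signal patterns.

A sample's distinct gene-probe count vectors are connected into a
rooted tree starting from the diploid state (2,2,...,2).  Each edge is
either a single-probe copy-number step (one coordinate changes by one)
or a whole-genome duplication (WGD: every coordinate doubles), each
costing one event.  Unobserved intermediate patterns required to link
observed ones are inserted as *transit* nodes.  The builder is a
deterministic greedy heuristic that attaches the closest unattached
pattern to the growing tree, routing new paths through shared branch
points (coordinate-wise medians) when that shortens later attachments.

A fully lost locus (count 0) is absorbing by default: no edge may raise
a coordinate from 0, and WGD keeps it at 0.

For small instances an exact oracle (:func:`steiner_oracle`) computes
the true minimum total event count by shortest-path search over the
copy-number lattice, enumerating the possible branch-point topologies
of a Steiner arborescence with up to three terminals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import NucleusRecord, SignalPattern, aggregate_patterns
from .panel import ProbePanel

_INF = float("inf")
_MAX_WGD = 2  # WGD rounds considered per edge-path in the heuristic


# ---------------------------------------------------------------------------
# tree data model
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    pattern: tuple[int, ...]
    observed: bool
    multiplicity: int = 0  # 0 for transit nodes

    @property
    def label(self) -> str:
        return "-".join(str(c) for c in self.pattern)


@dataclass
class TreeEdge:
    parent: int
    child: int
    event: tuple  # ("step", coordinate, +1 | -1) or ("wgd",)


@dataclass
class FishTree:
    nodes: list[TreeNode]
    edges: list[TreeEdge]
    root: int = 0
    gene_names: list[str] = field(default_factory=list)

    @property
    def total_events(self) -> int:
        return len(self.edges)

    @property
    def tree_depth(self) -> int:
        children: dict[int, list[int]] = {}
        for e in self.edges:
            children.setdefault(e.parent, []).append(e.child)
        depth = 0
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            depth = max(depth, d)
            for c in children.get(node, []):
                stack.append((c, d + 1))
        return depth

    @property
    def observed_patterns(self) -> set[tuple[int, ...]]:
        return {n.pattern for n in self.nodes if n.observed}

    def parent_of(self, index: int) -> int | None:
        for e in self.edges:
            if e.child == index:
                return e.parent
        return None

    def write_dot(self, path: str | Path) -> None:
        """DOT export: solid outline = observed pattern, dashed = transit."""
        lines = ["digraph fishtree {"]
        for i, node in enumerate(self.nodes):
            style = "solid" if node.observed else "dashed"
            label = node.label
            if node.observed and node.multiplicity:
                label += f"\\nx{node.multiplicity}"
            lines.append(f'  n{i} [label="{label}", style={style}];')
        for e in self.edges:
            tag = "WGD" if e.event[0] == "wgd" else ""
            attr = f' [label="{tag}"]' if tag else ""
            lines.append(f"  n{e.parent} -> n{e.child}{attr};")
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for i, node in enumerate(self.nodes):
            g.add_node(
                i,
                pattern=node.label,
                observed=node.observed,
                multiplicity=node.multiplicity,
            )
        for e in self.edges:
            g.add_edge(e.parent, e.child, event=e.event[0])
        nx.write_graphml(g, str(path))


def tree_metrics(tree: FishTree) -> tuple[int, int]:
    """(tree_depth, total_events) of a built tree."""
    return tree.tree_depth, tree.total_events


# ---------------------------------------------------------------------------
# pairwise event distance (unit steps + up to _MAX_WGD doublings)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _coord_plans(a: int, b: int, k: int, absorbing: bool):
    """Minimal per-coordinate step cost from a to b with k interleaved
    WGD rounds, and the coordinate values held when each WGD fires.

    Returns (cost, waypoints) where waypoints has length k.  Unit steps
    within one coordinate commute with everything else, so the total
    path cost separates coordinate-wise for a fixed WGD count.
    """
    if k == 0:
        if absorbing and a == 0 and b > 0:
            return _INF, ()
        return abs(a - b), ()
    hi = max(a, b) + 1
    best, best_way = _INF, ()
    if k == 1:
        for c in range(hi + 1):
            if absorbing and a == 0 and c > 0:
                continue
            if absorbing and c == 0 and b > 0:
                continue
            cost = abs(a - c) + abs(2 * c - b)
            if cost < best:
                best, best_way = cost, (c,)
        return best, best_way
    if k == 2:
        for c in range(hi + 1):
            if absorbing and a == 0 and c > 0:
                continue
            for d in range(2 * hi + 1):
                if absorbing and c == 0 and d > 0:
                    continue
                if absorbing and d == 0 and b > 0:
                    continue
                cost = abs(a - c) + abs(2 * c - d) + abs(2 * d - b)
                if cost < best:
                    best, best_way = cost, (c, d)
        return best, best_way
    raise ValueError("at most 2 WGD rounds supported per path")


@lru_cache(maxsize=262144)
def event_distance(
    a: tuple[int, ...],
    b: tuple[int, ...],
    allow_wgd: bool = True,
    absorbing_zero: bool = True,
) -> tuple[float, int, tuple[tuple[int, ...], ...]]:
    """Minimal number of events to evolve pattern ``a`` into ``b``.

    Returns ``(cost, n_wgd, waypoints)`` where ``waypoints`` are the
    full patterns at which each WGD fires (the path runs
    a --steps--> w1 --WGD--> 2*w1 --steps--> w2 --WGD--> ... --steps--> b).
    """
    max_k = _MAX_WGD if allow_wgd else 0
    best = (_INF, 0, ())
    for k in range(max_k + 1):
        total = k
        ways = []
        feasible = True
        for ai, bi in zip(a, b):
            cost, way = _coord_plans(ai, bi, k, absorbing_zero)
            if cost == _INF:
                feasible = False
                break
            total += cost
            ways.append(way)
        if feasible and total < best[0]:
            waypoints = tuple(
                tuple(w[j] for w in ways) for j in range(k)
            )
            best = (total, k, waypoints)
    return best


def _unit_path(a: tuple[int, ...], b: tuple[int, ...]):
    """Intermediate patterns stepping a -> b one coordinate unit at a
    time, coordinates adjusted fully in panel order."""
    cur = list(a)
    out = []
    for i in range(len(a)):
        step = 1 if b[i] > cur[i] else -1
        while cur[i] != b[i]:
            cur[i] += step
            out.append((tuple(cur), ("step", i, step)))
    return out


# ---------------------------------------------------------------------------
# greedy tree construction
# ---------------------------------------------------------------------------

def build_tree(
    patterns: list[SignalPattern],
    allow_wgd: bool = True,
    absorbing_zero: bool = True,
    gene_names: list[str] | None = None,
) -> FishTree:
    """Heuristic minimal-event tree over observed gene-probe patterns.

    Greedy nearest-attachment: repeatedly pick the unattached observed
    pattern with the smallest event distance to any node already in the
    tree (ties: earlier-inserted anchor, then lexicographically smaller
    pattern) and realise the connecting path with transit nodes.  Pure
    step paths are routed through the coordinate-wise median of
    (anchor, target, nearest remaining pattern), a free detour that
    creates shared branch points.
    """
    if not patterns:
        raise ValueError("build_tree: no patterns")
    dim = len(patterns[0].counts)
    if any(len(p.counts) != dim for p in patterns):
        raise ValueError("patterns must share one dimensionality")
    vecs = [tuple(p.counts) for p in patterns]
    if len(set(vecs)) != len(vecs):
        raise ValueError("patterns must be distinct")
    mult = {tuple(p.counts): p.multiplicity for p in patterns}

    non_root = sorted(v for v in vecs if v != (2,) * dim)
    best_tree = _grow_tree(mult, dim, allow_wgd, absorbing_zero, gene_names)
    if 1 < len(non_root) <= _EXHAUSTIVE_ORDER_LIMIT:
        # small instances: the attachment order matters (a pattern may sit
        # on another's WGD pre-path); enumerate orders and keep the best
        for order in itertools.permutations(non_root):
            tree = _grow_tree(
                mult, dim, allow_wgd, absorbing_zero, gene_names, list(order)
            )
            if tree.total_events < best_tree.total_events:
                best_tree = tree
    return best_tree


_EXHAUSTIVE_ORDER_LIMIT = 5


def _grow_tree(
    mult: dict[tuple[int, ...], int],
    dim: int,
    allow_wgd: bool,
    absorbing_zero: bool,
    gene_names: list[str] | None,
    order: list[tuple[int, ...]] | None = None,
) -> FishTree:
    root = (2,) * dim
    nodes = [TreeNode(root, root in mult, mult.get(root, 0))]
    node_index: dict[tuple[int, ...], int] = {root: 0}
    edges: list[TreeEdge] = []
    unattached = sorted(v for v in mult if v != root)
    queue = list(order) if order is not None else None

    def add_node(pattern: tuple[int, ...], parent: int, event: tuple) -> int:
        if pattern in node_index:
            # defensive: path crosses an existing node; continue from it
            return node_index[pattern]
        nodes.append(TreeNode(pattern, False, 0))
        idx = len(nodes) - 1
        node_index[pattern] = idx
        edges.append(TreeEdge(parent, idx, event))
        return idx

    # per-pattern best attachment so far; adding nodes only improves it,
    # so each (pattern, node) pair is examined once across the build
    best_for: dict[tuple[int, ...], tuple] = {}
    scanned_up_to = 0

    while unattached:
        for pat in unattached:
            current_best = best_for.get(pat)
            for anchor_idx in range(
                0 if current_best is None else scanned_up_to, len(nodes)
            ):
                cost, k, ways = event_distance(
                    nodes[anchor_idx].pattern, pat, allow_wgd, absorbing_zero
                )
                key = (cost, anchor_idx, pat)
                if current_best is None or key < current_best[0]:
                    current_best = (key, anchor_idx, pat, k, ways)
            best_for[pat] = current_best
        scanned_up_to = len(nodes)
        if queue is not None:
            best = best_for[queue.pop(0)]
        else:
            best = min(best_for.values(), key=lambda item: item[0])
        (cost, _, _), anchor_idx, pat, k, ways = best
        del best_for[pat]
        if cost == _INF:
            raise ValueError(
                f"pattern {'-'.join(map(str, pat))} is unroutable "
                "(cannot raise a fully lost locus)"
            )
        unattached.remove(pat)

        # free median detour for pure-step paths: branch through the
        # coordinate-wise median with the nearest remaining pattern
        via = None
        if k == 0 and unattached:
            anchor_pat = nodes[anchor_idx].pattern
            candidates = []
            for other in unattached:
                med = tuple(
                    sorted((ai, bi, oi))[1]
                    for ai, bi, oi in zip(anchor_pat, pat, other)
                )
                if med == anchor_pat or med == pat:
                    continue
                d_future, _, _ = event_distance(
                    med, other, allow_wgd, absorbing_zero
                )
                candidates.append((d_future, other, med))
            if candidates:
                candidates.sort()
                via = candidates[0][2]

        current = anchor_idx
        waypoints = list(ways) + [pat]
        for seg_i, target in enumerate(waypoints):
            is_last_segment = seg_i == len(waypoints) - 1
            stops = [target]
            if via is not None and seg_i == 0 and k == 0:
                stops = [via, target]
            for stop in stops:
                for inter, event in _unit_path(nodes[current].pattern, stop):
                    current = add_node(inter, current, event)
            if not is_last_segment:
                doubled = tuple(2 * c for c in nodes[current].pattern)
                current = add_node(doubled, current, ("wgd",))
        # mark the attached pattern observed
        nodes[node_index[pat]].observed = True
        nodes[node_index[pat]].multiplicity = mult[pat]

    return FishTree(nodes, edges, 0, gene_names or [])


def build_tree_from_records(
    records: list[NucleusRecord],
    panel: ProbePanel,
    allow_wgd: bool = True,
    absorbing_zero: bool = True,
) -> FishTree:
    """Aggregate nuclei to gene-probe patterns and build the tree."""
    idx = panel.gene_indices
    reduced: dict[tuple[int, ...], int] = {}
    for p in aggregate_patterns(records):
        key = tuple(p.counts[i] for i in idx)
        reduced[key] = reduced.get(key, 0) + p.multiplicity
    patterns = [
        SignalPattern(v, m)
        for v, m in sorted(reduced.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return build_tree(patterns, allow_wgd, absorbing_zero, panel.gene_names)


# ---------------------------------------------------------------------------
# exact oracle for small instances
# ---------------------------------------------------------------------------

def _lattice_graph(dim: int, cap: int, allow_wgd: bool, absorbing_zero: bool):
    """Directed unit-step (+WGD) move graph over {0..cap}^dim as CSR."""
    n = (cap + 1) ** dim
    strides = [(cap + 1) ** (dim - 1 - i) for i in range(dim)]
    idx = np.arange(n)
    digits = [(idx // strides[i]) % (cap + 1) for i in range(dim)]
    rows, cols = [], []
    for i in range(dim):
        d = digits[i]
        gain_ok = d < cap
        if absorbing_zero:
            gain_ok &= d >= 1
        src = idx[gain_ok]
        rows.append(src)
        cols.append(src + strides[i])
        loss_ok = d >= 1
        src = idx[loss_ok]
        rows.append(src)
        cols.append(src - strides[i])
    if allow_wgd:
        ok = np.ones(n, dtype=bool)
        dbl = np.zeros(n, dtype=np.int64)
        for i in range(dim):
            ok &= 2 * digits[i] <= cap
            dbl += 2 * digits[i] * strides[i]
        ok &= dbl != idx  # exclude the all-zero self loop
        rows.append(idx[ok])
        cols.append(dbl[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=np.float64)
    return csr_matrix((data, (rows, cols)), shape=(n, n)), strides


def steiner_oracle(
    patterns: list[tuple[int, ...]],
    allow_wgd: bool = True,
    max_dim: int = 4,
    max_copy: int = 6,
    absorbing_zero: bool = True,
) -> int:
    """Exact minimum total event count for up to three observed patterns.

    Solves the minimum Steiner arborescence rooted at the diploid state
    on the copy-number lattice by enumerating the branch-point
    topologies possible with <= 3 terminals; each branch point is
    located by shortest-path search (Dijkstra at unit edge weights).
    Intermediate patterns may overshoot the observed range up to twice
    the largest observed count, so WGD-then-loss routes are covered.
    """
    if not patterns:
        raise ValueError("steiner_oracle: no patterns")
    dim = len(patterns[0].counts) if hasattr(patterns[0], "counts") else len(
        patterns[0]
    )
    terms = [tuple(getattr(p, "counts", p)) for p in patterns]
    if len(set(terms)) != len(terms):
        raise ValueError("patterns must be distinct")
    if len(terms) > 3:
        raise ValueError("oracle supports at most 3 patterns")
    if dim > max_dim or max_dim > 4:
        raise ValueError(f"oracle supports at most {min(max_dim, 4)} probes")
    top = max(max(t) for t in terms)
    if top > max_copy or max_copy > 6:
        raise ValueError(f"oracle supports counts up to {min(max_copy, 6)}")

    cap = 2 * max(2, top) if allow_wgd else max(2, top)
    graph, strides = _lattice_graph(dim, cap, allow_wgd, absorbing_zero)
    graph_t = graph.T.tocsr()
    n = graph.shape[0]

    def index(vec: tuple[int, ...]) -> int:
        return int(sum(v * s for v, s in zip(vec, strides)))

    root = index((2,) * dim)
    terminals = [index(t) for t in terms if t != (2,) * dim]
    if not terminals:
        return 0

    d_root = dijkstra(graph, indices=root)
    d_to = {t: dijkstra(graph_t, indices=t) for t in terminals}

    if len(terminals) == 1:
        val = d_root[terminals[0]]
    elif len(terminals) == 2:
        t1, t2 = terminals
        val = np.min(d_root + d_to[t1] + d_to[t2])
    else:
        val = _INF
        for ta_i in range(3):
            ta = terminals[ta_i]
            tb, tc = [t for j, t in enumerate(terminals) if j != ta_i]
            g = d_to[tb] + d_to[tc]
            # W[m1] = min_m2 d(m1->m2) + g(m2): single Dijkstra on the
            # reverse graph from a virtual source with entry costs g
            finite = np.isfinite(g)
            m2 = np.nonzero(finite)[0]
            aug_rows = np.concatenate([graph_t.tocoo().row, np.full(len(m2), n)])
            aug_cols = np.concatenate([graph_t.tocoo().col, m2])
            aug_data = np.concatenate([graph_t.tocoo().data, g[m2]])
            aug = csr_matrix((aug_data, (aug_rows, aug_cols)), shape=(n + 1, n + 1))
            w = dijkstra(aug, indices=n)[:n]
            val = min(val, float(np.min(d_root + d_to[ta] + w)))
    if not np.isfinite(val):
        raise ValueError("instance is unroutable under the absorbing-zero rule")
    return int(round(float(val)))
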