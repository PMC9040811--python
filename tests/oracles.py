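"""Independent oracles used by the test suite and the acceptance script.

Each oracle recomputes a quantity by a route independent of the implementation
it checks: exhaustive enumeration for alignments and tree topologies, a naive
nested scan for motifs, and a random additive-matrix generator with known
splits for neighbor joining.
"""

from __future__ import annotations

import collections
import functools

import numpy as np


def brute_force_alignment_score(
    seq_a: str, seq_b: str, subscore, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine-gap score by exhaustive recursion over all
    alignments (memoized on position + gap-run state). Exponential paths,
    polynomial states — fine for len <= 8."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        best = -np.inf
        if i < len(seq_a) and j < len(seq_b):
            best = max(best, subscore(seq_a[i], seq_b[j]) + rec(i + 1, j + 1, 0))
        if j < len(seq_b):  # gap in A
            cost = gap_extend if state == 1 else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, 1))
        if i < len(seq_a):  # gap in B
            cost = gap_extend if state == 2 else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


# --- Unrooted topology enumeration + least-squares edge fit -------------------


def enumerate_unrooted_topologies(leaves: list[str]):
    """Yield every unrooted binary topology as an adjacency dict
    {node: set(neighbors)}; internal nodes are integers, leaves are labels."""
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")

    def edges_of(adj):
        seen = set()
        for a in adj:
            for b in adj[a]:
                key = tuple(sorted((str(a), str(b))))
                if key not in seen:
                    seen.add(key)
                    yield a, b

    first = {0: set(leaves[:3])}
    for leaf in leaves[:3]:
        first[leaf] = {0}
    trees = [first]
    next_internal = 1
    for leaf in leaves[3:]:
        new_trees = []
        for adj in trees:
            for a, b in list(edges_of(adj)):
                new = {k: set(v) for k, v in adj.items()}
                node = next_internal
                new[a].discard(b)
                new[b].discard(a)
                new[a].add(node)
                new[b].add(node)
                new[node] = {a, b, leaf}
                new[leaf] = {node}
                new_trees.append(new)
        trees = new_trees
        next_internal += 1
    return trees


def _topology_paths(adj, leaves):
    """For each leaf pair, the set of edges on the connecting path."""
    edge_index = {}
    for a in adj:
        for b in adj[a]:
            key = frozenset((a, b))
            if key not in edge_index:
                edge_index[key] = len(edge_index)
    paths = {}
    for src in leaves:
        prev = {src: None}
        dq = collections.deque([src])
        while dq:
            x = dq.popleft()
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    dq.append(y)
        for dst in leaves:
            if dst == src or (dst, src) in paths:
                continue
            path = []
            node = dst
            while prev[node] is not None:
                path.append(edge_index[frozenset((node, prev[node]))])
                node = prev[node]
            paths[(src, dst)] = path
    return paths, edge_index


def topology_splits(adj, leaves):
    """Canonical internal bipartitions of a topology (side without min leaf)."""
    ref = min(leaves)
    out = set()
    for a in adj:
        for b in adj[a]:
            if not isinstance(a, int) or not isinstance(b, int):
                continue
            if str(a) > str(b):
                continue
            seen = {a}
            dq = collections.deque([a])
            while dq:
                x = dq.popleft()
                for y in adj[x]:
                    if y == b and x == a:
                        continue
                    if y not in seen:
                        seen.add(y)
                        dq.append(y)
            side = frozenset(l for l in leaves if l in seen)
            canon = side if ref not in side else frozenset(leaves) - side
            if 2 <= len(canon) <= len(leaves) - 2:
                out.add(canon)
    return out


def least_squares_topology(matrix: np.ndarray, leaves: list[str]):
    """Best topology by exhaustive enumeration with ordinary least-squares
    edge-length fits; returns (splits, residual, fitted path distances)."""
    pairs = [
        (leaves[i], leaves[j])
        for i in range(len(leaves))
        for j in range(i + 1, len(leaves))
    ]
    d_vec = np.array(
        [matrix[leaves.index(a), leaves.index(b)] for a, b in pairs]
    )
    best = None
    for adj in enumerate_unrooted_topologies(leaves):
        paths, edge_index = _topology_paths(adj, leaves)
        A = np.zeros((len(pairs), len(edge_index)))
        for r, (a, b) in enumerate(pairs):
            path = paths.get((a, b)) or paths[(b, a)]
            for e in path:
                A[r, e] = 1.0
        x, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        resid = float(np.sum((A @ x - d_vec) ** 2))
        if best is None or resid < best[1]:
            best = (topology_splits(adj, leaves), resid, A @ x, pairs)
    return best


def random_additive_matrix(n: int, rng: np.random.Generator):
    """A random additive distance matrix from a random unrooted binary tree
    with strictly positive branch lengths; returns (matrix, leaves, splits)."""
    adj: dict = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    for leaf in ("L0", "L1", "L2"):
        add_edge("I0", leaf, float(rng.uniform(0.1, 1.0)))
    nxt, icount = 3, 1
    while nxt < n:
        all_edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = all_edges[rng.integers(0, len(all_edges))]
        w = adj[a][b]
        inew = f"I{icount}"
        icount += 1
        del adj[a][b]
        del adj[b][a]
        f = float(rng.uniform(0.2, 0.8))
        add_edge(a, inew, w * f)
        add_edge(inew, b, w * (1 - f))
        add_edge(inew, f"L{nxt}", float(rng.uniform(0.1, 1.0)))
        nxt += 1
    leaves = [f"L{i}" for i in range(n)]

    def dist(u, v):
        dq = collections.deque([(u, 0.0)])
        seen = {u}
        while dq:
            x, d = dq.popleft()
            if x == v:
                return d
            for y, w in adj[x].items():
                if y not in seen:
                    seen.add(y)
                    dq.append((y, d + w))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(leaves[i], leaves[j])

    ref = min(leaves)
    splits = set()
    for a in adj:
        for b in adj[a]:
            if not (str(a).startswith("I") and str(b).startswith("I")):
                continue
            if str(a) > str(b):
                continue
            seen = {a}
            dq = collections.deque([a])
            while dq:
                x = dq.popleft()
                for y in adj[x]:
                    if x == a and y == b:
                        continue
                    if y not in seen:
                        seen.add(y)
                        dq.append(y)
            side = frozenset(l for l in leaves if l in seen)
            canon = side if ref not in side else frozenset(leaves) - side
            if 2 <= len(canon) <= n - 2:
                splits.add(canon)
    return D, leaves, splits


def tree_path_lengths(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a qsmine PhyloTree, by traversal."""
    adj: dict = {}
    names: dict = {}

    def walk(node):
        if not node.children:
            names[id(node)] = node.name
        for child, blen in node.children:
            adj.setdefault(id(node), []).append((id(child), blen))
            adj.setdefault(id(child), []).append((id(node), blen))
            walk(child)

    walk(tree.root)
    out: dict[tuple[str, str], float] = {}
    for src in list(names):
        dq = collections.deque([(src, 0.0)])
        seen = {src}
        while dq:
            x, d = dq.popleft()
            if x in names and x != src:
                out[(names[src], names[x])] = d
            for y, w in adj.get(x, []):
                if y not in seen:
                    seen.add(y)
                    dq.append((y, d + w))
    return out


# --- Naive motif scanning -----------------------------------------------------


def naive_block_match(seq: str, pattern: str, start0: int, max_mm: int) -> bool:
    if start0 < 0 or start0 + len(pattern) > len(seq):
        return False
    mm = 0
    for k, pc in enumerate(pattern):
        if pc == "X":
            continue
        if seq[start0 + k] != pc or seq[start0 + k] == "X":
            mm += 1
    return mm <= max_mm


def naive_spaced_motif_hits(seq: str, blocks, spacers, max_mm) -> list[tuple[int, ...]]:
    """All complete chains by brute-force nested position loops, then the same
    greedy left-to-right non-overlap selection, returned as 1-based starts."""
    chains = [
        (s,)
        for s in range(len(seq))
        if naive_block_match(seq, blocks[0], s, max_mm[0])
    ]
    for k in range(1, len(blocks)):
        lo, hi = spacers[k - 1]
        new_chains = []
        for chain in chains:
            prev_end = chain[-1] + len(blocks[k - 1])
            for s in range(prev_end + lo, prev_end + hi + 1):
                if naive_block_match(seq, blocks[k], s, max_mm[k]):
                    new_chains.append(chain + (s,))
        chains = new_chains
    selected = []
    occupied = -1
    for chain in sorted(chains):
        if chain[0] > occupied:
            selected.append(tuple(s + 1 for s in chain))
            occupied = chain[-1] + len(blocks[-1]) - 1
    return selected
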