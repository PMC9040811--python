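"""Distance-based phylogenetics for QS protein families.

Progressive multiple alignment (k-mer guide tree + profile-profile
affine-gap alignment), pairwise-deletion p-distances, Poisson multiple-hit
correction d = -ln(1 - p), canonical neighbor-joining with deterministic tie
breaking, and column-resampling bootstrap with explicit replicate-failure
semantics: a replicate fails, and is excluded from the support denominator,
when any pairwise distance is undefined in the resample (no shared ungapped
sites, or all shared sites differ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from ._gotoh import gotoh_align
from .conservation import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    GAP,
    SCORING_ALPHABET,
    default_substitution_matrix,
    encode_sequence,
)

_GAP_CODE = SCORING_ALPHABET.index(GAP)


class UndefinedDistanceError(ValueError):
    """A pairwise distance is undefined (no shared sites, or p >= 1)."""


@dataclass
class Msa:
    """A multiple sequence alignment: ordered ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def encoded(self) -> np.ndarray:
        return np.stack([encode_sequence(r) for r in self.rows])

    def subset_columns(self, cols: Sequence[int]) -> "Msa":
        return Msa(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])

    def drop(self, seq_ids: Iterable[str]) -> "Msa":
        dropped = set(seq_ids)
        keep = [(i, r) for i, r in zip(self.ids, self.rows) if i not in dropped]
        return Msa([i for i, _ in keep], [r for _, r in keep])


# --- Progressive MSA ---------------------------------------------------------


def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    kmin = min(len(s) for s in seqs)
    k = max(1, min(k, kmin))
    sets = [frozenset(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return d


def _profile_freq(rows: list[str]) -> np.ndarray:
    codes = np.stack([encode_sequence(r) for r in rows])
    ncols = codes.shape[1]
    freq = np.zeros((ncols, len(SCORING_ALPHABET)))
    for c in range(ncols):
        counts = np.bincount(codes[:, c], minlength=len(SCORING_ALPHABET))
        freq[c] = counts / codes.shape[0]
    return freq


def _merge_profiles(
    rows_a: list[str],
    rows_b: list[str],
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    fa = _profile_freq(rows_a)
    fb = _profile_freq(rows_b)
    score = fa @ matrix @ fb.T
    path, _ = gotoh_align(score, gap_open, gap_extend)
    out_a = []
    out_b = []
    for i, j in path:
        out_a.append(
            tuple(r[i] for r in rows_a) if i is not None else (GAP,) * len(rows_a)
        )
        out_b.append(
            tuple(r[j] for r in rows_b) if j is not None else (GAP,) * len(rows_b)
        )
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def progressive_msa(
    sequences: Mapping[str, str] | list[tuple[str, str]],
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    guide_k: int = 3,
) -> Msa:
    """Progressive multiple alignment.

    The guide tree is UPGMA on k-mer set distances; clusters are merged by
    optimal profile-profile affine-gap alignment (column score: frequency-
    weighted average substitution score, gaps contributing zero). Deterministic
    for a fixed input order.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    ids = [i for i, _ in items]
    seqs = [s for _, s in items]
    if any(not s for s in seqs):
        raise ValueError("empty sequence")
    mat = matrix if matrix is not None else default_substitution_matrix()

    d = _kmer_distance_matrix(seqs, guide_k)
    n = len(seqs)
    condensed = d[np.triu_indices(n, k=1)]
    merge_order = linkage(condensed, method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (a, b, _dist, _cnt) in enumerate(merge_order):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _merge_profiles(rows_a, rows_b, mat, gap_open, gap_extend)
        clusters[n + step] = (idx_a + idx_b, new_a + new_b)

    (_, (order, rows)) = clusters.popitem()
    by_input = sorted(zip(order, rows))
    aligned = [row for _, row in by_input]
    return Msa(ids, aligned)


# --- Distances ---------------------------------------------------------------


def p_distance(row_a: str, row_b: str) -> tuple[float | None, int]:
    """Pairwise-deletion proportion of differing sites.

    Columns gapped in either row are excluded. Returns ``(p, shared_sites)``;
    ``p`` is None when no ungapped column is shared by the pair.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    shared = 0
    diff = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        shared += 1
        if a != b:
            diff += 1
    if shared == 0:
        return None, 0
    return diff / shared, shared


def poisson_correct(p: float | None) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), defined for 0 <= p < 1."""
    if p is None:
        raise UndefinedDistanceError("p undefined (no shared sites)")
    if not (0.0 <= p < 1.0):
        raise UndefinedDistanceError(f"p = {p} outside [0, 1)")
    return -math.log1p(-p)


@dataclass(frozen=True)
class DistanceFailure:
    id_a: str
    id_b: str
    reason: str  # "no_common_sites" or "saturated"


@dataclass
class DistanceMatrixResult:
    ids: list[str]
    d: np.ndarray  # Poisson-corrected distances; NaN where undefined
    p: np.ndarray
    shared: np.ndarray
    failures: list[DistanceFailure]

    @property
    def has_failures(self) -> bool:
        return bool(self.failures)

    def failed_sequence_ids(self) -> list[str]:
        """Greedy minimal-ish removal set: repeatedly drop the sequence
        involved in the most undefined pairs (ties broken lexicographically)
        until no undefined pair remains — mirrors removing offending
        sequences before tree building."""
        pairs = {(f.id_a, f.id_b) for f in self.failures}
        dropped: list[str] = []
        while pairs:
            counts: dict[str, int] = {}
            for a, b in pairs:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            victim = max(sorted(counts), key=lambda s: counts[s])
            dropped.append(victim)
            pairs = {(a, b) for a, b in pairs if victim not in (a, b)}
        return dropped


def _pairwise_distance_arrays(
    codes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised p/shared/d over encoded MSA rows; NaN marks undefined."""
    n = codes.shape[0]
    p = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    d = np.zeros((n, n))
    nongap = codes != _GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            mask = nongap[i] & nongap[j]
            s = int(mask.sum())
            shared[i, j] = shared[j, i] = s
            if s == 0:
                p[i, j] = p[j, i] = np.nan
                d[i, j] = d[j, i] = np.nan
                continue
            pij = float((codes[i, mask] != codes[j, mask]).mean())
            p[i, j] = p[j, i] = pij
            d[i, j] = d[j, i] = -math.log1p(-pij) if pij < 1.0 else np.nan
    return p, shared, d


def build_distance_matrix(msa: Msa) -> DistanceMatrixResult:
    """Poisson-corrected pairwise-deletion distance matrix with failure records.

    Undefined pairs (no common ungapped sites, or p = 1 so the correction
    diverges) are NaN in the matrix and listed in ``failures``; the caller
    decides whether to drop the offending sequences or abort.
    """
    if msa.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    codes = msa.encoded()
    p, shared, d = _pairwise_distance_arrays(codes)
    failures = []
    for i in range(msa.n_sequences):
        for j in range(i + 1, msa.n_sequences):
            if shared[i, j] == 0:
                failures.append(
                    DistanceFailure(msa.ids[i], msa.ids[j], "no_common_sites")
                )
            elif np.isnan(d[i, j]):
                failures.append(DistanceFailure(msa.ids[i], msa.ids[j], "saturated"))
    return DistanceMatrixResult(list(msa.ids), d, p, shared, failures)


# --- Neighbor joining --------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (stored with an arbitrary trifurcating root).

    Bootstrap supports, when attached, are percentages in [0, 100] keyed by
    canonical internal bipartitions (the side not containing the
    lexicographically first leaf).
    """

    root: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def _edges(self) -> list[tuple[frozenset, float]]:
        edges: list[tuple[frozenset, float]] = []

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for child, blen in node.children:
                sub = walk(child)
                edges.append((sub, blen))
                below |= sub
            return below

        walk(self.root)
        return edges

    def canonical(self, leaf_set: frozenset) -> frozenset:
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        return leaf_set if ref not in leaf_set else all_leaves - leaf_set

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        n = len(self.leaf_names)
        out = set()
        for side, _ in self._edges():
            size = len(side)
            if include_trivial or 2 <= size <= n - 2:
                out.add(self.canonical(side))
        return out

    def newick(self, decimals: int = 6) -> str:
        supports = self.supports or {}
        all_leaves = frozenset(self.leaf_names)

        def fmt(node: TreeNode) -> tuple[str, frozenset]:
            if not node.children:
                return node.name, frozenset([node.name])
            parts = []
            below = frozenset()
            for child, blen in node.children:
                text, sub = fmt(child)
                parts.append(f"{text}:{blen:.{decimals}f}")
                below |= sub
            label = ""
            canon = below if min(all_leaves) not in below else all_leaves - below
            if 2 <= len(canon) <= len(all_leaves) - 2 and canon in supports:
                label = str(int(round(supports[canon])))
            return f"({','.join(parts)}){label}", below

        text, _ = fmt(self.root)
        return text + ";"


def nj_tree(matrix: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei Q criterion).

    Deterministic: Q ties are broken by the lexicographically smallest sorted
    pair of cluster labels (a cluster is labelled by its smallest leaf).
    Negative branch lengths are clamped to zero with the deficit shifted to the
    sibling branch so the pair's total is preserved.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("matrix/ids size mismatch")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("matrix contains undefined distances")
    if not np.array_equal(D, D.T):
        raise ValueError("matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    labels: list[str] = [str(i) for i in ids]
    active = list(range(n))
    dist = D.copy()

    while len(active) > 3:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        # Select the minimum over the upper triangle only: q[i,j] and q[j,i]
        # may differ by one ulp (summation order), so a global min compared by
        # equality is not reliable. Ties break on the sorted label pair.
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                key = (
                    q[ai, bi],
                    tuple(sorted((labels[active[ai]], labels[active[bi]]))),
                )
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        _, ai, bi = best
        i_idx, j_idx = active[ai], active[bi]
        dij = sub[ai, bi]
        bi_len = 0.5 * dij + (row_sums[ai] - row_sums[bi]) / (2 * (r - 2))
        bj_len = dij - bi_len
        if bi_len < 0:
            bj_len += bi_len
            bi_len = 0.0
        if bj_len < 0:
            bi_len += bj_len
            bj_len = 0.0
        bi_len = max(bi_len, 0.0)
        bj_len = max(bj_len, 0.0)

        parent = TreeNode(
            children=[(nodes[i_idx], bi_len), (nodes[j_idx], bj_len)]
        )
        new_idx = dist.shape[0]
        new_row = 0.5 * (dist[i_idx] + dist[j_idx] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[new_idx, : new_idx] = new_row
        dist[: new_idx, new_idx] = new_row
        nodes.append(parent)
        labels.append(min(labels[i_idx], labels[j_idx]))
        active = [k for k in active if k not in (i_idx, j_idx)] + [new_idx]

    a, b, c = active
    # Three-cluster closed form: b_x = (d_xy + d_xz - d_yz) / 2.
    ba = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    bb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    bc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    root = TreeNode(
        children=[
            (nodes[a], max(ba, 0.0)),
            (nodes[b], max(bb, 0.0)),
            (nodes[c], max(bc, 0.0)),
        ]
    )
    return PhyloTree(root=root)


def is_monophyletic(tree: PhyloTree, leaf_subset: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly this leaf subset."""
    subset = frozenset(leaf_subset)
    leaves = frozenset(tree.leaf_names)
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not subset:
        raise ValueError("empty leaf subset")
    if subset == leaves or len(subset) in (1, len(leaves) - 1):
        return True
    return tree.canonical(subset) in tree.bipartitions()


# --- Bootstrap ---------------------------------------------------------------


@dataclass
class BootstrapResult:
    tree: PhyloTree
    supports: dict[frozenset, float]
    failed_count: int
    successful: int
    replicates: int


def bootstrap_supports(
    msa: Msa, replicates: int, seed: int
) -> BootstrapResult:
    """Column-resampling bootstrap supports for the NJ tree of ``msa``.

    Replicate r draws columns with replacement from a deterministic substream
    of ``seed``. A replicate fails — counted in ``failed_count`` and excluded
    from the denominator — when any pairwise distance is undefined in the
    resample. Supports are the percentage of successful replicates whose NJ
    tree contains each internal bipartition of the reference tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ref = build_distance_matrix(msa)
    if ref.has_failures:
        raise UndefinedDistanceError(
            "reference matrix has undefined distances; drop failing sequences first"
        )
    tree = nj_tree(ref.d, ref.ids)
    ref_splits = tree.bipartitions()
    counts = {split: 0 for split in ref_splits}

    codes = msa.encoded()
    n, L = codes.shape
    nongap_template = codes != _GAP_CODE
    failed = 0
    successful = 0
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        cols = rng.integers(0, L, size=L)
        sub = codes[:, cols]
        nongap = nongap_template[:, cols]
        dmat = np.zeros((n, n))
        ok = True
        for i in range(n):
            if not ok:
                break
            for j in range(i + 1, n):
                mask = nongap[i] & nongap[j]
                s = int(mask.sum())
                if s == 0:
                    ok = False
                    break
                pij = float((sub[i, mask] != sub[j, mask]).mean())
                if pij >= 1.0:
                    ok = False
                    break
                dmat[i, j] = dmat[j, i] = -math.log1p(-pij)
        if not ok:
            failed += 1
            continue
        successful += 1
        rep_tree = nj_tree(dmat, msa.ids)
        rep_splits = rep_tree.bipartitions()
        for split in ref_splits:
            if split in rep_splits:
                counts[split] += 1

    if successful == 0:
        raise UndefinedDistanceError("all bootstrap replicates failed")
    supports = {s: 100.0 * c / successful for s, c in counts.items()}
    tree.supports = supports
    return BootstrapResult(
        tree=tree,
        supports=supports,
        failed_count=failed,
        successful=successful,
        replicates=replicates,
    )


# --- Writers -----------------------------------------------------------------


def write_fasta_msa(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n{row}\n")


def write_phylip(result: DistanceMatrixResult, path) -> None:
    """PHYLIP-style square matrix; undefined distances written as ``NA``."""
    with open(path, "w") as fh:
        fh.write(f"{len(result.ids)}\n")
        for i, seq_id in enumerate(result.ids):
            cells = [
                "NA" if np.isnan(v) else f"{v:.6f}" for v in result.d[i]
            ]
            fh.write(f"{seq_id}\t" + "\t".join(cells) + "\n")


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
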