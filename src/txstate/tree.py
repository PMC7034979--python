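"""Expression-state trees of cell types by balanced minimum evolution.

Cell types are encoded as character sequences over {A, C, N} (one position
per informative gene: expressed / not expressed / uncertain), compared by
Hamming distance over unambiguous positions (pairwise deletion), and related
by an unrooted tree minimizing total balanced tree length (Pauplin's
criterion: L = sum over leaf pairs of 2^(1 - t_ij) * D_ij with t_ij the
topological distance). Construction is greedy taxon insertion followed by
nearest-neighbor-interchange hill climbing; branch lengths come from balanced
averages of the distance matrix; branch support from bootstrap resampling of
gene positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHAR_ON = "A"
CHAR_OFF = "C"
CHAR_UNKNOWN = "N"


@dataclass
class StateSequenceSet:
    """Per-cell-type expression 'sequences' over the alphabet {A, C, N}."""

    sequences: dict[str, str]
    genes: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences must all have the same length")
        if lengths and lengths.pop() != len(self.genes):
            raise ValueError("sequence length must equal the number of genes")
        bad = {ch for s in self.sequences.values() for ch in s} - {CHAR_ON, CHAR_OFF, CHAR_UNKNOWN}
        if bad:
            raise ValueError(f"unexpected characters in sequences: {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences.values()])


def select_informative_genes(
    fits: pd.DataFrame,
    min_on_mean: float = 3.0,
    min_separation: float = 1.5,
) -> list[str]:
    """Bimodal genes with a well-expressed, well-separated on component.

    Keeps genes selected bimodal whose on-component mean is at least
    ``min_on_mean`` (natural-log TPM; 3 ~ 21 TPM) and whose on/off component
    separation is at least ``min_separation`` (1.5 ~ 4.5-fold). Boundaries
    are inclusive.
    """
    keep = (
        (fits["model"] == "bimodal")
        & (fits["mu_on"] >= min_on_mean)
        & ((fits["mu_on"] - fits["mu_off"]) >= min_separation)
    )
    return list(fits.index[keep])


def encode_state_sequences(
    cell_probs: pd.DataFrame,
    genes: list[str] | None = None,
    on_cut: float = 0.8,
    off_cut: float = 0.2,
) -> StateSequenceSet:
    """Encode each cell type as a sequence: A (P >= on_cut), C (P <= off_cut), N.

    Thresholds are unified with the on/off discretization (inclusive
    boundaries); NA probabilities encode as N. Cell types are ordered
    lexicographically for deterministic downstream tie-breaking.
    """
    if genes is None:
        genes = list(cell_probs.index)
    missing = [g for g in genes if g not in cell_probs.index]
    if missing:
        raise ValueError(f"genes absent from probability matrix: {missing[:5]}")
    sub = cell_probs.loc[genes]
    sequences: dict[str, str] = {}
    for cell in sorted(cell_probs.columns):
        p = sub[cell].to_numpy(dtype=float)
        chars = np.where(p >= on_cut, CHAR_ON, np.where(p <= off_cut, CHAR_OFF, CHAR_UNKNOWN))
        chars = np.where(np.isnan(p), CHAR_UNKNOWN, chars)
        sequences[cell] = "".join(chars)
    return StateSequenceSet(sequences=sequences, genes=list(genes))


def hamming_distance_matrix(
    seqs: StateSequenceSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise mismatch proportion over positions where both are unambiguous.

    Positions where either sequence is N are deleted pairwise. Pairs with no
    comparable site get a NaN distance (tree building refuses NaN with a hard
    error). Returns (distance matrix, comparable-site counts).
    """
    names = seqs.names
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    arr = seqs.to_array()
    known = arr != CHAR_UNKNOWN
    n = len(names)
    dist = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = known[i] & known[i + 1 :]
        mism = (arr[i] != arr[i + 1 :]) & both
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(counts > 0, mism.sum(axis=1) / np.maximum(counts, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        sites[i, i + 1 :] = counts
        sites[i + 1 :, i] = counts
        sites[i, i] = int(known[i].sum())
    bad = [
        (names[i], names[j])
        for i, j in zip(*np.where(np.isnan(np.triu(dist, 1))))
        if j > i
    ]
    if bad:
        logger.warning("pairs with no comparable sites: %s", bad)
    return (
        pd.DataFrame(dist, index=names, columns=names),
        pd.DataFrame(sites, index=names, columns=names),
    )


# --------------------------------------------------------------------------
# unrooted binary trees as adjacency maps; leaves are 0..n-1 in taxon order
# --------------------------------------------------------------------------


@dataclass
class ExpressionTree:
    """Unrooted binary tree over cell types with balanced branch lengths."""

    adjacency: dict[int, set[int]]
    leaf_names: list[str]
    branch_lengths: dict[frozenset, float] = field(default_factory=dict)
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped: list[tuple] = field(default_factory=list)
    n_boot: int = 0
    n_boot_skipped: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def balanced_length(self, distances: pd.DataFrame) -> float:
        d = distances.loc[self.leaf_names, self.leaf_names].to_numpy()
        return _pauplin_length(self.adjacency, self.n_leaves, d)

    def total_branch_length(self) -> float:
        return float(sum(self.branch_lengths.values()))

    def bipartitions(self) -> dict[frozenset, frozenset]:
        """Internal edges mapped to the leaf-name set not containing taxon 0."""
        out = {}
        n = self.n_leaves
        for edge in _edges(self.adjacency):
            u, v = tuple(edge)
            if u < n or v < n:
                continue
            side = _side_leaves(self.adjacency, u, v, n)
            if 0 in side:
                side = set(range(n)) - side
            out[edge] = frozenset(self.leaf_names[i] for i in side)
        return out

    def newick(self, include_support: bool = True) -> str:
        """Newick string rooted at the internal node next to the first leaf;
        bootstrap supports (when present) label internal nodes."""
        n = self.n_leaves
        if n == 1:
            return f"{self.leaf_names[0]};"
        root = next(iter(self.adjacency[0]))

        def fmt_len(edge) -> str:
            if edge in self.branch_lengths:
                return f":{self.branch_lengths[edge]:.10g}"
            return ""

        def rec(node: int, parent: int) -> str:
            if node < n:
                return f"{self.leaf_names[node]}{fmt_len(frozenset((node, parent)))}"
            kids = sorted(k for k in self.adjacency[node] if k != parent)
            inner = ",".join(rec(k, node) for k in kids)
            edge = frozenset((node, parent))
            label = ""
            if include_support and edge in self.supports:
                label = f"{self.supports[edge]:.4g}"
            return f"({inner}){label}{fmt_len(edge)}"

        kids = sorted(k for k in self.adjacency[root])
        inner = ",".join(rec(k, root) for k in kids)
        return f"({inner});"


def _edges(adj: dict[int, set[int]]) -> list[frozenset]:
    return sorted(
        {frozenset((u, v)) for u, nbrs in adj.items() for v in nbrs},
        key=lambda e: tuple(sorted(e)),
    )


def _side_leaves(adj: dict[int, set[int]], u: int, v: int, n_leaves: int) -> set[int]:
    """Leaves on the v side of edge (u, v)."""
    seen = {u, v}
    stack = [v]
    out = set()
    while stack:
        node = stack.pop()
        if node < n_leaves:
            out.add(node)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return out


def _node_leaf_dists(adj: dict[int, set[int]], leaves: list[int]) -> dict[int, dict[int, int]]:
    """Topological distance from every node to every leaf (BFS per leaf)."""
    out: dict[int, dict[int, int]] = {node: {} for node in adj}
    for leaf in leaves:
        dist = {leaf: 0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    stack.append(nb)
        for node, d in dist.items():
            out[node][leaf] = d
    return out


def _pauplin_length(adj: dict[int, set[int]], n_leaves: int, d: np.ndarray) -> float:
    """Balanced tree length: sum over leaf pairs of 2^(1 - t_ij) d_ij."""
    size = max(adj) + 1
    nbr = [list(adj[i]) if i in adj else [] for i in range(size)]
    dist = np.empty(size, dtype=np.int64)
    total = 0.0
    for i in range(n_leaves - 1):
        dist[:] = -1
        dist[i] = 0
        stack = [i]
        while stack:
            u = stack.pop()
            du = dist[u] + 1
            for v in nbr[u]:
                if dist[v] < 0:
                    dist[v] = du
                    stack.append(v)
        t = dist[i + 1 : n_leaves]
        total += float((2.0 ** (1.0 - t) * d[i, i + 1 : n_leaves]).sum())
    return total


def balanced_me_tree(
    distances: pd.DataFrame, n_starts: int | None = None, spr: bool = True
) -> ExpressionTree:
    """Build the balanced minimum evolution tree from a distance matrix.

    Greedy taxon insertion (each new taxon goes on the edge minimizing the
    balanced tree length, lowest-index edge on ties) followed by
    nearest-neighbor-interchange and, when ``spr`` is true, subtree
    prune-and-regraft hill climbing to a local optimum of the same criterion.
    Because a single start can stall in a local optimum on noisy matrices,
    the greedy phase is repeated from ``n_starts`` rotated insertion orders
    (default: one per taxon, capped at 8) and the shortest result kept;
    everything is deterministic given the input order.
    Branch lengths are balanced least-squares estimates; negative estimates
    are clamped to zero and flagged.
    """
    names = list(distances.index)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d_full = distances.to_numpy(dtype=float)
    if not np.isfinite(d_full).all():
        bad = [
            (names[i], names[j])
            for i, j in zip(*np.where(~np.isfinite(d_full)))
            if j > i
        ]
        raise ValueError(f"distance matrix has NA/non-finite entries: {bad}")
    if not np.allclose(d_full, d_full.T):
        raise ValueError("distance matrix must be symmetric")
    if n_starts is None:
        n_starts = min(n, 8)
    n_starts = max(1, min(n_starts, n))

    best_adj = None
    best_len = np.inf
    for k in range(n_starts):
        order = list(range(k, n)) + list(range(k))
        adj = _greedy_insertion(d_full, order)
        adj = _nni(adj, n, d_full)
        if spr:
            adj = _spr(adj, n, d_full)
        length = _pauplin_length(adj, n, d_full)
        if length < best_len - 1e-12:
            best_len = length
            best_adj = adj
    tree = ExpressionTree(adjacency=best_adj, leaf_names=names)
    _balanced_branch_lengths(tree, d_full)
    return tree


def _greedy_insertion(d_full: np.ndarray, order: list[int]) -> dict[int, set[int]]:
    """Insert taxa in ``order``, each on the edge minimizing balanced length."""
    n = len(order)
    # star over the first three taxa of the order; internal ids start at n
    adj: dict[int, set[int]] = {
        order[0]: {n},
        order[1]: {n},
        order[2]: {n},
        n: {order[0], order[1], order[2]},
    }
    next_internal = n + 1
    for step in range(3, n):
        x = order[step]
        leaves = order[:step]
        nd = _node_leaf_dists(adj, leaves)
        t = np.array([[nd[i].get(j, 0) for j in leaves] for i in leaves], dtype=float)
        d_sub = d_full[np.ix_(leaves, leaves)]
        m = np.where(np.eye(step, dtype=bool), 0.0, 2.0 ** (1.0 - t)) * d_sub
        total = m.sum() / 2.0
        best_len = np.inf
        best_edge = None
        for edge in _edges(adj):
            u, v = sorted(edge)
            tu = np.array([nd[u][j] for j in leaves], dtype=float)
            tv = np.array([nd[v][j] for j in leaves], dtype=float)
            side_v = tv < tu
            ct = m[np.ix_(~side_v, side_v)].sum()
            new_term = (2.0 ** (-1.0 - np.minimum(tu, tv)) * d_full[x, leaves]).sum()
            length = total - 0.5 * ct + new_term
            if length < best_len - 1e-12:
                best_len = length
                best_edge = (u, v)
        u, v = best_edge
        mid = next_internal
        next_internal += 1
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].add(mid)
        adj[v].add(mid)
        adj[mid] = {u, v, x}
        adj[x] = {mid}
    return adj


def _nni(adj: dict[int, set[int]], n_leaves: int, d: np.ndarray) -> dict[int, set[int]]:
    """Best-improvement NNI hill climbing on balanced tree length."""
    current = _pauplin_length(adj, n_leaves, d)
    while True:
        best_len = current
        best_adj = None
        for edge in _edges(adj):
            u, v = sorted(edge)
            if u < n_leaves or v < n_leaves:
                continue
            a = sorted(x for x in adj[u] if x != v)
            b = sorted(x for x in adj[v] if x != u)
            for bx in b:
                cand = {k: set(vs) for k, vs in adj.items()}
                cand[u].remove(a[1])
                cand[v].remove(bx)
                cand[u].add(bx)
                cand[v].add(a[1])
                cand[a[1]].remove(u)
                cand[a[1]].add(v)
                cand[bx].remove(v)
                cand[bx].add(u)
                length = _pauplin_length(cand, n_leaves, d)
                if length < best_len - 1e-12:
                    best_len = length
                    best_adj = cand
        if best_adj is None:
            return adj
        adj = best_adj
        current = best_len


def _spr(adj: dict[int, set[int]], n_leaves: int, d: np.ndarray) -> dict[int, set[int]]:
    """Subtree prune-and-regraft hill climbing (with NNI re-polish).

    Escapes the local optima the NNI neighborhood alone can leave on noisy
    distance matrices. Each pass prunes every directed subtree and tries every
    regraft edge, applying the best strict improvement.
    """
    current = _pauplin_length(adj, n_leaves, d)
    while True:
        best_len = current
        best_adj = None
        for edge in _edges(adj):
            for u, v in (sorted(edge), sorted(edge)[::-1]):
                # prune the subtree on the v side; u must be internal so the
                # remaining tree stays binary after removing it
                if u < n_leaves:
                    continue
                a, b = sorted(x for x in adj[u] if x != v)
                base = {k: set(vs) for k, vs in adj.items()}
                # collapse u: connect a-b, detach (u, v)
                base[a].remove(u)
                base[b].remove(u)
                base[a].add(b)
                base[b].add(a)
                sub_nodes = _component(base, v, exclude={u})
                for redge in _edges(base):
                    p, q = sorted(redge)
                    if p in sub_nodes or q in sub_nodes or u in (p, q):
                        continue
                    cand = {k: set(vs) for k, vs in base.items() if k != u}
                    cand[p].remove(q)
                    cand[q].remove(p)
                    cand[p].add(u)
                    cand[q].add(u)
                    cand[u] = {p, q, v}
                    length = _pauplin_length(cand, n_leaves, d)
                    if length < best_len - 1e-12:
                        best_len = length
                        best_adj = cand
        if best_adj is None:
            return adj
        adj = _nni(best_adj, n_leaves, d)
        current = _pauplin_length(adj, n_leaves, d)


def _component(adj: dict[int, set[int]], start: int, exclude: set[int]) -> set[int]:
    seen = set(exclude) | {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen - exclude


def _balanced_weights(
    adj: dict[int, set[int]], n_leaves: int
) -> dict[tuple[int, int], np.ndarray]:
    """Leaf-weight vector of the subtree on the v side of each directed edge
    (u, v); weights halve at every internal branching and sum to one."""
    memo: dict[tuple[int, int], np.ndarray] = {}

    def rec(u: int, v: int) -> np.ndarray:
        key = (u, v)
        if key in memo:
            return memo[key]
        if v < n_leaves:
            w = np.zeros(n_leaves)
            w[v] = 1.0
        else:
            kids = [x for x in adj[v] if x != u]
            w = sum(rec(v, k) for k in kids) / len(kids)
        memo[key] = w
        return w

    for u, nbrs in adj.items():
        for v in nbrs:
            rec(u, v)
    return memo


def _balanced_branch_lengths(tree: ExpressionTree, d: np.ndarray) -> None:
    adj, n = tree.adjacency, tree.n_leaves
    w = _balanced_weights(adj, n)

    def delta(e1: tuple[int, int], e2: tuple[int, int]) -> float:
        return float(w[e1] @ d @ w[e2])

    lengths: dict[frozenset, float] = {}
    clamped = []
    for edge in _edges(adj):
        u, v = sorted(edge)
        if u < n:  # external edge: u is the leaf
            a, b = sorted(x for x in adj[v] if x != u)
            val = 0.5 * (delta((v, u), (v, a)) + delta((v, u), (v, b)) - delta((v, a), (v, b)))
        else:  # internal edge
            a1, a2 = sorted(x for x in adj[u] if x != v)
            c1, c2 = sorted(x for x in adj[v] if x != u)
            ac = delta((u, a1), (v, c1))
            ad = delta((u, a1), (v, c2))
            bc = delta((u, a2), (v, c1))
            bd = delta((u, a2), (v, c2))
            ab = delta((u, a1), (u, a2))
            cd = delta((v, c1), (v, c2))
            val = 0.25 * (ac + ad + bc + bd) - 0.5 * (ab + cd)
        if val < 0:
            clamped.append((tuple(sorted(edge)), float(val)))
            val = 0.0
        lengths[edge] = float(val)
    tree.branch_lengths = lengths
    tree.clamped = clamped
    if clamped:
        logger.info("%d negative branch-length estimates clamped to 0", len(clamped))


def _distance_from_chars(arr: np.ndarray) -> np.ndarray:
    """Hamming distance with pairwise deletion from an (n, L) char array."""
    known = arr != CHAR_UNKNOWN
    n = arr.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        both = known[i] & known[i + 1 :]
        counts = both.sum(axis=1)
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(counts > 0, mism / np.maximum(counts, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def bootstrap_support(
    seqs: StateSequenceSet,
    n_boot: int = 1000,
    seed: int | None = 0,
    replicate_starts: int = 1,
) -> ExpressionTree:
    """Bootstrap gene positions, rebuild trees, and annotate branch support.

    Support for each internal branch of the original tree is the fraction of
    successful bootstrap trees containing the same leaf bipartition.
    Replicates whose resampled columns leave some pair with no comparable
    site are skipped (counted and logged). Replicate trees use
    ``replicate_starts`` greedy starts and NNI polish only (no SPR), trading
    per-replicate optimality for speed; supports are frequencies, not optima.
    """
    names = seqs.names
    dist, _ = hamming_distance_matrix(seqs)
    tree = balanced_me_tree(dist)
    orig_bip = tree.bipartitions()
    counts = {edge: 0 for edge in orig_bip}
    arr = seqs.to_array()
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    used = 0
    skipped = 0
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        d = _distance_from_chars(arr[:, cols])
        if np.isnan(d).any():
            skipped += 1
            continue
        rep = balanced_me_tree(
            pd.DataFrame(d, index=names, columns=names),
            n_starts=replicate_starts,
            spr=False,
        )
        rep_bips = set(rep.bipartitions().values())
        used += 1
        for edge, bip in orig_bip.items():
            if bip in rep_bips:
                counts[edge] += 1
    if skipped:
        logger.warning("%d of %d bootstrap replicates skipped (no comparable sites)", skipped, n_boot)
    tree.supports = {
        edge: (counts[edge] / used if used else float("nan")) for edge in orig_bip
    }
    tree.n_boot = used
    tree.n_boot_skipped = skipped
    return tree
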