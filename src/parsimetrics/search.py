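"""Heuristic and exhaustive maximum-parsimony tree search.

The heuristic follows the classic "traditional search" recipe: for each
replicate a starting tree is built by random-addition-sequence stepwise
insertion, then improved by TBR (tree bisection and reconnection) branch
swapping, accepting strictly better trees and queueing equal-length (or
within-margin) trees breadth-wise up to a per-replicate cap.  Replicates
are pooled, deduplicated by bipartition set, and truncated to a global
buffer size.  All randomness flows from one seed; identical
configurations give identical results.

``exhaustive_search`` enumerates every unrooted binary topology (only
feasible for <= 9 taxa) and serves as the optimality oracle for the
heuristic, for Bremer values and for the partition metrics on fixtures.

Hot-path trees are plain adjacency dicts with leaves encoded as single
bits of an integer, so a bipartition is one int and a topology key is a
frozenset of ints; :class:`~parsimetrics.tree_model.PhyloTree` objects
are built only at the API boundary.
"""

from __future__ import annotations

from collections import OrderedDict, deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import SearchError, TreeError
from .matrix_io import CharacterMatrix
from .parsimony import fitch_on_adjacency
from .tree_model import Bipartition, PhyloTree

__all__ = [
    "SearchConfig",
    "TreeSet",
    "PRESETS",
    "random_addition_tree",
    "tbr_swap",
    "heuristic_search",
    "exhaustive_search",
]

Adj = Dict[int, Set[int]]
SplitKey = FrozenSet[int]


@dataclass(frozen=True)
class SearchConfig:
    """Settings of one heuristic search run.

    ``suboptimal_margin`` is the number of steps above the best length a
    retained tree may have (0 keeps optima only).
    """

    n_replicates: int = 10
    trees_per_replicate: int = 20
    max_trees_total: int = 200
    seed: int = 0
    suboptimal_margin: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise SearchError("n_replicates must be >= 1")
        if self.max_trees_total < self.trees_per_replicate:
            raise SearchError("max_trees_total must be >= trees_per_replicate")
        if self.suboptimal_margin < 0:
            raise SearchError("suboptimal_margin must be >= 0")


#: named setting profiles; the two "traditional-*" profiles are the
#: full-scale morphology protocols (150 or 10000 random-addition
#: replicates, 200 trees saved per replicate, 30000-tree buffer);
#: "fast" is a light profile for desk-scale matrices and
#: "bootstrap-light" the default for bootstrap pseudoreplicate searches
PRESETS: Dict[str, SearchConfig] = {
    "traditional-150": SearchConfig(150, 200, 30000, 0, 0),
    "traditional-10000": SearchConfig(10000, 200, 30000, 0, 0),
    "fast": SearchConfig(5, 20, 200, 0, 0),
    "bootstrap-light": SearchConfig(2, 5, 10, 0, 0),
}


@dataclass(frozen=True)
class TreeSet:
    """Deduplicated trees retained by a search, with their lengths."""

    trees: Tuple[PhyloTree, ...]
    lengths: Tuple[int, ...]
    best_length: int
    config: Optional[SearchConfig] = None
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.trees) != len(self.lengths):
            raise SearchError("trees and lengths differ in length")

    def __len__(self) -> int:
        return len(self.trees)


# -- low-level topology helpers (adjacency dicts + leaf bitmasks, hot path) -------


class _Arena:
    """Shared immutable context of one search: taxa order, leaf bits, masks."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa_sorted = sorted(matrix.taxa)
        # leaf node ids are the matrix row indices
        self.bit_of_label = {t: 1 << i for i, t in enumerate(self.taxa_sorted)}
        self.leafbit = {
            row: self.bit_of_label[t] for row, t in enumerate(matrix.taxa)
        }
        self.labels = {row: t for row, t in enumerate(matrix.taxa)}
        self.n = matrix.n_taxa
        self.full = (1 << self.n) - 1
        exp = matrix.expanded_masks()
        if matrix.n_chars <= 48:
            # plain-int rows feed the fast scoring path directly
            self.masks = {i: [int(x) for x in exp[i]] for i in range(self.n)}
        else:
            self.masks = {i: exp[i] for i in range(self.n)}

    def side_labels(self, mask: int) -> FrozenSet[str]:
        return frozenset(
            t for i, t in enumerate(self.taxa_sorted) if mask >> i & 1
        )

    def mask_of_terms(self, terms: Iterable[str]) -> int:
        m = 0
        for t in terms:
            try:
                m |= self.bit_of_label[t]
            except KeyError:
                raise TreeError(f"unknown taxon {t!r}") from None
        return m

    def canonical(self, mask: int) -> int:
        # canonical side: the one not containing the first (bit-0) taxon
        return mask if not (mask & 1) else self.full ^ mask


def _splits_i(adj: Adj, arena: _Arena) -> SplitKey:
    """Canonical nontrivial splits of a full tree as a frozenset of ints."""
    n = arena.n
    if n < 4:
        return frozenset()
    leafbit = arena.leafbit
    root = next(u for u in adj if u not in leafbit)
    order: List[Tuple[int, int]] = []
    stack = [(root, -1)]
    while stack:
        u, parent = stack.pop()
        order.append((u, parent))
        for v in adj[u]:
            if v != parent:
                stack.append((v, u))
    below: Dict[int, int] = {}
    out: Set[int] = set()
    full = arena.full
    for u, parent in reversed(order):
        m = leafbit.get(u)
        if m is None:
            m = 0
            for v in adj[u]:
                if v != parent:
                    m |= below[v]
        below[u] = m
        if parent != -1:
            c = m.bit_count()
            if 2 <= c <= n - 2:
                out.add(m if not (m & 1) else full ^ m)
    return frozenset(out)


def _edges(adj: Adj) -> List[Tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _attach_leaf(adj: Adj, leaf: int, edge: Tuple[int, int], new_internal: int) -> None:
    a, b = edge
    adj[a].discard(b)
    adj[b].discard(a)
    adj[new_internal] = {a, b, leaf}
    adj[a].add(new_internal)
    adj[b].add(new_internal)
    adj[leaf] = {new_internal}


def _detach_leaf(adj: Adj, leaf: int, edge: Tuple[int, int], new_internal: int) -> None:
    a, b = edge
    del adj[new_internal]
    del adj[leaf]
    adj[a].discard(new_internal)
    adj[b].discard(new_internal)
    adj[a].add(b)
    adj[b].add(a)


def _component(adj: Adj, start: int, blocked: int) -> Set[int]:
    """Nodes reachable from ``start`` without crossing the start-blocked edge."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == start and v == blocked:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _tbr_moves(adj: Adj, leaves: Set[int], next_id: int):
    """Yield the adjacency of every TBR rearrangement of a binary tree.

    Bisect each edge; on each side suppress the cut endpoint if it became
    degree-2; reconnect by subdividing any edge of one side and any edge
    of the other (a single-leaf side reattaches directly).  Rearrangements
    that recreate the original topology are *not* filtered here, nor are
    duplicates: callers deduplicate by split key only when a candidate
    survives scoring.
    """
    for u, v in _edges(adj):
        comp_u = _component(adj, u, v)
        comp_v = set(adj) - comp_u
        sides = []
        for w, comp in ((u, comp_u), (v, comp_v)):
            sub: Adj = {x: adj[x] & comp for x in comp}
            if len(comp) == 1:
                sides.append((sub, None, w))
                continue
            if w not in leaves and len(sub[w]) == 2:
                a, b = sorted(sub[w])
                sub[a].discard(w)
                sub[b].discard(w)
                sub[a].add(b)
                sub[b].add(a)
                del sub[w]
            eds = sorted((x, y) for x in sub for y in sub[x] if x < y)
            sides.append((sub, eds, None))
        (sub_a, eds_a, leaf_a), (sub_b, eds_b, leaf_b) = sides
        a_points: Sequence[Optional[Tuple[int, int]]] = [None] if leaf_a is not None else eds_a
        b_points: Sequence[Optional[Tuple[int, int]]] = [None] if leaf_b is not None else eds_b
        for ea in a_points:
            for eb in b_points:
                new: Adj = {x: set(ys) for x, ys in sub_a.items()}
                for x, ys in sub_b.items():
                    new[x] = set(ys)
                nid = next_id
                if ea is None:
                    x_node = leaf_a
                else:
                    p, q = ea
                    new[p].discard(q)
                    new[q].discard(p)
                    new[nid] = {p, q}
                    new[p].add(nid)
                    new[q].add(nid)
                    x_node = nid
                    nid += 1
                if eb is None:
                    y_node = leaf_b
                else:
                    p, q = eb
                    new[p].discard(q)
                    new[q].discard(p)
                    new[nid] = {p, q}
                    new[p].add(nid)
                    new[q].add(nid)
                    y_node = nid
                new[x_node].add(y_node)
                new[y_node].add(x_node)
                yield new


def _tree_from_adj(adj: Adj, arena: _Arena) -> PhyloTree:
    return PhyloTree(adj, {u: arena.labels[u] for u in adj if u in arena.labels})


def tbr_swap(tree: PhyloTree, matrix: Optional[CharacterMatrix] = None) -> List[PhyloTree]:
    """All distinct TBR neighbours of a binary tree (the tree itself excluded)."""
    if not tree.is_binary():
        raise SearchError("TBR swapping requires a binary tree")
    taxa = sorted(tree.taxa)
    bit_of = {t: 1 << i for i, t in enumerate(taxa)}
    # re-index so helper invariants (leaf bits) hold
    node_bit = {u: bit_of[lab] for u, lab in tree.leaf_label.items()}
    full = (1 << len(taxa)) - 1
    n = len(taxa)

    def key_of(a: Adj) -> SplitKey:
        out: Set[int] = set()
        root = next(x for x in a if x not in node_bit)
        stack = [(root, -1)]
        order = []
        while stack:
            x, p = stack.pop()
            order.append((x, p))
            stack.extend((y, x) for y in a[x] if y != p)
        below: Dict[int, int] = {}
        for x, p in reversed(order):
            m = node_bit.get(x)
            if m is None:
                m = 0
                for y in a[x]:
                    if y != p:
                        m |= below[y]
            below[x] = m
            if p != -1 and 2 <= m.bit_count() <= n - 2:
                out.add(m if not (m & 1) else full ^ m)
        return frozenset(out)

    own = key_of(tree.adj)
    seen: Set[SplitKey] = {own}
    out_trees: List[PhyloTree] = []
    leaves = set(tree.leaf_label)
    for nadj in _tbr_moves(tree.adj, leaves, max(tree.adj) + 1):
        k = key_of(nadj)
        if k in seen:
            continue
        seen.add(k)
        out_trees.append(PhyloTree(nadj, dict(tree.leaf_label)))
    return out_trees


# -- stepwise addition --------------------------------------------------------------


def _random_addition(arena: _Arena, rng: np.random.Generator) -> Adj:
    n = arena.n
    if n < 4:
        raise SearchError("stepwise addition requires >= 4 taxa")
    order = [int(i) for i in rng.permutation(n)]
    hub = n  # first internal node id
    adj: Adj = {order[0]: {hub}, order[1]: {hub}, order[2]: {hub},
                hub: {order[0], order[1], order[2]}}
    next_id = n + 1
    present = order[:3]
    for leaf in order[3:]:
        present.append(leaf)
        masks = {i: arena.masks[i] for i in present}
        best_len = None
        best_edges: List[Tuple[int, int]] = []
        for edge in _edges(adj):
            _attach_leaf(adj, leaf, edge, next_id)
            ln = fitch_on_adjacency(adj, masks)
            _detach_leaf(adj, leaf, edge, next_id)
            if best_len is None or ln < best_len:
                best_len, best_edges = ln, [edge]
            elif ln == best_len:
                best_edges.append(edge)
        choice = best_edges[int(rng.integers(len(best_edges)))]
        _attach_leaf(adj, leaf, choice, next_id)
        next_id += 1
    return adj


def random_addition_tree(matrix: CharacterMatrix, seed: int = 0) -> PhyloTree:
    """Binary starting tree from seeded random-addition-sequence insertion."""
    arena = _Arena(matrix)
    rng = np.random.default_rng(seed)
    return _tree_from_adj(_random_addition(arena, rng), arena)


# -- heuristic search ----------------------------------------------------------------


def _normalize_forbid(forbid: Optional[object], arena: _Arena) -> Optional[int]:
    if forbid is None:
        return None
    if isinstance(forbid, Bipartition):
        if forbid.full_set != frozenset(arena.taxa_sorted):
            raise TreeError("forbidden clade refers to a different taxon set")
        side = forbid.side
    else:
        side = frozenset(forbid)
    mask = arena.mask_of_terms(side)
    c = mask.bit_count()
    if not (2 <= c <= arena.n - 2):
        raise TreeError("forbidden clade must be nontrivial")
    return arena.canonical(mask)


def _hill_climb(
    adj: Adj,
    arena: _Arena,
    cap: int,
    margin: int,
    forbid: Optional[int],
) -> Tuple[Dict[SplitKey, Tuple[Adj, int]], int]:
    """TBR climb from one start; returns (kept: key -> (adj, len), best)."""
    masks = arena.masks
    leaves = set(arena.leafbit)
    best = fitch_on_adjacency(adj, masks)
    current = adj
    improved = True
    kept: "OrderedDict[SplitKey, Tuple[Adj, int]]" = OrderedDict()
    while improved:
        improved = False
        kept = OrderedDict()
        kept[_splits_i(current, arena)] = (current, best)
        work = deque(kept.keys())
        while work and not improved:
            base_adj, _ = kept[work.popleft()]
            for nadj in _tbr_moves(base_adj, leaves, max(base_adj) + 1):
                ln = fitch_on_adjacency(nadj, masks)
                if ln > best + margin:
                    continue
                nkey = _splits_i(nadj, arena)
                if forbid is not None and forbid in nkey:
                    continue
                if ln < best:
                    best = ln
                    current = nadj
                    improved = True
                    break
                if nkey not in kept and len(kept) < cap:
                    kept[nkey] = (nadj, ln)
                    work.append(nkey)
    return kept, best


def heuristic_search(
    matrix: CharacterMatrix,
    config: SearchConfig = PRESETS["fast"],
    forbid: Optional[object] = None,
) -> TreeSet:
    """Random-addition + TBR search; optionally rejecting trees that
    contain a forbidden clade (the converse-constrained mode used for
    Bremer support)."""
    arena = _Arena(matrix)
    forbid_mask = _normalize_forbid(forbid, arena)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_replicates)
    pool: Dict[SplitKey, Tuple[Adj, int]] = {}
    global_best: Optional[int] = None
    for child in children:
        rng = np.random.default_rng(child)
        adj = _random_addition(arena, rng)
        if forbid_mask is not None and forbid_mask in _splits_i(adj, arena):
            adj = _escape_forbidden(adj, arena, forbid_mask)
        kept, rep_best = _hill_climb(
            adj, arena, config.trees_per_replicate, config.suboptimal_margin, forbid_mask
        )
        if global_best is None or rep_best < global_best:
            global_best = rep_best
        for key, (a, ln) in kept.items():
            if key not in pool or pool[key][1] > ln:
                pool[key] = (a, ln)
    assert global_best is not None
    keep = [
        (ln, sorted(key), key, a)
        for key, (a, ln) in pool.items()
        if ln <= global_best + config.suboptimal_margin
    ]
    keep.sort(key=lambda item: (item[0], item[1]))
    keep = keep[: config.max_trees_total]
    return TreeSet(
        trees=tuple(_tree_from_adj(a, arena) for _, _, _, a in keep),
        lengths=tuple(ln for ln, _, _, _ in keep),
        best_length=global_best,
        config=config,
        provenance={
            "engine": "heuristic",
            "forbid": sorted(arena.side_labels(forbid_mask)) if forbid_mask else None,
        },
    )


def _escape_forbidden(adj: Adj, arena: _Arena, forbid: int) -> Adj:
    """Best TBR neighbour lacking the forbidden clade (start-tree repair)."""
    best_adj, best_len = None, None
    leaves = set(arena.leafbit)
    for nadj in _tbr_moves(adj, leaves, max(adj) + 2):
        if forbid in _splits_i(nadj, arena):
            continue
        ln = fitch_on_adjacency(nadj, arena.masks)
        if best_len is None or ln < best_len:
            best_adj, best_len = nadj, ln
    if best_adj is None:
        raise SearchError("no TBR neighbour avoids the forbidden clade")
    return best_adj


# -- exhaustive enumeration -----------------------------------------------------------


def _enumerate_topologies(n: int):
    """Yield the adjacency of every unrooted binary topology on leaves 0..n-1.

    Sequential construction (leaf k into every edge of every tree on the
    first k leaves), (2n-5)!! trees in total.  The same dict is yielded
    repeatedly in mutated states; consumers must not keep references.
    """
    hub = n
    adj: Adj = {0: {hub}, 1: {hub}, 2: {hub}, hub: {0, 1, 2}}

    def rec(next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield adj
            return
        for edge in _edges(adj):
            _attach_leaf(adj, next_leaf, edge, next_internal)
            yield from rec(next_leaf + 1, next_internal + 1)
            _detach_leaf(adj, next_leaf, edge, next_internal)

    if n == 3:
        yield adj
    else:
        yield from rec(3, n + 1)


MAX_EXHAUSTIVE_TAXA = 9


def exhaustive_search(
    matrix: CharacterMatrix,
    suboptimal_margin: int = 0,
    forbid: Optional[object] = None,
) -> TreeSet:
    """Score every unrooted binary topology; keep all within the margin of
    the global optimum.  Refuses more than 9 taxa (135135 topologies)."""
    n = matrix.n_taxa
    if n > MAX_EXHAUSTIVE_TAXA:
        raise SearchError(
            f"exhaustive search limited to {MAX_EXHAUSTIVE_TAXA} taxa, got {n}: "
            "use heuristic_search"
        )
    if n < 3:
        raise SearchError("need at least 3 taxa")
    arena = _Arena(matrix)
    forbid_mask = _normalize_forbid(forbid, arena)
    best: Optional[int] = None
    kept: List[Tuple[int, Adj, SplitKey]] = []
    for adj in _enumerate_topologies(n):
        ln = fitch_on_adjacency(adj, arena.masks)
        if best is not None and ln > best + suboptimal_margin:
            continue
        key = _splits_i(adj, arena)
        if forbid_mask is not None and forbid_mask in key:
            continue
        if best is None or ln < best:
            best = ln
            kept.append((ln, {u: set(vs) for u, vs in adj.items()}, key))
            kept = [item for item in kept if item[0] <= best + suboptimal_margin]
        elif ln <= best + suboptimal_margin:
            kept.append((ln, {u: set(vs) for u, vs in adj.items()}, key))
    if best is None:
        raise SearchError("no topology satisfies the constraint")
    kept = [(ln, a, k) for ln, a, k in kept if ln <= best + suboptimal_margin]
    kept.sort(key=lambda item: (item[0], sorted(item[2])))
    return TreeSet(
        trees=tuple(_tree_from_adj(a, arena) for _, a, _ in kept),
        lengths=tuple(ln for ln, _, _ in kept),
        best_length=best,
        config=None,
        provenance={"engine": "exhaustive", "suboptimal_margin": suboptimal_margin},
    )
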