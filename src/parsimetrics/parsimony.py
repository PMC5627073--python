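"""Parsimony length of a tree: Fitch scoring with Hartigan's extension.

Characters are unordered (any state-to-state change costs one step) and
equally weighted; an unknown cell contributes the full set of states
observed in its column.  On binary trees this is the classic Fitch
algorithm; multifurcating nodes are scored with Hartigan's rule — the
cost added at a node is (number of children) minus (the largest number
of children whose state sets share a state) — which is exact for the
minimum-mutation count on arbitrary trees.

The scoring core operates on a plain adjacency map so the tree-search
hot path can reuse it without building :class:`PhyloTree` objects.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np

from .errors import TreeError
from .matrix_io import CharacterMatrix
from .tree_model import PhyloTree

__all__ = [
    "fitch_length",
    "per_character_length",
    "brute_force_length",
    "parsimony_informative",
]

_BITS = np.arange(16, dtype=np.uint16)
_ONE = np.uint16(1)


def leaf_mask_map(tree_labels: Mapping[int, str], matrix: CharacterMatrix) -> Dict[int, np.ndarray]:
    """Per-leaf expanded state-mask vectors, keyed by tree node id."""
    exp = matrix.expanded_masks()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    out = {}
    for node, label in tree_labels.items():
        try:
            out[node] = exp[row_of[label]]
        except KeyError:
            raise TreeError(f"leaf {label!r} has no row in the matrix") from None
    return out


_SMALL_NCHARS = 48  # below this, plain-int scoring beats numpy


def _postorder(adj: Mapping[int, Iterable[int]], start: int, parent0: int):
    order: List[Tuple[int, int]] = []
    stack = [(start, parent0)]
    while stack:
        u, parent = stack.pop()
        order.append((u, parent))
        for v in adj[u]:
            if v != parent:
                stack.append((v, u))
    return order


def fitch_on_adjacency(
    adj: Mapping[int, Iterable[int]],
    leaf_masks: Mapping[int, np.ndarray],
    per_character: bool = False,
):
    """Minimum state changes on an unrooted tree given per-leaf mask vectors.

    ``adj`` maps node id -> neighbours; leaves are exactly the keys of
    ``leaf_masks`` that appear in ``adj``.  The tree is scored rooted on
    the edge of its lowest-id leaf: every node then combines its children
    with Hartigan's rule (plain Fitch at binary nodes), and the leaf's
    own edge contributes a final intersection step.  Returns an int (or
    the per-character vector when ``per_character``).
    """
    n_chars = len(next(iter(leaf_masks.values())))
    if len(adj) <= 2:
        cost = np.zeros(n_chars, dtype=np.int64)
        present = [u for u in adj if u in leaf_masks]
        if len(present) == 2:
            a, b = (np.asarray(leaf_masks[u]) for u in present)
            cost += (a & b) == 0
        return cost if per_character else int(cost.sum())
    root_leaf = min(u for u in adj if u in leaf_masks)
    (anchor,) = tuple(adj[root_leaf])
    order = _postorder(adj, anchor, root_leaf)
    if n_chars <= _SMALL_NCHARS and not per_character:
        return _fitch_smallint(adj, leaf_masks, order, root_leaf, anchor)
    cost = np.zeros(n_chars, dtype=np.int64)
    node_mask: Dict[int, np.ndarray] = {}
    for u, parent in reversed(order):
        if u in leaf_masks:
            node_mask[u] = leaf_masks[u]
            continue
        children = [node_mask[v] for v in adj[u] if v != parent]
        if len(children) == 2:
            a, b = children
            inter = a & b
            empty = inter == 0
            cost += empty
            node_mask[u] = np.where(empty, a | b, inter)
        else:
            stackm = np.stack(children)  # (k, C)
            counts = (
                (stackm[:, None, :] >> _BITS[None, :, None]) & _ONE
            ).sum(axis=0, dtype=np.int64)  # (16, C)
            kmax = counts.max(axis=0)
            cost += len(children) - kmax
            node_mask[u] = (
                ((counts == kmax[None, :]) & (counts > 0)).astype(np.uint16)
                * (np.uint16(1) << _BITS)[:, None]
            ).sum(axis=0, dtype=np.uint16)
    cost += (node_mask[anchor] & leaf_masks[root_leaf]) == 0
    return cost if per_character else int(cost.sum())


def _fitch_smallint(adj, leaf_masks, order, root_leaf, anchor) -> int:
    """Per-character Python-int scoring (fast for narrow matrices)."""
    lists: Dict[int, list] = {}
    total = 0
    for u, parent in reversed(order):
        if u in leaf_masks:
            masks = leaf_masks[u]
            lists[u] = masks if isinstance(masks, list) else masks.tolist()
            continue
        children = [lists[v] for v in adj[u] if v != parent]
        if len(children) == 2:
            ca, cb = children
            out = []
            append = out.append
            for a, b in zip(ca, cb):
                inter = a & b
                if inter:
                    append(inter)
                else:
                    total += 1
                    append(a | b)
            lists[u] = out
        else:
            out = []
            for col in zip(*children):
                freq: Dict[int, int] = {}
                for m in col:
                    while m:
                        b = m & -m
                        freq[b] = freq.get(b, 0) + 1
                        m ^= b
                kmax = max(freq.values())
                total += len(col) - kmax
                acc = 0
                for b, c in freq.items():
                    if c == kmax:
                        acc |= b
                out.append(acc)
            lists[u] = out
    rl = leaf_masks[root_leaf]
    rl = rl if isinstance(rl, list) else rl.tolist()
    for a, b in zip(lists[anchor], rl):
        if not (a & b):
            total += 1
    return total


def _check_leaf_match(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    if tree.taxa != frozenset(matrix.taxa):
        extra = sorted(tree.taxa - set(matrix.taxa))
        missing = sorted(set(matrix.taxa) - tree.taxa)
        raise TreeError(
            f"tree leaves do not match matrix taxa (tree-only {extra}, matrix-only {missing})"
        )


def per_character_length(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Fitch length of each character scored alone (vector of ints)."""
    _check_leaf_match(tree, matrix)
    masks = leaf_mask_map(tree.leaf_label, matrix)
    return fitch_on_adjacency(tree.adj, masks, per_character=True)


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Minimum total number of state changes the tree requires for the matrix."""
    _check_leaf_match(tree, matrix)
    masks = leaf_mask_map(tree.leaf_label, matrix)
    return fitch_on_adjacency(tree.adj, masks)


def brute_force_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Independent oracle: enumerate all ancestral state assignments.

    For every character, every assignment of a single state (from the
    column's observed alphabet) to every internal node is scored; a leaf
    contributes 0 if its state set contains the adjacent assigned state
    and 1 otherwise.  Exponential in the number of internal nodes — only
    for small validation cases.
    """
    _check_leaf_match(tree, matrix)
    exp = matrix.expanded_masks()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    internal = sorted(u for u in tree.adj if u not in tree.leaf_label)
    internal_pos = {u: k for k, u in enumerate(internal)}
    int_edges = [
        (u, v) for u, v in tree.edges() if u in internal_pos and v in internal_pos
    ]
    leaf_edges = [
        (u, v) if v in internal_pos else (v, u)
        for u, v in tree.edges()
        if (u in internal_pos) != (v in internal_pos)
    ]  # (leaf, internal)
    total = 0
    for c in range(matrix.n_chars):
        alphabet = [s for s in range(16) if int(matrix.column_alphabets[c]) >> s & 1]
        leaf_mask = {u: int(exp[row_of[lab], c]) for u, lab in tree.leaf_label.items()}
        if not internal:  # two-taxon tree
            a, b = leaf_mask.values()
            total += int(a & b == 0)
            continue
        best = None
        for assign in product(alphabet, repeat=len(internal)):
            changes = 0
            for u, v in int_edges:
                changes += assign[internal_pos[u]] != assign[internal_pos[v]]
            for leaf, node in leaf_edges:
                changes += not (leaf_mask[leaf] >> assign[internal_pos[node]] & 1)
            if best is None or changes < best:
                best = changes
        total += best
    return total


def parsimony_informative(matrix: CharacterMatrix) -> np.ndarray:
    """Boolean vector: character has >= 2 states each seen in >= 2 taxa.

    Only unambiguous single-state cells are counted; a character with at
    most one observed state is uninformative and scores 0 on any tree.
    """
    m = matrix.masks.astype(np.int64)
    single = (m != 0) & ((m & (m - 1)) == 0)
    out = np.zeros(matrix.n_chars, dtype=bool)
    for c in range(matrix.n_chars):
        col = m[single[:, c], c]
        if col.size == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        out[c] = (counts >= 2).sum() >= 2
    return out
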