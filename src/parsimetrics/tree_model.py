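"""Unrooted tree representation, newick I/O, bipartitions and strict consensus.

Trees are held unrooted: the topology is an acyclic graph whose degree-1
nodes are exactly the leaves, internal nodes have degree >= 3 (degree-2
nodes are suppressed on construction).  Parsimony length is invariant to
rooting, so no root is stored; for writing, trees are rooted on an
outgroup leaf when one is named.

A clade is represented as the :class:`Bipartition` separating its
terminal taxa from everything else, canonicalised as the side that does
not contain the lexicographically first taxon.
"""

from __future__ import annotations

import io
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy

from .errors import NexusParseError, TreeError

__all__ = [
    "Bipartition",
    "PhyloTree",
    "parse_newick",
    "strict_consensus",
    "read_trees_nexus",
    "write_trees_nexus",
]


class Bipartition:
    """A nontrivial split of a taxon set induced by one internal edge.

    ``side`` is the canonical half: the half that does *not* contain the
    lexicographically smallest taxon.  Two bipartitions compare equal iff
    they split the same full taxon set the same way.
    """

    __slots__ = ("side", "full_set", "_hash")

    def __init__(self, side: Iterable[str], full_set: Iterable[str]):
        full = frozenset(full_set)
        half = frozenset(side)
        if not half <= full:
            raise TreeError(f"bipartition side {sorted(half)} not a subset of the taxon set")
        if not (2 <= len(half) <= len(full) - 2):
            raise TreeError(
                f"trivial bipartition: side of size {len(half)} on {len(full)} taxa"
            )
        anchor = min(full)
        if anchor in half:
            half = full - half
        self.side: FrozenSet[str] = half
        self.full_set: FrozenSet[str] = full
        self._hash = hash((self.side, self.full_set))

    @property
    def other_side(self) -> FrozenSet[str]:
        return self.full_set - self.side

    def restrict_key(self) -> Tuple[str, ...]:
        return tuple(sorted(self.side))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side == other.side
            and self.full_set == other.full_set
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"Bipartition({'+'.join(sorted(self.side))})"


class PhyloTree:
    """Unrooted multifurcating tree over uniquely labelled leaves."""

    __slots__ = ("adj", "leaf_label", "_taxa", "_bipartitions")

    def __init__(self, adj: Dict[int, Set[int]], leaf_label: Dict[int, str]):
        # defensive copies; then normalize (suppress degree-2 internals)
        self.adj: Dict[int, Set[int]] = {u: set(vs) for u, vs in adj.items()}
        self.leaf_label: Dict[int, str] = dict(leaf_label)
        self._normalize()
        self._validate()
        self._taxa: FrozenSet[str] = frozenset(self.leaf_label.values())
        self._bipartitions: Optional[FrozenSet[Bipartition]] = None

    # -- construction helpers -------------------------------------------------

    def _normalize(self) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self.adj):
                if u in self.leaf_label:
                    continue
                nbrs = self.adj[u]
                if len(nbrs) == 2:
                    a, b = sorted(nbrs)
                    self.adj[a].discard(u)
                    self.adj[b].discard(u)
                    self.adj[a].add(b)
                    self.adj[b].add(a)
                    del self.adj[u]
                    changed = True
                elif len(nbrs) == 1 and len(self.adj) > 2:
                    # unlabeled pendant node: prune
                    (v,) = nbrs
                    self.adj[v].discard(u)
                    del self.adj[u]
                    changed = True

    def _validate(self) -> None:
        labels = list(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        if any(not lab for lab in labels):
            raise TreeError("empty leaf label")
        n_edges = sum(len(v) for v in self.adj.values())
        if n_edges % 2:
            raise TreeError("asymmetric adjacency")
        if len(self.adj) and n_edges // 2 != len(self.adj) - 1:
            raise TreeError("topology is not a tree (edge count mismatch)")
        # connectivity
        if self.adj:
            seen = set()
            stack = [next(iter(self.adj))]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(self.adj[u] - seen)
            if seen != set(self.adj):
                raise TreeError("topology is not connected")
        for u, nbrs in self.adj.items():
            deg = len(nbrs)
            if u in self.leaf_label:
                if deg != 1 and len(self.adj) > 2:
                    raise TreeError(f"leaf {self.leaf_label[u]!r} has degree {deg}")
            else:
                if deg < 3 and len(self.adj) > 2:
                    raise TreeError(f"internal node of degree {deg} after normalization")
        deg1 = {u for u, nbrs in self.adj.items() if len(nbrs) <= 1}
        if len(self.adj) > 1 and deg1 != set(self.leaf_label):
            raise TreeError("degree-1 nodes are not exactly the labelled leaves")

    # -- basic accessors -------------------------------------------------------

    @property
    def taxa(self) -> FrozenSet[str]:
        return self._taxa

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def edges(self) -> List[Tuple[int, int]]:
        """All undirected edges as (u, v) with u < v, deterministic order."""
        return sorted((min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v)

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == (1 if u in self.leaf_label else 3) for u, nbrs in self.adj.items()
        ) or self.n_leaves <= 3

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.adj, self.leaf_label)

    # -- bipartitions ----------------------------------------------------------

    def bipartitions(self) -> FrozenSet[Bipartition]:
        """The nontrivial splits, one per internal edge."""
        if self._bipartitions is not None:
            return self._bipartitions
        n = self.n_leaves
        out: Set[Bipartition] = set()
        if n >= 4 and self.adj:
            root = next(u for u in sorted(self.adj) if u not in self.leaf_label) \
                if any(u not in self.leaf_label for u in self.adj) else next(iter(self.adj))
            below: Dict[int, Set[str]] = {}
            order: List[Tuple[int, int]] = []  # (node, parent)
            stack = [(root, -1)]
            while stack:
                u, parent = stack.pop()
                order.append((u, parent))
                for v in self.adj[u]:
                    if v != parent:
                        stack.append((v, u))
            for u, parent in reversed(order):
                if u in self.leaf_label:
                    below[u] = {self.leaf_label[u]}
                else:
                    s: Set[str] = set()
                    for v in self.adj[u]:
                        if v != parent:
                            s |= below[v]
                    below[u] = s
                if parent != -1 and 2 <= len(below[u]) <= n - 2:
                    out.add(Bipartition(below[u], self._taxa))
        self._bipartitions = frozenset(out)
        return self._bipartitions

    def topology_key(self) -> Tuple[Tuple[str, ...], ...]:
        """Hashable canonical key: sorted tuple of split sides (as sorted tuples)."""
        return tuple(sorted(bp.restrict_key() for bp in self.bipartitions()))

    def contains_clade(self, terminals: Iterable[str]) -> bool:
        """True iff the split ``terminals | complement`` is an edge of the tree."""
        terms = frozenset(terminals)
        if not terms < self.taxa:
            raise TreeError(f"terminals {sorted(terms - self.taxa)} not a proper subset of the leaves")
        if not (2 <= len(terms) <= self.n_leaves - 2):
            raise TreeError("clade must contain between 2 and n_leaves-2 terminals")
        return Bipartition(terms, self.taxa) in self.bipartitions()

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.taxa == other.taxa and self.bipartitions() == other.bipartitions()

    # -- I/O -------------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, expected_taxa: Optional[Iterable[str]] = None) -> "PhyloTree":
        return parse_newick(text, expected_taxa)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        adj: Dict[int, Set[int]] = {}
        labels: Dict[int, str] = {}
        ids: Dict[int, int] = {}

        def nid(node: dendropy.Node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = len(ids)
                adj[ids[key]] = set()
            return ids[key]

        for node in tree.preorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else (node.label or "")
                labels[u] = label
            if node.parent_node is not None:
                p = nid(node.parent_node)
                adj[u].add(p)
                adj[p].add(u)
        return cls(adj, labels)

    def to_newick(self, outgroup: Optional[str] = None) -> str:
        """Deterministic newick string; rooted on ``outgroup`` when given."""
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            return f"{next(iter(self.leaf_label.values()))};"
        label_of = self.leaf_label
        if outgroup is not None:
            if outgroup not in self._taxa:
                raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
            og_node = next(u for u, lab in label_of.items() if lab == outgroup)
        else:
            og_node = min(label_of, key=lambda u: label_of[u])
        (anchor,) = self.adj[og_node] if len(self.adj[og_node]) == 1 else (next(iter(self.adj[og_node])),)

        mintax: Dict[int, str] = {}

        def subtree(u: int, parent: int) -> str:
            if u in label_of:
                mintax[u] = label_of[u]
                return _quote_label(label_of[u])
            parts = []
            for v in self.adj[u]:
                if v != parent:
                    parts.append((subtree(v, u), v))
            mintax[u] = min(mintax[v] for _, v in parts)
            parts.sort(key=lambda p: mintax[p[1]])
            return "(" + ",".join(p[0] for p in parts) + ")"

        og_str = subtree(og_node, anchor)
        rest = subtree(anchor, og_node)
        return f"({og_str},{rest});"

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_leaves} leaves: {self.to_newick()})"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>") or not label:
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str, expected_taxa: Optional[Iterable[str]] = None) -> PhyloTree:
    """Parse a newick string into an unrooted :class:`PhyloTree`.

    A rooted input is unrooted by suppressing a degree-2 root.  Branch
    lengths are ignored (parsimony lengths do not use them).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NexusParseError(f"newick parse failed: {exc}") from exc
    tree = PhyloTree.from_dendropy(dtree)
    if expected_taxa is not None:
        expected = frozenset(expected_taxa)
        if tree.taxa != expected:
            extra = sorted(tree.taxa - expected)
            missing = sorted(expected - tree.taxa)
            raise TreeError(f"leaf set mismatch: unexpected {extra}, missing {missing}")
    return tree


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    trees = list(trees)
    if not trees:
        raise TreeError("strict consensus of an empty collection")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("strict consensus requires a common leaf set")
    common = set(trees[0].bipartitions())
    for t in trees[1:]:
        common &= t.bipartitions()
    return tree_from_bipartitions(taxa, common)


def tree_from_bipartitions(taxa: Iterable[str], splits: Iterable[Bipartition]) -> PhyloTree:
    """Build the (possibly multifurcating) tree displaying the given
    pairwise-compatible splits and nothing else."""
    taxa = sorted(set(taxa))
    taxset = frozenset(taxa)
    anchor = taxa[0] if taxa else ""
    # express every split as the clade not containing the anchor taxon
    clades: List[FrozenSet[str]] = []
    for bp in splits:
        if bp.full_set != taxset:
            raise TreeError("split over a different taxon set")
        clades.append(bp.side if anchor not in bp.side else bp.full_set - bp.side)
    clades = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
    adj: Dict[int, Set[int]] = {}
    labels: Dict[int, str] = {}
    next_id = 0

    def new_node() -> int:
        nonlocal next_id
        u = next_id
        next_id += 1
        adj[u] = set()
        return u

    root = new_node()
    node_clade: Dict[int, FrozenSet[str]] = {root: taxset}
    # nested (compatible) clades: parent = smallest strictly-containing clade
    clade_node: Dict[FrozenSet[str], int] = {taxset: root}
    ordered_parents: List[FrozenSet[str]] = [taxset]
    for c in clades:
        parent = min(
            (p for p in ordered_parents if c < p), key=len, default=taxset
        )
        u = new_node()
        node_clade[u] = c
        p = clade_node[parent]
        adj[u].add(p)
        adj[p].add(u)
        clade_node[c] = u
        ordered_parents.append(c)
    for tax in taxa:
        holder = min(
            (c for c in ordered_parents if tax in c), key=len
        )
        u = new_node()
        labels[u] = tax
        p = clade_node[holder]
        adj[u].add(p)
        adj[p].add(u)
    return PhyloTree(adj, labels)


def read_trees_nexus(path: str) -> List[PhyloTree]:
    """Read every tree from a NEXUS TREES block (or a plain newick file)."""
    with open(path, "r") as fh:
        text = fh.read()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(data=text, schema=schema, preserve_underscores=True)
    except Exception as exc:
        raise NexusParseError(f"tree file parse failed: {exc}") from exc
    return [PhyloTree.from_dendropy(t) for t in tl]


def write_trees_nexus(path: str, trees: Sequence[PhyloTree],
                      names: Optional[Sequence[str]] = None,
                      outgroup: Optional[str] = None) -> None:
    """Write trees as a NEXUS TREES block with a TRANSLATE-free layout."""
    if names is None:
        names = [f"tree_{i + 1}" for i in range(len(trees))]
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN TREES;\n")
    for name, tree in zip(names, trees):
        og = outgroup if (outgroup is not None and outgroup in tree.taxa) else None
        buf.write(f"    TREE {name} = [&U] {tree.to_newick(outgroup=og)}\n")
    buf.write("END;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
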