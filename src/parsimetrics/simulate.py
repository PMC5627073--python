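"""Synthetic fixtures with known ground truth.

``plant_matrix`` builds a type-partitioned binary character matrix on a
known tree: each "clean" column is an uncontradicted synapomorphy of a
chosen clade (state 1 inside, 0 outside), each "homoplastic" column marks
a taxon subset that crosses the clade boundary (guaranteed to conflict
with it), and filler columns are constant.  With no homoplasy and no
noise, a clade planted with k clean columns has Bremer support exactly k,
so every stage of the support and Cs/Cd pipeline can be checked against
construction.  Default type names mirror a three-type morphological
matrix (general external, copulatory, photophore characters) with sizes
in roughly the 116:74:59 proportion when fillers are spread.

``mk_simulate`` is a generic discrete-character noise model for
robustness tests: a uniform root state and a fixed per-edge probability
of jumping to a different uniformly chosen state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import SearchError, TreeError
from .matrix_io import CharacterMatrix, CharacterPartition
from .tree_model import PhyloTree

__all__ = [
    "DEFAULT_TYPE_NAMES",
    "TypePlan",
    "FixtureSpec",
    "GroundTruth",
    "random_tree",
    "plant_matrix",
    "mk_simulate",
]

DEFAULT_TYPE_NAMES = ("general", "copulatory", "photophores")


def random_tree(
    n_taxa: int, seed: int = 0, labels: Optional[Sequence[str]] = None
) -> PhyloTree:
    """Uniform random unrooted binary topology on ``n_taxa`` leaves.

    Sequential construction: leaf k+1 is attached to an edge chosen
    uniformly among the 2k-3 edges of the tree on the first k leaves,
    which yields the uniform distribution over unrooted binary shapes.
    """
    if n_taxa < 4:
        raise TreeError("random_tree requires >= 4 taxa")
    if labels is None:
        width = len(str(n_taxa - 1))
        labels = [f"t{i:0{width}d}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise TreeError("need one label per taxon")
    rng = np.random.default_rng(seed)
    hub = n_taxa
    adj: Dict[int, set] = {0: {hub}, 1: {hub}, 2: {hub}, hub: {0, 1, 2}}
    next_id = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        a, b = edges[int(rng.integers(len(edges)))]
        adj[a].discard(b)
        adj[b].discard(a)
        adj[next_id] = {a, b, leaf}
        adj[a].add(next_id)
        adj[b].add(next_id)
        adj[leaf] = {next_id}
        next_id += 1
    return PhyloTree(adj, {i: labels[i] for i in range(n_taxa)})


@dataclass(frozen=True)
class TypePlan:
    """Columns to plant for one character type."""

    type_name: str
    clade: Tuple[str, ...]  # terminal taxa of the target clade
    n_clean: int  # uncontradicted synapomorphies of the clade
    n_homoplastic: int = 0  # clade-incompatible conflicting columns

    def __post_init__(self):
        if self.n_clean < 0 or self.n_homoplastic < 0:
            raise ValueError("column counts must be >= 0")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one planted fixture; generation is a pure function of it."""

    n_taxa: int
    plans: Tuple[TypePlan, ...]
    tree: Union[PhyloTree, str] = "random"
    background_constant: int = 3
    noise_rate: float = 0.0
    seed: int = 0
    type_names: Tuple[str, ...] = DEFAULT_TYPE_NAMES

    def __post_init__(self):
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must be in [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("need >= 4 taxa")
        unknown = {p.type_name for p in self.plans} - set(self.type_names)
        if unknown:
            raise ValueError(f"plans reference unlisted types: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the generating tree and, per (type, clade), the
    uncontradicted synapomorphy count k (= the clade's Bremer value when
    nothing conflicts)."""

    tree: PhyloTree
    plans: Tuple[TypePlan, ...]
    column_roles: Tuple[str, ...]  # per column: "clean:<type>", "homoplastic:<type>", "constant:<type>"

    def planted_bremer(self) -> Dict[Tuple[str, FrozenSet[str]], int]:
        out: Dict[Tuple[str, FrozenSet[str]], int] = {}
        for p in self.plans:
            key = (p.type_name, frozenset(p.clade))
            out[key] = out.get(key, 0) + p.n_clean
        return out


def _incompatible_subset(
    rng: np.random.Generator, taxa: Sequence[str], clade: FrozenSet[str]
) -> FrozenSet[str]:
    """Random taxon subset incompatible with the clade split (all four
    pairwise intersections of the two splits non-empty)."""
    inside = sorted(clade)
    outside = sorted(set(taxa) - clade)
    if len(inside) < 2 or len(outside) < 2:
        raise SearchError(
            "homoplastic columns need >= 2 taxa on each side of the clade"
        )
    n_in = int(rng.integers(1, len(inside)))  # leave >= 1 inside taxon out
    n_out = int(rng.integers(1, len(outside)))  # leave >= 1 outside taxon out
    pick_in = rng.choice(len(inside), size=n_in, replace=False)
    pick_out = rng.choice(len(outside), size=n_out, replace=False)
    return frozenset(
        [inside[i] for i in sorted(pick_in)] + [outside[i] for i in sorted(pick_out)]
    )


def plant_matrix(
    spec: FixtureSpec,
) -> Tuple[CharacterMatrix, CharacterPartition, GroundTruth]:
    """Generate (matrix, partition, ground truth) for a fixture recipe."""
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.tree, PhyloTree):
        tree = spec.tree
        if tree.n_leaves != spec.n_taxa:
            raise TreeError(
                f"spec names {spec.n_taxa} taxa but the tree has {tree.n_leaves} leaves"
            )
    else:
        tree = random_tree(spec.n_taxa, seed=int(rng.integers(2**31 - 1)))
    taxa = sorted(tree.taxa)
    taxset = frozenset(taxa)
    splits = {bp.side for bp in tree.bipartitions()} | {
        bp.other_side for bp in tree.bipartitions()
    }
    max_clades = max(0, tree.n_leaves - 3)
    planted_clades = {frozenset(p.clade) for p in spec.plans}
    if len(planted_clades) > max_clades:
        raise SearchError(
            f"plan names {len(planted_clades)} clades but the tree has only "
            f"{max_clades} internal edges"
        )
    for p in spec.plans:
        clade = frozenset(p.clade)
        if not clade < taxset or len(clade) < 2 or len(clade) > len(taxa) - 2:
            raise TreeError(f"planted clade {sorted(clade)} is not a nontrivial subset")
        if clade not in splits:
            raise TreeError(
                f"planted clade {sorted(clade)} is not a clade of the fixture tree"
            )

    columns: List[np.ndarray] = []
    roles: List[str] = []
    col_types: List[str] = []
    row_of = {t: i for i, t in enumerate(taxa)}

    for p in spec.plans:
        clade = frozenset(p.clade)
        inside = np.array([t in clade for t in taxa])
        for _ in range(p.n_clean):
            columns.append(inside.astype(np.int8))
            roles.append(f"clean:{p.type_name}")
            col_types.append(p.type_name)
        for _ in range(p.n_homoplastic):
            subset = _incompatible_subset(rng, taxa, clade)
            columns.append(np.array([t in subset for t in taxa], dtype=np.int8))
            roles.append(f"homoplastic:{p.type_name}")
            col_types.append(p.type_name)

    # constant fillers round-robin over the declared types so the
    # partition stays total even for types with no planted columns
    for j in range(spec.background_constant):
        tname = spec.type_names[j % len(spec.type_names)]
        columns.append(np.zeros(len(taxa), dtype=np.int8))
        roles.append(f"constant:{tname}")
        col_types.append(tname)

    if not columns:
        raise SearchError("fixture would have no characters")

    # noise: with probability noise_rate a planted column gets one extra flip
    for j, role in enumerate(roles):
        if role.startswith("constant"):
            continue
        if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
            i = int(rng.integers(len(taxa)))
            columns[j] = columns[j].copy()
            columns[j][i] = 1 - columns[j][i]

    grid = np.stack(columns, axis=1)  # (n_taxa, n_chars)
    masks = (np.uint16(1) << grid.astype(np.uint16)).astype(np.uint16)
    matrix = CharacterMatrix(taxa, masks, symbols="01")
    present_types = tuple(t for t in spec.type_names if t in col_types)
    partition = CharacterPartition(
        present_types, {j: t for j, t in enumerate(col_types)}
    )
    truth = GroundTruth(tree=tree, plans=tuple(spec.plans), column_roles=tuple(roles))
    return matrix, partition, truth


def mk_simulate(
    tree: PhyloTree,
    n_chars: int,
    n_states: int = 2,
    change_prob_per_edge: float = 0.1,
    seed: int = 0,
) -> CharacterMatrix:
    """Simulate characters on a tree under a symmetric jump model.

    The root state is uniform over ``n_states``; along each edge the state
    jumps, with the given probability, to a different state chosen
    uniformly.  Columns evolve independently.
    """
    if n_states < 2 or n_states > 10:
        raise ValueError("n_states must be in 2..10")
    if not (0.0 <= change_prob_per_edge <= 1.0):
        raise ValueError("change_prob_per_edge must be in [0, 1]")
    if n_chars < 1:
        raise ValueError("need at least one character")
    rng = np.random.default_rng(seed)
    adj = tree.adj
    root = next(u for u in sorted(adj) if u not in tree.leaf_label)
    states: Dict[int, np.ndarray] = {
        root: rng.integers(0, n_states, size=n_chars).astype(np.int8)
    }
    order: List[Tuple[int, int]] = [(root, -1)]
    stack = [(root, -1)]
    while stack:
        u, parent = stack.pop()
        for v in adj[u]:
            if v != parent:
                jump = rng.random(n_chars) < change_prob_per_edge
                offset = rng.integers(1, n_states, size=n_chars)
                child = np.where(
                    jump, (states[u] + offset) % n_states, states[u]
                ).astype(np.int8)
                states[v] = child
                stack.append((v, u))
    taxa = sorted(tree.taxa)
    node_of = {lab: u for u, lab in tree.leaf_label.items()}
    rows = [states[node_of[t]] for t in taxa]
    grid = np.stack(rows, axis=0).astype(np.uint16)
    masks = (np.uint16(1) << grid).astype(np.uint16)
    return CharacterMatrix(taxa, masks, symbols="0123456789"[:n_states])
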