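"""Clade support: nonparametric bootstrap, Bremer (decay) values, and the
joint significance rule.

Bootstrap: characters are resampled with replacement; each pseudoreplicate
is analysed with a (light) heuristic search and contributes to a clade's
count iff the clade appears in that pseudoreplicate's strict consensus.

Bremer: the decay value of a clade is ``L(no-clade) - L(best)`` where
``L(no-clade)`` is the best length over trees *not* containing the clade,
found by a converse-constrained search (trees containing the clade are
rejected during swapping).  A clade absent from the strict consensus of
the unconstrained optima has support 0 by convention.  A buffer-based
cross-check (decay read off a suboptimal tree buffer, capped by its
margin) is available, as is exact computation by exhaustive enumeration
for small instances.

A clade is flagged significant iff bootstrap > 80% AND Bremer > 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .errors import SearchError, TreeError
from .matrix_io import CharacterMatrix
from .search import PRESETS, SearchConfig, TreeSet, exhaustive_search, heuristic_search
from .tree_model import Bipartition, PhyloTree, strict_consensus

__all__ = [
    "BOOTSTRAP_THRESHOLD",
    "BREMER_THRESHOLD",
    "is_significant",
    "SupportValue",
    "BootstrapSupport",
    "SupportTable",
    "bootstrap_support",
    "bremer_support",
    "support_table",
]

BOOTSTRAP_THRESHOLD = 80.0  # strictly greater than
BREMER_THRESHOLD = 3  # strictly greater than


def is_significant(bootstrap_pct: float, bremer: int) -> bool:
    """Joint rule: bootstrap > 80% and Bremer decay > 3, both strict."""
    return bootstrap_pct > BOOTSTRAP_THRESHOLD and bremer > BREMER_THRESHOLD


@dataclass(frozen=True)
class SupportValue:
    clade: Bipartition
    bootstrap_pct: float
    bremer: int

    def __post_init__(self):
        if not (0.0 <= self.bootstrap_pct <= 100.0):
            raise ValueError("bootstrap_pct must be within [0, 100]")
        if self.bremer < 0:
            raise ValueError("bremer must be >= 0")

    @property
    def significant(self) -> bool:
        return is_significant(self.bootstrap_pct, self.bremer)


@dataclass(frozen=True)
class BootstrapSupport:
    """Pseudoreplicate consensus counts for every bipartition observed."""

    counts: Mapping[Bipartition, int]
    n_pseudoreplicates: int
    taxa: FrozenSet[str]
    seed: int

    def pct(self, clade: Iterable[str]) -> float:
        bp = clade if isinstance(clade, Bipartition) else Bipartition(clade, self.taxa)
        return 100.0 * self.counts.get(bp, 0) / self.n_pseudoreplicates

    def as_dict(self) -> Dict[Bipartition, float]:
        return {
            bp: 100.0 * c / self.n_pseudoreplicates for bp, c in self.counts.items()
        }


@dataclass(frozen=True)
class SupportTable:
    """Per-clade support for every clade of the reference strict consensus."""

    entries: Mapping[Bipartition, SupportValue]
    reference_consensus: PhyloTree
    best_length: int

    def significance(self) -> Dict[Bipartition, bool]:
        return {bp: sv.significant for bp, sv in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


def _resolve_clade(clade: object, taxa: Iterable[str]) -> Bipartition:
    if isinstance(clade, Bipartition):
        return clade
    return Bipartition(frozenset(clade), frozenset(taxa))


def _optimal_consensus(base: TreeSet) -> PhyloTree:
    """Strict consensus of the minimum-length trees in a tree set (a set
    retained with a suboptimal margin also holds longer trees, which do
    not define the reference consensus)."""
    optima = [t for t, ln in zip(base.trees, base.lengths) if ln == base.best_length]
    return strict_consensus(optima)


def bootstrap_support(
    matrix: CharacterMatrix,
    n_pseudoreplicates: int,
    seed: int = 0,
    search_config: Optional[SearchConfig] = None,
) -> BootstrapSupport:
    """Standard character bootstrap (resampling columns with replacement).

    Each pseudoreplicate matrix is analysed with ``search_config``
    (default: the light ``bootstrap-light`` profile) and a clade counts
    iff it is in the pseudoreplicate's strict consensus.
    """
    if n_pseudoreplicates < 1:
        raise SearchError("need at least one pseudoreplicate")
    base = search_config or PRESETS["bootstrap-light"]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_pseudoreplicates)
    counts: Dict[Bipartition, int] = {}
    taxa = frozenset(matrix.taxa)
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.integers(0, matrix.n_chars, size=matrix.n_chars)
        try:
            pseudo = matrix.take_columns([int(c) for c in cols])
        except Exception:
            # a resample can draw only all-missing columns on pathological
            # matrices; such a replicate supports nothing
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ts = heuristic_search(pseudo, replace(base, seed=sub_seed))
        cons = strict_consensus(ts.trees)
        for bp in cons.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return BootstrapSupport(
        counts=counts, n_pseudoreplicates=n_pseudoreplicates, taxa=taxa, seed=seed
    )


def bremer_support(
    matrix: CharacterMatrix,
    clade: object,
    config: Optional[SearchConfig] = None,
    engine: str = "constrained",
    base: Optional[TreeSet] = None,
) -> int:
    """Decay value of a clade.

    engine:
        ``constrained``  converse-constrained heuristic search (default);
        ``exhaustive``   exact enumeration (<= 9 taxa);
        ``buffer``       read the decay off a suboptimal-tree buffer (the
                         search margin caps the measurable value).
    """
    bp = _resolve_clade(clade, matrix.taxa)
    if bp.full_set != frozenset(matrix.taxa):
        raise TreeError("clade references taxa outside the matrix")
    cfg = config or PRESETS["fast"]
    if engine == "exhaustive":
        if base is None:
            base = exhaustive_search(matrix)
        if bp not in _optimal_consensus(base).bipartitions():
            return 0
        counter = exhaustive_search(matrix, forbid=bp)
        return max(0, counter.best_length - base.best_length)
    if base is None:
        base = heuristic_search(matrix, cfg)
    if bp not in _optimal_consensus(base).bipartitions():
        return 0
    if engine == "buffer":
        margin_cfg = cfg if cfg.suboptimal_margin > 0 else replace(cfg, suboptimal_margin=3)
        buffered = heuristic_search(matrix, margin_cfg)
        lacking = [
            ln
            for t, ln in zip(buffered.trees, buffered.lengths)
            if bp not in t.bipartitions()
        ]
        if not lacking:
            return margin_cfg.suboptimal_margin + 1  # censored at the margin
        return max(0, min(lacking) - buffered.best_length)
    if engine != "constrained":
        raise ValueError(f"unknown Bremer engine {engine!r}")
    counter = heuristic_search(matrix, cfg, forbid=bp)
    return max(0, counter.best_length - base.best_length)


def support_table(
    matrix: CharacterMatrix,
    config: Optional[SearchConfig] = None,
    n_pseudoreplicates: int = 100,
    bootstrap_config: Optional[SearchConfig] = None,
    seed: Optional[int] = None,
    engine: str = "constrained",
) -> SupportTable:
    """Full pipeline: search, strict consensus, both support bases, rule."""
    cfg = config or PRESETS["fast"]
    run_seed = cfg.seed if seed is None else seed
    if engine == "exhaustive":
        base = exhaustive_search(matrix)
    else:
        base = heuristic_search(matrix, replace(cfg, seed=run_seed))
    cons = _optimal_consensus(base)
    boot = bootstrap_support(
        matrix,
        n_pseudoreplicates,
        seed=(run_seed * 2 + 1) % (2**31 - 1),
        search_config=bootstrap_config,
    )
    entries: Dict[Bipartition, SupportValue] = {}
    for bp in sorted(cons.bipartitions(), key=lambda b: sorted(b.side)):
        br = bremer_support(matrix, bp, cfg, engine=engine, base=base)
        entries[bp] = SupportValue(clade=bp, bootstrap_pct=boot.pct(bp), bremer=br)
    return SupportTable(
        entries=entries, reference_consensus=cons, best_length=base.best_length
    )
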