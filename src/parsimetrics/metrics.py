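"""Character-type contribution metrics Cs and Cd.

For a character type *i* and a clade, the support contribution is

    Cs_i = S_i+ - S_i-

where ``S_i+`` is the clade's support when only type-*i* characters are in
the matrix and ``S_i-`` its support when all but the type-*i* characters
are included.  A clade absent from the strict consensus of an analysis has
support 0 in that analysis.

The divergence (within-clade resolution) contribution is

    Cd_i = D_i+/(n-1) - D_i-/(n-1)

where ``D_i+``/``D_i-`` are the sums of support over resolved branches
strictly inside the clade in the two analyses and ``n`` is the number of
terminal taxa in the clade.  The clade's own stem branch is excluded by
default (its support is what Cs already measures); ``include_stem=True``
gives the alternative reading.  For n = 2 there are no internal branches
and Cd = 0.

Both metrics are computed on the Bremer and the bootstrap basis; a type's
contribution is called positive overall if any basis gives a positive
value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import SearchError, TreeError
from .matrix_io import CharacterMatrix, CharacterPartition, subset_matrix
from .search import PRESETS, SearchConfig, TreeSet, exhaustive_search, heuristic_search
from .support import BootstrapSupport, bootstrap_support, bremer_support
from .tree_model import Bipartition, PhyloTree, strict_consensus

__all__ = [
    "MetricResult",
    "clade_support_under_partition",
    "cs_metric",
    "cd_metric",
    "contribution_table",
    "derive_seed",
]

BASES = ("bremer", "bootstrap")


def derive_seed(master: int, *tokens: object) -> int:
    """Deterministic sub-seed (< 2**31) for a named sub-run of one master seed."""
    digest = hashlib.blake2b(
        repr((int(master),) + tokens).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass(frozen=True)
class MetricResult:
    """One Cs or Cd evaluation for a clade x character type x support basis."""

    clade: Bipartition
    clade_name: Optional[str]
    type_name: str
    basis: str
    metric: str  # "cs" or "cd"
    s_plus: Optional[float] = None
    s_minus: Optional[float] = None
    cs: Optional[float] = None
    d_plus: Optional[float] = None
    d_minus: Optional[float] = None
    n: Optional[int] = None
    cd: Optional[float] = None

    @property
    def value(self) -> float:
        return self.cs if self.metric == "cs" else self.cd

    @property
    def positive(self) -> bool:
        return self.value is not None and self.value > 0


class _PartitionRun:
    """One analysis of an include- or exclude-subset matrix, lazily shared
    across clades, metrics and bases."""

    def __init__(
        self,
        matrix: CharacterMatrix,
        config: SearchConfig,
        engine: str,
        n_pseudoreplicates: int,
        boot_config: Optional[SearchConfig],
        seed: int,
    ):
        self.matrix = matrix
        self.config = config
        self.engine = engine
        self.n_pseudoreplicates = n_pseudoreplicates
        self.boot_config = boot_config
        self.seed = seed
        self._base: Optional[TreeSet] = None
        self._consensus: Optional[PhyloTree] = None
        self._boot: Optional[BootstrapSupport] = None
        self._bremer_cache: Dict[Bipartition, int] = {}

    @property
    def base(self) -> TreeSet:
        if self._base is None:
            if self.engine == "exhaustive":
                self._base = exhaustive_search(self.matrix)
            else:
                from dataclasses import replace

                self._base = heuristic_search(
                    self.matrix, replace(self.config, seed=self.seed)
                )
        return self._base

    @property
    def consensus(self) -> PhyloTree:
        if self._consensus is None:
            self._consensus = strict_consensus(self.base.trees)
        return self._consensus

    @property
    def boot(self) -> BootstrapSupport:
        if self._boot is None:
            self._boot = bootstrap_support(
                self.matrix,
                self.n_pseudoreplicates,
                seed=derive_seed(self.seed, "bootstrap"),
                search_config=self.boot_config,
            )
        return self._boot

    def support(self, clade: Bipartition, basis: str) -> float:
        """Clade support under this analysis; 0 if absent from the consensus."""
        if clade not in self.consensus.bipartitions():
            return 0.0
        if basis == "bremer":
            if clade not in self._bremer_cache:
                from dataclasses import replace

                cfg = replace(self.config, seed=derive_seed(self.seed, "bremer", clade.restrict_key()))
                self._bremer_cache[clade] = bremer_support(
                    self.matrix,
                    clade,
                    cfg,
                    engine="exhaustive" if self.engine == "exhaustive" else "constrained",
                    base=self.base,
                )
            return float(self._bremer_cache[clade])
        if basis == "bootstrap":
            return self.boot.pct(clade)
        raise ValueError(f"unknown basis {basis!r}")


CladeSpec = Union[Bipartition, Iterable[str]]


def _terminals_of(clade: CladeSpec, taxa: Iterable[str]) -> FrozenSet[str]:
    if isinstance(clade, Bipartition):
        return clade.side
    terms = frozenset(clade)
    unknown = terms - frozenset(taxa)
    if unknown:
        raise TreeError(f"clade references unknown taxa: {sorted(unknown)}")
    return terms


class MetricsRunner:
    """Shared machinery behind :func:`cs_metric`, :func:`cd_metric` and
    :func:`contribution_table` — one cached analysis per (type, mode)."""

    def __init__(
        self,
        matrix: CharacterMatrix,
        partition: CharacterPartition,
        config: Optional[SearchConfig] = None,
        engine: str = "heuristic",
        n_pseudoreplicates: int = 100,
        boot_config: Optional[SearchConfig] = None,
        seed: int = 0,
        include_stem: bool = False,
    ):
        if partition.n_chars != matrix.n_chars:
            raise SearchError("partition does not cover the matrix")
        self.matrix = matrix
        self.partition = partition
        self.config = config or PRESETS["fast"]
        self.engine = engine
        self.n_pseudoreplicates = n_pseudoreplicates
        self.boot_config = boot_config
        self.seed = seed
        self.include_stem = include_stem
        self._runs: Dict[Tuple[str, str], _PartitionRun] = {}

    def run(self, type_name: str, mode: str) -> _PartitionRun:
        key = (type_name, mode)
        if key not in self._runs:
            sub = subset_matrix(self.matrix, self.partition, type_name, mode)
            self._runs[key] = _PartitionRun(
                sub,
                self.config,
                self.engine,
                self.n_pseudoreplicates,
                self.boot_config,
                seed=derive_seed(self.seed, type_name, mode),
            )
        return self._runs[key]

    def _bipartition(self, terminals: FrozenSet[str]) -> Bipartition:
        return Bipartition(terminals, frozenset(self.matrix.taxa))

    def cs(
        self, type_name: str, clade: CladeSpec, basis: str, clade_name: Optional[str] = None
    ) -> MetricResult:
        terms = _terminals_of(clade, self.matrix.taxa)
        bp = self._bipartition(terms)
        s_plus = self.run(type_name, "include").support(bp, basis)
        s_minus = self.run(type_name, "exclude").support(bp, basis)
        return MetricResult(
            clade=bp,
            clade_name=clade_name,
            type_name=type_name,
            basis=basis,
            metric="cs",
            s_plus=s_plus,
            s_minus=s_minus,
            cs=s_plus - s_minus,
            n=len(terms),
        )

    def cd(
        self, type_name: str, clade: CladeSpec, basis: str, clade_name: Optional[str] = None
    ) -> MetricResult:
        terms = _terminals_of(clade, self.matrix.taxa)
        bp = self._bipartition(terms)
        n = len(terms)
        if n < 2:
            raise TreeError("a clade needs at least 2 terminal taxa")
        if n == 2:
            d_plus = d_minus = 0.0
        else:
            d_plus = self._within(type_name, "include", terms, basis)
            d_minus = self._within(type_name, "exclude", terms, basis)
        return MetricResult(
            clade=bp,
            clade_name=clade_name,
            type_name=type_name,
            basis=basis,
            metric="cd",
            d_plus=d_plus,
            d_minus=d_minus,
            n=n,
            cd=(d_plus - d_minus) / (n - 1),
        )

    def _within(
        self, type_name: str, mode: str, terms: FrozenSet[str], basis: str
    ) -> float:
        run = self.run(type_name, mode)
        total = 0.0
        for bp in run.consensus.bipartitions():
            inner = None
            if bp.side < terms or (self.include_stem and bp.side == terms):
                inner = bp.side
            elif bp.other_side < terms or (self.include_stem and bp.other_side == terms):
                inner = bp.other_side
            if inner is None:
                continue
            total += run.support(bp, basis)
        return total

    def table(
        self,
        clades: Union[Mapping[str, Iterable[str]], Sequence[Tuple[str, Iterable[str]]]],
        bases: Sequence[str] = BASES,
    ) -> pd.DataFrame:
        if isinstance(clades, Mapping):
            items = list(clades.items())
        else:
            items = list(clades)
        rows: List[dict] = []
        for name, terminals in items:
            terms = frozenset(terminals)
            for type_name in self.partition.type_names:
                for basis in bases:
                    for metric_fn in (self.cs, self.cd):
                        r = metric_fn(type_name, terms, basis, clade_name=name)
                        rows.append(
                            {
                                "clade": name,
                                "terminals": ",".join(sorted(terms)),
                                "type": type_name,
                                "basis": basis,
                                "metric": r.metric,
                                "plus": r.s_plus if r.metric == "cs" else r.d_plus,
                                "minus": r.s_minus if r.metric == "cs" else r.d_minus,
                                "n": r.n,
                                "value": r.value,
                                "positive": r.positive,
                            }
                        )
        df = pd.DataFrame(
            rows,
            columns=[
                "clade", "terminals", "type", "basis", "metric",
                "plus", "minus", "n", "value", "positive",
            ],
        )
        if len(df):
            overall = (
                df.groupby(["clade", "type", "metric"])["positive"]
                .any()
                .rename("positive_overall")
            )
            df = df.merge(overall, on=["clade", "type", "metric"], how="left")
        else:
            df["positive_overall"] = pd.Series(dtype=bool)
        return df


# -- thin functional wrappers ---------------------------------------------------------


def clade_support_under_partition(
    matrix: CharacterMatrix,
    partition: CharacterPartition,
    type_name: str,
    mode: str,
    clade: CladeSpec,
    basis: str = "bremer",
    config: Optional[SearchConfig] = None,
    engine: str = "heuristic",
    n_pseudoreplicates: int = 100,
    seed: int = 0,
) -> float:
    """Support of a clade after restricting the matrix to (or away from)
    one character type; 0 when the clade drops out of the strict consensus."""
    runner = MetricsRunner(
        matrix, partition, config=config, engine=engine,
        n_pseudoreplicates=n_pseudoreplicates, seed=seed,
    )
    terms = _terminals_of(clade, matrix.taxa)
    bp = Bipartition(terms, frozenset(matrix.taxa))
    return runner.run(type_name, mode).support(bp, basis)


def cs_metric(
    matrix: CharacterMatrix,
    partition: CharacterPartition,
    type_name: str,
    clade: CladeSpec,
    basis: str = "bremer",
    config: Optional[SearchConfig] = None,
    engine: str = "heuristic",
    n_pseudoreplicates: int = 100,
    seed: int = 0,
) -> MetricResult:
    runner = MetricsRunner(
        matrix, partition, config=config, engine=engine,
        n_pseudoreplicates=n_pseudoreplicates, seed=seed,
    )
    return runner.cs(type_name, clade, basis)


def cd_metric(
    matrix: CharacterMatrix,
    partition: CharacterPartition,
    type_name: str,
    clade: CladeSpec,
    basis: str = "bremer",
    config: Optional[SearchConfig] = None,
    engine: str = "heuristic",
    n_pseudoreplicates: int = 100,
    seed: int = 0,
    include_stem: bool = False,
) -> MetricResult:
    runner = MetricsRunner(
        matrix, partition, config=config, engine=engine,
        n_pseudoreplicates=n_pseudoreplicates, seed=seed, include_stem=include_stem,
    )
    return runner.cd(type_name, clade, basis)


def contribution_table(
    matrix: CharacterMatrix,
    partition: CharacterPartition,
    clades: Union[Mapping[str, Iterable[str]], Sequence[Tuple[str, Iterable[str]]]],
    config: Optional[SearchConfig] = None,
    engine: str = "heuristic",
    bases: Sequence[str] = BASES,
    n_pseudoreplicates: int = 100,
    seed: int = 0,
    include_stem: bool = False,
) -> pd.DataFrame:
    """Long-format Cs/Cd table over clades x types x bases.

    Columns: clade, terminals, type, basis, metric (cs|cd), plus, minus,
    n, value, positive, positive_overall (any-positive across bases).
    """
    runner = MetricsRunner(
        matrix, partition, config=config, engine=engine,
        n_pseudoreplicates=n_pseudoreplicates, seed=seed, include_stem=include_stem,
    )
    return runner.table(clades, bases=bases)
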