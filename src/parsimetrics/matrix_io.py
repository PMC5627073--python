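"""Character matrices, character-type partitions, and NEXUS I/O.

Characters are discrete, unordered (non-additive) and equally weighted,
with states drawn from the NEXUS SYMBOLS list (default ``0123456789``).
Missing data ('?') and gaps ('-') are both treated as "state unknown":
at a leaf they stand for the full set of states observed in that
character column.  Polymorphic cells like ``(01)`` are kept as the
corresponding restricted state set.

Internally each cell is a bitmask over symbol positions (bit ``s`` set
iff state ``s`` is possible); a mask of 0 encodes "unknown".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import dendropy

from .errors import MatrixValidationError, NexusParseError, PartitionError

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "CharacterPartition",
    "read_nexus",
    "write_nexus",
    "read_partition",
    "partition_from_ranges",
    "subset_matrix",
    "write_tsv",
]

#: sentinel for an unknown state in user-facing state grids
MISSING = -1

DEFAULT_SYMBOLS = "0123456789"

StateLike = Union[int, None, Iterable[int]]


def _mask_of(state: StateLike) -> int:
    if state is None or state == MISSING:
        return 0
    if isinstance(state, (int, np.integer)):
        if state < 0:
            raise MatrixValidationError(f"negative state code {state}")
        return 1 << int(state)
    mask = 0
    for s in state:
        if s < 0:
            raise MatrixValidationError(f"negative state code {s} in ambiguity set")
        mask |= 1 << int(s)
    return mask


class CharacterMatrix:
    """Taxa x characters grid of unordered discrete states.

    Parameters
    ----------
    taxa
        Ordered, unique, non-empty taxon labels.
    masks
        ``(n_taxa, n_chars)`` uint16 array of state bitmasks; 0 = unknown.
    char_indices
        Original (0-based) column indices, kept through subsetting so a
        column can always be traced back to its position in the source
        matrix.
    """

    __slots__ = ("taxa", "masks", "char_indices", "symbols", "_alphabet", "_expanded")

    def __init__(
        self,
        taxa: Sequence[str],
        masks: np.ndarray,
        char_indices: Optional[Sequence[int]] = None,
        symbols: str = DEFAULT_SYMBOLS,
    ):
        taxa = tuple(taxa)
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon labels: {dupes}")
        if any(not t for t in taxa):
            raise MatrixValidationError("empty taxon label")
        masks = np.asarray(masks, dtype=np.uint16)
        if masks.ndim != 2 or masks.shape[0] != len(taxa):
            raise MatrixValidationError(
                f"state grid shape {masks.shape} does not match {len(taxa)} taxa"
            )
        if masks.shape[1] == 0:
            raise MatrixValidationError("matrix has no characters")
        self.taxa = taxa
        self.masks = masks
        self.symbols = symbols
        if char_indices is None:
            char_indices = range(masks.shape[1])
        self.char_indices = tuple(int(i) for i in char_indices)
        if len(self.char_indices) != masks.shape[1]:
            raise MatrixValidationError("char_indices length does not match columns")
        alphabet = np.bitwise_or.reduce(masks, axis=0)
        if np.any(alphabet == 0):
            bad = [self.char_indices[j] for j in np.nonzero(alphabet == 0)[0]]
            raise MatrixValidationError(f"characters {bad} contain only missing data")
        self._alphabet = alphabet.astype(np.uint16)
        self._expanded: Optional[np.ndarray] = None

    # -- constructors ----------------------------------------------------------

    @classmethod
    def from_states(
        cls,
        taxa: Sequence[str],
        rows: Sequence[Sequence[StateLike]],
        char_indices: Optional[Sequence[int]] = None,
        symbols: str = DEFAULT_SYMBOLS,
    ) -> "CharacterMatrix":
        """Build from per-taxon rows of ints, ``None``/``MISSING`` or state sets."""
        if len(rows) != len(taxa):
            raise MatrixValidationError("one row per taxon required")
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise MatrixValidationError(f"ragged rows: widths {sorted(widths)}")
        masks = np.array(
            [[_mask_of(s) for s in row] for row in rows], dtype=np.uint16
        )
        return cls(taxa, masks, char_indices, symbols)

    # -- accessors -------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.masks.shape[1]

    @property
    def column_alphabets(self) -> np.ndarray:
        """Per-column bitmask of all states observed in that column."""
        return self._alphabet

    def expanded_masks(self) -> np.ndarray:
        """Leaf masks with unknown cells expanded to the column's alphabet."""
        if self._expanded is None:
            exp = self.masks.copy()
            missing = exp == 0
            exp[missing] = np.broadcast_to(self._alphabet, exp.shape)[missing]
            self._expanded = exp
        return self._expanded

    def states(self) -> np.ndarray:
        """Int grid: state code, ``MISSING`` for unknown, ``-2`` for polymorphic."""
        out = np.full(self.masks.shape, MISSING, dtype=np.int16)
        m = self.masks.astype(np.int64)
        single = (m != 0) & ((m & (m - 1)) == 0)
        out[single] = np.log2(m[single]).astype(np.int16)
        out[(m != 0) & ~single] = -2
        return out

    def cell_symbol(self, i: int, j: int) -> str:
        mask = int(self.masks[i, j])
        if mask == 0:
            return "?"
        states = [s for s in range(16) if mask >> s & 1]
        if len(states) == 1:
            return self.symbols[states[0]]
        return "(" + "".join(self.symbols[s] for s in states) + ")"

    def take_columns(self, cols: Sequence[int]) -> "CharacterMatrix":
        cols = list(cols)
        if not cols:
            raise MatrixValidationError("resulting matrix would have 0 characters")
        return CharacterMatrix(
            self.taxa,
            self.masks[:, cols],
            [self.char_indices[c] for c in cols],
            self.symbols,
        )

    def take_taxa(self, names: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in names]
        return CharacterMatrix(names, self.masks[idx, :], self.char_indices, self.symbols)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.masks.shape == other.masks.shape
            and bool(np.all(self.masks == other.masks))
        )

    def __repr__(self) -> str:
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_chars} characters)"


@dataclass(frozen=True)
class CharacterPartition:
    """Total, disjoint assignment of character indices to named types."""

    type_names: Tuple[str, ...]
    assignment: Mapping[int, str]

    def __post_init__(self):
        names = self.type_names
        if len(set(names)) != len(names):
            raise PartitionError("duplicate type names")
        seen = set(self.assignment.values())
        missing_types = [t for t in names if t not in seen]
        if missing_types:
            raise PartitionError(f"empty character types: {missing_types}")
        unknown = sorted(seen - set(names))
        if unknown:
            raise PartitionError(f"assignment refers to unlisted types: {unknown}")
        n = len(self.assignment)
        idx = sorted(self.assignment)
        if idx != list(range(n)):
            gaps = sorted(set(range(max(idx) + 1)) - set(idx)) if idx else []
            raise PartitionError(
                f"assignment is not total over 0..{max(idx) if idx else 0}: unassigned {gaps}"
            )

    @property
    def n_chars(self) -> int:
        return len(self.assignment)

    def indices(self, type_name: str) -> List[int]:
        if type_name not in self.type_names:
            raise PartitionError(f"unknown character type {type_name!r}")
        return sorted(i for i, t in self.assignment.items() if t == type_name)

    def sizes(self) -> Dict[str, int]:
        return {t: len(self.indices(t)) for t in self.type_names}


def partition_from_ranges(
    ranges: Mapping[str, Sequence[Tuple[int, int]]], n_chars: int
) -> CharacterPartition:
    """Build a partition from named 0-based inclusive index ranges.

    Every index in ``0..n_chars-1`` must be covered exactly once.
    """
    assignment: Dict[int, str] = {}
    for name, spans in ranges.items():
        for lo, hi in spans:
            if lo > hi:
                raise PartitionError(f"empty range {lo}-{hi} for type {name!r}")
            if hi >= n_chars:
                raise PartitionError(
                    f"range {lo}-{hi} for type {name!r} exceeds matrix width {n_chars}"
                )
            for i in range(lo, hi + 1):
                if i in assignment:
                    raise PartitionError(
                        f"character {i} assigned to both {assignment[i]!r} and {name!r}"
                    )
                assignment[i] = name
    unassigned = sorted(set(range(n_chars)) - set(assignment))
    if unassigned:
        raise PartitionError(f"indices unassigned to any type: {unassigned}")
    return CharacterPartition(tuple(ranges.keys()), assignment)


# -- NEXUS I/O ------------------------------------------------------------------


def read_nexus(path: str) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    '?' and '-' map to unknown; other symbols map to integer codes by
    their position in the FORMAT SYMBOLS list (default ``0123456789``).
    Interleaved and non-interleaved layouts are both accepted.
    """
    _precheck_duplicate_taxa(path)
    try:
        cm = dendropy.StandardCharacterMatrix.get(
            path=path, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise NexusParseError(f"NEXUS parse failed for {path}: {exc}") from exc
    sa = cm.default_state_alphabet
    declared = [s.symbol for s in sa.fundamental_state_iter() if s.symbol not in "-?"]
    code_of = {sym: i for i, sym in enumerate(declared)}
    full = frozenset(declared)
    taxa = [t.label for t in cm.taxon_namespace]
    lengths = {len(cm[t]) for t in cm.taxon_namespace}
    if len(lengths) > 1:
        raise MatrixValidationError(f"ragged matrix: row lengths {sorted(lengths)}")
    rows: List[List[int]] = []
    for t in cm.taxon_namespace:
        row = []
        for cell in cm[t]:
            fund = {s.symbol for s in cell.fundamental_states} - {"-", "?"}
            if not fund or fund >= full:
                row.append(0)  # unknown
            else:
                mask = 0
                for sym in fund:
                    if sym not in code_of:
                        raise MatrixValidationError(
                            f"symbol {sym!r} outside declared SYMBOLS"
                        )
                    mask |= 1 << code_of[sym]
                row.append(mask)
        rows.append(row)
    symbols = "".join(declared) if declared else DEFAULT_SYMBOLS
    return CharacterMatrix(taxa, np.array(rows, dtype=np.uint16), symbols=symbols)


def _precheck_duplicate_taxa(path: str) -> None:
    """dendropy folds repeated labels into one taxon; catch them up front."""
    try:
        with open(path, "r") as fh:
            text = fh.read()
    except OSError as exc:
        raise NexusParseError(f"cannot read {path}: {exc}") from exc
    m = re.search(r"\bMATRIX\b(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return
    labels = []
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line or line.startswith("["):
            continue
        if line.startswith("'"):
            end = line.find("'", 1)
            if end > 0:
                labels.append(line[1:end])
        else:
            labels.append(line.split()[0])
    # interleaved files repeat each label the same number of times; a
    # genuine duplicate shows up as unequal repetition counts or as
    # duplicates within the first block
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if counts and len(set(counts.values())) == 1:
        return
    dupes = sorted(lab for lab, c in counts.items() if c > min(counts.values()))
    if dupes:
        raise MatrixValidationError(f"duplicate taxon labels in MATRIX: {dupes}")


def write_nexus(
    matrix: CharacterMatrix,
    path: str,
    partition: Optional[CharacterPartition] = None,
) -> None:
    """Write the matrix (and optional SETS charsets) as NEXUS."""
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        f"    FORMAT DATATYPE=STANDARD SYMBOLS=\"{matrix.symbols}\" MISSING=? GAP=-;",
        "    MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        cells = "".join(matrix.cell_symbol(i, j) for j in range(matrix.n_chars))
        label = f"'{taxon}'" if " " in taxon else taxon
        lines.append(f"    {label:<{width}} {cells}")
    lines += ["    ;", "END;"]
    if partition is not None:
        if partition.n_chars != matrix.n_chars:
            raise PartitionError("partition width does not match matrix")
        lines += ["", "BEGIN SETS;"]
        for name in partition.type_names:
            spans = _as_spans(partition.indices(name))
            spec = " ".join(
                f"{lo + 1}-{hi + 1}" if lo != hi else f"{lo + 1}" for lo, hi in spans
            )
            lines.append(f"    charset {name} = {spec};")
        lines += ["END;"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _as_spans(indices: Sequence[int]) -> List[Tuple[int, int]]:
    spans: List[Tuple[int, int]] = []
    for i in indices:
        if spans and i == spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], i)
        else:
            spans.append((i, i))
    return spans


_CHARSET_RE = re.compile(
    r"^\s*charset\s+(\S+)\s*=\s*([-0-9,\s]+?)\s*;?\s*$", re.IGNORECASE
)


def read_partition(path: str, n_chars: int) -> CharacterPartition:
    """Read a character-type partition.

    Two dialects are accepted:

    * NEXUS ``charset`` lines (inside or outside a SETS block), with the
      standard 1-based inclusive ranges: ``charset copulatory = 117-190;``
    * a plain two-column text dialect with 0-based inclusive ranges:
      ``copulatory<TAB>116-189`` (several comma-separated ranges allowed).

    Every character index ``0..n_chars-1`` must be assigned to exactly one
    type; unlisted indices are an error, never a silent default type.
    """
    with open(path, "r") as fh:
        text = fh.read()
    is_nexus = text.lstrip().upper().startswith("#NEXUS") or re.search(
        r"^\s*charset\b", text, re.IGNORECASE | re.MULTILINE
    )
    ranges: Dict[str, List[Tuple[int, int]]] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "[")):
            continue
        if is_nexus:
            m = _CHARSET_RE.match(stripped)
            if not m:
                continue
            name, spec = m.group(1), m.group(2)
            offset = 1  # NEXUS is 1-based
        else:
            parts = re.split(r"[\t ]+", stripped, maxsplit=1)
            if len(parts) != 2:
                raise PartitionError(f"cannot parse partition line: {line!r}")
            name, spec = parts
            offset = 0
        spans = ranges.setdefault(name, [])
        for token in re.split(r"[,\s]+", spec.strip()):
            if not token:
                continue
            if "-" in token:
                lo_s, hi_s = token.split("-", 1)
                lo, hi = int(lo_s) - offset, int(hi_s) - offset
            else:
                lo = hi = int(token) - offset
            spans.append((lo, hi))
    if not ranges:
        raise PartitionError(f"no character sets found in {path}")
    return partition_from_ranges(ranges, n_chars)


def subset_matrix(
    matrix: CharacterMatrix,
    partition: CharacterPartition,
    type_name: str,
    mode: str = "include",
) -> CharacterMatrix:
    """Keep only (``include``) or all but (``exclude``) one type's characters."""
    if partition.n_chars != matrix.n_chars:
        raise PartitionError(
            f"partition covers {partition.n_chars} characters, matrix has {matrix.n_chars}"
        )
    wanted = set(partition.indices(type_name))
    if mode == "include":
        cols = [j for j in range(matrix.n_chars) if j in wanted]
    elif mode == "exclude":
        cols = [j for j in range(matrix.n_chars) if j not in wanted]
    else:
        raise ValueError(f"mode must be 'include' or 'exclude', got {mode!r}")
    return matrix.take_columns(cols)


def write_tsv(matrix: CharacterMatrix, path: str) -> None:
    """Debug export: one row per taxon, one symbol column per character."""
    with open(path, "w") as fh:
        header = "taxon\t" + "\t".join(f"c{idx}" for idx in matrix.char_indices)
        fh.write(header + "\n")
        for i, taxon in enumerate(matrix.taxa):
            cells = "\t".join(matrix.cell_symbol(i, j) for j in range(matrix.n_chars))
            fh.write(f"{taxon}\t{cells}\n")
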