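import numpy as np
import pytest

from parsimetrics import (
    MISSING,
    CharacterMatrix,
    CharacterPartition,
    read_nexus,
    read_partition,
    subset_matrix,
    write_nexus,
)
from parsimetrics.errors import MatrixValidationError, NexusParseError, PartitionError
from parsimetrics.matrix_io import partition_from_ranges, write_tsv


class TestReadNexus:
    def test_toy_matrix_dimensions_and_states(self, toy_nexus):
        m = read_nexus(str(toy_nexus))
        assert m.n_taxa == 4 and m.n_chars == 3
        assert m.taxa == ("taxA", "taxB", "taxC", "taxD")
        states = m.states()
        assert states[0].tolist() == [0, 0, 1]
        assert states[3].tolist() == [1, 1, 0]

    def test_question_mark_is_missing(self, toy_nexus):
        m = read_nexus(str(toy_nexus))
        assert m.states()[2, 1] == MISSING
        assert int(m.masks[2, 1]) == 0

    def test_gap_treated_as_missing(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=2;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
a 0-
b 01
c 10
d 1?
;
END;
"""
        p = tmp_path / "gap.nex"
        p.write_text(text)
        m = read_nexus(str(p))
        assert m.states()[0, 1] == MISSING
        assert m.states()[3, 1] == MISSING

    def test_polymorphic_cell_is_state_set(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=2;
FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=?;
MATRIX
a 0(01)
b 01
c 12
d 20
;
END;
"""
        p = tmp_path / "poly.nex"
        p.write_text(text)
        m = read_nexus(str(p))
        assert int(m.masks[0, 1]) == 0b011  # states {0, 1}

    def test_interleaved_equals_sequential(self, tmp_path):
        seq = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=4;
FORMAT DATATYPE=STANDARD SYMBOLS="01";
MATRIX
a 0011
b 0110
c 1100
;
END;
"""
        inter = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=4;
FORMAT DATATYPE=STANDARD SYMBOLS="01" INTERLEAVE;
MATRIX
a 00
b 01
c 11

a 11
b 10
c 00
;
END;
"""
        p1, p2 = tmp_path / "s.nex", tmp_path / "i.nex"
        p1.write_text(seq)
        p2.write_text(inter)
        assert read_nexus(str(p1)) == read_nexus(str(p2))

    def test_ragged_rows_rejected(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
FORMAT SYMBOLS="01";
MATRIX
a 00
b 011
;
END;
"""
        p = tmp_path / "ragged.nex"
        p.write_text(text)
        with pytest.raises((NexusParseError, MatrixValidationError)):
            read_nexus(str(p))

    def test_duplicate_taxon_rejected(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
FORMAT SYMBOLS="01";
MATRIX
a 00
a 11
;
END;
"""
        p = tmp_path / "dup.nex"
        p.write_text(text)
        with pytest.raises((NexusParseError, MatrixValidationError)):
            read_nexus(str(p))

    def test_symbol_outside_declared_alphabet_rejected(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
FORMAT SYMBOLS="01";
MATRIX
a 02
b 11
;
END;
"""
        p = tmp_path / "bad.nex"
        p.write_text(text)
        with pytest.raises((NexusParseError, MatrixValidationError)):
            read_nexus(str(p))

    def test_malformed_block_names_problem(self, tmp_path):
        p = tmp_path / "broken.nex"
        p.write_text("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2;\nMATRIX a 0")
        with pytest.raises(NexusParseError):
            read_nexus(str(p))


class TestWriteNexus:
    def test_round_trip_exact(self, tmp_path):
        m = CharacterMatrix.from_states(
            ["sp one", "sp_two", "sp3"],
            [[0, 1, None], [1, {0, 1}, 2], [2, 0, 0]],
            symbols="012",
        )
        path = tmp_path / "rt.nex"
        write_nexus(m, str(path))
        back = read_nexus(str(path))
        assert back.taxa == m.taxa
        assert np.array_equal(back.masks, m.masks)

    def test_round_trip_with_partition(self, tmp_path):
        m = CharacterMatrix.from_states(["a", "b", "c"], [[0, 1, 0], [1, 0, 1], [0, 0, 1]])
        part = partition_from_ranges({"general": [(0, 1)], "photophores": [(2, 2)]}, 3)
        path = tmp_path / "rtp.nex"
        write_nexus(m, str(path), partition=part)
        back_part = read_partition(str(path), 3)
        assert back_part.sizes() == {"general": 2, "photophores": 1}

    def test_all_missing_column_rejected(self):
        with pytest.raises(MatrixValidationError, match="missing"):
            CharacterMatrix.from_states(["a", "b"], [[0, None], [1, None]])

    def test_tsv_export(self, tmp_path):
        m = CharacterMatrix.from_states(["a", "b"], [[0, None], [1, 1]])
        path = tmp_path / "m.tsv"
        write_tsv(m, str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "taxon\tc0\tc1"
        assert lines[1] == "a\t0\t?"


class TestPartition:
    # the printed three-type layout: 116 general external, 74 copulatory,
    # 59 photophore characters over a 249-character matrix
    RANGES = {"general": [(0, 115)], "copulatory": [(116, 189)], "photophores": [(190, 248)]}

    def test_three_type_partition_valid(self):
        part = partition_from_ranges(self.RANGES, 249)
        assert part.sizes() == {"general": 116, "copulatory": 74, "photophores": 59}

    def test_unassigned_indices_rejected(self):
        with pytest.raises(PartitionError, match="unassigned"):
            partition_from_ranges(self.RANGES, 253)

    def test_single_type_covering_everything(self):
        part = partition_from_ranges({"all": [(0, 9)]}, 10)
        assert part.sizes() == {"all": 10}

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(PartitionError, match="both"):
            partition_from_ranges({"a": [(0, 5)], "b": [(5, 9)]}, 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(PartitionError, match="exceeds"):
            partition_from_ranges({"a": [(0, 10)]}, 10)

    def test_empty_type_rejected(self):
        with pytest.raises(PartitionError):
            CharacterPartition(("a", "b"), {0: "a", 1: "a"})

    def test_text_dialect_zero_based(self, tmp_path):
        p = tmp_path / "parts.txt"
        p.write_text("general\t0-3\ncopulatory\t4-5,7\nphotophores\t6\n")
        part = read_partition(str(p), 8)
        assert part.indices("copulatory") == [4, 5, 7]
        assert part.indices("photophores") == [6]

    def test_nexus_charset_one_based(self, tmp_path):
        p = tmp_path / "parts.nex"
        p.write_text("#NEXUS\nBEGIN SETS;\ncharset left = 1-2;\ncharset right = 3-4;\nEND;\n")
        part = read_partition(str(p), 4)
        assert part.indices("left") == [0, 1]
        assert part.indices("right") == [2, 3]

    def test_no_sets_found(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("\n")
        with pytest.raises(PartitionError):
            read_partition(str(p), 4)


class TestSubsetMatrix:
    def make(self, n_chars=249):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(4, n_chars))
        rows[0] = 0  # avoid all-missing; keep deterministic content
        return CharacterMatrix.from_states(
            ["a", "b", "c", "d"], rows.tolist()
        )

    def test_include_exclude_sizes(self):
        m = self.make()
        part = partition_from_ranges(TestPartition.RANGES, 249)
        inc = subset_matrix(m, part, "photophores", "include")
        exc = subset_matrix(m, part, "photophores", "exclude")
        assert inc.n_chars == 59
        assert exc.n_chars == 190

    def test_include_exclude_partition_columns(self):
        m = self.make(12)
        part = partition_from_ranges({"x": [(0, 5)], "y": [(6, 11)]}, 12)
        for t in ("x", "y"):
            inc = subset_matrix(m, part, t, "include")
            exc = subset_matrix(m, part, t, "exclude")
            assert set(inc.char_indices) & set(exc.char_indices) == set()
            assert sorted(set(inc.char_indices) | set(exc.char_indices)) == list(range(12))

    def test_original_indices_retained(self):
        m = self.make(10)
        part = partition_from_ranges({"x": [(0, 3)], "y": [(4, 9)]}, 10)
        inc = subset_matrix(m, part, "y", "include")
        assert inc.char_indices == tuple(range(4, 10))

    def test_unknown_type(self):
        m = self.make(10)
        part = partition_from_ranges({"x": [(0, 9)]}, 10)
        with pytest.raises(PartitionError):
            subset_matrix(m, part, "zz", "include")

    def test_empty_result_rejected(self):
        m = self.make(10)
        part = partition_from_ranges({"x": [(0, 9)]}, 10)
        with pytest.raises(MatrixValidationError):
            subset_matrix(m, part, "x", "exclude")

    def test_width_mismatch_rejected(self):
        m = self.make(10)
        part = partition_from_ranges({"x": [(0, 8)]}, 9)
        with pytest.raises(PartitionError):
            subset_matrix(m, part, "x", "include")
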