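import numpy as np
import pytest

from parsimetrics import (
    CharacterMatrix,
    FixtureSpec,
    PRESETS,
    SearchConfig,
    TypePlan,
    bremer_support,
    cd_metric,
    clade_support_under_partition,
    contribution_table,
    cs_metric,
    parse_newick,
    plant_matrix,
)
from parsimetrics.errors import TreeError
from parsimetrics.matrix_io import partition_from_ranges
from tests.conftest import driver_fixture


class TestCladeSupportUnderPartition:
    def test_driver_type_carries_all_signal(self):
        matrix, partition, focal, _ = driver_fixture(seed=2)
        inc = clade_support_under_partition(
            matrix, partition, "general", "include", focal,
            basis="bremer", engine="exhaustive",
        )
        full = bremer_support(matrix, focal, engine="exhaustive")
        assert inc == full  # non-driver columns are irrelevant to this clade

    def test_excluding_driver_type_collapses_clade(self):
        matrix, partition, focal, _ = driver_fixture(seed=2)
        exc = clade_support_under_partition(
            matrix, partition, "general", "exclude", focal,
            basis="bremer", engine="exhaustive",
        )
        assert exc == 0.0

    def test_single_type_include_recovers_unpartitioned_pipeline(self):
        matrix, _, focal, _ = driver_fixture(seed=5)
        whole = partition_from_ranges({"all": [(0, matrix.n_chars - 1)]}, matrix.n_chars)
        inc = clade_support_under_partition(
            matrix, whole, "all", "include", focal, basis="bremer", engine="exhaustive"
        )
        assert inc == bremer_support(matrix, focal, engine="exhaustive")


class TestCsMetric:
    def test_cs_is_exactly_s_plus_minus_s_minus(self):
        matrix, partition, focal, _ = driver_fixture(seed=7)
        for type_name in partition.type_names:
            r = cs_metric(matrix, partition, type_name, focal,
                          basis="bremer", engine="exhaustive")
            assert r.cs == r.s_plus - r.s_minus

    def test_driver_positive_others_nonpositive(self):
        matrix, partition, focal, _ = driver_fixture(seed=3)
        values = {
            t: cs_metric(matrix, partition, t, focal, basis="bremer",
                         engine="exhaustive")
            for t in partition.type_names
        }
        assert values["general"].cs > 0 and values["general"].positive
        for t in ("copulatory", "photophores"):
            assert values[t].cs <= 0 and not values[t].positive

    def test_equal_support_means_zero_not_positive(self):
        # same clade signal planted in two types -> excluding either still
        # leaves the other half, S+ == S- and cs == 0
        tree = parse_newick("(((A,B),C),((D,E),F));")
        spec = FixtureSpec(
            n_taxa=6,
            plans=(TypePlan("general", ("A", "B"), 2),
                   TypePlan("copulatory", ("A", "B"), 2)),
            tree=tree, background_constant=2, seed=0,
        )
        matrix, partition, _ = plant_matrix(spec)
        r = cs_metric(matrix, partition, "general", ("A", "B"),
                      basis="bremer", engine="exhaustive")
        assert r.s_plus == r.s_minus == 2
        assert r.cs == 0 and not r.positive

    def test_uninformative_type_gives_minus_full_support(self):
        # photophores holds only constant fillers -> S+ = 0, S- = full support
        tree = parse_newick("(((A,B),C),((D,E),F));")
        spec = FixtureSpec(
            n_taxa=6,
            plans=(TypePlan("general", ("A", "B"), 3),),
            tree=tree, background_constant=3, seed=0,
        )
        matrix, partition, _ = plant_matrix(spec)
        full = bremer_support(matrix, ("A", "B"), engine="exhaustive")
        r = cs_metric(matrix, partition, "photophores", ("A", "B"),
                      basis="bremer", engine="exhaustive")
        assert r.s_plus == 0
        assert r.cs == -full <= 0

    def test_invariant_under_type_relabel_and_column_shuffle(self):
        matrix, partition, focal, _ = driver_fixture(seed=11)
        base = cs_metric(matrix, partition, "general", focal,
                         basis="bremer", engine="exhaustive").cs
        # shuffle columns within each type, rename the types
        rng = np.random.default_rng(1)
        new_order = []
        for t in partition.type_names:
            idx = partition.indices(t)
            new_order.extend(rng.permutation(idx).tolist())
        shuffled = matrix.take_columns(new_order)
        renamed = partition_from_ranges(
            {
                "X" + t: [(start, start + len(partition.indices(t)) - 1)]
                for t, start in zip(
                    partition.type_names,
                    np.cumsum([0] + [len(partition.indices(t))
                                     for t in partition.type_names[:-1]]).tolist(),
                )
            },
            matrix.n_chars,
        )
        again = cs_metric(shuffled, renamed, "Xgeneral", focal,
                          basis="bremer", engine="exhaustive").cs
        assert again == base


class TestCdMetric:
    @staticmethod
    def nested_fixture():
        """8 taxa; focal clade ABCD resolved internally by photophore
        characters (two cherries, k=3 each) and held together by general
        characters; copulatory drives an unrelated clade."""
        tree = parse_newick("((((A,B),(C,D)),(E,F)),(G,H));")
        plans = (
            TypePlan("general", ("A", "B", "C", "D"), 3),
            TypePlan("photophores", ("A", "B"), 3),
            TypePlan("photophores", ("C", "D"), 3),
            TypePlan("copulatory", ("E", "F"), 2),
        )
        spec = FixtureSpec(n_taxa=8, plans=plans, tree=tree,
                           background_constant=3, seed=4)
        matrix, partition, _ = plant_matrix(spec)
        return matrix, partition

    def test_cd_arithmetic_and_signs(self):
        matrix, partition = self.nested_fixture()
        focal = ("A", "B", "C", "D")
        r_ph = cd_metric(matrix, partition, "photophores", focal,
                         basis="bremer", engine="exhaustive")
        # only-photophores: both cherries supported at Bremer 3 -> D+ = 6;
        # all-but-photophores: no within-clade resolution -> D- = 0
        assert r_ph.n == 4
        assert r_ph.d_plus == 6.0 and r_ph.d_minus == 0.0
        assert r_ph.cd == pytest.approx((6.0 - 0.0) / 3)
        r_g = cd_metric(matrix, partition, "general", focal,
                        basis="bremer", engine="exhaustive")
        # general holds the stem, not the interior: D+ = 0, D- = 6
        assert r_g.d_plus == 0.0 and r_g.d_minus == 6.0
        assert r_g.cd == pytest.approx(-2.0)

    def test_two_taxon_clade_has_zero_cd(self):
        matrix, partition = self.nested_fixture()
        r = cd_metric(matrix, partition, "photophores", ("A", "B"),
                      basis="bremer", engine="exhaustive")
        assert r.d_plus == 0.0 and r.d_minus == 0.0 and r.cd == 0.0

    def test_include_stem_counts_the_stem_branch(self):
        matrix, partition = self.nested_fixture()
        focal = ("A", "B", "C", "D")
        without = cd_metric(matrix, partition, "general", focal,
                            basis="bremer", engine="exhaustive")
        with_stem = cd_metric(matrix, partition, "general", focal,
                              basis="bremer", engine="exhaustive",
                              include_stem=True)
        # the stem is supported by 3 general synapomorphies in the
        # include-run; counting it moves D+ from 0 to 3
        assert without.d_plus == 0.0
        assert with_stem.d_plus == 3.0

    def test_single_taxon_clade_rejected(self):
        matrix, partition = self.nested_fixture()
        with pytest.raises(TreeError):
            cd_metric(matrix, partition, "general", ("A",), basis="bremer")


class TestContributionTable:
    def test_cardinality_one_clade(self):
        matrix, partition, focal, _ = driver_fixture(seed=13)
        df = contribution_table(
            matrix, partition, {"focal": focal},
            engine="exhaustive", n_pseudoreplicates=30, seed=1,
        )
        assert len(df) == 12  # 1 clade x 3 types x 2 bases x {cs, cd}
        assert (df[df.metric == "cs"].shape[0] == 6
                and df[df.metric == "cd"].shape[0] == 6)

    def test_empty_clade_list(self):
        matrix, partition, _, _ = driver_fixture(seed=13)
        df = contribution_table(matrix, partition, {}, n_pseudoreplicates=5)
        assert len(df) == 0

    def test_positive_pattern_matches_planted_diagonal(self):
        # three clades, each driven by a different type
        tree = parse_newick("((((A,B),C),(D,E)),((F,G),H));")
        plans = (
            TypePlan("general", ("A", "B"), 3),
            TypePlan("copulatory", ("D", "E"), 3),
            TypePlan("photophores", ("F", "G"), 3),
        )
        spec = FixtureSpec(n_taxa=8, plans=plans, tree=tree,
                           background_constant=3, seed=8)
        matrix, partition, _ = plant_matrix(spec)
        clades = {"c1": ("A", "B"), "c2": ("D", "E"), "c3": ("F", "G")}
        df = contribution_table(
            matrix, partition, clades, engine="exhaustive",
            bases=("bremer",), n_pseudoreplicates=10, seed=3,
        )
        cs = df[df.metric == "cs"].set_index(["clade", "type"])["positive"]
        driver_of = {"c1": "general", "c2": "copulatory", "c3": "photophores"}
        for clade, driver in driver_of.items():
            for t in partition.type_names:
                assert cs.loc[(clade, t)] == (t == driver)

    def test_unknown_taxon_in_clade_rejected(self):
        matrix, partition, _, _ = driver_fixture(seed=13)
        with pytest.raises(TreeError):
            contribution_table(matrix, partition, {"bad": ("t0", "nope")},
                               n_pseudoreplicates=5)
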