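import numpy as np
import pytest

from parsimetrics import (
    CharacterMatrix,
    FixtureSpec,
    TypePlan,
    parse_newick,
    plant_matrix,
    random_tree,
)


@pytest.fixture
def quartet_tree():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_matrix():
    return CharacterMatrix.from_states(["A", "B", "C", "D"], [[0], [0], [1], [1]])


@pytest.fixture
def toy_nexus(tmp_path):
    text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=3;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
taxA 001
taxB 011
taxC 0?1
taxD 110
;
END;
"""
    path = tmp_path / "toy.nex"
    path.write_text(text)
    return path


def random_matrix(rng, n_taxa, n_chars, n_states=2, missing_rate=0.0):
    """Seeded random matrix; resamples any all-missing column."""
    while True:
        rows = []
        for _ in range(n_taxa):
            row = []
            for _ in range(n_chars):
                if missing_rate and rng.random() < missing_rate:
                    row.append(None)
                else:
                    row.append(int(rng.integers(0, n_states)))
            rows.append(row)
        try:
            return CharacterMatrix.from_states(
                [f"t{i}" for i in range(n_taxa)], rows
            )
        except Exception:
            continue


def driver_fixture(seed, n_taxa=7, k_driver=4, driver="general"):
    """A fixture whose focal clade is supported only by the driver type.

    Returns (matrix, partition, focal clade terminals, ground truth).
    """
    tree = random_tree(n_taxa, seed=seed)
    bps = sorted(tree.bipartitions(), key=lambda b: (len(b.side), sorted(b.side)))
    focal = tuple(sorted(bps[-1].side))
    other = tuple(sorted(bps[0].side))
    names = ("general", "copulatory", "photophores")
    plans = [TypePlan(driver, focal, k_driver)]
    for name in names:
        if name != driver:
            plans.append(TypePlan(name, other, 2))
    spec = FixtureSpec(
        n_taxa=n_taxa,
        plans=tuple(plans),
        tree=tree,
        background_constant=3,
        seed=seed,
    )
    matrix, partition, truth = plant_matrix(spec)
    return matrix, partition, focal, truth
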