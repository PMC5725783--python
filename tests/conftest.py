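import numpy as np
import pytest

import opsinevol as ov


@pytest.fixture(scope="session")
def five_leaf_tree():
    return ov.read_tree("((Out:0.3,(A:0.1,B:0.12):0.08):0.05,(C:0.1,E:0.15):0.1);")


@pytest.fixture(scope="session")
def five_leaf_table():
    return ov.ActivityTable.from_records(
        [
            ("Out", "D", "nonsnake"),
            ("A", "D", "colubrinae"),
            ("B", "D", "dipsadinae"),
            ("C", "N", "dipsadinae"),
            ("E", "N", "dipsadinae"),
        ]
    )


@pytest.fixture(scope="session")
def activity_tree():
    """8 leaves: outgroup, henophidian, 3 diurnal and 3 nocturnal colubrids."""
    return ov.read_tree(
        "((Out:0.4,Heno:0.3):0.1,((D1:0.05,(D2:0.06,D3:0.04):0.03):0.08,"
        "(N1:0.05,(N2:0.06,N3:0.04):0.03):0.08):0.1);"
    )


@pytest.fixture(scope="session")
def activity_table():
    return ov.ActivityTable.from_records(
        [
            ("Out", "D", "nonsnake"),
            ("Heno", "N", "henophidian"),
            ("D1", "D", "colubrinae"),
            ("D2", "D", "dipsadinae"),
            ("D3", "D", "dipsadinae"),
            ("N1", "N", "dipsadinae"),
            ("N2", "N", "dipsadinae"),
            ("N3", "N", "colubrinae"),
        ]
    )


@pytest.fixture(scope="session")
def activity_partition(activity_tree, activity_table):
    return ov.label_branches(activity_tree, activity_table, "4w-activity")


@pytest.fixture(scope="session")
def small_sim(five_leaf_tree, five_leaf_table):
    """A 2-omega-class simulated alignment with known truth."""
    part = ov.label_branches(five_leaf_tree, five_leaf_table, "2w")
    spec = ov.SimulationSpec(
        tree=five_leaf_tree,
        partition=part,
        omega_by_class={"nonsnake": 0.1, "snake": 0.5},
        kappa=2.0,
        L=400,
        seed=5,
    )
    aln, truth = ov.simulate_alignment(spec)
    return aln, truth, part


def random_alignment(rng, taxa, n_sites, ambiguity=True):
    """Small random codon alignment (possibly with ambiguous cells)."""
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_sites):
            k = int(rng.integers(1, 4)) if ambiguity else 1
            row.append(frozenset(int(x) for x in rng.choice(61, size=k, replace=False)))
        cells.append(row)
    return ov.CodonAlignment(taxa=list(taxa), cells=cells, nt_length=3 * n_sites)
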