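"""Shared fixtures: tiny structures, Example-2 class averages, PDB snippets."""

from __future__ import annotations

import numpy as np
import pytest

from ballhist import (
    BallHistogram,
    ClassAverages,
    PropertyTable,
    ProteinStructure,
    Residue,
    Template,
    marginalize,
)


def make_structure(id: str, residues: list[tuple[str, tuple[float, float, float]]]):
    """Structure from (res_type, position) pairs with sequential numbering."""
    return ProteinStructure(
        id,
        [
            Residue(res_type=t, ca_position=pos, chain_id="A", seq_index=i + 1)
            for i, (t, pos) in enumerate(residues)
        ],
    )


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture()
def single_arg() -> ProteinStructure:
    return make_structure("single_arg", [("ARG", (0.0, 0.0, 0.0))])


@pytest.fixture()
def arg_gly_far() -> ProteinStructure:
    """Arg and Gly with CA separation 10 A (> 2R for R = 4): two disjoint
    non-empty regions of equal volume."""
    return make_structure(
        "arg_gly_far", [("ARG", (0.0, 0.0, 0.0)), ("GLY", (10.0, 0.0, 0.0))]
    )


def histogram(props: tuple[str, ...], bins: dict, radius: float = 8.0) -> BallHistogram:
    return BallHistogram(Template(props), radius, bins)


@pytest.fixture(scope="session")
def worked_example_averages() -> ClassAverages:
    """The printed pairwise 2x2 joints of the two classes, as class averages.

    Binding: Arg and Lys perfectly co-occur; non-binding: they are mutually
    exclusive — so every marginal of length 1 is identical across classes
    while the (Arg, Lys) joint separates them perfectly.
    """
    pool = ("Arg", "Lys", "Gly")
    pos = {
        Template(("Arg", "Lys")): histogram(("Arg", "Lys"), {(1, 1): 0.5, (0, 0): 0.5}),
        Template(("Arg", "Gly")): histogram(
            ("Arg", "Gly"), {(1, 1): 0.4, (1, 0): 0.1, (0, 1): 0.2, (0, 0): 0.3}
        ),
        Template(("Lys", "Gly")): histogram(
            ("Lys", "Gly"), {(1, 1): 0.4, (1, 0): 0.1, (0, 1): 0.2, (0, 0): 0.3}
        ),
    }
    neg = {
        Template(("Arg", "Lys")): histogram(("Arg", "Lys"), {(1, 0): 0.5, (0, 1): 0.5}),
        Template(("Arg", "Gly")): histogram(
            ("Arg", "Gly"), {(1, 1): 0.1, (1, 0): 0.4, (0, 1): 0.3, (0, 0): 0.2}
        ),
        Template(("Lys", "Gly")): histogram(
            ("Lys", "Gly"), {(1, 1): 0.1, (1, 0): 0.4, (0, 1): 0.3, (0, 0): 0.2}
        ),
    }
    for side in (pos, neg):
        for name in pool:
            parent = next(t for t in list(side) if name in t.properties)
            side[Template((name,))] = marginalize(side[parent], Template((name,)))
    return ClassAverages.from_marginals(pool, pos, neg)


MINI_PDB = """\
ATOM      1  CA  ARG A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  LYS A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AARG A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BARG A   1       2.000   0.000   0.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return str(p)


@pytest.fixture()
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return str(p)


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return str(p)
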