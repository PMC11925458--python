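"""Structure reading/writing, annotation and dot-bracket handling."""

import numpy as np
import pytest

from rnatangle.fixtures import FixtureSpec, make_entangled, make_helix, helix_pairs
from rnatangle.geometry import rotation_about_axis
from rnatangle.structure import (
    StructureError, annotate_base_pairs, pairs_to_dotbracket, parse_dotbracket,
    read_dotbracket, read_structure, write_structure, BasePair,
)

MINIMAL_G_PDB = """\
ATOM      1  P     G A   1       3.063   8.025  -4.135  1.00  0.00           P
ATOM      2  OP1   G A   1       3.223   8.856  -5.350  1.00  0.00           O
ATOM      3  OP2   G A   1       1.891   8.290  -3.264  1.00  0.00           O
ATOM      4  O5'   G A   1       4.396   8.078  -3.249  1.00  0.00           O
ATOM      5  C5'   G A   1       4.500   7.361  -2.004  1.00  0.00           C
ATOM      6  C4'   G A   1       5.697   7.819  -1.215  1.00  0.00           C
ATOM      7  O4'   G A   1       5.540   9.180  -0.748  1.00  0.00           O
ATOM      8  C3'   G A   1       5.922   6.965   0.014  1.00  0.00           C
ATOM      9  O3'   G A   1       6.738   5.843  -0.240  1.00  0.00           O
ATOM     10  C2'   G A   1       6.576   7.924   1.010  1.00  0.00           C
ATOM     11  O2'   G A   1       7.983   7.951   0.863  1.00  0.00           O
ATOM     12  C1'   G A   1       5.940   9.268   0.666  1.00  0.00           C
ATOM     13  N9    G A   1       4.789  09.576   1.511  1.00  0.00           N
ATOM     14  C8    G A   1       3.544   9.060   1.306  1.00  0.00           C
ATOM     15  N7    G A   1       2.706   9.486   2.211  1.00  0.00           N
ATOM     16  C5    G A   1       3.417  10.324   3.057  1.00  0.00           C
ATOM     17  C6    G A   1       3.038  11.075   4.193  1.00  0.00           C
ATOM     18  O6    G A   1       1.905  11.155   4.666  1.00  0.00           O
ATOM     19  N1    G A   1       4.078  11.774   4.786  1.00  0.00           N
ATOM     20  C2    G A   1       5.355  11.745   4.316  1.00  0.00           C
ATOM     21  N2    G A   1       6.283  12.465   4.961  1.00  0.00           N
ATOM     22  N3    G A   1       5.730  11.051   3.255  1.00  0.00           N
ATOM     23  C4    G A   1       4.717  10.351   2.671  1.00  0.00           C
END
"""


def test_minimal_single_residue(tmp_path):
    """One complete nucleotide parses to one residue with no backbone link."""
    p = tmp_path / "g.pdb"
    p.write_text(MINIMAL_G_PDB)
    s = read_structure(p)
    assert len(s) == 1
    assert s.residues[0].base_identity == "G"
    assert s.covalent_links == set()


def test_round_trip_preserves_geometry(tmp_path, helix8):
    """Write->read returns identical identifiers and coordinates (1e-3 Å)."""
    p = tmp_path / "helix.pdb"
    write_structure(helix8, p)
    back = read_structure(p)
    assert len(back) == len(helix8)
    for r1, r2 in zip(helix8.residues, back.residues):
        assert r1.key == r2.key
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert np.allclose(a1.position, a2.position, atol=1e-3)


def test_chain_break_detection(tmp_path, helix8):
    """A stretched O3'-P junction removes the covalent link."""
    s = helix8.copy()
    # translate the second half of chain A away along z
    for r in s.residues[4:8]:
        for a in r.atoms:
            a.position = a.position + np.array([0.0, 0.0, 8.0])
    from rnatangle.structure import _compute_covalent_links

    s.covalent_links = _compute_covalent_links(s)
    assert (3, 4) not in s.covalent_links
    assert (4, 5) in s.covalent_links


def test_empty_structure_write_rejected(tmp_path, helix8):
    from rnatangle.structure import Structure

    with pytest.raises(Exception):
        write_structure(Structure([helix8.residues[0]]).__class__([]), tmp_path / "x.pdb")


def test_annotation_recovers_helix_pairs(helix8):
    ss = annotate_base_pairs(helix8)
    assert ss.pair_set() == {(p.i, p.j) for p in helix_pairs(8)}


def test_annotation_rotation_invariant(helix8):
    """A rigid motion of all atoms leaves the pair list unchanged."""
    R = rotation_about_axis([1.0, 2.0, 3.0], 1.1)
    rotated = helix8.transformed(R, np.array([5.0, -3.0, 2.0]))
    assert annotate_base_pairs(rotated).pair_set() == annotate_base_pairs(helix8).pair_set()


def test_single_nucleotide_unpaired(tmp_path):
    p = tmp_path / "g.pdb"
    p.write_text(MINIMAL_G_PDB)
    s = read_structure(p)
    ss = annotate_base_pairs(s)
    assert ss.pairs == []
    assert ss.dotbracket == "."


@pytest.mark.parametrize("text,expected", [
    ("((..))", {(0, 5), (1, 4)}),
    ("([)]", {(0, 2), (1, 3)}),
])
def test_dotbracket_decoding(text, expected):
    assert {(p.i, p.j) for p in parse_dotbracket(text)} == expected


def test_dotbracket_unbalanced():
    with pytest.raises(ValueError):
        parse_dotbracket("((..)")


def test_dotbracket_file_override(tmp_path, helix8):
    db = "." * 16
    f = tmp_path / "ss.db"
    f.write_text(">helix\n" + "G" * 16 + "\n" + db + "\n")
    ss = read_dotbracket(f, helix8)
    assert ss.pairs == []
    f2 = tmp_path / "bad.db"
    f2.write_text("." * 15 + "\n")
    with pytest.raises(ValueError):
        read_dotbracket(f2, helix8)


def test_pairs_to_dotbracket_pseudoknot_layers():
    pairs = [BasePair(0, 4), BasePair(2, 6)]
    db = pairs_to_dotbracket(pairs, 8)
    assert db == "(.[.).]."
    assert {(p.i, p.j) for p in parse_dotbracket(db)} == {(0, 4), (2, 6)}
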