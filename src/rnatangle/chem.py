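"""Chemical reference tables for RNA heavy atoms.

Atom naming follows PDB v3 conventions (primes, ``OP1/OP2``). Hydrogens are
ignored throughout the package because predicted models frequently lack them.
"""

from __future__ import annotations

BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

#: ring atoms per base, used for plane fitting and base centroids
BASE_RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: exocyclic heavy atoms per base
BASE_EXOCYCLIC_ATOMS = {
    "A": ("N6",),
    "G": ("O6", "N2"),
    "C": ("O2", "N4"),
    "U": ("O2", "O4"),
}

BASE_ATOMS = {b: BASE_RING_ATOMS[b] + BASE_EXOCYCLIC_ATOMS[b] for b in "AGCU"}

#: Watson-Crick-Franklin edge atom of each base (purine N1, pyrimidine N3)
WCF_EDGE_ATOM = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}

GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

#: unordered canonical WCF base identities
CANONICAL_PAIRS = frozenset({frozenset("AU"), frozenset("GC"), frozenset("GU")})

#: van der Waals radii (Å) for heavy elements, used by the clash score
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}

#: parent base for common modified nucleotides (mapped when ring atoms exist)
MODIFIED_PARENT = {
    "1MA": "A", "2MA": "A", "6MA": "A", "MIA": "A", "A2M": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G", "G7M": "G", "GTP": "G",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "5MU": "U", "PSU": "U", "4SU": "U", "H2U": "U", "OMU": "U", "UR3": "U", "70U": "U",
    "I": "G", "DU": "U",
}

# intra-residue covalent bonds (heavy atoms), shared backbone part
_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "O2'"), ("C2'", "C1'"), ("C1'", "O4'"),
]

_PURINE_RING_BONDS = [
    ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
    ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
]
_PYRIMIDINE_RING_BONDS = [
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
]

RESIDUE_BONDS = {
    "A": _BACKBONE_BONDS + [("C1'", "N9")] + _PURINE_RING_BONDS + [("C6", "N6")],
    "G": _BACKBONE_BONDS + [("C1'", "N9")] + _PURINE_RING_BONDS + [("C6", "O6"), ("C2", "N2")],
    "C": _BACKBONE_BONDS + [("C1'", "N1")] + _PYRIMIDINE_RING_BONDS + [("C2", "O2"), ("C4", "N4")],
    "U": _BACKBONE_BONDS + [("C1'", "N1")] + _PYRIMIDINE_RING_BONDS + [("C2", "O2"), ("C4", "O4")],
}

STANDARD_BASES = frozenset("ACGU")


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a (nucleic-acid) atom name."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


#: planar base heavy-atom coordinates (Å) in the standard base-pair
#: reference frame (x toward the major groove, y along the C1'-C1' long
#: axis, base plane z = 0). The Watson-Crick complement of a base is
#: obtained by the 2-fold rotation (x, y) -> (x, -y).
STD_BASE_FRAME = {
    "A": {"C1'": (-2.479, 5.346), "N9": (-1.291, 4.498), "C8": (0.024, 4.897),
          "N7": (0.877, 3.902), "C5": (0.071, 2.771), "C6": (0.369, 1.398),
          "N6": (1.611, 0.909), "N1": (-0.668, 0.532), "C2": (-1.912, 1.023),
          "N3": (-2.320, 2.290), "C4": (-1.267, 3.124)},
    "G": {"C1'": (-2.477, 5.399), "N9": (-1.289, 4.551), "C8": (0.023, 4.962),
          "N7": (0.870, 3.969), "C5": (0.071, 2.833), "C6": (0.424, 1.460),
          "O6": (1.554, 0.955), "N1": (-0.700, 0.641), "C2": (-1.999, 1.087),
          "N2": (-2.949, 0.139), "N3": (-2.342, 2.364), "C4": (-1.265, 3.177)},
    "C": {"C1'": (-2.477, 5.402), "N1": (-1.285, 4.542), "C2": (-1.472, 3.158),
          "O2": (-2.628, 2.709), "N3": (-0.391, 2.344), "C4": (0.837, 2.868),
          "N4": (1.875, 2.027), "C5": (1.056, 4.275), "C6": (-0.023, 5.068)},
    "U": {"C1'": (-2.481, 5.354), "N1": (-1.284, 4.500), "C2": (-1.462, 3.131),
          "O2": (-2.563, 2.608), "N3": (-0.302, 2.397), "C4": (0.989, 2.884),
          "O4": (1.935, 2.094), "C5": (1.089, 4.311), "C6": (-0.024, 5.053)},
}
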