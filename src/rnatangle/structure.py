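"""RNA structures, secondary structure, and their file formats.

Reads PDB/mmCIF through biotite, keeps only nucleotide residues, and
establishes the residue conventions used by every downstream module:
residues are identified externally by ``(chain_id, author_number,
insertion_code)`` and internally by a contiguous 0-based ``internal_index``;
consecutive residues of a chain are covalently linked iff their O3'-P
distance is at most ``CHAIN_BREAK`` (2.0 Å, covalent P-O is ~1.6 Å plus a
modelling-noise margin).

Canonical Watson-Crick-Franklin pairs are annotated geometrically: AU/GC/GU
identity, WCF-edge N-N distance in [2.6, 3.5] Å, base-plane normals within
65°, and C1'-C1' distance in [9.0, 11.0] Å, with greedy conflict resolution
by ascending N-N distance. A user-supplied dot-bracket file (with
pseudoknot bracket layers) overrides the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .geometry import plane_normal

logger = logging.getLogger(__name__)

#: O3'(i)-P(i+1) distance (Å) above which the backbone is considered broken
CHAIN_BREAK = 2.0

# geometric windows of the canonical-pair criteria
NN_RANGE = (2.6, 3.5)
C1C1_RANGE = (9.0, 11.0)
MAX_NORMAL_ANGLE_DEG = 65.0

OPEN_BRACKETS = "([{<ABCD"
CLOSE_BRACKETS = ")]}>abcd"


class StructureError(ValueError):
    """Raised for unreadable or chemically incomplete structures."""


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise StructureError("empty atom name")


@dataclass
class Residue:
    chain_id: str
    author_number: int
    insertion_code: str
    base_identity: str  # A, C, G, U or "other"
    name: str  # residue name as read from the file
    atoms: list[AtomRecord]
    internal_index: int = -1
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_name = {a.name: a for a in self.atoms}

    def atom(self, name: str) -> Optional[AtomRecord]:
        return self._by_name.get(name)

    def coord(self, name: str) -> np.ndarray:
        a = self._by_name.get(name)
        if a is None:
            raise StructureError(
                f"residue {self.chain_id}{self.author_number}{self.insertion_code or ''} "
                f"({self.name}) lacks atom {name}"
            )
        return a.position

    def has(self, name: str) -> bool:
        return name in self._by_name

    @property
    def key(self):
        return (self.chain_id, self.author_number, self.insertion_code)

    def base_atom_coords(self) -> np.ndarray:
        """Coordinates of the base heavy atoms present (ring + exocyclic)."""
        if self.base_identity not in chem.STANDARD_BASES:
            return np.empty((0, 3))
        names = chem.BASE_ATOMS[self.base_identity]
        return np.array([self._by_name[n].position for n in names if n in self._by_name])

    def base_centroid(self) -> Optional[np.ndarray]:
        coords = self.base_atom_coords()
        if len(coords) == 0:
            return None
        return coords.mean(axis=0)

    def base_normal(self) -> Optional[np.ndarray]:
        if self.base_identity not in chem.STANDARD_BASES:
            return None
        names = chem.BASE_RING_ATOMS[self.base_identity]
        coords = np.array([self._by_name[n].position for n in names if n in self._by_name])
        if len(coords) < 3:
            return None
        return plane_normal(coords)


@dataclass
class Structure:
    residues: list[Residue]
    chains: list[str] = field(default_factory=list)
    covalent_links: set = field(default_factory=set)

    def __post_init__(self):
        for i, r in enumerate(self.residues):
            r.internal_index = i
        if not self.chains:
            seen = []
            for r in self.residues:
                if r.chain_id not in seen:
                    seen.append(r.chain_id)
            self.chains = seen

    def __len__(self):
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def sequence(self) -> str:
        return "".join(r.base_identity if r.base_identity in chem.STANDARD_BASES else "N"
                       for r in self.residues)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([[a.position for a in r.atoms] for r in self.residues])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        """A copy with every atom mapped through ``x -> R x + t``."""
        residues = []
        for r in self.residues:
            atoms = [AtomRecord(a.name, a.element, R @ a.position + t, a.occupancy)
                     for a in r.atoms]
            residues.append(Residue(r.chain_id, r.author_number, r.insertion_code,
                                    r.base_identity, r.name, atoms))
        return Structure(residues, list(self.chains), set(self.covalent_links))

    def copy(self) -> "Structure":
        return self.transformed(np.eye(3), np.zeros(3))


@dataclass(frozen=True, order=True)
class BasePair:
    i: int
    j: int
    canonical: bool = True

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("BasePair requires i < j")


@dataclass
class SecondaryStructure:
    pairs: list[BasePair]
    dotbracket: str

    def __post_init__(self):
        self.pairs = sorted(self.pairs)

    @property
    def n(self) -> int:
        return len(self.dotbracket)

    def partner_map(self) -> np.ndarray:
        """Array mapping each residue to its canonical partner (-1 if none)."""
        pm = np.full(self.n, -1, dtype=int)
        for p in self.pairs:
            if p.canonical:
                pm[p.i] = p.j
                pm[p.j] = p.i
        return pm

    def pair_set(self) -> frozenset:
        return frozenset((p.i, p.j) for p in self.pairs)


# ---------------------------------------------------------------------------
# reading / writing


def _identity_of(res_name: str, atom_names: set) -> Optional[str]:
    name = res_name.strip()
    parent = name if name in chem.STANDARD_BASES else chem.MODIFIED_PARENT.get(name)
    if parent is not None:
        ring = chem.BASE_RING_ATOMS[parent]
        if sum(a in atom_names for a in ring) >= len(ring) - 1:
            return parent
        return "other"
    # unknown residue: treat as nucleotide iff it has a ribose trace
    if "C4'" in atom_names and "C1'" in atom_names:
        return "other"
    return None  # hetero / solvent / protein -> skipped


def _from_atom_array(array) -> Structure:
    import biotite.structure as struc

    residues: list[Residue] = []
    chains: list[str] = []
    for start, stop in zip(*_residue_slices(array)):
        sub = array[start:stop]
        atom_names = {n.strip() for n in sub.atom_name}
        res_name = str(sub.res_name[0])
        identity = _identity_of(res_name, atom_names)
        if identity is None:
            continue
        if "P" not in atom_names and "C4'" not in atom_names:
            raise StructureError(
                f"residue {sub.chain_id[0]}{sub.res_id[0]} ({res_name}) lacks both P and C4'"
            )
        occ = sub.occupancy if "occupancy" in sub.get_annotation_categories() else np.ones(len(sub))
        ins = sub.ins_code[0].strip() if "ins_code" in sub.get_annotation_categories() else ""
        atoms = []
        seen = set()
        for k in range(len(sub)):
            aname = str(sub.atom_name[k]).strip()
            if aname in seen or aname.startswith("H") or str(sub.element[k]).upper() == "H":
                continue
            seen.add(aname)
            elem = str(sub.element[k]).strip().upper() or chem.element_of(aname)
            atoms.append(AtomRecord(aname, elem, np.array(sub.coord[k], float), float(occ[k])))
        chain_id = str(sub.chain_id[0])
        if chain_id not in chains:
            chains.append(chain_id)
        residues.append(Residue(chain_id, int(sub.res_id[0]), ins, identity, res_name, atoms))
    if not residues:
        raise StructureError("no nucleotide residues found")
    s = Structure(residues, chains)
    s.covalent_links = _compute_covalent_links(s)
    return s


def _residue_slices(array):
    import biotite.structure as struc

    starts = struc.get_residue_starts(array)
    stops = np.append(starts[1:], len(array))
    return starts, stops


def _compute_covalent_links(s: Structure) -> set:
    links = set()
    for i in range(len(s) - 1):
        a, b = s.residues[i], s.residues[i + 1]
        if a.chain_id != b.chain_id:
            continue
        if a.has("O3'") and b.has("P"):
            d = np.linalg.norm(a.coord("O3'") - b.coord("P"))
            if d <= CHAIN_BREAK:
                links.add((i, i + 1))
    return links


def read_structure(path, model_index: Optional[int] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``model_index`` is 1-based as in the file; multi-model files without an
    explicit index default to the first model (logged).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            import biotite.structure.io.pdbx as pdbx

            f = pdbx.CIFFile.read(str(path))
            count = pdbx.get_model_count(f)
            if model_index is None:
                if count > 1:
                    logger.info("multi-model file %s: using model 1 of %d", path, count)
                model_index = 1
            array = pdbx.get_structure(f, model=model_index, extra_fields=["occupancy"])
        else:
            import biotite.structure.io.pdb as pdb

            f = pdb.PDBFile.read(str(path))
            count = f.get_model_count()
            if model_index is None:
                if count > 1:
                    logger.info("multi-model file %s: using model 1 of %d", path, count)
                model_index = 1
            array = pdb.get_structure(f, model=model_index, extra_fields=["occupancy"])
    except StructureError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _from_atom_array(array)


def to_atom_array(s: Structure):
    """Convert to a biotite ``AtomArray`` (heavy atoms, author numbering)."""
    import biotite.structure as struc

    n = s.n_atoms
    array = struc.AtomArray(n)
    array.add_annotation("occupancy", dtype=float)
    k = 0
    for r in s.residues:
        for a in r.atoms:
            array.coord[k] = a.position
            array.chain_id[k] = r.chain_id
            array.res_id[k] = r.author_number
            array.ins_code[k] = r.insertion_code
            array.res_name[k] = r.name
            array.atom_name[k] = a.name
            array.element[k] = a.element
            array.occupancy[k] = a.occupancy
            array.hetero[k] = False
            k += 1
    return array


def write_structure(s: Structure, path) -> None:
    """Write ``s`` as a PDB file (sequential serials, identifiers preserved)."""
    import biotite.structure.io.pdb as pdb

    if len(s) == 0 or s.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    if s.n_atoms > 99999:
        logger.warning("structure has %d atoms; serial numbers wrap per PDB convention",
                       s.n_atoms)
    array = to_atom_array(s)
    f = pdb.PDBFile()
    f.set_structure(array)
    f.write(str(path))


# ---------------------------------------------------------------------------
# canonical base-pair annotation


def annotate_base_pairs(s: Structure) -> SecondaryStructure:
    """Annotate canonical WCF pairs with the package's geometric criteria."""
    n = len(s)
    edge_atoms = np.full((n, 3), np.nan)
    c1 = np.full((n, 3), np.nan)
    normals = [None] * n
    for r in s.residues:
        b = r.base_identity
        if b not in chem.STANDARD_BASES:
            continue
        ea = r.atom(chem.WCF_EDGE_ATOM[b])
        c1a = r.atom("C1'")
        if ea is None or c1a is None:
            continue
        edge_atoms[r.internal_index] = ea.position
        c1[r.internal_index] = c1a.position
        normals[r.internal_index] = r.base_normal()

    valid = np.where(np.isfinite(edge_atoms[:, 0]))[0]
    candidates = []
    if len(valid) >= 2:
        tree = cKDTree(edge_atoms[valid])
        for a, b in tree.query_pairs(NN_RANGE[1]):
            i, j = int(valid[a]), int(valid[b])
            if i > j:
                i, j = j, i
            ri, rj = s.residues[i], s.residues[j]
            if frozenset((ri.base_identity, rj.base_identity)) not in chem.CANONICAL_PAIRS:
                continue
            if ri.chain_id == rj.chain_id and j - i <= 1:
                continue  # covalent neighbours cannot form a WCF pair
            d = float(np.linalg.norm(edge_atoms[i] - edge_atoms[j]))
            if not (NN_RANGE[0] <= d <= NN_RANGE[1]):
                continue
            dc1 = float(np.linalg.norm(c1[i] - c1[j]))
            if not (C1C1_RANGE[0] <= dc1 <= C1C1_RANGE[1]):
                continue
            ni, nj = normals[i], normals[j]
            if ni is None or nj is None:
                continue
            cosang = abs(float(ni @ nj))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang > MAX_NORMAL_ANGLE_DEG:
                continue
            candidates.append((d, i, j))

    candidates.sort()
    used = set()
    pairs = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(BasePair(i, j, canonical=True))
    return SecondaryStructure(pairs, pairs_to_dotbracket(pairs, n))


# ---------------------------------------------------------------------------
# dot-bracket


def pairs_to_dotbracket(pairs: Iterable[BasePair], n: int) -> str:
    """Layered dot-bracket string; each layer is internally non-crossing."""
    layers: list[list[tuple]] = []
    assignment = {}
    for p in sorted(pairs):
        placed = False
        for li, layer in enumerate(layers):
            if all(not _crosses((p.i, p.j), q) for q in layer):
                layer.append((p.i, p.j))
                assignment[(p.i, p.j)] = li
                placed = True
                break
        if not placed:
            layers.append([(p.i, p.j)])
            assignment[(p.i, p.j)] = len(layers) - 1
    if len(layers) > len(OPEN_BRACKETS):
        raise ValueError("too many pseudoknot layers to encode")
    out = ["."] * n
    for (i, j), li in assignment.items():
        out[i] = OPEN_BRACKETS[li]
        out[j] = CLOSE_BRACKETS[li]
    return "".join(out)


def _crosses(a: tuple, b: tuple) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def parse_dotbracket(text: str) -> list[BasePair]:
    """Decode a layered dot-bracket string into base pairs."""
    stacks: dict[str, list[int]] = {b: [] for b in OPEN_BRACKETS}
    pairs = []
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in OPEN_BRACKETS:
            stacks[ch].append(pos)
        elif ch in CLOSE_BRACKETS:
            opener = OPEN_BRACKETS[CLOSE_BRACKETS.index(ch)]
            if not stacks[opener]:
                raise ValueError(f"unbalanced bracket {ch!r} at position {pos}")
            i = stacks[opener].pop()
            pairs.append(BasePair(i, pos, canonical=True))
        else:
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced bracket {opener!r} (position {stack[-1]})")
    return sorted(pairs)


def read_dotbracket(path, s: Structure) -> SecondaryStructure:
    """Read a dot-bracket file as a user override of the annotation.

    Format: optional ``>`` header line, optional sequence line, last
    non-empty line is the structure string.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if not lines:
        raise ValueError(f"no dot-bracket content in {path}")
    text = lines[-1]
    if len(text) != len(s):
        raise ValueError(
            f"dot-bracket length {len(text)} does not match residue count {len(s)}"
        )
    pairs = parse_dotbracket(text)
    return SecondaryStructure(pairs, text)
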