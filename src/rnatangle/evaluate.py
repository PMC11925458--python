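"""Model-quality metrics: RMSD, interaction-network fidelity, clash score.

* ``rmsd`` — optimal least-squares (Kabsch) superposition over atoms matched
  by ``(chain, author number, insertion code, atom name)``, then the root
  mean square deviation.
* ``inf`` — Interaction Network Fidelity between two base-pair sets:
  ``INF = sqrt(PPV * STY)`` with ``PPV = TP/(TP+FP)``, ``STY = TP/(TP+FN)``.
  By default the canonical WCF pairs are compared (the annotator's scope).
* ``clash_score`` — steric clashes per 1000 heavy atoms. A clash is an
  unordered non-bonded pair of heavy atoms whose centre distance is below
  the sum of van der Waals radii minus 0.4 Å; pairs separated by up to
  three covalent bonds are excluded. This is a simplified surrogate of the
  MolProbity ClashScore (probe-based, hydrogen-aware), not a reimplementation
  of it; values below 10 are conventionally considered acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .geometry import kabsch, rmsd_fixed
from .structure import BasePair, Structure

#: van der Waals overlap (Å) that counts as a clash
CLASH_OVERLAP = 0.4
#: covalent-bond separation up to which atom pairs are exempt
CLASH_BOND_EXCLUSION = 3


@dataclass
class EvaluationDelta:
    metric: str
    before: Optional[float]
    after: Optional[float]

    @property
    def delta(self) -> Optional[float]:
        if self.before is None or self.after is None:
            return None
        return self.after - self.before

    def to_json(self) -> dict:
        return {"metric": self.metric, "before": self.before, "after": self.after,
                "delta": self.delta}


# ---------------------------------------------------------------------------
# RMSD


def _matched_coords(a: Structure, b: Structure, atom_selection=None):
    index_b = {}
    for r in b.residues:
        for atom in r.atoms:
            index_b[(r.chain_id, r.author_number, r.insertion_code, atom.name)] = atom.position
    pa, pb = [], []
    for r in a.residues:
        for atom in r.atoms:
            if atom_selection is not None and atom.name not in atom_selection:
                continue
            key = (r.chain_id, r.author_number, r.insertion_code, atom.name)
            if key in index_b:
                pa.append(atom.position)
                pb.append(index_b[key])
    return np.array(pa), np.array(pb)


def rmsd(a: Structure, b: Structure, atom_selection=None) -> float:
    """All-common-heavy-atom RMSD after optimal rigid superposition."""
    pa, pb = _matched_coords(a, b, atom_selection)
    if len(pa) < 3:
        raise ValueError(f"only {len(pa)} common atoms; need at least 3")
    R, t = kabsch(pa, pb)
    return rmsd_fixed(pa @ R.T + t, pb)


def rmsd_fixed_frame(a: Structure, b: Structure, residue_indices=None) -> float:
    """RMSD over matched atoms without superposition (shared frame).

    ``residue_indices`` restricts the selection to those internal indices
    of ``a`` (used for per-region fold-preservation checks).
    """
    keep = None if residue_indices is None else set(residue_indices)
    pa, pb = [], []
    index_b = {}
    for r in b.residues:
        for atom in r.atoms:
            index_b[(r.chain_id, r.author_number, r.insertion_code, atom.name)] = atom.position
    for r in a.residues:
        if keep is not None and r.internal_index not in keep:
            continue
        for atom in r.atoms:
            key = (r.chain_id, r.author_number, r.insertion_code, atom.name)
            if key in index_b:
                pa.append(atom.position)
                pb.append(index_b[key])
    if not pa:
        return 0.0
    return rmsd_fixed(np.array(pa), np.array(pb))


# ---------------------------------------------------------------------------
# INF


def inf(ref_pairs, model_pairs) -> Optional[float]:
    """Interaction Network Fidelity; ``None`` when both sets are empty."""
    ref = {(p.i, p.j) if isinstance(p, BasePair) else tuple(p) for p in ref_pairs}
    mod = {(p.i, p.j) if isinstance(p, BasePair) else tuple(p) for p in model_pairs}
    if not ref and not mod:
        return None
    tp = len(ref & mod)
    fp = len(mod - ref)
    fn = len(ref - mod)
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    sty = tp / (tp + fn)
    return float(np.sqrt(ppv * sty))


def pair_counts(ref_pairs, model_pairs) -> dict:
    ref = {(p.i, p.j) if isinstance(p, BasePair) else tuple(p) for p in ref_pairs}
    mod = {(p.i, p.j) if isinstance(p, BasePair) else tuple(p) for p in model_pairs}
    return {"TP": len(ref & mod), "FP": len(mod - ref), "FN": len(ref - mod)}


# ---------------------------------------------------------------------------
# clash score


def _bond_graph_distances(s: Structure, max_sep: int):
    """Atom pairs within ``max_sep`` covalent bonds, as a set of index pairs."""
    import networkx as nx

    g = nx.Graph()
    offsets = []
    k = 0
    for r in s.residues:
        offsets.append(k)
        names = {a.name: k + i for i, a in enumerate(r.atoms)}
        template = chem.RESIDUE_BONDS.get(r.base_identity)
        if template is None:
            # unknown residue: chain the atoms in file order as a fallback
            template = [(r.atoms[i].name, r.atoms[i + 1].name)
                        for i in range(len(r.atoms) - 1)]
        for x, y in template:
            if x in names and y in names:
                g.add_edge(names[x], names[y])
        k += len(r.atoms)
    for (i, j) in s.covalent_links:
        ri, rj = s.residues[i], s.residues[j]
        ni = {a.name: offsets[i] + t for t, a in enumerate(ri.atoms)}
        nj = {a.name: offsets[j] + t for t, a in enumerate(rj.atoms)}
        if "O3'" in ni and "P" in nj:
            g.add_edge(ni["O3'"], nj["P"])
    excluded = set()
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node, cutoff=max_sep)
        for other, d in lengths.items():
            if other > node and d >= 1:
                excluded.add((node, other))
    return excluded


def count_clashes(s: Structure) -> int:
    coords = []
    radii = []
    for r in s.residues:
        for a in r.atoms:
            coords.append(a.position)
            radii.append(chem.VDW_RADII.get(a.element, 1.70))
    coords = np.array(coords)
    radii = np.array(radii)
    excluded = _bond_graph_distances(s, CLASH_BOND_EXCLUSION)
    tree = cKDTree(coords)
    cutoff = 2 * radii.max() - CLASH_OVERLAP
    clashes = 0
    for i, j in tree.query_pairs(cutoff):
        if (min(i, j), max(i, j)) in excluded:
            continue
        d = np.linalg.norm(coords[i] - coords[j])
        if d < radii[i] + radii[j] - CLASH_OVERLAP:
            clashes += 1
    return clashes


def clash_score(s: Structure) -> float:
    """Clashes per 1000 heavy atoms."""
    n = s.n_atoms
    if n == 0:
        raise ValueError("structure has no atoms")
    return 1000.0 * count_clashes(s) / n


# ---------------------------------------------------------------------------
# run evaluation


def evaluate_run(before: Structure, after: Structure,
                 reference: Optional[Structure] = None,
                 ss_ref=None, ss_before=None, ss_after=None) -> list:
    """Metric deltas mirroring before/after untangling reporting.

    RMSD and INF are computed against ``reference`` when given (else
    against ``before``); the clash score is reference-free.
    """
    from .structure import annotate_base_pairs

    ref = reference if reference is not None else before
    deltas = []
    rmsd_before = 0.0 if ref is before else rmsd(before, ref)
    deltas.append(EvaluationDelta("rmsd", rmsd_before, rmsd(after, ref)))

    if ss_ref is None:
        ss_ref = annotate_base_pairs(ref)
    if ss_before is None:
        ss_before = ss_ref if ref is before else annotate_base_pairs(before)
    if ss_after is None:
        ss_after = annotate_base_pairs(after)
    deltas.append(EvaluationDelta(
        "inf",
        inf(ss_ref.pairs, ss_before.pairs),
        inf(ss_ref.pairs, ss_after.pairs)))
    deltas.append(EvaluationDelta("clash_score", clash_score(before), clash_score(after)))
    return deltas


def deltas_to_tsv(model: str, deltas) -> str:
    lines = ["model\tmetric\tbefore\tafter\tdelta"]
    fmt = lambda v: "NA" if v is None else f"{v:.4f}"
    for d in deltas:
        lines.append(f"{model}\t{d.metric}\t{fmt(d.before)}\t{fmt(d.after)}\t{fmt(d.delta)}")
    return "\n".join(lines) + "\n"
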