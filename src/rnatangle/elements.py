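"""Structural elements and their wireframe polygonal chains.

An RNA secondary structure induces a graph on residues whose edges are the
covalent backbone links and the canonical base pairs. Three kinds of
elements are derived from it:

* ``dinucleotide_step`` — the 4-cycle of two consecutive stacked pairs
  (i, j), (i+1, j-1) with both backbone links present;
* ``loop`` — any other minimal closed cycle (hairpin, internal loop/bulge,
  n-way junction, pseudoknot-closed cycle), with its closing pairs;
* ``single_strand`` — a maximal unpaired run not inside any cycle
  (dangling ends and connectors).

Element extraction depends only on the pairing/connectivity pattern, never
on 3D coordinates. The wireframe of an element is the polygonal chain
through the P and C4' atoms of its residues in traversal order, with one
node at the centroid of the base heavy atoms of each closing pair; closed
elements yield closed chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .structure import BasePair, SecondaryStructure, Structure


@dataclass
class WireframeNode:
    position: np.ndarray
    kind: str  # "P", "C4prime" or "pair_centroid"
    source_residues: tuple

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        n_src = len(self.source_residues)
        if self.kind == "pair_centroid":
            if n_src != 2:
                raise ValueError("pair_centroid nodes reference exactly 2 residues")
        elif n_src != 1:
            raise ValueError("backbone nodes reference exactly 1 residue")


@dataclass
class StructuralElement:
    kind: str  # "loop", "dinucleotide_step" or "single_strand"
    residues: list  # ordered internal indices (traversal order)
    closing_pairs: list = field(default_factory=list)
    chain_nodes: list = field(default_factory=list)
    closed: bool = False

    @property
    def residue_set(self) -> frozenset:
        return frozenset(self.residues)

    def node_positions(self) -> np.ndarray:
        return np.array([n.position for n in self.chain_nodes])

    def label(self, s: Optional[Structure] = None) -> str:
        kind = {"loop": "L", "dinucleotide_step": "D", "single_strand": "S"}[self.kind]
        lo, hi = min(self.residues), max(self.residues)
        if s is not None:
            a, b = s.residues[lo], s.residues[hi]
            return f"{kind}[{a.chain_id}{a.author_number}-{b.chain_id}{b.author_number}]"
        return f"{kind}[{lo}-{hi}]"

    def to_json(self, s: Optional[Structure] = None) -> dict:
        out = {"kind": self.kind, "residues": sorted(self.residues),
               "closing_pairs": [[p.i, p.j] for p in self.closing_pairs],
               "closed": self.closed}
        if s is not None:
            out["ranges"] = _author_ranges(self.residues, s)
        return out


def _author_ranges(indices, s: Structure) -> list:
    """Contiguous internal-index runs mapped to author numbering."""
    runs = []
    for idx in sorted(indices):
        if runs and idx == runs[-1][1] + 1:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    out = []
    for lo, hi in runs:
        a, b = s.residues[lo], s.residues[hi]
        out.append({"chain": a.chain_id, "from": a.author_number, "to": b.author_number})
    return out


# ---------------------------------------------------------------------------
# extraction


def extract_elements(s: Structure, ss: SecondaryStructure) -> list[StructuralElement]:
    """Derive all loops, dinucleotide steps, and single strands.

    Coordinates are never consulted; the result is a function of
    ``(ss.pairs, s.covalent_links)`` alone.
    """
    n = len(s)
    pairs = [p for p in ss.pairs if p.canonical]
    pair_set = {(p.i, p.j) for p in pairs}
    links = set(s.covalent_links)

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(links)
    graph.add_edges_from(pair_set)

    # dinucleotide steps: consecutive stacked pairs, both strands linked
    steps = []
    step_cycles = set()
    for (i, j) in sorted(pair_set):
        if (i + 1, j - 1) in pair_set and (i, i + 1) in links and (j - 1, j) in links:
            residues = [i, i + 1, j - 1, j]
            steps.append(StructuralElement(
                "dinucleotide_step", residues,
                closing_pairs=[BasePair(i, j), BasePair(i + 1, j - 1)],
                closed=True))
            step_cycles.add(frozenset(residues))

    # loops: minimal cycles of the secondary-structure graph that are not steps
    loops = []
    for cycle in nx.minimum_cycle_basis(graph):
        cyc = frozenset(cycle)
        if cyc in step_cycles:
            continue
        ordered = _order_cycle(graph, cycle)
        closing = [BasePair(min(a, b), max(a, b))
                   for a, b in zip(ordered, ordered[1:] + ordered[:1])
                   if (min(a, b), max(a, b)) in pair_set]
        loops.append(StructuralElement("loop", ordered, closing_pairs=closing, closed=True))

    in_cycle = set()
    for e in steps + loops:
        in_cycle.update(e.residues)

    # single strands: maximal unpaired runs outside every cycle
    paired = {p.i for p in pairs} | {p.j for p in pairs}
    strands = []
    run: list[int] = []
    for idx in range(n + 1):
        free = idx < n and idx not in paired and idx not in in_cycle
        if free and run and (run[-1], idx) not in links:
            strands.append(StructuralElement("single_strand", run, closed=False))
            run = []
        if free:
            run.append(idx)
        elif run:
            strands.append(StructuralElement("single_strand", run, closed=False))
            run = []

    elements = steps + loops + strands
    elements.sort(key=lambda e: (min(e.residues), e.kind))
    return elements


def _order_cycle(graph: nx.Graph, nodes) -> list:
    """Order a cycle's node set by walking the induced subgraph.

    The walk starts at the smallest residue and proceeds toward its smaller
    neighbour's opposite, giving a deterministic orientation.
    """
    sub = graph.subgraph(nodes)
    start = min(nodes)
    neighbours = sorted(sub.neighbors(start))
    if len(neighbours) < 2:
        raise ValueError("cycle nodes do not induce a cycle")
    ordered = [start]
    prev, current = start, neighbours[-1]
    while current != start:
        ordered.append(current)
        options = [x for x in sub.neighbors(current) if x != prev]
        if not options:
            raise ValueError("cycle traversal failed")
        prev, current = current, min(options)
    if len(ordered) != len(set(nodes)):
        # fall back to a simple-cycle search restricted to these nodes
        cycles = nx.cycle_basis(nx.Graph(sub))
        for cyc in cycles:
            if len(cyc) == len(set(nodes)):
                return cyc
        raise ValueError("cycle nodes do not induce a single cycle")
    return ordered


# ---------------------------------------------------------------------------
# wireframes


def _pair_centroid(s: Structure, pair: BasePair) -> np.ndarray:
    coords = [s.residues[pair.i].base_atom_coords(), s.residues[pair.j].base_atom_coords()]
    coords = np.vstack([c for c in coords if len(c)])
    if len(coords) == 0:
        raise ValueError(f"pair ({pair.i},{pair.j}) has no base heavy atoms")
    return coords.mean(axis=0)


def _backbone_nodes(s: Structure, idx: int, forward: bool, allow_missing_p: bool) -> list:
    r = s.residues[idx]
    nodes = []
    if r.has("P"):
        nodes.append(WireframeNode(r.coord("P"), "P", (idx,)))
    elif not allow_missing_p:
        raise ValueError(
            f"residue {r.chain_id}{r.author_number} lacks P at a non-terminal position")
    nodes.append(WireframeNode(r.coord("C4'"), "C4prime", (idx,)))
    if not forward:
        nodes.reverse()
    return nodes


def build_wireframe(e: StructuralElement, s: Structure,
                    ss: SecondaryStructure) -> StructuralElement:
    """Fill ``e.chain_nodes`` with the element's polygonal chain.

    Traversal follows 5'->3' along each strand segment; at a closing pair
    the chain jumps across via the pair-centroid node. Closed elements end
    on a repeat of their first node.
    """
    pair_lookup = {}
    for p in e.closing_pairs:
        pair_lookup[p.i] = p
        pair_lookup[p.j] = p

    nodes: list[WireframeNode] = []
    if not e.closed:
        for k, idx in enumerate(e.residues):
            is_5prime = (idx - 1, idx) not in s.covalent_links
            nodes.extend(_backbone_nodes(s, idx, True, allow_missing_p=(k == 0 and is_5prime)))
        e.chain_nodes = nodes
        return e

    res = e.residues
    m = len(res)
    for k, idx in enumerate(res):
        nxt = res[(k + 1) % m]
        forward = _is_forward(res, k)
        nodes.extend(_backbone_nodes(s, idx, forward, allow_missing_p=False))
        pair = pair_lookup.get(idx)
        if pair is not None and (pair.i == idx and pair.j == nxt or
                                 pair.j == idx and pair.i == nxt):
            nodes.append(WireframeNode(_pair_centroid(s, pair), "pair_centroid",
                                       (pair.i, pair.j)))
    nodes.append(nodes[0])
    e.chain_nodes = nodes
    return e


def _is_forward(res: list, k: int) -> bool:
    """Whether traversal passes residue ``res[k]`` in 5'->3' direction."""
    m = len(res)
    nxt = res[(k + 1) % m]
    prv = res[(k - 1) % m]
    if nxt == res[k] + 1:
        return True
    if prv == res[k] - 1:
        return True
    if nxt == res[k] - 1:
        return False
    if prv == res[k] + 1:
        return False
    return True


def build_all_wireframes(s: Structure, ss: SecondaryStructure) -> list[StructuralElement]:
    """Extract every element and construct its wireframe."""
    elements = extract_elements(s, ss)
    for e in elements:
        build_wireframe(e, s, ss)
    return elements
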