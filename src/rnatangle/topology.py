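"""Entanglement detection on triangulated wireframe meshes.

The interior of every closed element is covered by a triangle fan from the
vertex centroid, recursively subdivided (4-way midpoint) until every edge is
shorter than ``max_edge``. Wireframe edges of a partner element are tested
against the mesh with the Möller–Trumbore segment/triangle intersection
test; signed crossings give a linking parity that, for closed curves,
equals the Gauss linking number in magnitude.

Classification of an element pair:

* closed-closed with nonzero linking parity — interlace (D&D / D&L / L&L);
* closed pierced an odd net number of times by an open element, or pierced
  by a closed element with zero mutual linking parity — lasso ``A(B)``
  with ``A`` the pierced (lassoing) element;
* lassos carry a threading depth in nucleotides; an ``L(*)`` lasso with
  depth <= 5 nt is shallow (spontaneously resolvable), everything else —
  interlaces, ``D(*)`` lassos, deep ``L(*)`` lassos — is an artifact.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .elements import StructuralElement, build_all_wireframes
from .structure import SecondaryStructure, Structure

logger = logging.getLogger(__name__)

#: determinant below which a segment is treated as parallel to a triangle
MT_EPS = 1e-9
#: barycentric slack: boundary hits count as hits to avoid parity leaks
BARY_EPS = 1e-9

SHALLOW_MAX_DEPTH = 5  # nt; lassoed fragments spanning <= 5 nt are shallow

INTERLACE_CLASSES = ("D&D", "D&L", "L&L")
LASSO_CLASSES = ("D(D)", "D(L)", "D(S)", "L(D)", "L(L)", "L(S)")
ALL_CLASSES = INTERLACE_CLASSES + LASSO_CLASSES

_KIND_LETTER = {"loop": "L", "dinucleotide_step": "D", "single_strand": "S"}


@dataclass
class DetectionSettings:
    max_edge: float = 2.0  # Å, mesh-refinement stop criterion

    def to_json(self) -> dict:
        return {"max_edge": self.max_edge}


@dataclass
class IntersectionPoint:
    position: np.ndarray
    pierced_element: StructuralElement
    piercing_element: StructuralElement
    piercing_edge: tuple  # node-index pair in the piercer's chain
    orientation: int  # +1/-1, sign of the crossing


@dataclass
class Entanglement:
    cls: str
    element_a: StructuralElement  # lassoing/first element
    element_b: StructuralElement
    points: list
    depth_nt: Optional[int] = None
    shallow: bool = False
    artifact: bool = True

    def to_json(self, s: Optional[Structure] = None) -> dict:
        return {
            "class": self.cls,
            "elements": [self.element_a.to_json(s), self.element_b.to_json(s)],
            "points": [[round(float(x), 3) for x in p.position] for p in self.points],
            "depth": self.depth_nt,
            "shallow": self.shallow,
            "artifact": self.artifact,
        }


@dataclass
class EntanglementReport:
    structure_id: str
    entanglements: list
    puncture_counts: dict
    settings: DetectionSettings = field(default_factory=DetectionSettings)

    def to_json(self, s: Optional[Structure] = None) -> dict:
        return {
            "model": self.structure_id,
            "settings": self.settings.to_json(),
            "entanglements": [e.to_json(s) for e in self.entanglements],
            "puncture_counts": {k: v for k, v in sorted(self.puncture_counts.items())},
        }

    def dumps(self, s: Optional[Structure] = None) -> str:
        return json.dumps(self.to_json(s), indent=2)


# ---------------------------------------------------------------------------
# triangulation


def _distinct_vertices(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, dtype=float)
    if len(chain) > 1 and np.allclose(chain[0], chain[-1]):
        chain = chain[:-1]
    keep = [0]
    for k in range(1, len(chain)):
        if np.linalg.norm(chain[k] - chain[keep[-1]]) > 1e-9:
            keep.append(k)
    return chain[keep]


def triangulate(chain: np.ndarray, max_edge: float):
    """Fan-plus-subdivision mesh over a closed polygonal chain.

    Returns ``(triangles, parents)`` where ``triangles`` has shape
    ``(T, 3, 3)`` and ``parents[t]`` is the index of the fan triangle the
    t-th triangle was subdivided from (used to deduplicate hits).
    """
    verts = _distinct_vertices(chain)
    if len(verts) < 3:
        logger.warning("degenerate chain with <3 distinct vertices; empty mesh")
        return np.empty((0, 3, 3)), np.empty(0, dtype=int)
    centroid = verts.mean(axis=0)
    tris = []
    for k in range(len(verts)):
        tris.append([centroid, verts[k], verts[(k + 1) % len(verts)]])
    tris = np.array(tris)
    areas = _areas(tris)
    keep = areas > 1e-9
    if not np.any(keep):
        logger.warning("collinear chain; empty mesh")
        return np.empty((0, 3, 3)), np.empty(0, dtype=int)
    tris = tris[keep]
    parents = np.arange(len(tris))

    while True:
        edges = tris - np.roll(tris, 1, axis=1)
        longest = np.sqrt((edges ** 2).sum(-1)).max(axis=1)
        split = longest > max_edge
        if not np.any(split):
            break
        big, pb = tris[split], parents[split]
        small, ps = tris[~split], parents[~split]
        a, b, c = big[:, 0], big[:, 1], big[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        new = np.concatenate([
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ])
        tris = np.concatenate([small, new])
        parents = np.concatenate([ps, np.tile(pb, 4)])
    return tris, parents


def _areas(tris: np.ndarray) -> np.ndarray:
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.sqrt((np.cross(e1, e2) ** 2).sum(-1))


# ---------------------------------------------------------------------------
# Möller–Trumbore


def segment_triangle_intersection(p0, p1, triangle):
    """Möller–Trumbore test of segment [p0, p1] against one triangle.

    Returns ``(point, orientation)`` or ``None``; orientation is the sign
    of the segment direction against the triangle normal.
    """
    hits = _mt_batch(np.asarray(p0, float)[None], np.asarray(p1, float)[None],
                     np.asarray(triangle, float)[None])
    if not hits:
        return None
    _, _, t, point, orient = hits[0]
    return point, orient


def _mt_batch(p0s: np.ndarray, p1s: np.ndarray, tris: np.ndarray) -> list:
    """All (segment, triangle) intersections.

    Returns a list of tuples ``(segment_index, triangle_index, t, point,
    orientation)`` with ``t`` the parameter along the segment.
    """
    E, T = len(p0s), len(tris)
    if E == 0 or T == 0:
        return []
    # bound the (E, T, 3) broadcast memory on large meshes
    max_cells = 2_000_000
    if E * T > max_cells:
        out = []
        step = max(max_cells // max(T, 1), 1)
        for lo in range(0, E, step):
            for ei, ti, t, point, orient in _mt_batch(p0s[lo:lo + step],
                                                      p1s[lo:lo + step], tris):
                out.append((ei + lo, ti, t, point, orient))
        return out
    d = (p1s - p0s)[:, None, :]  # (E,1,3)
    v0 = tris[None, :, 0, :]
    e1 = (tris[:, 1] - tris[:, 0])[None, :, :]
    e2 = (tris[:, 2] - tris[:, 0])[None, :, :]
    h = np.cross(np.broadcast_to(d, (E, T, 3)), np.broadcast_to(e2, (E, T, 3)))
    a = (e1 * h).sum(-1)  # (E,T)
    ok = np.abs(a) > MT_EPS
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = p0s[:, None, :] - v0
    u = f * (s * h).sum(-1)
    q = np.cross(s, np.broadcast_to(e1, (E, T, 3)))
    v = f * (np.broadcast_to(d, (E, T, 3)) * q).sum(-1)
    t = f * (np.broadcast_to(e2, (E, T, 3)) * q).sum(-1)
    # segments are half-open in t so a crossing at a node shared by two
    # consecutive piercer edges is counted exactly once
    hit = (ok & (u >= -BARY_EPS) & (v >= -BARY_EPS) & (u + v <= 1.0 + BARY_EPS)
           & (t >= -BARY_EPS) & (t < 1.0 - MT_EPS))
    out = []
    for ei, ti in zip(*np.nonzero(hit)):
        tt = float(t[ei, ti])
        point = p0s[ei] + tt * (p1s[ei] - p0s[ei])
        orient = -int(np.sign(a[ei, ti]))
        out.append((int(ei), int(ti), tt, point, orient))
    return out


# ---------------------------------------------------------------------------
# punctures and parity


def _piercer_segments(piercer: StructuralElement):
    pos = piercer.node_positions()
    return pos[:-1], pos[1:]


def find_punctures(pierced: StructuralElement, piercer: StructuralElement,
                   max_edge: float = 2.0, mesh=None) -> list:
    """Intersection points of the piercer's wireframe with the pierced mesh.

    Piercer edges incident to nodes shared with the pierced boundary are
    excluded; duplicate hits of one edge on subdivided triangles of the
    same parent (or coincident boundary hits) are deduplicated.
    """
    if not pierced.closed:
        raise ValueError("pierced element must be closed")
    if pierced.residue_set & piercer.residue_set:
        return []
    if mesh is None:
        mesh = triangulate(pierced.node_positions(), max_edge)
    tris, parents = mesh
    if len(tris) == 0 or len(piercer.chain_nodes) < 2:
        return []
    p0s, p1s = _piercer_segments(piercer)

    # exclude edges touching nodes shared with the pierced boundary
    pierced_pos = pierced.node_positions()
    shared = np.zeros(len(p0s), dtype=bool)
    for k, (a, b) in enumerate(zip(p0s, p1s)):
        da = np.min(np.sqrt(((pierced_pos - a) ** 2).sum(-1)))
        db = np.min(np.sqrt(((pierced_pos - b) ** 2).sum(-1)))
        if da < 1e-9 or db < 1e-9:
            shared[k] = True
    keep_idx = np.nonzero(~shared)[0]
    if len(keep_idx) == 0:
        return []

    hits = _mt_batch(p0s[keep_idx], p1s[keep_idx], tris)
    per_edge: dict = {}
    for ei, ti, t, point, orient in hits:
        per_edge.setdefault(int(keep_idx[ei]), []).append((t, int(parents[ti]), point, orient))

    punctures = []
    for edge_idx, edge_hits in sorted(per_edge.items()):
        edge_hits.sort(key=lambda h: h[0])
        taken: list = []
        for t, parent, point, orient in edge_hits:
            # a hit on a boundary shared by subdivided triangles appears in
            # both at (numerically) the same t — keep one
            if any(abs(t - t2) < 1e-7 for t2 in taken):
                continue
            taken.append(t)
            punctures.append(IntersectionPoint(
                position=point, pierced_element=pierced, piercing_element=piercer,
                piercing_edge=(edge_idx, edge_idx + 1), orientation=orient))
    return punctures


def linking_parity(a: np.ndarray, b: np.ndarray, max_edge: float = 2.0) -> int:
    """Signed crossing sum of chain ``b`` through the mesh over chain ``a``.

    For closed curves its absolute value equals the magnitude of the Gauss
    linking number.
    """
    ea = StructuralElement("loop", [0], closed=True)
    ea.chain_nodes = [_node(p) for p in _close(a)]
    eb = StructuralElement("loop", [1], closed=True)
    eb.chain_nodes = [_node(p, res=1) for p in _close(b)]
    punct = find_punctures(ea, eb, max_edge)
    return int(sum(p.orientation for p in punct))


def _close(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, float)
    if not np.allclose(chain[0], chain[-1]):
        chain = np.vstack([chain, chain[0]])
    return chain


def _node(p, res=0):
    from .elements import WireframeNode

    return WireframeNode(p, "P", (res,))


# ---------------------------------------------------------------------------
# classification


def _chain_bounds(s: Structure, idx: int) -> tuple:
    """Internal-index range [lo, hi) of the chain containing residue idx."""
    cid = s.residues[idx].chain_id
    ids = [r.internal_index for r in s.residues if r.chain_id == cid]
    return min(ids), max(ids) + 1


def _edge_residue_span(piercer: StructuralElement, edge: tuple) -> tuple:
    nodes = piercer.chain_nodes
    srcs = set(nodes[edge[0]].source_residues) | set(nodes[edge[1]].source_residues)
    return min(srcs), max(srcs)


def lasso_depth(s: Structure, piercer: StructuralElement, punctures: list) -> int:
    """Threaded-fragment size in nucleotides.

    Punctures split the piercer's chain into segments (bounded by punctures
    and by the chain termini); the depth is the smallest segment adjacent
    to a puncture — for a terminal piercer this is the residue distance
    from the puncture to the nearer end of the strand.
    """
    spans = sorted(_edge_residue_span(piercer, p.piercing_edge) for p in punctures)
    lo, hi = _chain_bounds(s, piercer.residues[0])
    sizes = []
    first_a = spans[0][0]
    sizes.append(first_a - lo + 1)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        sizes.append(max(a2 - b1 + 1, 0))
    sizes.append(hi - spans[-1][1])
    return int(min(sizes))


def classify_pair(a: StructuralElement, b: StructuralElement,
                  punctures_ab: list, punctures_ba: list,
                  s: Optional[Structure] = None) -> Optional[Entanglement]:
    """Classify one element pair from its mutual puncture lists.

    ``punctures_ab`` are punctures of ``a``'s mesh by ``b``;
    ``punctures_ba`` the converse (empty when ``b`` is open).
    """
    parity_ab = sum(p.orientation for p in punctures_ab)
    parity_ba = sum(p.orientation for p in punctures_ba)

    if a.closed and b.closed and (parity_ab != 0 or parity_ba != 0):
        letters = sorted((_KIND_LETTER[a.kind], _KIND_LETTER[b.kind]))
        cls = f"{letters[0]}&{letters[1]}"
        first, second = sorted((a, b), key=lambda e: min(e.residues))
        points = punctures_ab + punctures_ba
        return Entanglement(cls, first, second, points, None, False, True)

    if not b.closed:
        if parity_ab % 2 == 1:
            pierced, piercer, points = a, b, punctures_ab
        else:
            return None
    else:
        if not punctures_ab and not punctures_ba:
            return None
        # zero linking: the element with more crossings through it is lassoed
        if len(punctures_ab) > len(punctures_ba):
            pierced, piercer, points = a, b, punctures_ab
        elif len(punctures_ba) > len(punctures_ab):
            pierced, piercer, points = b, a, punctures_ba
        else:
            pierced, piercer, points = sorted(
                ((a, b, punctures_ab), (b, a, punctures_ba)),
                key=lambda t: min(t[0].residues))[0]
    if s is not None:
        depth = lasso_depth(s, piercer, points)
    else:
        depth = None
    cls = f"{_KIND_LETTER[pierced.kind]}({_KIND_LETTER[piercer.kind]})"
    shallow = cls.startswith("L(") and depth is not None and depth <= SHALLOW_MAX_DEPTH
    artifact = not shallow
    return Entanglement(cls, pierced, piercer, points, depth, shallow, artifact)


# ---------------------------------------------------------------------------
# end-to-end detection


def detect_entanglements(s: Structure, ss: Optional[SecondaryStructure] = None,
                         settings: Optional[DetectionSettings] = None,
                         structure_id: str = "model",
                         elements: Optional[list] = None) -> EntanglementReport:
    """Run the full detection: elements -> wireframes -> pairwise topology."""
    from .structure import annotate_base_pairs

    if ss is None:
        ss = annotate_base_pairs(s)
    if settings is None:
        settings = DetectionSettings()
    if elements is None:
        elements = build_all_wireframes(s, ss)

    closed = [e for e in elements
              if e.closed and len(_distinct_vertices(e.node_positions())) >= 3]
    meshes = {id(e): triangulate(e.node_positions(), settings.max_edge) for e in closed}

    found = []
    counts: dict = {}
    for a, b in itertools.combinations(elements, 2):
        if not (a.closed or b.closed):
            continue
        if a.residue_set & b.residue_set:
            continue
        if not a.closed:
            a, b = b, a
        if a not in closed:
            continue
        p_ab = find_punctures(a, b, settings.max_edge, mesh=meshes[id(a)])
        p_ba = []
        if b.closed and b in closed:
            p_ba = find_punctures(b, a, settings.max_edge, mesh=meshes[id(b)])
        ent = classify_pair(a, b, p_ab, p_ba, s)
        if ent is not None:
            found.append(ent)
            for e, cnt in ((a, len(p_ab)), (b, len(p_ba))):
                if cnt:
                    counts[e.label(s)] = counts.get(e.label(s), 0) + cnt
    found.sort(key=lambda e: (min(min(e.element_a.residues), min(e.element_b.residues)),
                              e.cls))
    return EntanglementReport(structure_id, found, counts, settings)
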