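"""Pre-simulation step: merge related entanglements and plan loop reduction.

Entanglements that share a structural element are merged into one group
when their remaining elements are themselves connected (sequence-adjacent,
overlapping, or nested); the group is then treated as a single case.

For the classes amenable to it (the L&L and D&L interlaces and the L(S)
and D(S) lassos) every loop or strand larger than 5 nt is reduced to a
short window of unpaired residues nearest the intersection points; if all
of a loop's residues are paired, a window around two consecutive residues
that do not belong to one dinucleotide step is used instead, and when no
such segment exists the element stays unreduced and the group falls back
to whole-loop steering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .elements import StructuralElement
from .structure import SecondaryStructure, Structure
from .topology import Entanglement

#: elements larger than this many nucleotides get reduced
REDUCTION_SIZE_LIMIT = 5
#: classes the reduced-swap scheme applies to
REDUCIBLE_CLASSES = frozenset({"L&L", "D&L", "L(S)", "D(S)"})
#: the reduced window spans the anchor residues +/-1, clamped to [2, 6]
WINDOW_MIN = 2
WINDOW_MAX = 6


@dataclass
class EntanglementGroup:
    members: list

    @property
    def involved_elements(self) -> list:
        seen = []
        for e in self.members:
            for el in (e.element_a, e.element_b):
                if not any(el is s for s in seen):
                    seen.append(el)
        return seen

    @property
    def residue_set(self) -> frozenset:
        out = set()
        for el in self.involved_elements:
            out |= el.residue_set
        return frozenset(out)


@dataclass
class ReductionPlan:
    #: element id -> (start, stop) half-open residue window, or None
    windows: dict = field(default_factory=dict)
    strategy: str = "full_loop"  # or "reduced_swap"

    def window_for(self, element: StructuralElement) -> Optional[tuple]:
        return self.windows.get(id(element))

    def to_json(self, group: EntanglementGroup) -> dict:
        return {
            "strategy": self.strategy,
            "windows": [
                {"element": el.label(), "window": list(self.windows[id(el)])}
                for el in group.involved_elements
                if self.windows.get(id(el)) is not None
            ],
        }


def _elements_connected(a: StructuralElement, b: StructuralElement) -> bool:
    """Adjacent in sequence (gap <= 1), overlapping, or nested ranges."""
    ra = a.residue_set
    rb = b.residue_set
    if ra & rb:
        return True
    lo_a, hi_a = min(ra), max(ra)
    lo_b, hi_b = min(rb), max(rb)
    if lo_a >= lo_b and hi_a <= hi_b or lo_b >= lo_a and hi_b <= hi_a:
        return True
    gap = max(lo_a, lo_b) - min(hi_a, hi_b)
    return gap <= 2  # boundary residues at most 1 apart


def _should_merge(e1: Entanglement, e2: Entanglement) -> bool:
    els1 = [e1.element_a, e1.element_b]
    els2 = [e2.element_a, e2.element_b]
    shared = [(x, y) for x in els1 for y in els2 if x is y]
    if not shared:
        return False
    rest1 = [x for x in els1 if not any(x is s for s, _ in shared)]
    rest2 = [y for y in els2 if not any(y is s for _, s in shared)]
    if not rest1 or not rest2:
        return True
    return any(_elements_connected(x, y) for x in rest1 for y in rest2)


def merge_entanglements(entanglements) -> list:
    """Union-find merge to disjoint groups; idempotent and order-invariant."""
    es = sorted(entanglements,
                key=lambda e: (min(min(e.element_a.residues), min(e.element_b.residues)),
                               e.cls))
    parent = list(range(len(es)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(es)):
        for j in range(i + 1, len(es)):
            if _should_merge(es[i], es[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict = {}
    for i in range(len(es)):
        groups.setdefault(find(i), []).append(es[i])
    return [EntanglementGroup(v) for _, v in sorted(groups.items())]


# ---------------------------------------------------------------------------
# reduction planning


def _unpaired_runs(residues, ss: SecondaryStructure):
    pm = ss.partner_map()
    runs, run = [], []
    for idx in sorted(residues):
        if pm[idx] == -1:
            if run and idx != run[-1] + 1:
                runs.append(run)
                run = []
            run.append(idx)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    return runs


def _element_steps(element: StructuralElement, ss: SecondaryStructure, links) -> set:
    """Residues of the element that belong to some dinucleotide step."""
    pm = ss.partner_map()
    out = set()
    for i in element.residues:
        j = pm[i]
        if j == -1:
            continue
        lo, hi = min(i, j), max(i, j)
        for (a, b) in (((lo, hi), (lo + 1, hi - 1)), ((lo - 1, hi + 1), (lo, hi))):
            (i1, j1), (i2, j2) = a, b
            if j2 <= i2:
                continue
            if pm[i1] == j1 and 0 <= i2 < len(pm) and pm[i2] == j2 \
                    and (i1, i1 + 1) in links and (j2, j2 + 1) in links:
                out.add(i)
    return out


def _nearest_window(candidates, points, element, s: Structure):
    """Window of candidate residues around the one nearest the punctures."""
    if not candidates:
        return None
    best = None
    for idx in sorted(candidates):
        r = s.residues[idx]
        coords = [a.position for a in r.atoms if a.name in ("P", "C4'")]
        d = min(float(np.linalg.norm(c - p)) for c in coords for p in points)
        if best is None or d < best[0]:
            best = (d, idx)
    anchor = best[1]
    cand = sorted(candidates)
    pos = cand.index(anchor)
    lo = pos
    hi = pos + 1
    # grow to anchor +/- 1 within the candidate run, bounded by WINDOW_MAX
    while hi - lo < WINDOW_MAX:
        grew = False
        if lo > 0 and cand[lo - 1] == cand[lo] - 1 and hi - lo < WINDOW_MAX:
            lo -= 1
            grew = True
        if hi < len(cand) and hi - lo < WINDOW_MAX and (hi == len(cand) or True):
            if hi < len(cand) and cand[hi] == cand[hi - 1] + 1:
                hi += 1
                grew = True
        if not grew:
            break
        if hi - lo >= 3:  # anchor +/- 1 achieved
            break
    if hi - lo < WINDOW_MIN:
        # extend along the element regardless of pairing as a last resort
        return None
    return (cand[lo], cand[hi - 1] + 1)


def plan_reduction(group: EntanglementGroup, ss: SecondaryStructure,
                   s: Structure) -> ReductionPlan:
    """Reduction windows for one merged group.

    Only groups whose every member is in a reducible class are eligible for
    the reduced-swap scheme; any element that cannot be reduced (too small
    elements are left whole, which is fine) keeps the group on reduced_swap
    unless a large loop is fully paired with no usable segment.
    """
    plan = ReductionPlan()
    if any(e.cls not in REDUCIBLE_CLASSES for e in group.members):
        plan.strategy = "full_loop"
        return plan
    points = [p.position for e in group.members for p in e.points]
    plan.strategy = "reduced_swap"
    for el in group.involved_elements:
        if len(el.residues) <= REDUCTION_SIZE_LIMIT:
            plan.windows[id(el)] = None
            if el.closed and all(ss.partner_map()[i] != -1 for i in el.residues):
                # a small fully-paired ring (a dinucleotide step) cannot be
                # swapped without destroying its pairs
                plan.strategy = "full_loop"
            continue
        # exclude residues of closing pairs where possible
        closing = {r for p in el.closing_pairs for r in (p.i, p.j)}
        unpaired = [i for i in el.residues
                    if ss.partner_map()[i] == -1 and i not in closing]
        window = _nearest_window(unpaired, points, el, s)
        if window is None:
            # fully paired loop: look for two consecutive residues not in
            # one dinucleotide step
            in_step = _element_steps(el, ss, s.covalent_links)
            res = sorted(el.residues)
            pairable = [i for i in res if i not in in_step]
            window = _nearest_window(pairable, points, el, s)
            if window is None:
                plan.windows[id(el)] = None
                plan.strategy = "full_loop"
                continue
        plan.windows[id(el)] = window
    return plan
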