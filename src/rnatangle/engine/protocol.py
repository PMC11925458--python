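"""The untangling protocol: detect, steer apart, restore, backmap.

Per merged entanglement group the protocol (i) minimises the coarse-grained
system, (ii) steers the entangled elements apart with virtual sites while
their mutual excluded volume is off, checking the topology periodically,
(iii) restores the original fold with ramped tethers and excluded volume
back on (which blocks re-threading), and (iv) re-checks the topology. A
failed attempt escalates from the reduced-swap scheme to whole-loop
steering, up to a bounded number of attempts. Finally the system is
backmapped to all-atom coordinates and re-annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..elements import StructuralElement, build_all_wireframes
from ..preprocess import EntanglementGroup, ReductionPlan, merge_entanglements, plan_reduction
from ..structure import SecondaryStructure, Structure, annotate_base_pairs
from ..topology import DetectionSettings, EntanglementReport, classify_pair, detect_entanglements, find_punctures, triangulate
from .cg import MCState, backmap, coarse_grain
from .mc import minimize, run_mc
from .model import EnergyModel, EngineSettings

logger = logging.getLogger(__name__)


@dataclass
class VirtualSite:
    position: np.ndarray
    role: str  # loop_center, closing_pair_midpoint, swap_midpoint
    attached_element: Optional[StructuralElement]
    fixed: bool


@dataclass
class GroupOutcome:
    group_index: int
    classes: list
    strategy: str
    outcome: str  # resolved, transformed, unresolved
    attempts: int
    sweeps: int
    residues: list  # sorted residue indices involved

    def to_json(self) -> dict:
        return {"group": self.group_index, "classes": self.classes,
                "strategy": self.strategy, "outcome": self.outcome,
                "attempts": self.attempts, "sweeps": self.sweeps,
                "residues": self.residues}


@dataclass
class UntangleResult:
    structure: Structure
    outcomes: list
    initial_report: EntanglementReport
    final_report: EntanglementReport
    pair_disruptions: list = field(default_factory=list)

    @property
    def all_resolved(self) -> bool:
        return all(o.outcome == "resolved" for o in self.outcomes)

    def to_json(self) -> dict:
        return {
            "outcomes": [o.to_json() for o in self.outcomes],
            "initial_entanglements": len(self.initial_report.entanglements),
            "final_entanglements": len(self.final_report.entanglements),
            "pair_disruptions": self.pair_disruptions,
        }


# ---------------------------------------------------------------------------
# bead masks and virtual sites


def _element_bead_mask(state: MCState, element: StructuralElement) -> np.ndarray:
    mask = np.zeros(state.n_beads, dtype=bool)
    for r in element.residues:
        mask[2 * r] = True
        mask[2 * r + 1] = True
    return mask


def _group_masks(state: MCState, group: EntanglementGroup):
    """Boolean masks of the two element sides of a group (a-side, b-side)."""
    mask_a = np.zeros(state.n_beads, dtype=bool)
    mask_b = np.zeros(state.n_beads, dtype=bool)
    for e in group.members:
        mask_a |= _element_bead_mask(state, e.element_a)
        mask_b |= _element_bead_mask(state, e.element_b)
    return mask_a, mask_b


def _beads_centroid(state: MCState, residues) -> np.ndarray:
    idx = [b for r in residues for b in (2 * r, 2 * r + 1)]
    return state.positions[idx].mean(axis=0)


def _gyration_radius(state: MCState, element: StructuralElement) -> float:
    idx = [b for r in element.residues for b in (2 * r, 2 * r + 1)]
    pts = state.positions[idx]
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum(-1).mean()))


def place_virtual_sites(group: EntanglementGroup, plan: ReductionPlan,
                        state: MCState) -> list:
    """Virtual sites for one group under the planned strategy."""
    sites: list = []
    if plan.strategy == "reduced_swap":
        for e in group.members:
            for el in (e.element_a, e.element_b):
                window = plan.window_for(el)
                residues = range(*window) if window else el.residues
                sites.append(VirtualSite(_beads_centroid(state, residues),
                                         "swap_midpoint", el, fixed=True))
    else:
        seen = set()
        for el in group.involved_elements:
            if not el.closed or id(el) in seen:
                continue
            seen.add(id(el))
            sites.append(VirtualSite(_beads_centroid(state, el.residues),
                                     "loop_center", el, fixed=False))
            for p in el.closing_pairs:
                mid = 0.5 * (state.positions[2 * p.i + 1] + state.positions[2 * p.j + 1])
                sites.append(VirtualSite(mid, "closing_pair_midpoint", el, fixed=False))
    return sites


def _wire_steering(model: EnergyModel, state: MCState, group: EntanglementGroup,
                   plan: ReductionPlan, sites: list):
    """Install the steering terms for one group attempt."""
    s = model.settings
    model.clear_steering()
    if plan.strategy == "reduced_swap":
        by_el = {id(st.attached_element): st for st in sites}
        for e in group.members:
            a, b = e.element_a, e.element_b
            sa, sb = by_el[id(a)], by_el[id(b)]
            for el, own, opp in ((a, sa, sb), (b, sb, sa)):
                window = plan.window_for(el)
                residues = range(*window) if window else el.residues
                for r in residues:
                    for bead in (2 * r, 2 * r + 1):
                        model.add_steering(bead, own.position, 0,
                                           s.k_swap_repel, s.r_swap_repel)
                        model.add_steering(bead, opp.position, 1,
                                           s.k_swap_attract, 0.0)
    else:
        by_el: dict = {}
        for st in sites:
            by_el.setdefault(id(st.attached_element), []).append(st)
        for e in group.members:
            for el, partner in ((e.element_a, e.element_b), (e.element_b, e.element_a)):
                partner_sites = by_el.get(id(partner), [])
                if not partner_sites:
                    continue
                rad = _gyration_radius(state, partner) + s.steer_pad
                for r in el.residues:
                    for bead in (2 * r, 2 * r + 1):
                        for st in partner_sites:
                            if st.role == "loop_center":
                                model.add_steering(bead, st.position, 0,
                                                   s.k_steer, rad)
                            else:
                                model.add_steering(bead, st.position, 0,
                                                   s.k_barrier, s.r_barrier)
    model.finalize_steering()


# ---------------------------------------------------------------------------
# topology checks on current coordinates


def _elements_by_set(structure: Structure, ss: SecondaryStructure) -> dict:
    els = build_all_wireframes(structure, ss)
    return {(e.kind, e.residue_set): e for e in els}


def _group_entangled(state: MCState, original: Structure, ss: SecondaryStructure,
                     group: EntanglementGroup, settings: EngineSettings):
    """Re-classify the group's element pairs on current coordinates.

    Returns the list of (member, detected entanglement or None).
    """
    current = backmap(state, original, ss, regularise=False)
    lookup = _elements_by_set(current, ss)
    results = []
    for e in group.members:
        a = lookup.get((e.element_a.kind, e.element_a.residue_set))
        b = lookup.get((e.element_b.kind, e.element_b.residue_set))
        if a is None or b is None:
            results.append((e, None))
            continue
        if not a.closed:
            a, b = b, a
        p_ab = find_punctures(a, b, settings.mesh_edge)
        p_ba = find_punctures(b, a, settings.mesh_edge) if b.closed else []
        results.append((e, classify_pair(a, b, p_ab, p_ba, current)))
    return results


def _group_cleared(state, original, ss, group, settings) -> bool:
    return all(ent is None for _, ent in _group_entangled(
        state, original, ss, group, settings))


# ---------------------------------------------------------------------------
# protocol phases


def steer_apart(state: MCState, model: EnergyModel, sites: list,
                group: EntanglementGroup, plan: ReductionPlan,
                original: Structure, ss: SecondaryStructure,
                rng: np.random.Generator) -> bool:
    """Metropolis steering until the group's topology clears (or budget).

    Loop-center and closing-pair sites track their elements; fixed
    swap-midpoint sites do not. Returns True when re-detection cleared.
    """
    s = model.settings
    cleared = [False]

    def update_sites(_sweep=None):
        if plan.strategy != "reduced_swap":
            for st in sites:
                if st.fixed:
                    continue
                el = st.attached_element
                if st.role == "loop_center":
                    st.position = _beads_centroid(state, el.residues)
            # re-wire steering with moved sites
            _wire_steering(model, state, group, plan, sites)

    def check(sweep):
        update_sites()
        if _group_cleared(state, original, ss, group, settings=s):
            cleared[0] = True
            return True
        return False

    chunk = max(s.site_update_every, 1)
    done = 0
    consolidating = 0
    ramp_hold = None
    while done < s.sweeps_steer:
        n = min(chunk, s.sweeps_steer - done)
        f0 = done / s.sweeps_steer
        f1 = (done + n) / s.sweeps_steer
        # ramp to full strength over the first quarter; once separation is
        # detected, hold the ramp so consolidation does not overshoot
        ramp0 = ramp_hold if ramp_hold is not None else min(4 * f0, 1.0)
        ramp1 = ramp_hold if ramp_hold is not None else min(4 * f1, 1.0)
        run_mc(state, model, n, greedy=False, ramp_from=ramp0, ramp_to=ramp1,
               rng=rng)
        done += n
        update_sites()
        if consolidating:
            consolidating -= n
            if consolidating <= 0:
                # separation must persist, not just flicker through a check
                if _group_cleared(state, original, ss, group, settings=s):
                    cleared[0] = True
                    break
                consolidating = 0
                ramp_hold = None
        elif done % s.redetect_every < chunk:
            if _group_cleared(state, original, ss, group, settings=s):
                consolidating = min(1000, s.sweeps_steer - done)
                ramp_hold = min(4 * done / s.sweeps_steer, 1.0)
                if consolidating <= 0:
                    cleared[0] = True
                    break
    return cleared[0]


def _disk_distance(p, centre, axis, r_disk) -> float:
    d = p - centre
    ax = float(d @ axis)
    rad = max(float(np.linalg.norm(d - ax * axis)) - r_disk, 0.0)
    return float(np.hypot(ax, rad))


def _guard_terms(model: EnergyModel, state: MCState, group: EntanglementGroup,
                 original: Structure, ss: SecondaryStructure,
                 sides: Optional[dict] = None):
    """Repulsive disks over each pierced ring, tracking its current shape.

    The ring geometry is taken from the current backmapped wireframe (the
    same nodes the detector uses), so the guarded disk covers the actual
    pierced surface. The guard herds each piercer off the ring surface as
    the ring migrates back to its reference, so the tethers cannot pull
    the threaded fragment back through.
    """
    from ..geometry import plane_normal

    s = model.settings
    model.clear_steering()
    blocked: dict = {}
    current = backmap(state, original, ss, regularise=False)
    lookup = _elements_by_set(current, ss)
    for e in group.members:
        for pierced, piercer in ((e.element_a, e.element_b),
                                 (e.element_b, e.element_a)):
            if not pierced.closed or len(pierced.residues) < 3:
                continue
            cur = lookup.get((pierced.kind, pierced.residue_set))
            if cur is None or len(cur.chain_nodes) < 4:
                continue
            nodes = cur.node_positions()
            centre = nodes.mean(axis=0)
            axis = plane_normal(nodes)
            rel = nodes - centre
            axial = rel @ axis
            lateral = np.sqrt(np.maximum((rel ** 2).sum(-1) - axial ** 2, 0))
            r_disk = float(lateral.max()) + 1.0
            # the wall must cover the ring's off-plane excursions or a
            # strand can slip through the collar between the flat disk and
            # the actual ring curve
            pad = float(np.abs(axial).max()) + s.guard_pad
            beads = [b for r in piercer.residues for b in (2 * r, 2 * r + 1)]
            # one-sided wall: the allowed side is where the formerly
            # threaded fragment sits when restoration starts (its
            # references lie within the disk region); the choice is pinned
            # for the whole restoration so the wall can never flip sides
            key = (id(pierced), id(piercer))
            if sides is not None and key in sides:
                # orientation pinned at restoration start: re-sign the
                # current (drifting) normal against the stored direction
                oriented = axis if float(sides[key] @ axis) >= 0 else -axis
            else:
                core = [b for b in beads
                        if _disk_distance(state.reference[b], centre, axis,
                                          r_disk) < pad]
                witnesses = core if core else beads
                side = sum(float((state.positions[b] - centre) @ axis)
                           for b in witnesses)
                oriented = axis if side >= 0 else -axis
                if sides is not None:
                    sides[key] = oriented.copy()
            for bead in beads:
                model.add_steering(bead, centre, 3, s.k_guard,
                                   pad, axis=oriented, radius2=r_disk)
                # references at or behind the wall are only reachable via
                # a detour around the rim; taper those tethers so the
                # detour slack spreads over several bonds instead of
                # tearing the backbone next to the ring
                d_ref = _disk_distance(state.reference[bead], centre, oriented,
                                       r_disk)
                scale = min(max((d_ref - 4.0) / 10.0, 0.05), 1.0)
                blocked[bead] = min(blocked.get(bead, 1.0), scale)
    model.finalize_steering()
    return blocked


def steered_restore(state: MCState, model: EnergyModel, free_mask,
                    rng: np.random.Generator,
                    group: Optional[EntanglementGroup] = None,
                    original: Optional[Structure] = None,
                    ss: Optional[SecondaryStructure] = None) -> None:
    """Restore the fold while a tracking guard protects the new topology.

    The separation steering is removed and excluded volume is back on;
    tethers to the reference positions ramp up linearly, followed by a
    greedy quench that removes the thermal noise. One residual biasing
    term remains throughout — a repulsive disk spanning each formerly
    pierced ring (:func:`_guard_terms`), refreshed as the ring migrates
    back — because the tethers' global minimum IS the original, entangled
    configuration, and an open ring several bead diameters wide cannot be
    blocked by excluded volume alone.
    """
    s = model.settings
    model.clear_steering()
    chunk = 500
    total = s.sweeps_restore
    done = 0
    free_idx = np.nonzero(free_mask)[0]

    def set_ramped_tethers(frac, blocked):
        # every bead ramps toward the strong restore tether (elements were
        # steered, but their neighbourhood may have been dragged too);
        # tapered piercer beads stay weak near the wall
        k_final = np.full(state.n_beads, s.k_tether_restore)
        for bead, scale in blocked.items():
            k_final[bead] = s.k_tether_restore * scale
        k_now = np.maximum(frac * k_final, s.k_tether)
        k_now[free_idx] = frac * k_final[free_idx]
        model.tether_k[:] = k_now

    blocked: dict = {}
    sides: dict = {}
    refresh = 0
    while done < total:
        n = min(chunk, total - done)
        if group is not None and refresh <= 0:
            blocked = _guard_terms(model, state, group, original, ss, sides)
            refresh = 2
        refresh -= 1
        set_ramped_tethers(done / total, blocked)
        run_mc(state, model, n, greedy=False, rng=rng)
        done += n
    # greedy quench toward the references under the same guard
    for sweeps, sigma in ((1000, None), (1000, 0.1), (1500, 0.04)):
        if group is not None:
            blocked = _guard_terms(model, state, group, original, ss, sides)
        set_ramped_tethers(1.0, blocked)
        minimize(state, model, sweeps, rng=rng, move_sigma=sigma)


# ---------------------------------------------------------------------------
# full protocol


def run_protocol(s: Structure, ss: Optional[SecondaryStructure] = None,
                 settings: Optional[EngineSettings] = None) -> UntangleResult:
    """Run the full detection + untangling + restoration pipeline."""
    settings = settings or EngineSettings()
    if ss is None:
        ss = annotate_base_pairs(s)
    det = DetectionSettings(max_edge=settings.mesh_edge)
    initial = detect_entanglements(s, ss, det)
    if not initial.entanglements:
        return UntangleResult(s.copy(), [], initial, initial)

    groups = merge_entanglements(initial.entanglements)
    state = coarse_grain(s, seed=settings.seed)
    model = EnergyModel.build(s, state, settings, ss=ss)
    outcomes = []
    for gi, group in enumerate(groups):
        group_seed = settings.seed + gi
        rng = np.random.default_rng(group_seed)
        plan = plan_reduction(group, ss, s)
        mask_a, mask_b = _group_masks(state, group)
        free = mask_a | mask_b
        # for lassos only the piercer is steered away; the lassoing ring
        # stays tethered so the rest of the fold is not dragged along
        all_lassos = all(e.depth_nt is not None for e in group.members)
        steer_free = mask_b if all_lassos else free
        snapshot = state.positions.copy()
        outcome = "unresolved"
        attempts = 0
        strategy_used = plan.strategy
        for attempt in range(settings.max_attempts):
            attempts += 1
            attempt_plan = plan
            if attempt > 0:
                attempt_plan = ReductionPlan(strategy="full_loop")
            strategy_used = attempt_plan.strategy
            state.positions[:] = snapshot
            # phase 1: minimisation with full excluded volume
            model.reset_phase(None, None)
            model.set_tethers(settings.k_tether)
            model.clear_steering()
            minimize(state, model, rng=rng)
            # phase 2: steering with cross excluded volume off; when the
            # piercer is an open strand, the pierced element keeps its
            # tether so that separation comes from the strand leaving, not
            # from the ring drifting off the strand
            model.reset_phase(mask_a, mask_b, cross_off=True)
            model.set_tethers(settings.k_tether, steer_free, 0.0)
            sites = place_virtual_sites(group, attempt_plan, state)
            _wire_steering(model, state, group, attempt_plan, sites)
            steer_apart(state, model, sites, group, attempt_plan, s, ss, rng)
            # phase 3: restoration; excluded volume is back on with the
            # native-contact exemption (reference-close pairs are not
            # penalised — the topology is protected by the ring wall, and
            # repelling native contacts would distort the restored fold)
            model.reset_phase(None, None)
            model.set_tethers(settings.k_tether)
            steered_restore(state, model, free, rng, group, s, ss)
            detected = _group_entangled(state, s, ss, group, settings)
            if all(ent is None for _, ent in detected):
                outcome = "resolved"
                break
            if any(ent is not None and ent.cls != member.cls
                   for member, ent in detected):
                outcome = "transformed"
            else:
                outcome = "unresolved"
        outcomes.append(GroupOutcome(
            gi, [e.cls for e in group.members], strategy_used, outcome,
            attempts, state.sweeps, sorted(group.residue_set)))

    final_structure = backmap(state, s, ss)
    scope = set()
    for g in groups:
        lo, hi = min(g.residue_set), max(g.residue_set)
        scope.update(range(max(lo - 2, 0), min(hi + 3, len(s))))
    _final_regularisation(final_structure, protect=frozenset(
        r for r in range(len(s)) if r not in scope))
    final_report = detect_entanglements(final_structure, ss, det)
    disruptions = _pair_disruptions(final_structure, ss, groups)
    return UntangleResult(final_structure, outcomes, initial, final_report,
                          disruptions)


def _final_regularisation(structure: Structure, protect=frozenset()) -> None:
    """All-atom geometric clean-up standing in for force-field refinement.

    Local clash polishing (backbone/ribose atoms only, P and C1' pinned)
    plus the bounded O3'-P junction regularisation. Displacements are
    fractions of an Ångström, far below anything that could alter the
    topology.
    """
    from ..fixtures import _polish_residue, polish_clashes

    residues = [(r.base_identity if r.base_identity in "ACGU" else "A",
                 {a.name: a.position.copy() for a in r.atoms})
                for r in structure.residues]
    polish_clashes(residues, max_rounds=2, protect=protect)
    # any backbone junction still over length is repaired by refitting its
    # 5' residue (the refit re-anchors O3' exactly one bond from the next P)
    for _ in range(2):
        over = []
        for (i, j) in sorted(structure.covalent_links):
            a1 = residues[i][1].get("O3'")
            a2 = residues[j][1].get("P")
            if a1 is not None and a2 is not None                     and np.linalg.norm(a1 - a2) > 2.1:
                over.append(i)
        if not over:
            break
        for i in over:
            _polish_residue(residues, i)
    for r, (_, atoms) in zip(structure.residues, residues):
        for a in r.atoms:
            if a.name in atoms:
                a.position = atoms[a.name]


def _pair_disruptions(final: Structure, ss: SecondaryStructure, groups) -> list:
    """Canonical pairs of formerly entangled loops lost after the protocol.

    A disrupted pair can silently turn a previously detectable entanglement
    undetectable, so it is reported rather than trusted.
    """
    new_ss = annotate_base_pairs(final)
    new_pairs = new_ss.pair_set()
    lost = []
    involved = set()
    for g in groups:
        for el in g.involved_elements:
            for p in el.closing_pairs:
                involved.add((p.i, p.j))
    for pair in sorted(involved):
        if pair not in new_pairs:
            lost.append(list(pair))
    return lost
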