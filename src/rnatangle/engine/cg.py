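"""Two-bead-per-residue coarse graining and all-atom backmapping.

Each residue contributes a backbone bead at its C4' atom and a base bead at
the centroid of its base heavy atoms (residues without base atoms get a
pseudo-base bead at a fixed 4 Å offset). Backmapping transplants each
residue's original all-atom geometry rigidly, using the least-squares fit
of its own and flanking reference beads onto the current beads, followed by
a bounded geometric regularisation of O3'-P junction lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..geometry import kabsch, unit
from ..structure import AtomRecord, Residue, Structure

#: target backbone junction length (Å) for regularisation
JUNCTION_TARGET = 1.6
#: junctions longer than this (Å) count as broken
JUNCTION_BROKEN = 2.2


@dataclass
class MCState:
    """Bead coordinates plus bookkeeping of one coarse-grained system."""

    positions: np.ndarray  # (2n, 3); bead 2k = backbone, 2k+1 = base
    reference: np.ndarray  # (2n, 3), immutable original positions
    residue_of: np.ndarray  # (2n,) residue internal index per bead
    seed: int = 0
    sweeps: int = 0
    accepted: int = 0
    attempted: int = 0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return self.n_beads // 2

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0

    def backbone_bead(self, residue: int) -> int:
        return 2 * residue

    def base_bead(self, residue: int) -> int:
        return 2 * residue + 1

    def copy(self) -> "MCState":
        return MCState(self.positions.copy(), self.reference.copy(),
                       self.residue_of.copy(), self.seed, self.sweeps,
                       self.accepted, self.attempted)


def coarse_grain(s: Structure, seed: int = 0) -> MCState:
    """Build the two-bead representation of a structure."""
    import logging

    n = len(s)
    pos = np.zeros((2 * n, 3))
    residue_of = np.repeat(np.arange(n), 2)
    for r in s.residues:
        k = r.internal_index
        pos[2 * k] = r.coord("C4'")
        centroid = r.base_centroid()
        if centroid is None:
            logging.getLogger(__name__).warning(
                "residue %s%d lacks base atoms; pseudo-base bead used",
                r.chain_id, r.author_number)
            centroid = r.coord("C4'") + 4.0 * np.array([1.0, 0.0, 0.0])
        pos[2 * k + 1] = centroid
    return MCState(pos, pos.copy(), residue_of, seed=seed)


def _fit_indices(state: MCState, residue: int, links, partner: int = -1) -> list:
    idx = [state.backbone_bead(residue), state.base_bead(residue)]
    if (residue - 1, residue) in links:
        idx.append(state.backbone_bead(residue - 1))
    if (residue, residue + 1) in links:
        idx.append(state.backbone_bead(residue + 1))
    if partner >= 0:
        idx.append(state.base_bead(partner))
    return idx


def backmap(state: MCState, original: Structure, ss=None,
            regularise: bool = True) -> Structure:
    """All-atom structure from the current bead configuration.

    When the secondary structure is given, a paired residue's rigid fit
    also includes its partner's base bead, which keeps the base aimed at
    its partner and preserves the pair geometry.
    """
    out = original.copy()
    links = original.covalent_links
    partner = None
    if ss is not None:
        partner = ss.partner_map()

    def own_disp(k):
        own = [state.backbone_bead(k), state.base_bead(k)]
        return float(np.sqrt(((state.positions[own] - state.reference[own]) ** 2
                              ).sum(-1)).max())

    done = set()
    for r in out.residues:
        k = r.internal_index
        if k in done:
            continue
        p = int(partner[k]) if partner is not None else -1
        if own_disp(k) < 0.5 and (p < 0 or own_disp(p) < 0.5):
            # sub-resolution move: the two-bead model cannot resolve it,
            # so the residue keeps its exact original geometry
            done.add(k)
            continue
        if p >= 0:
            # paired residues move as one rigid body, which preserves the
            # pair geometry exactly through any displacement
            idx = []
            for q in (k, p):
                idx.extend([state.backbone_bead(q), state.base_bead(q)])
                if (q - 1, q) in links:
                    idx.append(state.backbone_bead(q - 1))
                if (q, q + 1) in links:
                    idx.append(state.backbone_bead(q + 1))
            weights = np.array([8.0 if i in (2 * k, 2 * k + 1, 2 * p, 2 * p + 1)
                                else 1.0 for i in idx])
            R, t = kabsch(state.reference[idx], state.positions[idx], weights)
            for q in (k, p):
                for a in out.residues[q].atoms:
                    a.position = R @ a.position + t
                done.add(q)
            continue
        idx = _fit_indices(state, k, links, -1)
        weights = np.array([8.0, 8.0] + [1.0] * (len(idx) - 2))
        R, t = kabsch(state.reference[idx], state.positions[idx], weights)
        for a in r.atoms:
            a.position = R @ a.position + t
        done.add(k)
    if regularise:
        _regularise_junctions(out, partner=partner)
    return out


def _regularise_junctions(s: Structure, max_iter: int = 40,
                          max_shift: float = 2.5, partner=None) -> None:
    """Pull O3'-P junction lengths toward the covalent target.

    Each offending junction moves both flanking residues rigidly by half
    the correction (capped per step), iterated to propagate along the
    chain. A paired residue drags its partner along, so regularisation
    never shears a base pair apart. The cumulative displacement per
    residue is bounded by ``max_shift`` so regularisation can never drag a
    strained fragment across another element (which would silently change
    the topology).
    """
    moved = np.zeros(len(s))
    for _ in range(max_iter):
        worst = 0.0
        for (i, j) in sorted(s.covalent_links):
            ri, rj = s.residues[i], s.residues[j]
            if not (ri.has("O3'") and rj.has("P")):
                continue
            o3 = ri.coord("O3'")
            p = rj.coord("P")
            d = float(np.linalg.norm(p - o3))
            err = d - JUNCTION_TARGET
            if abs(err) < 0.45:
                continue
            worst = max(worst, abs(err))
            step = np.clip(0.5 * err, -0.35, 0.35)
            for res, sgn in ((ri, 1.0), (rj, -1.0)):
                group = [res.internal_index]
                if partner is not None and partner[res.internal_index] >= 0:
                    group.append(int(partner[res.internal_index]))
                allowed = min(max_shift - moved[k] for k in group)
                if allowed <= 0:
                    continue
                mag = float(np.clip(abs(step), 0, allowed))
                shift = unit(p - o3) * sgn * np.sign(step) * mag
                for k in group:
                    moved[k] += mag
                    for a in s.residues[k].atoms:
                        a.position = a.position + shift
        if worst < 0.65:
            break


def broken_junctions(s: Structure) -> int:
    count = 0
    for (i, j) in s.covalent_links:
        ri, rj = s.residues[i], s.residues[j]
        if ri.has("O3'") and rj.has("P"):
            if np.linalg.norm(ri.coord("O3'") - rj.coord("P")) > JUNCTION_BROKEN:
                count += 1
    return count
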