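"""Energy model and tunable constants of the untangling simulation.

All strengths are in kT and kT/Å² (the sampler runs at kT = 1). The terms:

* backbone bonds — harmonic springs on consecutive backbone beads and on
  each residue's backbone-base bead pair, at their reference lengths;
* tethers — harmonic wells at each bead's reference position (off for
  entangled-element beads while steering, ramped up during restoration);
* excluded volume — purely repulsive truncated-shifted quadratic with
  contact distance sigma; native contacts (bead pairs already within sigma
  in the reference) are exempt, and cross pairs of the entangled elements
  are switched off during steering so the elements may pass through each
  other, then re-enabled for the restoration run, where they block
  re-threading;
* steering — half-harmonic repulsion shells and harmonic attractions to
  virtual sites, ramped linearly over the steering run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..structure import Structure
from .cg import MCState


@dataclass
class EngineSettings:
    k_bond: float = 10.0        # kT/Å², backbone + intra-residue bonds
    k_tether: float = 0.5       # kT/Å², background tether
    k_tether_restore: float = 2.0  # kT/Å², final restore tether strength
    sigma_ev: float = 4.0       # Å, excluded-volume contact distance
    k_ev: float = 10.0          # kT/Å², excluded-volume strength
    k_steer: float = 2.0        # kT/Å², loop-site repulsion
    steer_pad: float = 6.0      # Å added to the partner gyration radius
    k_barrier: float = 2.0      # kT/Å², closing-pair midpoint barrier
    r_barrier: float = 3.0      # Å, barrier radius
    k_swap_repel: float = 2.0   # kT/Å², own-site repulsion (reduced swap)
    r_swap_repel: float = 8.0   # Å, own-site repulsion shell
    k_swap_attract: float = 0.2  # kT/Å², opposite-site attraction
    k_guard: float = 100.0        # kT/Å², re-threading guard during restore
    guard_pad: float = 5.0      # Å, guard shell clearance beyond the ring spread
    move_sigma: float = 0.3     # Å, Gaussian single-bead move
    kT: float = 1.0
    sweeps_minimize: int = 1500
    sweeps_steer: int = 20000
    sweeps_restore: int = 10000
    redetect_every: int = 2000
    site_update_every: int = 200
    max_attempts: int = 3
    seed: int = 0
    mesh_edge: float = 2.0

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "EngineSettings":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class EnergyModel:
    settings: EngineSettings
    # bonds
    bond_idx: np.ndarray  # (B, 2) int64
    bond_r0: np.ndarray   # (B,)
    adj_start: np.ndarray  # (N+1,) flattened per-bead bond adjacency
    adj_partner: np.ndarray
    adj_r0: np.ndarray
    # tether
    tether_k: np.ndarray  # (N,)
    tether_ref: np.ndarray  # (N, 3)
    # excluded volume: uint8 matrix, 1 = active
    ev_active: np.ndarray
    native_excluded: np.ndarray  # bool, reference-contact exemption
    # steering (flattened per bead)
    st_start: np.ndarray = None
    st_site: np.ndarray = None
    #: 0 = half-harmonic repel inside R, 1 = harmonic attract,
    #: 2 = half-harmonic repel from a finite disk (axis + disk radius)
    st_kind: np.ndarray = None
    st_k: np.ndarray = None
    st_R: np.ndarray = None
    st_axis: np.ndarray = None
    st_R2: np.ndarray = None
    st_entries: list = field(default_factory=list)

    @classmethod
    def build(cls, s: Structure, state: MCState,
              settings: Optional[EngineSettings] = None,
              ss=None) -> "EnergyModel":
        settings = settings or EngineSettings()
        n = state.n_beads
        bonds = []
        for k in range(state.n_residues):
            bonds.append((2 * k, 2 * k + 1))
        for (i, j) in sorted(s.covalent_links):
            bonds.append((2 * i, 2 * j))
        if ss is not None:
            # canonical pairs are structural springs: they keep duplexes
            # intact while elements are steered and restored
            for p in ss.pairs:
                if p.canonical:
                    bonds.append((2 * p.i, 2 * p.j))
                    bonds.append((2 * p.i + 1, 2 * p.j + 1))
        bond_idx = np.array(bonds, dtype=np.int64)
        ref = state.reference
        bond_r0 = np.sqrt(((ref[bond_idx[:, 0]] - ref[bond_idx[:, 1]]) ** 2).sum(-1))

        adj = [[] for _ in range(n)]
        for (a, b), r0 in zip(bond_idx, bond_r0):
            adj[a].append((b, r0))
            adj[b].append((a, r0))
        adj_start = np.zeros(n + 1, dtype=np.int64)
        partners, r0s = [], []
        for i in range(n):
            adj_start[i + 1] = adj_start[i] + len(adj[i])
            for p, r0 in adj[i]:
                partners.append(p)
                r0s.append(r0)
        model = cls(
            settings=settings,
            bond_idx=bond_idx, bond_r0=bond_r0,
            adj_start=adj_start,
            adj_partner=np.array(partners, dtype=np.int64),
            adj_r0=np.array(r0s),
            tether_k=np.full(n, settings.k_tether),
            tether_ref=ref.copy(),
            ev_active=np.ones((n, n), dtype=np.uint8),
            native_excluded=np.zeros((n, n), dtype=bool),
        )
        d = np.sqrt(((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1))
        model.native_excluded = d < settings.sigma_ev
        model.reset_phase(None, None)
        model.clear_steering()
        return model

    # -- phase configuration ------------------------------------------------

    def reset_phase(self, mask_a, mask_b, cross_off: bool = False):
        """Configure excluded volume for a protocol phase.

        ``mask_a``/``mask_b`` are boolean bead masks of the two entangled
        element sets. During steering (``cross_off=True``) their cross
        pairs are switched off entirely; otherwise cross pairs are active
        even when they are reference contacts (so the elements cannot slip
        through each other while restoring).
        """
        act = (~self.native_excluded).astype(np.uint8)
        np.fill_diagonal(act, 0)
        if mask_a is not None and mask_b is not None:
            cross = (np.outer(mask_a, mask_b) | np.outer(mask_b, mask_a))
            if cross_off:
                act[cross] = 0
            else:
                act[cross] = 1
                np.fill_diagonal(act, 0)
                # bonded pairs stay off regardless
                for (a, b) in self.bond_idx:
                    act[a, b] = act[b, a] = 0
        self.ev_active = act

    def set_tethers(self, k_background: float, free_mask=None, k_free: float = 0.0):
        n = len(self.tether_k)
        self.tether_k = np.full(n, k_background)
        if free_mask is not None:
            self.tether_k[free_mask] = k_free

    def clear_steering(self):
        self.st_entries = []
        self._flatten_steering()

    def add_steering(self, bead: int, site, kind: int, k: float, radius: float,
                     axis=None, radius2: float = 0.0):
        axis = np.zeros(3) if axis is None else np.asarray(axis, float)
        self.st_entries.append((int(bead), np.asarray(site, float), kind, k,
                                radius, axis, radius2))
        # caller flattens once after adding everything

    def _flatten_steering(self):
        n = len(self.tether_k)
        per = [[] for _ in range(n)]
        for bead, site, kind, k, radius, axis, radius2 in self.st_entries:
            per[bead].append((site, kind, k, radius, axis, radius2))
        start = np.zeros(n + 1, dtype=np.int64)
        sites, kinds, ks, rs, axes, r2s = [], [], [], [], [], []
        for i in range(n):
            start[i + 1] = start[i] + len(per[i])
            for site, kind, k, radius, axis, radius2 in per[i]:
                sites.append(site)
                kinds.append(kind)
                ks.append(k)
                rs.append(radius)
                axes.append(axis)
                r2s.append(radius2)
        self.st_start = start
        self.st_site = np.array(sites) if sites else np.zeros((0, 3))
        self.st_kind = np.array(kinds, dtype=np.int8) if kinds else np.zeros(0, np.int8)
        self.st_k = np.array(ks) if ks else np.zeros(0)
        self.st_R = np.array(rs) if rs else np.zeros(0)
        self.st_axis = np.array(axes) if axes else np.zeros((0, 3))
        self.st_R2 = np.array(r2s) if r2s else np.zeros(0)

    def finalize_steering(self):
        self._flatten_steering()

    def update_site_positions(self, updater):
        """Refresh tracking site positions via ``updater(entry) -> site``."""
        changed = False
        for k, entry in enumerate(self.st_entries):
            new = updater(entry)
            if new is not None:
                self.st_entries[k] = (entry[0], np.asarray(new, float)) + entry[2:]
                changed = True
        if changed:
            self._flatten_steering()

    # -- energies (python-side, for tests and minimisation checks) ----------

    def total_energy(self, pos: np.ndarray, ramp: float = 1.0) -> float:
        e = 0.0
        d = np.sqrt(((pos[self.bond_idx[:, 0]] - pos[self.bond_idx[:, 1]]) ** 2).sum(-1))
        e += 0.5 * self.settings.k_bond * ((d - self.bond_r0) ** 2).sum()
        e += 0.5 * (self.tether_k * ((pos - self.tether_ref) ** 2).sum(-1)).sum()
        dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        sig = self.settings.sigma_ev
        viol = np.where((dist < sig) & (self.ev_active == 1),
                        sig - dist, 0.0)
        e += 0.5 * self.settings.k_ev * (viol ** 2).sum() / 2.0  # pairs counted twice
        for bead, site, kind, k, radius, axis, radius2 in self.st_entries:
            d = pos[bead] - site
            if kind == 2:
                ax = float(d @ axis)
                rad = max(float(np.linalg.norm(d - ax * axis)) - radius2, 0.0)
                dd = float(np.hypot(ax, rad))
                if dd < radius:
                    e += 0.5 * ramp * k * (radius - dd) ** 2
                continue
            if kind == 3:
                ax = float(d @ axis)
                rad = max(float(np.linalg.norm(d - ax * axis)) - radius2, 0.0)
                fall = 1.0 - rad / 3.0
                pen = (radius - ax) * fall
                if fall > 0.0 and pen > 0.0:
                    e += 0.5 * ramp * k * pen ** 2
                continue
            r = float(np.linalg.norm(d))
            if kind == 0 and r < radius:
                e += 0.5 * ramp * k * (radius - r) ** 2
            elif kind == 1:
                e += 0.5 * ramp * k * r ** 2
        return float(e)
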