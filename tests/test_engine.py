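"""Coarse-grained engine: beads, Monte Carlo, backmapping."""

import numpy as np
import pytest

from rnatangle.engine.cg import backmap, broken_junctions, coarse_grain
from rnatangle.engine.mc import minimize, run_mc
from rnatangle.engine.model import EnergyModel, EngineSettings
from rnatangle.evaluate import rmsd
from rnatangle.geometry import rotation_about_axis


class TestCoarseGrain:
    def test_two_beads_per_residue(self, helix8):
        state = coarse_grain(helix8)
        assert state.n_beads == 2 * len(helix8)

    def test_identity_backmap(self, helix8):
        state = coarse_grain(helix8)
        assert rmsd(helix8, backmap(state, helix8)) < 0.1

    def test_translation_equivariance(self, helix8):
        state = coarse_grain(helix8)
        t = np.array([3.0, -4.0, 12.0])
        moved = helix8.transformed(np.eye(3), t)
        state2 = coarse_grain(moved)
        assert np.allclose(state2.positions, state.positions + t)

    def test_rigid_rotation_backmap(self, helix8):
        """Rotating the beads rigidly rotates the backmapped atoms."""
        state = coarse_grain(helix8)
        R = rotation_about_axis([1, 1, 2], 0.9)
        t = np.array([5.0, 1.0, -2.0])
        state.positions = state.positions @ R.T + t
        out = backmap(state, helix8)
        expect = helix8.transformed(R, t)
        assert rmsd(expect, out) < 0.1


class TestMonteCarlo:
    def test_zero_energy_at_reference(self, helix8):
        state = coarse_grain(helix8)
        model = EnergyModel.build(helix8, state)
        assert model.total_energy(state.positions) == pytest.approx(0.0, abs=1e-9)

    def test_minimisation_monotone(self, helix8):
        """Greedy descent never increases the energy."""
        state = coarse_grain(helix8, seed=5)
        model = EnergyModel.build(helix8, state)
        rng = np.random.default_rng(5)
        state.positions = state.positions + rng.normal(0, 1.0, state.positions.shape)
        energies = [model.total_energy(state.positions)]
        for _ in range(5):
            minimize(state, model, 100, rng=rng)
            energies.append(model.total_energy(state.positions))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]

    def test_minimisation_fixpoint(self, helix8):
        state = coarse_grain(helix8, seed=1)
        model = EnergyModel.build(helix8, state)
        e0 = model.total_energy(state.positions)
        minimize(state, model, 200, rng=np.random.default_rng(1))
        assert model.total_energy(state.positions) <= e0 + 1e-9

    def test_determinism(self, helix8):
        runs = []
        for _ in range(2):
            state = coarse_grain(helix8, seed=3)
            model = EnergyModel.build(helix8, state)
            run_mc(state, model, 300, rng=np.random.default_rng(3))
            runs.append(state.positions.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_repulsion_separates_overlapping_beads(self):
        """Two beads 1 Å apart relax outward under excluded volume."""
        from rnatangle.engine.cg import MCState
        from rnatangle.structure import AtomRecord, Residue, Structure

        def res(x, number):
            atoms = [AtomRecord("C4'", "C", np.array([x, 0.0, 0.0])),
                     AtomRecord("N1", "N", np.array([x, 30.0, 0.0]))]
            return Residue("A", number, "", "other", "UNK", atoms)

        s = Structure([res(0.0, 1), res(1.0, 50)])
        state = coarse_grain(s, seed=0)
        model = EnergyModel.build(s, state)
        model.native_excluded[:] = False
        model.reset_phase(None, None)
        model.set_tethers(0.0)
        d0 = np.linalg.norm(state.positions[0] - state.positions[2])
        e0 = model.total_energy(state.positions)
        minimize(state, model, 400, rng=np.random.default_rng(0))
        d1 = np.linalg.norm(state.positions[0] - state.positions[2])
        assert d1 >= d0
        assert model.total_energy(state.positions) < e0

    def test_harmonic_bond_boltzmann_distribution(self):
        """Metropolis sampling of one harmonic bond matches the closed form.

        A single bond of stiffness k at kT=1 has bond-length density
        p(r) ∝ r^2 exp(-k (r - r0)^2 / 2). The sampled lengths (thinned to
        be effectively independent) must pass a two-sided KS test.
        """
        from scipy import stats
        from scipy.integrate import cumulative_trapezoid
        from rnatangle.engine.cg import MCState

        k_bond = 10.0
        r0 = 5.0
        pos = np.array([[0.0, 0, 0], [r0, 0, 0], [0, 50.0, 0], [r0, 50.0, 0]])
        state = MCState(pos.copy(), pos.copy(), np.array([0, 0, 1, 1]), seed=11)
        from rnatangle.structure import AtomRecord, Residue, Structure

        def res(y, number):
            atoms = [AtomRecord("C4'", "C", np.array([0.0, y, 0.0])),
                     AtomRecord("N1", "N", np.array([r0, y, 0.0]))]
            return Residue("A", number, "", "other", "UNK", atoms)

        s = Structure([res(0.0, 1), res(50.0, 2)])
        settings = EngineSettings(k_bond=k_bond)
        model = EnergyModel.build(s, state, settings)
        model.set_tethers(0.0)
        model.ev_active[:] = 0

        rng = np.random.default_rng(11)
        thin = 25
        samples = []
        for _ in range(100_000 // thin):
            run_mc(state, model, thin, rng=rng)
            samples.append(np.linalg.norm(state.positions[1] - state.positions[0]))
        samples = np.array(samples)

        grid = np.linspace(max(r0 - 3.0, 1e-3), r0 + 3.0, 4000)
        dens = grid ** 2 * np.exp(-0.5 * k_bond * (grid - r0) ** 2)
        cdf_grid = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, grid, cdf_grid)

        result = stats.kstest(samples, cdf)
        assert result.pvalue > 0.01


class TestBackmapIntegrity:
    def test_junction_lengths_bounded_after_motion(self, helix8):
        state = coarse_grain(helix8, seed=9)
        rng = np.random.default_rng(9)
        model = EnergyModel.build(helix8, state)
        run_mc(state, model, 400, rng=rng)
        minimize(state, model, 400, rng=rng)
        out = backmap(state, helix8)
        assert broken_junctions(out) == 0
        for (i, j) in out.covalent_links:
            d = np.linalg.norm(out.residues[i].coord("O3'") - out.residues[j].coord("P"))
            assert 1.0 <= d <= 2.2
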