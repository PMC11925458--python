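"""RMSD, INF and clash-score unit behaviour."""

import numpy as np
import pytest

from rnatangle.evaluate import clash_score, count_clashes, evaluate_run, inf, rmsd
from rnatangle.geometry import rotation_about_axis, superposed_rmsd
from rnatangle.structure import AtomRecord, BasePair, Residue, Structure


def _two_atom_structure(x2):
    atoms = [AtomRecord("C4'", "C", np.array([0.0, 0.0, 0.0])),
             AtomRecord("C1'", "C", np.array([x2, 0.0, 0.0]))]
    return Structure([Residue("A", 1, "", "other", "UNK", atoms)])


class TestRmsd:
    def test_identity(self, helix8):
        assert rmsd(helix8, helix8) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, helix8):
        R = rotation_about_axis([0, 1, 1], 0.7)
        moved = helix8.transformed(R, np.array([5.0, 0.0, 0.0]))
        assert rmsd(helix8, moved) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        """{(0,0,0),(1,0,0)} vs {(0,0,0),(2,0,0)} optimally superposes to 0.5."""
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert superposed_rmsd(a, b) == pytest.approx(0.5, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            rmsd(_two_atom_structure(1.0), _two_atom_structure(2.0))

    def test_symmetry(self, helix8, ls_fixture):
        a = helix8
        b = helix8.transformed(rotation_about_axis([1, 0, 0], 0.2),
                               np.zeros(3))
        for r in b.residues[:4]:
            for atom in r.atoms:
                atom.position = atom.position + 0.3
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-9)


class TestInf:
    def test_identical_sets(self):
        pairs = [BasePair(0, 9), BasePair(1, 8)]
        assert inf(pairs, pairs) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert inf([BasePair(0, 9)], [BasePair(1, 8)]) == pytest.approx(0.0)

    def test_half_overlap_closed_form(self):
        """ref {p,q}, model {p,r}: PPV = STY = 1/2, INF = 0.5 exactly."""
        ref = [BasePair(0, 9), BasePair(1, 8)]
        model = [BasePair(0, 9), BasePair(2, 7)]
        assert inf(ref, model) == pytest.approx(0.5, abs=1e-12)

    def test_undefined_when_both_empty(self):
        assert inf([], []) is None

    def test_monotone_under_intersection_removal(self):
        ref = [BasePair(i, 20 - i) for i in range(5)]
        model = list(ref)
        last = None
        for k in range(5):
            val = inf(ref, model[: 5 - k])
            if last is not None:
                assert val <= last + 1e-12
            last = val


class TestClashScore:
    def _structure_with_pair(self, d, n_pad=0):
        """Two isolated C atoms at distance d, plus distant padding atoms."""
        residues = []
        atoms = [AtomRecord("C1'", "C", np.zeros(3)),
                 AtomRecord("C4'", "C", np.array([d, 0.0, 0.0]))]
        residues.append(Residue("A", 1, "", "other", "UNK", [atoms[0]]))
        residues.append(Residue("A", 50, "", "other", "UNK", [atoms[1]]))
        for k in range(n_pad):
            residues.append(Residue("A", 100 + k, "", "other", "UNK", [
                AtomRecord("C1'", "C", np.array([100.0 + 10 * k, 0, 0]))]))
        return Structure(residues)

    def test_no_overlap(self):
        assert clash_score(self._structure_with_pair(5.0)) == 0.0

    def test_boundary_exactness(self):
        """C+C threshold is 1.70+1.70-0.4 = 3.00 Å exactly."""
        assert count_clashes(self._structure_with_pair(3.01)) == 0
        assert count_clashes(self._structure_with_pair(2.99)) == 1

    def test_one_clash_per_1000_atoms(self):
        s = self._structure_with_pair(2.5, n_pad=998)
        assert s.n_atoms == 1000
        assert clash_score(s) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_motion_invariance(self, ls_fixture):
        s = ls_fixture.structure
        moved = s.transformed(rotation_about_axis([1, 2, 0], 1.0),
                              np.array([10.0, -5.0, 3.0]))
        assert count_clashes(moved) == count_clashes(s)

    def test_bonded_pairs_exempt(self, helix8):
        # O3'-P are ~1.6 Å apart but never counted as clashes
        assert count_clashes(helix8) == 0


def test_evaluate_run_identity(helix8):
    deltas = {d.metric: d for d in evaluate_run(helix8, helix8.copy())}
    assert deltas["rmsd"].delta == pytest.approx(0.0, abs=1e-6)
    assert deltas["inf"].before == pytest.approx(1.0)
    assert deltas["clash_score"].delta == 0.0
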