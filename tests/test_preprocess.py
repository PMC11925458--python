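"""Entanglement merging and reduction planning."""

import itertools

import numpy as np
import pytest

from rnatangle.elements import StructuralElement
from rnatangle.preprocess import (
    EntanglementGroup, merge_entanglements, plan_reduction,
)
from rnatangle.topology import Entanglement, detect_entanglements


def _loop(residues):
    return StructuralElement("loop", list(residues), closed=True)


def _ent(a, b, cls="L&L"):
    return Entanglement(cls, a, b, [], None, False, True)


class TestMerge:
    def setup_method(self):
        self.L1 = _loop(range(0, 6))
        self.L2 = _loop(range(10, 16))
        self.L3 = _loop(range(6, 10))  # adjacent to L1
        self.L4 = _loop(range(30, 36))  # unrelated

    def test_shared_element_with_connected_partners(self):
        e1 = _ent(self.L1, self.L2)
        e2 = _ent(self.L2, self.L3)  # L3 adjacent to L1
        groups = merge_entanglements([e1, e2])
        assert len(groups) == 1
        assert len(groups[0].members) == 2

    def test_disjoint_entanglements_stay_separate(self):
        e1 = _ent(self.L1, self.L2)
        e2 = _ent(self.L4, _loop(range(40, 46)))
        assert len(merge_entanglements([e1, e2])) == 2

    def test_shared_element_alone_is_insufficient(self):
        e1 = _ent(self.L1, self.L2)
        e2 = _ent(self.L2, self.L4)  # L1 and L4 unrelated
        assert len(merge_entanglements([e1, e2])) == 2

    def test_order_invariant_and_idempotent(self):
        e1 = _ent(self.L1, self.L2)
        e2 = _ent(self.L2, self.L3)
        e3 = _ent(self.L4, _loop(range(40, 46)))
        reference = None
        for perm in itertools.permutations([e1, e2, e3]):
            groups = merge_entanglements(list(perm))
            signature = sorted(
                tuple(sorted(map(tuple, (sorted(m.element_a.residues),
                                         sorted(m.element_b.residues))))
                      for m in g.members)
                for g in groups)
            if reference is None:
                reference = signature
            assert signature == reference


class TestPlanReduction:
    def test_thread_fixture_gets_reduced_swap(self, ls_fixture):
        s, ss = ls_fixture.structure, ls_fixture.secondary
        report = detect_entanglements(s, ss)
        groups = merge_entanglements(report.entanglements)
        plan = plan_reduction(groups[0], ss, s)
        assert plan.strategy == "reduced_swap"
        windows = [w for w in plan.windows.values() if w is not None]
        assert windows, "large elements should get windows"
        for lo, hi in windows:
            assert 2 <= hi - lo <= 6

    def test_window_contains_nearest_unpaired_residue(self, ls_fixture):
        s, ss = ls_fixture.structure, ls_fixture.secondary
        report = detect_entanglements(s, ss)
        groups = merge_entanglements(report.entanglements)
        plan = plan_reduction(groups[0], ss, s)
        points = [p.position for e in groups[0].members for p in e.points]
        pm = ss.partner_map()
        for el in groups[0].involved_elements:
            window = plan.windows.get(id(el))
            if window is None:
                continue
            lo, hi = window
            assert all(i in el.residue_set for i in range(lo, hi))
            assert all(pm[i] == -1 for i in range(lo, hi))
            # the window holds the eligible residue nearest a puncture
            def dist(i):
                r = s.residues[i]
                return min(np.linalg.norm(r.coord("C4'") - p) for p in points)
            eligible = [i for i in el.residues if pm[i] == -1]
            nearest = min(eligible, key=dist)
            assert lo <= nearest < hi

    def test_interlace_of_steps_never_swaps(self):
        """Classes outside the reducible set keep whole-loop steering."""
        from rnatangle.fixtures import FixtureSpec, make_entangled

        f = make_entangled(FixtureSpec("D&D", seed=1))
        report = detect_entanglements(f.structure, f.secondary)
        groups = merge_entanglements(report.entanglements)
        plan = plan_reduction(groups[0], f.secondary, f.structure)
        assert plan.strategy == "full_loop"

    def test_small_loop_unreduced(self):
        """Elements of five or fewer residues are never reduced."""
        small = _loop(range(0, 5))
        big = _loop(range(10, 22))
        group = EntanglementGroup([_ent(small, big, "L&L")])
        # no punctures recorded: planning still runs and leaves small whole
        from rnatangle.structure import SecondaryStructure
        from rnatangle.fixtures import FixtureSpec, make_entangled

        f = make_entangled(FixtureSpec("L&L", seed=1))
        report = detect_entanglements(f.structure, f.secondary)
        groups = merge_entanglements(report.entanglements)
        plan = plan_reduction(groups[0], f.secondary, f.structure)
        for el in groups[0].involved_elements:
            if len(el.residues) <= 5:
                assert plan.windows.get(id(el)) is None
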