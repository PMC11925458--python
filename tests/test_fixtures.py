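"""Synthetic fixture generators as the pipeline's oracle."""

import numpy as np
import pytest

from rnatangle.evaluate import clash_score, count_clashes
from rnatangle.fixtures import (
    CLASSES, FixtureSpec, FixtureError, make_clash_seeded, make_clean,
    make_entangled, make_helix, helix_pairs,
)
from rnatangle.structure import annotate_base_pairs
from rnatangle.topology import detect_entanglements


class TestHelix:
    def test_eight_bp(self):
        h = make_helix(8)
        assert len(h) == 16
        ss = annotate_base_pairs(h)
        assert ss.pair_set() == {(p.i, p.j) for p in helix_pairs(8)}

    def test_minimal_single_pair(self):
        h = make_helix(1)
        assert len(h) == 2
        assert len(annotate_base_pairs(h).pairs) == 1

    def test_determinism(self):
        a = make_helix(4).all_coords()
        b = make_helix(4).all_coords()
        assert np.array_equal(a, b)

    def test_invalid_sequence_rejected(self):
        with pytest.raises(FixtureError):
            make_helix(3, "GXT")

    def test_clash_free(self):
        assert count_clashes(make_helix(8)) == 0


class TestGenerators:
    def test_clean_control_has_no_entanglements(self, clean_fixture):
        report = detect_entanglements(clean_fixture.structure, clean_fixture.secondary)
        assert report.entanglements == []
        assert count_clashes(clean_fixture.structure) <= 1

    def test_seed_changes_placement_not_topology(self):
        f1 = make_entangled(FixtureSpec("L(S)", seed=1))
        f2 = make_entangled(FixtureSpec("L(S)", seed=2))
        assert not np.allclose(f1.structure.all_coords(), f2.structure.all_coords())
        assert f1.expected.cls == f2.expected.cls == "L(S)"

    def test_same_spec_bit_identical(self):
        a = make_entangled(FixtureSpec("L&L", seed=5)).structure.all_coords()
        b = make_entangled(FixtureSpec("L&L", seed=5)).structure.all_coords()
        assert np.array_equal(a, b)

    def test_backbone_connectivity(self, ls_fixture):
        s = ls_fixture.structure
        # a single chain: every consecutive pair is covalently linked
        assert len(s.covalent_links) == len(s) - 1

    def test_impossible_depth_rejected(self):
        with pytest.raises(FixtureError):
            make_entangled(FixtureSpec("L(L)", depth_nt=40, seed=0))


class TestClashSeeding:
    def test_exact_count(self):
        base = make_entangled(FixtureSpec("L(S)", seed=3))
        baseline = count_clashes(base.structure)
        seeded = make_clash_seeded(FixtureSpec("L(S)", clash_k=5, seed=3))
        assert count_clashes(seeded.structure) == baseline + 5

    def test_zero_is_noop(self, clean_fixture):
        spec = FixtureSpec("clean", clash_k=0, seed=1)
        f = make_clash_seeded(spec)
        assert count_clashes(f.structure) == count_clashes(clean_fixture.structure)

    def test_score_positive(self):
        seeded = make_clash_seeded(FixtureSpec("L(S)", clash_k=3, seed=3))
        assert clash_score(seeded.structure) > 0
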