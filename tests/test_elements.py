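"""Element extraction and wireframe construction."""

import numpy as np
import pytest

from rnatangle.elements import build_all_wireframes, build_wireframe, extract_elements
from rnatangle.fixtures import FixtureSpec, _hairpin_motif, _to_structure, make_entangled
from rnatangle.structure import BasePair, SecondaryStructure, annotate_base_pairs, pairs_to_dotbracket


@pytest.fixture(scope="module")
def hairpin():
    s = _to_structure(_hairpin_motif(6, 4).residues)
    ss = annotate_base_pairs(s)
    return s, ss


def test_hairpin_inventory(hairpin):
    """6-bp stem + 4-nt loop: 5 steps, 1 hairpin loop, no strands."""
    s, ss = hairpin
    assert ss.dotbracket == "((((((....))))))"
    els = extract_elements(s, ss)
    kinds = sorted(e.kind for e in els)
    assert kinds.count("dinucleotide_step") == 5
    assert kinds.count("loop") == 1
    assert kinds.count("single_strand") == 0
    loop = next(e for e in els if e.kind == "loop")
    assert loop.residue_set == frozenset(range(5, 11))
    assert loop.closing_pairs == [BasePair(5, 10)]
    assert set().union(*(e.residue_set for e in els)) == set(range(16))


def test_unpaired_strand_inventory():
    """A fully unpaired 10-mer is one single strand and nothing else."""
    from rnatangle.fixtures import P_SPACING, _strand_residues

    anchors = np.array([[k * P_SPACING, 0.0, 0.0] for k in range(11)])
    s = _to_structure(_strand_residues(anchors, "A" * 10))
    ss = SecondaryStructure([], "." * 10)
    els = extract_elements(s, ss)
    assert [e.kind for e in els] == ["single_strand"]
    assert els[0].residues == list(range(10))
    assert not els[0].closed


def test_two_hairpins_with_linker_and_tail(clean_fixture):
    s, ss = clean_fixture.structure, clean_fixture.secondary
    els = extract_elements(s, ss)
    kinds = [e.kind for e in els]
    assert kinds.count("loop") == 2
    assert kinds.count("dinucleotide_step") == 6  # 3 per 4-bp stem
    assert kinds.count("single_strand") == 2  # linker + 3' tail


def test_extraction_ignores_coordinates(hairpin):
    """Scrambling atom positions leaves the element inventory unchanged."""
    s, ss = hairpin
    before = [(e.kind, e.residue_set) for e in extract_elements(s, ss)]
    scrambled = s.copy()
    rng = np.random.default_rng(0)
    for r in scrambled.residues:
        for a in r.atoms:
            a.position = rng.uniform(-50, 50, 3)
    after = [(e.kind, e.residue_set) for e in extract_elements(scrambled, ss)]
    assert before == after


def test_wireframe_node_counts(hairpin):
    s, ss = hairpin
    els = build_all_wireframes(s, ss)
    step = next(e for e in els if e.kind == "dinucleotide_step")
    kinds = [n.kind for n in step.chain_nodes]
    assert kinds.count("pair_centroid") == 2
    # 4 residues x (P + C4') + 2 centroids + closure repeat
    assert len(step.chain_nodes) == 11
    assert np.allclose(step.chain_nodes[0].position, step.chain_nodes[-1].position)


def test_open_strand_wireframe_counts():
    from rnatangle.fixtures import P_SPACING, _strand_residues
    from rnatangle.structure import SecondaryStructure

    anchors = np.array([[k * P_SPACING, 0.0, 0.0] for k in range(6)])
    s = _to_structure(_strand_residues(anchors, "A" * 5))
    ss = SecondaryStructure([], "." * 5)
    els = build_all_wireframes(s, ss)
    strand = els[0]
    assert len(strand.chain_nodes) == 10  # P + C4' per residue, open chain
    assert not np.allclose(strand.chain_nodes[0].position,
                           strand.chain_nodes[-1].position)


def test_closed_wireframes_have_enough_vertices(hairpin):
    s, ss = hairpin
    for e in build_all_wireframes(s, ss):
        if e.closed:
            pts = e.node_positions()
            assert len(np.unique(np.round(pts, 6), axis=0)) >= 3
            seglen = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(-1))
            assert np.isfinite(seglen).all() and seglen.sum() > 0
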