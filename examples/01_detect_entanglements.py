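"""Detect topological entanglements in an RNA 3D model.

Builds a synthetic model whose unpaired 3' strand is threaded six
nucleotides deep through a hairpin loop — a deep L(S) lasso — and runs the
detector on it. The report lists each entanglement with its class, the two
structural elements involved, the intersection points of the piercing
element with the triangulated surface of the pierced one, the threading
depth, and whether the case counts as a modelling artifact.
"""

from rnatangle.fixtures import FixtureSpec, make_entangled
from rnatangle.topology import detect_entanglements

fixture = make_entangled(FixtureSpec("L(S)", depth_nt=6, seed=1))
report = detect_entanglements(fixture.structure, fixture.secondary,
                              structure_id="threaded-hairpin")

print(f"model: {report.structure_id}")
print(f"residues: {len(fixture.structure)}")
print(f"entanglements found: {len(report.entanglements)}")
for ent in report.entanglements:
    a = ent.element_a.label(fixture.structure)
    b = ent.element_b.label(fixture.structure)
    print(f"  class {ent.cls}: {a} lassoes {b}")
    print(f"  punctures: {len(ent.points)}  depth: {ent.depth_nt} nt")
    print(f"  shallow: {ent.shallow}  artifact: {ent.artifact}")
# A depth of six puts this lasso just past the shallow/deep boundary
# (five nucleotides), so it is classified as an artifact worth removing.
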