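"""Generate the synthetic fixture suite.

Each generator builds a full heavy-atom RNA whose topology is known by
construction: three interlace classes, six lasso classes and clean
controls. The expected-topology descriptor doubles as the oracle for
testing the detector.
"""

from rnatangle.fixtures import CLASSES, FixtureSpec, make_clean, make_entangled
from rnatangle.structure import write_structure
from rnatangle.topology import detect_entanglements

for cls in CLASSES:
    fixture = make_entangled(FixtureSpec(cls, seed=1))
    report = detect_entanglements(fixture.structure, fixture.secondary)
    detected = report.entanglements[0].cls if report.entanglements else "none"
    print(f"{cls:5s}: {len(fixture.structure):3d} residues, "
          f"expected {fixture.expected.cls}, detected {detected}")

clean = make_clean(FixtureSpec("clean", seed=1))
report = detect_entanglements(clean.structure, clean.secondary)
print(f"clean: {len(clean.structure):3d} residues, "
      f"{len(report.entanglements)} entanglements")

write_structure(clean.structure, "clean_control.pdb")
print("wrote clean_control.pdb")
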