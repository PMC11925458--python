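"""Model-quality metrics: RMSD, INF and clash score.

Compares a clash-seeded model against its untangled version, mirroring
the before/after reporting used when refining predicted structures.
"""

from rnatangle.engine.model import EngineSettings
from rnatangle.engine.protocol import run_protocol
from rnatangle.evaluate import clash_score, deltas_to_tsv, evaluate_run
from rnatangle.fixtures import FixtureSpec, make_clash_seeded

fixture = make_clash_seeded(FixtureSpec("L(S)", clash_k=10, seed=5))
print(f"clash score before: {clash_score(fixture.structure):.2f} per 1000 atoms")

result = run_protocol(fixture.structure, fixture.secondary, EngineSettings(seed=5))
deltas = evaluate_run(fixture.structure, result.structure,
                      ss_before=fixture.secondary)
print(deltas_to_tsv("seeded-lasso", deltas))
# The ten engineered overlaps sit between the lassoing loop and the
# threaded strand; separating the two elements removes most of them.
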