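# rnatangle

Detection and removal of topological entanglements in RNA 3D models.

Computationally predicted RNA structures frequently contain *entanglements*:
one structural element threaded through another in a way essentially never
seen in experimentally solved RNA. A loop may be interlaced with another
loop, or lasso an element that passes through it. Such models are usually
discarded even when everything outside the entangled region is predicted
well. `rnatangle` finds these artifacts and removes them by a steered
coarse-grained simulation that changes the topology while leaving the rest
of the fold in place, producing a clean all-atom model suitable for
ordinary force-field refinement.

## What it computes

**Detection.** Canonical Watson–Crick–Franklin base pairs are annotated
geometrically (or supplied as dot-bracket), and the secondary structure is
decomposed into *loops* (L: hairpins, internal loops, junctions),
*dinucleotide steps* (D: the 4-cycle of two stacked pairs), and *single
strands* (S). Each element becomes a wireframe polygon through its P and
C4′ atoms and base-pair centroids; closed elements are spanned by a
recursively subdivided triangle mesh, and every partner element's edges are
tested against it with the Möller–Trumbore segment/triangle intersection.
Signed crossings give a linking parity (equal in magnitude to the Gauss
linking number for closed curves). Element pairs are classified into the
nine entanglement classes

    interlaces:  D&D   D&L   L&L          (two closed elements linked)
    lassos:      D(D)  D(L)  D(S)         (a step encircles ...)
                 L(D)  L(L)  L(S)         (a loop encircles ...)

with a threading depth in nucleotides for lassos. An `L(*)` lasso threaded
at most 5 nt deep is *shallow* (can resolve spontaneously); interlaces,
`D(*)` lassos, and deep `L(*)` lassos are artifacts.

**Removal.** Entanglements sharing elements are merged; large loops and
strands of the amenable classes (L&L, D&L, L(S), D(S)) are reduced to short
unpaired windows nearest the intersection points. The structure is coarse
grained to two beads per residue (C4′ + base centroid), energy-minimised,
and the entangled elements are steered apart by Metropolis Monte Carlo with
virtual sites — repulsion from the partner loop's centre and closing-pair
midpoints, or a position swap of the two reduced segments — while the
excluded volume between the entangled pair is switched off so they can pass
through each other. A steered restoration run then ramps tethers back to
the original coordinates (a repulsive wall over the formerly pierced ring
prevents immediate re-threading), the topology is re-checked, and the
result is backmapped to all-atom coordinates with rigid per-residue
templates plus geometric regularisation.

**Evaluation.** All-atom RMSD (Kabsch superposition), Interaction Network
Fidelity `INF = sqrt(PPV * STY)` over base-pair sets, and a van-der-Waals
clash score (overlaps ≥ 0.4 Å per 1000 heavy atoms), with before/after
deltas.

**Fixtures.** A deterministic generator builds full heavy-atom synthetic
RNAs for each entanglement class (plus clean controls and clash-seeded
variants) whose topology is known by construction — the oracle for every
end-to-end test.

## Worked example

```python
from rnatangle.fixtures import FixtureSpec, make_entangled
from rnatangle.engine.protocol import run_protocol
from rnatangle.engine.model import EngineSettings
from rnatangle.topology import detect_entanglements

fx = make_entangled(FixtureSpec("L(S)", depth_nt=6, seed=1))
report = detect_entanglements(fx.structure, fx.secondary)
for e in report.entanglements:
    print(e.cls, e.depth_nt, e.shallow, e.artifact)

result = run_protocol(fx.structure, fx.secondary, EngineSettings(seed=1))
print([o.outcome for o in result.outcomes],
      len(result.final_report.entanglements))
```

prints

```
L(S) 6 False True
['resolved'] 0
```

— a strand threaded 6 nt through a hairpin loop (deep, an artifact) is
detected and removed; the final re-detection finds nothing. The scripts in
`examples/` walk through detection, untangling, evaluation and fixture
generation with commentary on the numbers they print.

The same pipeline is available from the shell:

```sh
rnatangle fixture "L(S)" --seed 1 -o model.pdb     # build a test model
rnatangle detect model.pdb                          # exit 2: entangled
rnatangle untangle model.pdb --seed 1 -o fixed.pdb  # exit 0: resolved
rnatangle evaluate fixed.pdb --before model.pdb
```

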