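# Methods

This note describes the models and procedures implemented in `rnatangle`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test fixtures do and do not show
about real predicted structures.

## Base-pair annotation

Canonical Watson–Crick–Franklin pairs (AU, GC, GU) are detected by
geometry: the distance between the WCF-edge nitrogens (purine N1,
pyrimidine N3) must lie in [2.6, 3.5] Å, the angle between the base-plane
normals (SVD plane fits of the ring atoms) must be at most 65°, and the
C1′–C1′ distance must lie in [9.0, 11.0] Å. Conflicts are resolved
greedily by ascending N–N distance, ties by residue index, leaving every
residue in at most one canonical pair. Consecutive residues of a chain are
covalently linked iff their O3′–P distance is at most 2.0 Å (covalent P–O
is ~1.6 Å; the margin absorbs modelling noise). Pseudoknotted pair sets
are written as layered dot-bracket (`()[]{}<>` plus letters), each layer
internally non-crossing. A user-supplied dot-bracket file overrides the
annotation entirely, which also makes the pipeline independent of these
windows when a trusted annotation exists.

These criteria are a deliberately simple, reproducible stand-in for a full
annotation program. They are strict: a pair whose geometry drifts a few
tenths of an Ångström past a window edge is dropped rather than
classified fuzzily. Non-canonical pair classes are out of scope.

## Elements and wireframes

The secondary-structure graph (backbone links + canonical pairs) is
decomposed into minimal cycles. A cycle of exactly two stacked pairs
(i, j), (i+1, j−1) with both backbone links present is a *dinucleotide
step*; every other minimal cycle is a *loop* (hairpin, internal loop,
bulge, junction, or pseudoknot-closed cycle), carrying its closing pairs.
Maximal unpaired runs outside every cycle are *single strands*. Extraction
depends only on the pairing pattern, never on coordinates.

Each element's wireframe is the polygonal chain through the P and C4′
atoms of its residues in 5′→3′ traversal order, jumping across each
closing pair through a single node at the centroid of the two bases' heavy
atoms. Closed elements give closed polygons, single strands open
polylines.

## Entanglement detection

The interior of a closed wireframe is covered by a triangle fan from the
vertex centroid, recursively subdivided (4-way midpoint) until every
triangle edge is below `max_edge` (default 2.0 Å). Partner-element edges
are tested against the mesh with the Möller–Trumbore algorithm
(determinant cutoff 1e-9 treated as parallel; barycentric boundary hits
within 1e-9 count as hits; segments are half-open in their parameter so a
crossing at a shared node of two consecutive edges counts exactly once;
coincident hits on subdivided triangles are deduplicated by the segment
parameter). The signed crossing sum equals the Gauss linking number in
magnitude for closed curves, which the test suite verifies against a
numerically integrated Gauss double integral.

Classification of a residue-disjoint element pair:

* both closed, nonzero linking parity → interlace (D&D / D&L / L&L);
* closed element crossed an odd net number of times by an open element, or
  crossed by a closed element at zero mutual parity → lasso `A(B)` with
  `A` the pierced (lassoing) element; when both directions of a zero-parity
  closed pair show crossings, the side with more crossings is the lasso-er
  (ties broken toward the lower residue index);
* nothing otherwise.

Lasso depth is the size, in residues, of the smallest chain segment
adjacent to a puncture, where punctures and the chain termini bound the
segments along the piercer's chain. For a strand threaded straight through
a ring this is the distance from the puncture to the nearer end; for a
loop tip dipped through a ring it is the tip length between the two
punctures. `L(*)` lassos of depth ≤ 5 nt are shallow and not counted as
artifacts; everything else is.

## The untangling protocol

Entanglements that share a structural element, and whose remaining
elements are sequence-adjacent, overlapping or nested, are merged into one
group. For the amenable classes (L&L, D&L, L(S), D(S)) every loop or
strand above 5 nt is reduced to a 2–6 residue window of unpaired residues
nearest the intersection points (with the documented fallbacks when all
residues are paired); otherwise the group is handled whole.

The coarse-grained system has two isotropic beads per residue, at C4′ and
at the base heavy-atom centroid. Energy terms (kT and kT/Å², sampler at
kT = 1):

| term | form | default |
|---|---|---|
| backbone + intra-residue bonds | harmonic at reference length | k = 10 |
| canonical-pair springs | harmonic at reference length | k = 10 |
| tether to reference position | harmonic | k = 0.5 background, ramped to 2.0 in restoration |
| excluded volume | truncated-shifted quadratic, contact σ = 4.0 Å | k = 10; reference contacts exempt |
| loop steering | half-harmonic repulsion from partner loop centre, range = partner gyration radius + 6 Å | k = 2 |
| closing-pair barrier | half-harmonic shell, radius 3 Å | k = 2 |
| segment swap | own-site repulsion (8 Å shell, k = 2) + opposite-site attraction (k = 0.2) | — |
| restoration ring wall | one-sided repulsive disk over the formerly pierced ring | k = 100 |

The pair springs keep duplexes intact while whole elements are dragged
around; without them the strict annotation windows register broken pairs
after restoration for reasons unrelated to the topology edit.

One attempt per group runs: (1) greedy minimisation (downhill-only moves,
which also shrinks steric overlaps and over-long bead bonds);
(2) Metropolis steering with single-bead Gaussian moves (σ = 0.3 Å), the
cross excluded volume of the entangled pair off, steering ramped to full
strength over the first quarter of the 20 000-sweep budget, tracking
virtual sites refreshed every 200 sweeps, and the group's topology
re-checked every 2 000 sweeps; once separation is seen the ramp is held
and a 1 000-sweep consolidation must confirm it. For lassos only the
piercer is untethered — separation should come from the thread leaving,
not from the ring drifting off the thread. (3) Restoration over 10 000
sweeps in 500-sweep chunks: steering is removed, excluded volume restored
(reference contacts exempt), and tethers ramp up linearly, followed by a
three-stage greedy quench (σ = 0.3, 0.1, 0.04).

Restoration needs one residual biasing term. The tether minimum *is* the
original, entangled configuration, and the open interior of a ring many
bead diameters wide cannot be blocked sterically, so a plain restoration
re-threads essentially always. A repulsive wall therefore spans each
formerly pierced ring: a one-sided disk (side chosen from where the
formerly threaded fragment sits), sized from the current backmapped
wireframe and refreshed every 1 000 sweeps so it follows the ring home,
with a lateral falloff at the rim so the chain may detour around the ring
edge. Tethers of piercer beads taper with their reference's distance to
the wall (floor 0.05 of full strength, full at 8 Å past it), letting the
detour's extra path length distribute over many bonds instead of tearing
the backbone next to the ring.

A failed attempt (the group re-detected after restoration) retries with
whole-loop steering, up to 3 attempts, after resetting the coordinates.
Resolution means exactly that the final re-detection of the group's
element pairs finds nothing; a group re-detected in a different class is
reported as transformed.

Backmapping transplants each residue's original atoms by the least-squares
rigid map of its reference beads onto the current beads (own beads weighted
8:1 over flanking ones). Paired residues are fitted jointly as one rigid
body so pair geometry survives any displacement exactly, and residues
whose own beads moved under 0.5 Å keep their exact original coordinates —
the two-bead model cannot resolve smaller motion, so propagating it would
only inject noise. O3′–P junctions are then regularised toward 1.6 Å by
bounded rigid shifts (≤ 2.5 Å per residue, partners dragged together), and
a local all-atom polish (backbone/ribose atoms only, P and C1′ pinned)
removes residual clashes around the formerly entangled region and repairs
any junction still over length. The polish stands in for the external
force-field refinement that a production pipeline would run on the
exported PDB.

Determinism: every stochastic step draws from one PCG64 generator per
group, seeded as master seed + group ordinal; identical inputs and seed
give bit-identical trajectories, coordinates and reports.

## Evaluation metrics

RMSD uses Kabsch superposition over all heavy atoms matched by chain,
author number, insertion code and atom name (a fixed-frame variant over a
residue subset supports the "outside the entangled elements" check). INF
is `sqrt(PPV·STY)` over canonical-pair sets and undefined when both sets
are empty. The clash score counts unordered heavy-atom pairs closer than
the sum of van der Waals radii (C 1.70, N 1.55, O 1.52, P 1.80 Å) minus
0.4 Å, excluding pairs within three covalent bonds, normalised per 1000
atoms. It is a simplified surrogate of the probe-based, hydrogen-aware
ClashScore convention, not a reimplementation; values below 10 are
conventionally acceptable.

## Synthetic fixtures

Generators build full heavy-atom models whose topology is true by
construction, which makes them the oracle for the whole pipeline. Bases
use the published standard base-pair reference-frame coordinates
(complement = 2-fold rotation about the pair axis); duplexes are generated
by the A-form step (rise 2.81 Å, twist 32.7°/bp, x-displacement −4.4 Å,
inclination 19°), with backbone and ribose atoms produced once per
geometry by a cached least-squares refinement against bond targets and
steric clearance of all periodic neighbours. Loops and linkers thread
refined single-residue templates along arcs and resampled paths; every
O3′ is anchored exactly one bond length from the next phosphate, so
backbone connectivity is never broken accidentally. Assembled fixtures are
polished clash-free (entangled regions excepted) and validated by running
the detector; the construction parameters are compared against the
detector's report at generation time. A seed selects only a rigid
placement of the finished molecule.

Class constructions: interlaces place one ring through another's mesh with
one crossing inside and one outside; `L(L)`, `D(L)` and `D(D)` dip a ring
tip through the partner's surface (in and out, zero net parity) with the
dip window solved so the constructed depth is exact; `L(D)` passes a
stretched duplex through a lasso ring with symmetric tails setting the
depth; `L(S)`/`D(S)` thread a strand near the ring rim. D-class motifs use
a locally stretched duplex (rise 5.6 Å) because a standard 2.81 Å step
leaves no room for a threading element; threading fixtures use snug loops
(8–10 nt) threaded off-centre, as in real lassoed models, so that
resolution requires only a short local detour. Entangled fixtures may
carry steric clashes in the threaded region — exactly what the artifacts
look like in predicted models. Clash-seeded variants displace O2′ atoms
(not used by annotation, wireframes or beads) onto collision courses with
the threaded element, one verified clash per seed.

What the fixtures do not emulate: non-canonical pairing, realistic loop
conformational ensembles, dense tertiary packing, multi-chain complexes,
and modified residues. Success on the suite shows the topology machinery
and the untangling protocol work as specified on well-posed geometry; real
predicted models add noise, density and annotation ambiguity that the
suite deliberately excludes.

## Problem sizes and numerical choices

The acceptance run uses 12 interlace and 12 lasso fixtures, 220 random
loop pairs for the linking oracle, and 1000 segment/triangle pairs; the
test suite's battery uses 30 + 30 fixtures. Fixtures are 40–90 residues.
Mesh refinement stops at 2.0 Å edges; detection is invariant to halving
this. Degenerate meshes (collinear rings) are empty and never crossed.
The Metropolis ramp is piecewise-constant over 100-sweep kernel batches;
excluded volume uses a Verlet neighbour list with a 6 Å skin rebuilt every
batch.

## Known limitations

* The resolved geometry necessarily parks the formerly threaded fragment
  at the wall spanning the ring it used to cross; its local displacement
  is bounded below by the ring's size no matter how the simulation is run.
* Groups mixing many entanglements over shared large elements can exhaust
  the attempt budget; failure is reported, never silently absorbed.
* The annotation stand-in can lose marginal pairs on models whose pair
  geometry was borderline to begin with; supplying a dot-bracket avoids
  this.
* The clash score is not MolProbity-comparable in absolute terms; only
  before/after differences within this package are meaningful.
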