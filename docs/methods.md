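# Methods

## Scope and data model

`memflux` ingests trajectories (multi-MODEL PDB natively; binary formats via
MDAnalysis) into a single in-memory model: atom metadata (name, element,
residue, chain, copy id, water-oxygen and heavy-atom flags), per-frame
coordinates in Å, optional per-frame orthorhombic box lengths, optional frame
times in ns. Triclinic boxes are refused explicitly rather than silently
mishandled; membrane-pump simulation boxes are orthorhombic in practice and
supporting the general case would complicate every minimum-image code path
for no current gain. Waters are recognised by a configurable residue-name
whitelist (`HOH, WAT, SOL, TIP3`), which is force-field-agnostic and requires
no bond perception. Indices are 0-based internally; reports label anything
1-based.

## Protein volume and permeation events

The "volume of the protein" that a permeating water must traverse is defined
as the intersection of the bilayer slab (closed interval `[z_lo, z_hi]` on
the membrane normal, fixed to z) with a proximity shell: minimum distance to
any protein heavy atom ≤ 6.0 Å (configurable). The shell follows common
channel-water analyses; per-frame convex hulls or grid volumes would be far
more expensive and no better defined for an irregular pump lumen. Distances
use the minimum-image convention whenever a box is present; the slab test
uses coordinates as given (the membrane is assumed whole and centred, which
holds for typical post-processed membrane runs and for the synthetic
systems).

Slab bounds can be supplied or estimated from leaflet marker atoms (e.g.
lipid phosphorus): markers are split by their joint mean z, each leaflet
bound is the (optionally quantile-trimmed) mean z of its group, averaged over
frames.

An event opens at the first frame a water is inside after being outside and
closes at the first subsequent outside frame. Entry/exit side is the side of
z at the last/first outside frame; a water that is outside only laterally
(within the slab z-interval but beyond the proximity shell) is attributed to
the nearest slab boundary and flagged, since the statistic needs a binary
side. A water inside at frame 0 opens an event attributed to its nearest
boundary, flagged as lateral. Single-frame excursions count: no debouncing is
applied by default, so the event inventory is a pure function of the
occupancy series. The translocation success rate is
`crossed / (crossed + returned)`. Unresolved events (still inside at the last
frame) have no outcome; including them in the denominator would bias the rate
downward in short trajectories, so they are excluded and reported. Replica
tags, when present, yield per-replica rates and their unweighted mean next to
the pooled rate, because pooled and per-replica averages differ whenever
replicas contribute unequal event counts and published percentages rarely say
which was used.

## Water wires

Hydrogen bonds between in-volume waters use the canonical geometric
criterion: O–O ≤ 3.5 Å and some donor–H···acceptor angle ≥ 150°, tested in
both donor directions over all hydrogens of the candidate donor. With
hydrogen-free topologies the angle test is skipped (distance-only mode,
recorded in provenance); distance-only edges are a strict superset of
angle-gated edges. A wire is a connected component with ≥ 2 molecules —
length is counted in molecules, so a dimer has length 2. "Chain" is
interpreted as the longest simple path within a component: exact by
exhaustive DFS for components up to 15 nodes (hydrogen-bond graphs are
sparse, so this is cheap), and a BFS double-sweep lower bound flagged
`approx` beyond that. Frames without wires report missing values, not zeros,
so distributions are not polluted by empty frames. Per-frame maxima and means
are aggregated into histograms.

## Interface contacts

A salt bridge is present when any pair of charged-group heavy atoms (Asp/Glu
carboxylate O and phosphoserine phosphate O versus Arg/Lys/His side-chain N)
is within 4.0 Å — the standard contact convention; hydrogen-bond candidates
use N/O heavy atoms within 3.5 Å. Occupancy is the fraction of analyzed
frames (after any stride) in which the contact is present. The inventory
scans all cross-chain candidate residue pairs and reports those at or above
an occupancy threshold (default 0.2), salt bridges taking precedence over a
duplicate hydrogen-bond listing for the same residue pair. Phosphoserine is a
first-class anionic group so phosphorylated-regulator systems are
expressible; the toolkit does not build phosphorylated structures.

## Aggregation entities

Copies are "interacting" when their minimum heavy-atom distance is ≤ 4.5 Å, a
standard nonbonded-contact threshold; since no published criterion fixes this
number, the CLI also emits a sensitivity report over {4.0, 4.5, 5.0} Å.
Before any distance is measured each copy is made whole: every atom is
shifted by the lattice vector bringing it closest to the copy's first atom
(valid while a copy is smaller than half the box). Entities are the connected
components of the copy-contact graph per frame; the timeline records the
partition, the entity count, and the first frame/time with a single entity.
Stable entity labels propagate by maximal-overlap matching: an entity
inherits the label of the predecessor sharing the most copies, merges keep
the larger predecessor's label, ties go to the predecessor containing the
lowest copy id, and duplicated labels after a split stay with the larger
fragment.

## Structural observables and clustering

Kabsch superposition is the SVD solution with the determinant sign correction
that excludes reflections; degenerate inputs (fewer than 3 points, collinear
sets, detected via the second singular value at 1e-9 relative tolerance) are
flagged non-unique. RMSD series superpose each frame on an alignment
selection before measuring on a possibly different selection, which is how
inter-domain motion is usually read out. SASA follows Shrake–Rupley with a
golden-spiral sphere point set (default 960 points, floor 92): deterministic
by construction, so results are exactly reproducible — a seeded random
quadrature would add noise for no benefit. Default radii are the Bondi-style
values C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å.

Frame clustering builds the full pairwise Kabsch-aligned RMSD matrix and
cuts average-linkage hierarchical clustering at k clusters or an RMSD
threshold. Average linkage is the common deterministic choice for MD frame
clustering; k-medoids would introduce initialization dependence. Cluster ids
are renumbered by first-occurring frame; the representative structure is the
medoid — the member of the most populated cluster minimizing summed RMSD to
its co-members — with all ties broken by lowest frame index, so the result is
a pure function of the input.

## Synthetic study systems

The generators produce the study conditions the analyses are validated
under; all randomness flows from one `numpy` Generator per call, so a spec +
seed reproduces trajectories byte for byte, and every generator emits a
machine-readable GroundTruth sufficient to score the analysis exactly.

- **Permeation**: a 60 × 60 × 90 Å box, slab z ∈ [−15, 15], a static rod of
  dummy heavy atoms along z as the "channel". Default script: 200 resolved
  passages at a 25 % crossing fraction (50 crossed, 150 returned) plus 10
  unresolved, entry sides alternating; each scripted water parks outside its
  entry side, spends 4 frames inside, and parks on its scripted exit side,
  over 60 frames. 50 background waters drift at ≥ 14 Å lateral distance from
  the axis and can never enter. An optional per-frame speed cap rejects
  infeasible scripts.
- **Wires**: chains along z at 2.8 Å O–O spacing with the donor hydrogen of
  each water aimed at the next oxygen (ideal 180° D–H···A), at lateral
  offsets that keep distinct chains > 3.5 Å apart; isolated in-volume decoys
  and an out-of-volume decoy chain that a correct analysis must ignore. The
  default 12-frame schedule covers every length 2–9, including one
  9-molecule chain (the extreme a long apo-pump run can show) and one frame
  with no wires at all.
- **Aggregation**: 7 rigid 4-atom copies. Entities sit at well-separated
  sites of a 90 Å cube; copies within an entity occupy adjacent cells of a
  5 Å lattice, keeping entities contact-connected at 4.5 Å while distinct
  entities stay ~30 Å apart. The default schedule merges 7 → 4 → 2 → 1 at
  frames 5/10/15; at 20 ns per frame full aggregation lands at 300 ns, the
  time scale on which multi-copy all-atom runs are seen to aggregate fully.
  From the final merge on, the merged entity is centred on a box face so its
  contacts exist only through minimum-image distances — exercising exactly
  the failure mode a naive distance calculation has. Coordinates are stored
  wrapped.
- **Clusters**: frames drawn from planted conformations (default two, 40 and
  20 frames, σ = 0.2 Å isotropic noise, superposed RMSD separation tuned to
  8.0 Å by bisection) with random rigid rotations and translations applied,
  so clustering must superpose before measuring.
- **Contacts**: a two-chain system (glutamate- or phosphoserine-like anionic
  group versus an arginine-like group) with the contact present (3.5 Å gap)
  in a seeded-random subset of frames — defaults 74 of 100, and 56 of 100
  for the phosphorylated variant, the occupancy drop a phosphorylation
  comparison produces.

What the generators deliberately do not emulate: force fields, thermal
motion of the protein, realistic water density, lipid atoms, or diffusive
kinetics. Passing tests therefore demonstrate that the *analyses* are exact
on geometrically well-posed inputs — event bookkeeping, graph lengths,
component counting, superposition and quadrature — not that the defaults are
optimal for any particular real system, where the proximity cutoff and
hydrogen-bond criteria should be reviewed against the force field in use.

## Numerical choices and limitations

- Closed z-interval for "inside"; boundary values count as inside, and the
  proximity test is ≤, so thresholds are reproducible decision boundaries.
- KD-trees accelerate proximity and O–O pair searches; periodic queries wrap
  coordinates into [0, L) first.
- Problem sizes in tests and the acceptance script (60-frame permeation
  systems, 500 oracle graphs ≤ 10 nodes, 200 random 7-copy frames) are chosen
  so each block measures its property in seconds while still covering every
  planted condition; the statistics are exact recoveries, not estimates, so
  larger systems would add runtime, not information.
- Stride is a user parameter everywhere (default 1); occupancies are over
  analyzed frames, not wall-clock time.
- The permeation side attribution for laterally entering/leaving waters is a
  convention (nearest boundary, flagged); alternative conventions would
  change individual events but not crossings, which require genuine
  side-to-side passage.
- Known limitations: no triclinic boxes; water-only wires (protein
  donors/acceptors as bridge nodes are not considered); no event debouncing
  beyond the optional dwell filter; `make_whole` assumes copies smaller than
  half the box; SASA is not cached across frames.
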