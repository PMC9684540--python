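# Methods

## The design problem

`foldsmith` builds small-protein backbones (roughly 30–80 residues) from a
*fold definition*: a declarative document naming the secondary-structure
elements of a target fold, their allowed length ranges, the loop
conformations permitted between them, which elements pair (strand–strand
with register shifts and bulges, helix–helix, helix–sheet), and loose
distance constraints between element anchors.  The engine searches this
ranged space — lengths, loop types, registers and torsions are all sampled
during a single design trajectory — so one definition yields a family of
shape-diverse backbones rather than a single blueprint-specified structure.

## Backbone model

A chain is parameterised entirely by its (φ, ψ, ω) torsions.  Cartesian
coordinates are produced by sequential natural-extension (NeRF) placement
with fixed covalent geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°
(Engh–Huber-style ideal values).  Carbonyl oxygens are placed in the
carbonyl plane along the external bisector of the CA–C and C–N(next)
directions; the terminal oxygen uses a virtual next nitrogen built with
ψ = 180° when ψ is undefined.  Dihedrals follow the standard IUPAC sign
convention (α-helix φ ≈ −57°), verified against an independent structural
library.  Torsions → coordinates → torsions round-trips to below 1e-6°.

Backbone torsion space is partitioned into the five-letter alphabet
A/B/E/G/O: O for cis peptide bonds (|ω| < 90°); for trans, φ < 0 splits
into A (ψ ∈ [−75°, 50°)) and B, and φ ≥ 0 into G (ψ ∈ [−100°, 100°)) and
E.  The boundary values are this package's commitment — the alphabet is
conventionally drawn graphically — and every (φ, ψ, ω) maps to exactly one
letter.

## Fragment sampling

Structured fragments are generated analytically rather than harvested from
a structure database: each letter has a canonical centre (A: −63°/−42°,
B: −135°/135°, E: 75°/170°, G: 75°/−10°) and torsions are drawn from a
Gaussian around it, rejection-sampled to stay inside the region.  Region
dispersions default to 10° (A) and 20° (B/E/G); ω is 180° ± 3° (0° for O).
The *folder* draws helix and strand interiors more tightly (σ = 4° and 10°
respectively): independent wide draws model neither real fragments'
internal correlation nor their sterics — at σ = 10° per residue a 14-mer
"helix" usually carries intrinsic O–N contacts under 2.5 Å and bends of
20–40°, which no amount of annealing can repair.  Loops keep the full
regional dispersion, because loop diversity is where shape diversity comes
from.  A user-supplied fragment file (ABEGO string plus torsion rows) can
replace analytic sampling entirely.

Loops draw their ABEGO strings from packaged connector menus keyed by the
flanking element classes (helix→strand, strand→helix, strand→strand,
helix→helix), reflecting the small set of loop conformations that actually
occur between such elements; a fold definition may override the menu per
loop.

## Divide-and-conquer planning

The planner enumerates every contiguous partition of the fold's
secondary-structure elements and keeps those where (1) the first block
contains a complete pairing (both partners inside the block; a helix–sheet
pairing is complete only when the helix and *all* its strands are present)
and (2) every element of a later block is anchored by a pairing into the
same or an earlier block.  Among valid partitions it returns the one with
the smallest first block, then lexicographically smallest block sizes,
tie-broken by document order.  For the three-stranded β–β–α–β topology
this reproduces the canonical division: fold the hairpin, add the helix,
add the last strand.  Loop segments travel with the block of the element
they lead into.

## Monte-Carlo folding of a subsegment

Each subsegment is folded onto the frozen context by Metropolis Monte
Carlo in torsion space.  The objective combines:

* steric clashes — CA pairs under 3.7 Å plus (in the late phase) backbone
  heavy-atom pairs under 2.5 Å, counted only for pairs involving a mobile
  residue, weighted 8→20 over the trajectory so early moves can pass
  through collisions;
* the fold's distance constraints (harmonic or flat-bottomed, quadratic
  near the target with a gentle linear far field so distant elements feel
  a steady pull that cannot overpower repulsion);
* pairing-derived terms: each registered strand partner pair is pulled to
  CA–CA 4.9 Å (flat bottom ± 0.4 Å), strand and helix pair orientations are
  scored by direction-vector dot products, helix–helix midpoints target
  10 Å and helix–sheet midpoints 9 Å (flat bottom ± 2 Å);
* a sheet-ordering term requiring successive strand midpoints of a
  declared sheet to advance along a consistent lateral direction, which
  removes the mirror degeneracy that pure distance terms leave;
* a helix-straightness term that penalises bends above 10°.

Moves mix 3-mer fragment redraws (crossing barriers; frequent early) with
single-residue Gaussian nudges of σ 5° that stay inside the residue's
torsion bin (zipping pairings shut; frequent late).  Loop positions are
drawn four times more often than secondary-structure interiors, since loop
torsions steer the topology.  The schedule anneals T = 2.0 → 0.5 over the
first 70 % of moves and quenches at T = 0.05 thereafter; trajectories are
2 000 moves per 15 mobile residues (scaled to block size).  A change at
position p re-places only residues p..p+span and moves the tail rigidly
with the frame of the last re-placed residue, so a move costs O(span)
atom placements plus one rigid transform; the inner loop is compiled with
numba.

Before any trajectory runs, a *reachability probe* (best of 150 cheap
random redraws, scored by pairing/constraint terms only) estimates whether
the new element can be placed at all from this context.  Single-element
attachments with no random placement anywhere near their pairing basin
fail immediately — the frozen context, not the sampling, is the problem —
and the best probe draw seeds the first trajectory.  Multi-element blocks
cannot be placed by random redraws, so their probe only harvests a seed.
Trajectories whose score is still hopeless at the phase switch or late in
the quench are abandoned early.

A subsegment is accepted when the full filter battery passes (checked at
periodic checkpoints once the score is low, and at trajectory end).
Accepted subsegments get a short greedy small-move polish (500 steps),
kept only if the battery still passes.

## Perturbation, backtracking, restarts

When a task exhausts its trajectories, the perturber resamples exactly one
parameter class — segment lengths, loop ABEGO, register shift, torsion
seed — in rotation, always excluding the current value, within the
declared ranges (combinations that leave a sheet uncoverable are
rejected).  When the perturbation budget is exhausted the builder
*backtracks*: the previously accepted subsegment is discarded and
re-folded with fresh parameters before the failing task is retried,
because a frozen context (for instance a helix whose C-terminus points
away from the sheet edge the next strand must reach) can make the next
pairing geometrically unreachable, and no perturbation of the failing task
can repair that.  After the backtrack budget, the whole build restarts
with fresh parameters.  A global trajectory cap bounds the total work per
build call.  Everything is driven by one seeded generator, so a build is a
pure function of (fold, seed, limits).

## Filters

* secondary-structure identity: ABEGO-derived labels (A→H, B/E→E, else L)
  must match the fold for every helix/strand interior residue (±1 at the
  termini exempt);
* helix kink: every helix must bend < 15°.  The bend is the angle between
  local axis directions averaged over the first and last four 4-residue
  windows; the local axis comes from the cross product of consecutive
  second differences of the CA trace, which is exact for an ideal helix,
  so a straight helix measures 0° regardless of where the windows sit on
  the helical period.  (A least-squares line through sliding window
  centroids was tried first and rejected: the 4-CA centroids of an ideal
  helix spiral slightly because 4 is not a multiple of the 3.6-residue
  period, and the fitted axes of a perfectly straight helix came out up to
  17° apart.)  Helices under 8 residues are not evaluable and pass with a
  note;
* distance constraints: within 2 × SD of the target (harmonic), or of the
  flat-bottom edges (bounded);
* strand pairing: the measured register — the integer shift maximising the
  number of partner CA pairs inside the 4.2–5.7 Å pleated-sheet window,
  ties broken toward the declared register because short strands make
  neighbouring shifts genuinely ambiguous — must equal the declared
  register, the strand direction vectors must agree with the declared
  orientation, and at least 70 % of partner pairs must sit inside the
  window.  The fraction floor rejects barely-zipped sheets while
  tolerating realistic edge fraying;
* ω/Ramachandran: every non-terminal ω within 180 ± 20° unless the residue
  is assigned the cis letter, and every (φ, ψ) inside its assigned region
  with at most a 5° excursion;
* clash: no backbone heavy-atom pair under 2.5 Å between residues ≥ 2
  apart in sequence.

All filters are pure functions; every success-status build re-passes the
entire battery.

## Sequence design

Residues are layered by a burial proxy: the number of CA atoms within
10.5 Å lying inside a 70° half-angle cone around the CA→pseudo-CB
direction (pseudo-CB by the standard ideal-tetrahedral linear
combination).  Burial ≥ 5 is core, ≤ 2 surface, else boundary.  The plain
protocol draws each position from its layer palette (core hydrophobic,
surface polar/charged, boundary mixed), with glycine at positive-φ loop
positions and an N-cap palette (D/N/S/T) at helix N-termini.  The motif
protocol first seeds pairs of core positions whose pseudo-CB distance
falls inside a pair-motif window, visiting candidate pairs nearest-first;
the packaged ~40-entry motif table is a hydrophobic-biased toy standing in
for a crystal-structure-derived database and uses the same documented
format, so a real table can be dropped in.  There is no rotamer packing
and no all-atom energy: palettes plus motifs capture the combinatorial
layer of the protocol only.

## Shape descriptors

Helix axes are least-squares lines through sliding 4-CA window centroids
(adequate here because the windows span the whole helix).  Hm-d is the
distance between the first two helices' axis midpoints.  H-dih is the
dihedral through (H1 axis end, H1 mid, H2 mid, H2 axis end) — end points
taken on the same flank so two aligned parallel helices measure ≈ 0° and
antiparallel ones ≈ 180°.  Opening angles H1a/H2a are the angles between
each helix axis and the partner element's least-squares CA plane.  The
sheet dihedral runs through the N- and C-end CAs of the first outer strand
then the N- and C-end CAs of the last, in sheet order, so a perfectly flat
sheet measures 180° and curvature moves it away; mirroring flips the sign
of all dihedral-valued descriptors.  Ensemble correlations are
pairwise-complete Pearson with NaN for zero-variance columns.

Per-protease stability scores combine by the minimum — a protein cleaved
by either protease is unfolded, so a high trypsin score cannot rescue a
negative chymotrypsin score — and a fold's success rate is the fraction of
designs with combined score strictly above 0.5.

## Stability classifier

The feature registry is a representative ~20-feature set (length, charge,
composition, secondary-structure fractions, contact-network degree
statistics, the most-connected "hub" residue's contact-weighted burial,
buried-hydrophobic counts, local-geometry fragment agreement as the mean
CA RMSD of 9-residue windows against ideal-torsion rebuilds, contact
order, radius of gyration).  It is name-keyed and data-driven so features
can be added without touching the model.  The classifier is a
500-tree random forest with the Gini criterion, bootstrap resampling with
out-of-bag accuracy, sqrt feature subsetting and fivefold stratified
cross-validation (scikit-learn provides the trees; the Gini index itself,
1 − Σ pᵢ², is also exposed directly).  AUC is rank-based with average-rank
tie handling, identical to the normalised Mann–Whitney U.  Fold-dropout
evaluation trains on all folds but one, scores the held-out fold, repeats
with fresh seeds, and reports min/median/max per fold plus a whole-set
(out-of-bag) AUC and a pooled held-out AUC; single-class folds are flagged
and excluded.

## Synthetic data and what passing tests show

Test inputs are generated, never downloaded: ideal and kinked helices,
ideal strands, rigid-placement hairpins and sheets with exact ground
truth, scrambled-torsion decoys, and Gaussian feature tables whose labels
follow a fold-independent rule (or none).  These fixtures exercise the
geometry, the filters and the estimators, but they do not contain real
proteins' sequence–structure coupling, solvation, or measurement noise —
so green tests demonstrate that the machinery computes what it claims, not
that designed sequences would fold in the laboratory.

## Problem sizes and numerical choices

Desk-scale runs use shortened schedules (600 moves per 15 mobile residues,
3 trajectories and 3 perturbations per task, up to 12 backtracks, 7
restarts, a 240-trajectory cap per build); the committed defaults are the
larger 2 000/20/100 schedule.  The buildability survey in the acceptance
script runs the packaged ferredoxin definition (strands 4–6, helices
10–16, loops 2–4, register shifts −2..2, default 8 Å/2 Å constraints) over
50 seeds and reports the smallest passing design.  Parameters are drawn
uniformly from their declared ranges, except registers, which are drawn
proportionally to the square of the number of residues they pair —
builders favour well-zipped strands, and a register pairing only the
strand tips rarely closes with a short loop.  Degenerate inputs
(collinear dihedrals, helices too short to measure, single-class training
data, zero-variance features) return sentinels or explicit errors rather
than silent values.

## Known limitations

No hydrogen bonds, side chains or energies: sheets are maintained by
CA-level pairing geometry, so β-pleat registration is approximate and the
2.5 Å clash cutoff is deliberately permissive.  The analytic fragment
sampler has no sequence dependence (no proline/glycine-specific maps).
Buildability rates for mixed α/β folds are sensitive to the guiding
constraints in the fold definition, exactly as they are in practice;
fold families beyond the packaged examples may need an extra constraint
or register range to build efficiently.  The classifier's feature set is
representative, not exhaustive, and its accuracy on real designs depends
on training data this package does not ship.
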