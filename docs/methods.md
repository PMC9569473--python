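# Methods

## Distance restraints from cross-linker geometry

An amine-reactive cross-linker joining two lysines bounds their Cα–Cα
distance by the sum of its spacer length, the two side-chain arms, and an
allowance for backbone flexibility and structural dynamics. The DSSO preset
uses a 10.1 Å spacer, 6.29 Å per lysine arm and a 3.0 Å allowance, giving a
raw bound of 25.68 Å. The reported threshold rounds the raw sum to the
nearest integer (26 Å); both values are retained and either can be used for
classification (default: reported).

Classification partitions measured distances into three bands:

- **satisfied**: d ≤ threshold (the boundary is closed — a link at exactly
  26.0 Å counts as within the limit);
- **marginal**: threshold < d ≤ grace (default grace 30 Å). The grace band
  names the "slightly beyond the limit" group that practitioners report
  separately from hard violations; it is a convention of this package, not a
  chemical constant, and is configurable;
- **violated**: d > grace.

Restraints whose endpoints are missing from the model (unmodeled loops,
excluded termini) are **unmeasurable** and are counted separately from the
measured total: `n_identified = n_measured + n_unmeasurable`. This mirrors
real validation campaigns, where a handful of identified links fall in
regions the models do not cover.

Disulfide pairs are evaluated on the SG–SG distance with a 5.6 Å bound. On
Cα-only trace models, where no sulfur coordinates exist, the evaluation
falls back to Cα–Cα with a wider 7.5 Å default bound and carries an explicit
fallback flag; 7.5 Å was chosen as a generous Cβ-geometry-free proxy for
"close enough that correctly rotameric sulfurs could bond".

Cross-links are canonicalized (smaller residue first) and deduplicated
before evaluation; counts always refer to unique links.

## Segmentation bookkeeping

A segmentation scheme lists named segments at three levels — subunit, domain,
coil — as inclusive 1-based ranges in full preproprotein numbering. Multi-
range segments are allowed (apoB-100 subunit IV domain 3 is assembled from
three separate sequence stretches). Ranges may not overlap within a level;
residues may be unassigned at the domain level (inter-domain linkers).
Link topology is derived from segment lookup: endpoints in different
subunits → inter-subunit; same subunit and same domain → intra-domain;
otherwise intra-subunit.

The packaged apoB-100 scheme records the mature protein span 28–4563
(signal peptide 1–27 keeps its coordinates but lies outside the span) and a
coverage mask excluding 2551–2590, which the subunit IV model leaves
unmodeled. Coverage fractions are percentages of the 4536-residue span,
rounded to one decimal (note: subunit II computes to 23.3% under this
rounding).

Secondary-structure content tables default to the *percent of total
content* convention: each cell is a segment's residues of that class divided
by the whole-span length, so all cells of the table sum to ~100 and the
Total row is the column sums. A per-segment normalization is available as an
option.

Consensus domain boundaries cluster per-window predictions by single
linkage (gaps > tolerance split clusters; default tolerance 10 residues),
represent each cluster by the rounded median, and keep clusters supported by
at least `min(min_support, number of windows covering the representative)`
distinct windows (default min_support 2). All three knobs are configurable;
the defaults are this package's own choice of a reasonable comparison rule
for overlapping sliding-window predictions.

In-silico digestion implements trypsin (cleave after K/R, suppressed before
P), enumerates peptides with up to the requested number of missed cleavages
(MS-search-style defaults: 3 missed cleavages, minimum length 5), and
reports 1-based coordinates. Non-standard residues raise by default; a
skip-site mode treats them as ordinary non-cleaving residues.

## Rigid-body assembly

Each mobile segment is placed by minimizing

    loss = Σ_links max(0, d − d_max)² + λ · clashes

over the 6 rigid-body parameters, where the clash count is the number of
inter-body Cα pairs closer than 4 Å (KD-tree, identical to brute force) and
λ defaults to 100 Å² per clash. Restraints with an endpoint in a coil-level
segment receive extra slack on d_max (default +10 Å): coils are flexible,
and a rigid placement cannot reproduce their local torsion adjustments.

The optimizer is a seeded multi-start search (default 20 uniform random
rotations; translation initialized to superpose restraint-anchor centroids).
Each start is refined in two stages:

1. **Projection**: violated anchors are pulled onto their restraint spheres
   and the anchor set re-superposed (Kabsch), iterated to rapidly drive the
   restraint excess toward zero. Plain coordinate descent from random starts
   recovered poses far less reliably, which motivated this stage.
2. **Coordinate descent** over the 6 pose parameters with step halving
   (rotations applied about the current anchor centroid), convergence at
   Δloss < 1e-6 or 500 iterations. During descent the clash term is a
   smooth soft-core penalty Σ (1 − d/cutoff)² over too-close pairs; it has
   exactly the same zero set as the count but gives descent a direction out
   of overlaps. Reported losses always use the count form.

Greedy sequential assembly anchors the first segment in the given order and
fits each following segment against the union of already-placed ones, using
all restraints bridging to them. A segment with no bridging restraints is
skipped with a warning. The default order (I, II, III, V, IV) follows the
practice of anchoring the best-constrained N-terminal segments and placing
the large β-propeller subunit last.

### Mirror-image ambiguity

Distance-only restraints determine a rigid placement at best up to
reflection: reflecting a zero-loss configuration through any plane yields
another zero-loss configuration (up to clashes). When `allow_mirror` is set,
the optimizer additionally searches the reflected copy of the mobile body
and returns the improper solution only when its combined loss is strictly
lower. Improper poses are always flagged and never applied silently, because
reflecting real atomic coordinates inverts chirality; the flag tells the
modeler that the segment's fold is likely the mirror image of the true
structure and should be re-modeled or repositioned rather than literally
reflected.

A caveat established while designing the recovery tests: one-sided (upper
bound) restraints pin a pose only when the anchor pull directions surround
the body — sparse restraints to one side leave large zero-loss families,
and bodies with internal symmetry (an ideal helix's screw symmetry) leave
near-degenerate alternative placements. Recovery fixtures therefore use an
asymmetric coil body inside a surrounding anchor cage with restraints to the
three nearest cage vertices per residue; under those conditions the fitted
pose lands within 2 Å RMSD of the truth in ≥95% of seeded runs. Assembly
quality in general is asserted through restraint satisfaction, not RMSD.

### Lipoprotein particle shells

The LDL particle is modeled as a 200×200×110 Å discoid: an elliptical disk
(the footprint shrunk by the rim radius dz/2) swept with a ball of radius
dz/2, i.e. flat faces with a hemitoroidal rim. The signed distance is
computed as distance-to-disk minus rim radius; the in-plane distance to the
ellipse boundary is found numerically over a dense boundary sampling (2048
points, error far below coordinate noise). The VLDL particle is a 300 Å
diameter sphere. Shell containment reports the fraction of Cα atoms whose
signed surface distance lies within (−inner, +outer), default ±20 Å — about
the half-thickness of a protein monolayer draped on a lipid surface.

## Surface exposure

SASA uses the Shrake–Rupley construction with a deterministic golden-spiral
point lattice (default 960 points per atom, probe 1.4 Å) and element-based
van der Waals radii; Cα-only trace models use an enlarged 3.0 Å pseudo-atom
radius to stand in for the missing side chain. Relative accessibilities
divide by published tripeptide maximum areas (Tien et al. 2013 theoretical
values, shipped as data and swappable); values above 1 are flagged and
clipped at 1.2. Per-residue areas are rotation-invariant to within the
point-sampling error (≈0.5% at 3840 points, ≈3% at the 960-point default).

Protein painting: a peptide is paint-positive iff present in **all**
unpainted replicates and absent from **all** painted replicates (default
three replicates per condition); the output is the merged residue ranges of
paint-positive peptides. The rule is deliberately strict — a single painted
detection or a single unpainted dropout removes a peptide — so the output is
monotone under added painted detections. Mono-link concordance is the
fraction of hydrolyzed-linker sites falling inside painted ranges, reported
as a number with no pass threshold (the underlying comparison is
qualitative); it is undefined (None) without sites.

## Synthetic fixtures

The generator produces idealized Cα traces with closed-form oracles: helices
(radius 2.3 Å, rise 1.5 Å/residue, twist 100°/residue — consecutive-residue
chord ≈ 3.8 Å), strands (3.8 Å steps, alternating ±5° zigzag), and coils
(self-avoiding random walks, 3.8 Å steps, 3.5 Å minimum non-bonded
separation, rejection sampling with restarts). Everything is deterministic
under a seed.

`plant_crosslinks` samples residue pairs whose true distances fall in
requested classification bands and stores the ground truth, so reports can
be checked against construction. `scramble` applies a recorded random rigid
(optionally reflecting) displacement for recovery tests.

The packaged toy fixture scales the five apoB-100 subunits to one tenth
(99/106/48/151/51 residues, contiguous numbering). Segments are compact coil
blobs — ideal strands at this length would be ~570 Å rods, incompatible with
a particle-sized architecture — arranged like the real protein: II beside I,
III and V on either side of II, IV bridging III and V. Thirteen
inter-segment links (echoing the real inter-subunit count, over pairs I–II,
II–III, II–V, III–IV, IV–V) plus five intra-segment links are planted at
comfortably satisfiable distances (≤ 0.8 × threshold). Layout is by sliding
each randomly oriented blob along a placement direction until it clears the
placed union (≥ 6 Å) while staying in link range of its designated
neighbours; the occasional geometrically infeasible seed retries
deterministically with an offset sub-seed. `make_painting_dataset` digests a
sequence and marks peptides overlapping exposed ranges absent in painted
replicates, with optional i.i.d. dropout noise.

What the fixtures do *not* emulate: real side chains and backbone geometry,
lipid, spectra and identification noise, ambiguous residue-level link
assignments, and model error within segments (fixture segments are placed
rigidly from their true internal coordinates). Passing tests therefore
demonstrate the correctness of the bookkeeping, geometry and optimization
machinery under the stated model — not that any particular real protein's
models are accurate.

## Problem sizes and numerical choices

Test and acceptance runs use toy scales chosen as the smallest sizes that
exercise every code path: 12-atom anchor cages, 20-residue mobile bodies,
the 455-residue five-segment toy, 20-seed recovery batches. Distances are
exact Euclidean computations; classification boundaries are closed; reports
round distances to 2 decimals and percentages to 1; histogram bins are 2 Å
wide, right-open, starting at 0. Degenerate optimizer inputs (collinear
anchors) produce a diagnostic warning rather than an error, since the pose
family is then genuinely non-unique.

## Known limitations

- Rigid-body only: no flexible refinement; coil flexibility is approximated
  by per-restraint slack.
- The loss form (squared excess + clash penalty) is this package's choice;
  manual fitting practice it formalizes has no published objective.
- Upper-bound restraints rarely pin poses uniquely in real data; the
  assembler reports satisfaction and clashes, and leaves interpretation of
  degenerate placements to the modeler.
- The discoid signed distance is numeric (boundary sampling), exact only to
  ~1e-2 Å; adequate for ±20 Å shells.
- PDB output is minimal (ATOM/END records); mmCIF is not written.
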