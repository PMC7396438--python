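# Methods

This note documents the models and numerical choices behind xlinkdock: what
each stage computes, the parameters that matter, what the synthetic systems
do and do not emulate, and the design decisions taken where the design was
genuinely open.

## Coordinate model and PDB I/O

Structures are a chain → residue → atom hierarchy in ångströms, in the frame
of the input file; no renumbering or re-orientation is applied (structures
of the target system conventionally number residues including signal
peptides, and that numbering is taken as-is). Parsing and serialisation go
through gemmi. Alternate locations keep the first-listed conformer —
deterministic and in line with common practice. Insertion codes are part of
residue identity. Hydrogens are parsed but excluded by the default "heavy"
atom filter, since crystal and cryo-EM inputs mostly lack them. Non-standard
residue codes are accepted through an alias table mapping to a parent amino
acid (defaults cover MSE→MET, a benzophenone site→PHE, SEC→CYS, PYL→LYS;
extendable from a two-column text file).

## Docking

**Grids.** Heavy atoms of non-blocked residues are projected onto a cubic
grid: a cell is occupied when its cube intersects the atom sphere
(occupancy radius 1.6 Å). Occupied cells with at least one empty 6-neighbour
are *surface*; fully enclosed cells are *core*. Cells owed solely to
blocked residues (the membrane-embedded region of the receptor) are
cleared, so they contribute neither contact reward nor clash penalty.

**Scoring.** For every integer translation,
`score = Σ f(receptor cell, ligand cell)` with `f(surface, occupied) = +1`,
`f(core, occupied) = −C` (default C = 9, configurable), `f(empty, ·) = 0`,
computed with `scipy.signal.fftconvolve`. The test suite verifies exact
agreement (to 1e-6) with an O(G²) double-loop oracle on random grids up to
12³. The full published pairwise-shape-complementarity function carries
desolvation and electrostatic grid terms; those live in the rescoring stage
instead, because the docking score is used only to rank and filter.

**Rotations.** Uniform random unit quaternions from a seeded generator,
with the identity prepended so the input orientation is always scanned
(pipeline default: 24 rotations). The angular sampling density of the
original workflow is not public; determinism under a seed was prioritised
over a fixed Euler deck.

**Grid spacing.** Default 2.0 Å. The surface shell is exactly one cell
thick, so the spacing sets the thickness of the contact-rewarding envelope;
with the ~1.7 Å envelope overlap of two pseudo-protein bodies in atomic
contact, a sub-1.5 Å spacing makes genuine contact read as core clash. 2.0 Å
matches the 4 Å residue lattice of the synthetic systems. Spacing, clash
penalty, occupancy radius and the 128³ grid cap are all configurable.

**Retention.** Per rotation, translation candidates closer than one cell to
a kept candidate are merged keeping the higher score (for integer offsets
this removes exact duplicates only); the global top-N (default 60) by
score, with deterministic tie-breaking (rotation index, then lexicographic
offset), become poses. Poses store the full real-space transform
x → R x + t reconstructed from grid indices; an all-empty ligand yields an
empty pose list with a warning rather than an error, so batch runs survive
degenerate inputs.

## Pose analysis

* **Interface**: all residue pairs with heavy-atom minimum distance below a
  cutoff. The per-operation default is 5.0 Å (no cutoff is standard across
  studies; it is exposed in config). The pipeline uses 7.0 Å, one grid cell
  more than the synthetic native contact gap, so that a pose within one
  cell of the native placement still registers every native contact.
* **Clustering**: greedy leader clustering on the transformed ligand
  centroid (descending docking score, pose-id tie-break; default radius
  10 Å). Centroid clustering was chosen over full-atom RMSD because it is
  cheap, deterministic and sufficient for leader clustering at this scale.
* **Density**: number of poses (including itself) whose ligand centroid
  lies within a radius. The module default equals the cluster radius; the
  pipeline uses 4.0 Å — about two grid cells — so that density counts
  rotations agreeing on one placement rather than how crowded a receptor
  face is. On 60-pose toy ensembles a 10 Å density sphere covers most of
  the receptor and carries no signal.
* **Filtering**: a pose passes when (i) every required receptor residue is
  in its interface, (ii) at least `min_domain_fraction` (default 0.5,
  operationalising "mainly through the docking domain") of its ligand
  interface residues lie in the required ligand domain, and (iii) the
  interface contains at least `min_count` required-orientation residues and
  at most `max_count` forbidden ones. Every failure is recorded per
  criterion. Criteria referencing residues absent from the structures raise
  a config error listing them. A qualitative criterion like "around residue
  N" is operationalised as an ±5-residue window when criteria are built
  from real data.

## Cross-link restraints

Spacer-arm lengths are maxima, so satisfaction is inclusive
(`distance ≤ max_distance`), tested at exactly 6.8 and 12.0 Å. Anchors:
amine–amine → lysine NZ on both sides; amine–sulfhydryl → cysteine SG and
lysine NZ (measured to NZ/SG specifically — whether the original analysis
used NZ or any side-chain atom is not stated, so the NZ convention is a
documented decision); photo-cross-links are residue-level and anchor on CB
with CA fallback, with a 10 Å default reach for restraint-style use (photo
contacts primarily flow through the interface criteria instead). A receptor
position engineered as a cysteine point mutant in the experiment may lack
SG in wild-type coordinates; the amine–sulfhydryl anchor then falls back to
CB and the report notes it. A wildcard "any-Lys" ligand anchor scans all
ligand lysines and reports every partner within reach sorted by distance.

## Rescoring and model selection

Pairwise heavy-atom terms within 9 Å: a Lennard-Jones 6-12 well (uniform
depth 0.1, per-element radii, combined radius = sum) split into its
negative (attractive) and positive (repulsive) parts; screened Coulomb with
distance-dependent dielectric ε(r) = 4r on residue-typed formal charges
(+1 Lys NZ/Arg CZ, −1 Asp CG/Glu CD), split the same way; and a contact
desolvation score from a polarity-class matrix with a linear distance
taper. All tables and the cutoff are overridable. The published 7-term
rescoring function (with a short/long-range electrostatic split) is
collapsed to this 5-term form because the rescoring is used only ordinally
and full parameter fidelity is unverifiable from public text; weights
(defaults 1.0/0.8/0.4/0.4/1.0) are configuration, not claims. Distances are
floored at 0.5 Å to keep the r⁻¹² term finite on degenerate input.

Final models: Pareto-non-dominated records on (density ↑, docking score ↑,
rescore ↓) ordered lexicographically in that priority, dominated records
deferred behind the front, pose-id tie-break, top-k returned (default 5).

## Validation

**Dihedrals** use the standard atan2 torsion formula; chain-terminal
residues, missing backbone atoms and collinear geometry give undefined
angles with a reason rather than an exception. **Ramachandran regions** are
shipped as package data (`data/rama_regions.txt`): a two-level
favoured+allowed set collapsed to one "favorable" classification, with
polygons for the right-handed helix, sheet (wrapping across ψ = ±180°) and
left-handed helix basins; classification is invariant to ±360° shifts. The
original study's proprietary region set is unavailable, so its exact
outlier count is not a target.

**Burial** is a Shrake–Rupley-style accessible-surface estimate: a
deterministic Fibonacci sphere lattice (default 128 points, minimum 92) at
radius r_atom + probe (probe 1.4 Å), occlusion by neighbouring expanded
spheres, aggregated to a side-chain buried fraction
`1 − accessible_in_complex / accessible_isolated` (CA stands in for absent
side chains). Doubling the point count moves fractions by < 0.05 on the
shipped fixtures.

**3D-1D profile.** Each residue gets one of 18 environment classes: burial
(exposed < 0.4 ≤ partial < 0.7 ≤ buried) × environment polarity (fraction
of polar N/O neighbour atoms within 4.5 Å of the side chain ≥ 0.35) ×
secondary structure (helix/sheet/other from φ/ψ bins — no hydrogen-bond
machinery is needed at toy scale). Scores come from a packaged 20×18 table
(`data/profile3d_scores.tsv`, regenerable with
`scripts/make_profile_table.py`): a smooth hydropathy-vs-burial/polarity
compatibility function with a small helix-former bonus, spanning roughly
[−0.75, 0.7] per residue as published 3D-1D tables do. The Verify Score is
the per-residue sum. The Expected High Score defaults to the length
calibration exp(−0.83 + 1.008 ln L) from the original 3D-1D literature and
can be overridden; the Expected Low Score is always 45% of the high score —
the one numeric relation the validation stage treats as fixed. Outcomes:
at or above the low score is "mostly correct" (with an explicit band field
separating above-high from the intermediate band, boundary inclusive at the
low score); below it is "grossly misfolded".

## Stoichiometry arithmetic

Adduct mass = Σ count × monomer mass (kDa). Band quantification divides
each band by its nonspecific internal-control band and normalises to a
reference lane (1.00), making the result invariant to global intensity
rescaling and unit choice; replicates are averaged with a standard
deviation (n = 2 in the motivating experiments).

## Synthetic systems

`make_block_complex` emulates the *shape* of the real problem — a mobile
ligand docking onto a dedicated site of a larger receptor whose
membrane-embedded face is excluded — with pseudo-proteins: residues are 3–5
pseudo-atoms (N, CA, C plus side-chain points) on a 4 Å lattice with 0.1 Å
jitter. The receptor carries a walled socket (pocket floor, a stacked ring
wall with ~3 Å clearance, a wide base) and a blocked slab ≥ 8 Å from the
docked ligand; the ligand is a two-layer slab that fits the socket. The
native pose is the identity transform; because the native placement touches
the floor and all four walls at once, it is the global optimum of the
shape-complementarity search (verified across dozens of seeds), while every
other face offers a single flat contact. Planted anchors sit at exact
distances — 10.0 Å NZ–NZ inside the 12 Å amine–amine arm, and 4.0 Å SG–NZ
inside the 6.8 Å amine–sulfhydryl arm, the latter short enough that a pose
one grid cell from the native placement still satisfies it. Anchor atoms
sit on exact lattice positions so these margins are deterministic under
jitter. The docking domain and "upper" orientation set are the ligand
residues contacting the receptor in the native pose; the "bottom" set is
the rest, and the generated criteria tolerate one forbidden residue in the
interface because a pose one cell from native can pull a single
just-outside-the-cutoff residue in, whereas flipped poses show many.

What the toys do **not** emulate: real side-chain rotamers and packing,
sequence composition, solvent, conformational flexibility, and the
fuzziness of real cross-linking data (every planted restraint is exactly
satisfiable). Passing the planted-recovery tests therefore demonstrates
that the search, filters, restraints and selection machinery are correct
and deterministic — not that the scoring function would rank real docking
decoys the way the original software does.

`make_decoys` applies random-axis rotations (normal angle, sd in degrees)
about the ligand centroid plus isotropic normal translation noise; zero
sigmas reproduce the native pose exactly, and restraint violation grows
monotonically with translation noise. `make_helix_backbone` builds an ideal
α-helix (φ = −57°, ψ = −47°, ω = 180°) by natural-extension placement with
standard bond lengths and angles, as a fixture with exactly known
dihedrals.

## Tolerances and problem sizes

"Within one grid cell of the native translation" is checked per axis as
|Δ| ≤ 1.5 × spacing: the search can only emit lattice translations whose
sub-cell phase relative to the native placement is arbitrary (up to half a
cell per axis), so one cell of slack around the nearest achievable
translation corresponds to 1.5 cells around the native itself. Pipeline
study sizes — 139-residue receptor, 18-residue ligand, 24 rotations, top-60
poses, 200 far decoys, three seeds per recovery study — were chosen as the
smallest systems that exercise every stage with clear margins; a full
pipeline run takes about one second.

## Known limitations

* The docking score is contact counting; it has no electrostatic or
  desolvation grid terms, so absolute score values are not comparable with
  published docking scores.
* Rescoring weights and tables are plausible defaults, not fitted values;
  only ordinal properties (clash-heavy decoys score worse than compact
  natives, linearity in weights) are guaranteed.
* The 3D-1D score table is a documented heuristic; total Verify Scores are
  comparable between models scored by this package but not with values
  from proprietary implementations.
* mmCIF input, assemblies/symmetry expansion and occupancy-weighted
  coordinates are out of scope; flexible docking and side-chain repacking
  are not attempted.
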