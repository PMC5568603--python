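# Methods

`slimdock` models protein-protein association mediated by a short linear
motif (SLiM): a contiguous peptide segment of one protein (the partner)
that contributes most of the binding interface with the other (the
receptor).  The pipeline has three stages: (1) flexible coarse-grained
docking of the motif *sequence* to the receptor by replica exchange
Monte Carlo (REMC); (2) density-based selection of representative docked
poses; (3) reconstruction of the full protein-protein complex by rigid
superposition of the partner onto the docked motif, with a steric clash
report in place of an energetic refinement stage.  When a reference
complex is available, models are scored by interface RMSD (iRMSD),
fraction of native contacts (fNC) and ligand RMSD (L-RMSD).

Only the motif's sequence enters the docking stage.  Bound-state
coordinates of the peptide, when they exist, are used exclusively by the
evaluation stage as reference — the sampler never sees them.

## Coarse-grained representation

Each residue carries up to four interaction sites: the alpha carbon
(CA), the beta carbon (CB), a united side chain (SC) and the
peptide-bond centre (PB).  From all-atom input, CB is copied (or rebuilt
from N/CA/C by ideal tetrahedral geometry when missing), SC is the
centroid of the side-chain heavy atoms (so an alanine's SC coincides
with its CB; glycine has neither), and PB is the midpoint of C(i) and
N(i+1).  Generated peptides are CA traces with exact 3.8 A virtual
bonds; their CB/SC sit along the inverted bisector of the two adjacent
virtual bonds at per-residue-type distances (1.5-4.1 A), and PB is
approximated by consecutive-CA midpoints.  The model is off-lattice:
continuous coordinates with a fixed 3.8 A CA-CA virtual bond are simpler
than a lattice and sufficient for the protocol's structure.  A chain
read from experiment must have all consecutive CA-CA distances within
[3.2, 4.3] A (cis-peptides and resolution noise); anything outside is
treated as a chain break, not silently accepted.  PB sites are stored
for fidelity to the representation but carry no energy term by default.

A backbone-only file (CA/CB) read back in cannot be re-coarse-grained:
a missing side chain raises rather than silently degrading SC to CB.

## Energy model

The potential is a transparent knowledge-based surrogate with five
terms, every constant exposed as configuration:

- **Contact term.** A symmetric 20x20 residue-type table evaluated on
  SC-SC site pairs (CA for glycine) across the two chains within 6.5 A.
  The shipped default table is derived from Kyte-Doolittle hydropathies,
  `e_ij = -w (h_i + h_j)` with `w = 0.15`, so hydrophobic pairs attract
  (I-I: -1.35) and charged-polar pairs are mildly repulsive (a crude
  solvation proxy).  It lives in `data/contact_energies.csv` and is
  user-replaceable by any symmetric table on the same residue order —
  the funnel-recovery test suite, for instance, substitutes a table
  engineered around a synthetic complex's planted contacts.
- **Excluded volume.** Quadratic penalty `w_ev (r_hc - d)^2` below the
  hard-core radius `r_hc = 3.5 A`, over all inter-chain pseudo-atom
  pairs and intra-chain pairs with sequence separation >= 2.
  Intra-residue and adjacent-residue pairs are excluded because they can
  never be separated by `r_hc` (a CA and its own peptide-bond centre sit
  ~1.9 A apart); including them would only add a large constant.
- **Virtual bonds.** Harmonic terms (k = 5 energy/A^2) on consecutive
  CA-CA distances: about 3.8 A for the peptide, about the *starting*
  distances for the receptor (experimental bond lengths vary within the
  validity window and should be preserved, not idealised).
- **Receptor restraints.** Flat-bottom harmonics (half-width 1 A, k = 1
  energy/A^2) at the starting CA-CA distance for every residue pair with
  sequence separation >= 5 and starting distance in [5, 15] A — the
  standard near-native restraining recipe.  All restraints score zero at
  the input conformation.
- **Centre-of-mass tether.** A weak flat-bottom term (free within the
  placement distance + 10 A, k = 0.05 energy/A^2) on the peptide
  centroid.  It is the continuous-space counterpart of a lattice
  simulation box: without it an unbound peptide is transient in 3-D and
  can diffuse away for good.  It exerts no force anywhere near the
  receptor.

Energies are dimensionless; temperatures are expressed in the same
units (Boltzmann constant 1).

## Sampling

Ten replicas run Metropolis Monte Carlo on a geometric temperature
ladder, T in [1.0, 3.0] by default.  The move set (all proposals
symmetric, so detailed balance holds with the plain Metropolis rule):
rigid peptide translation (<= 2 A) and rotation (<= 30 deg);
single-residue CA displacement (<= 1 A) with re-derivation of the
dependent CB/SC/PB sites; two-bond crankshaft and terminal-residue pivot
(<= 30 deg); single-residue receptor displacement (<= 0.5 A, the
residue's sites moving rigidly).  A sweep is peptide-length + 2 move
attempts per replica.  Configurations (with their energies) swap between
adjacent temperature slots with probability
`min(1, exp((1/T_i - 1/T_j)(E_i - E_j)))`, in alternating even/odd
pairings.

Replicas start as fresh self-avoiding random conformers, rigidly placed
in uniformly random directions with their minimum pseudo-atom distance
to the receptor equal to the placement distance (20 A) to within 0.01 A
(bracketed root find on the translation).

Defaults produce 1000 snapshots per replica at a fixed cadence across
the whole run — 10,000 models in all.  Snapshots are taken across the
entire trajectory, not post-equilibration: early high-energy snapshots
are eliminated later by the energy filter, and a burn-in cutoff would
add a parameter with no observable benefit at these system sizes.
Exchange is attempted every 10 sweeps by default; the bundled
funnel-recovery experiments use every 2 sweeps, where the faster
temperature mixing measurably accelerates escape from partially docked
states.  One root seed drives everything: per-replica streams, the
placement stream and the exchange stream are spawned children, so
per-replica trajectories do not depend on how many replicas exist.

Energy bookkeeping is incremental by components (receptor-internal,
peptide-internal, interaction), with caches that travel with
configurations through exchanges; the suite asserts agreement with
from-scratch recomputation to 1e-6 after thousands of moves.

## Selection and ranking

The 100 lowest-energy snapshots of each replica (1000 poses in all, ties
broken by snapshot index) are aligned into a common frame: each
snapshot's receptor is superposed onto the starting receptor and the
transform applied to its peptide.  The receptor moves during sampling,
so without this alignment the peptide comparison would be contaminated
by receptor drift.  L-RMSD — peptide CA RMSD with no further fitting —
is then a pseudo-metric on poses; the full 1000x1000 matrix is computed
by the Gram-matrix identity and is the dominant selection cost.

Clustering is k-medoids (k = 10): k++-style seeded initialisation on
the distance matrix, then alternating nearest-medoid assignment and
within-cluster medoid refresh until stable (total distance-to-medoid is
non-increasing, so termination is guaranteed; a medoid always claims
itself, so clusters cannot empty).  Clusters are ranked by density =
member count / mean pairwise L-RMSD, ties broken by larger membership
then lower medoid energy.  A single-member cluster's density is an
infinite sentinel (the mean over zero pairs is undefined); it ranks
above all multi-member clusters and the sentinel is configurable to a
finite cap.  The 10 medoids of the densest clusters are the
representative models.

## Complex reconstruction

The partner protein is placed by a least-squares rigid superposition
(proper rotations only; reflections excluded by determinant correction)
of its motif CA atoms onto the docked pose's CA trace — CA is the only
currency the coarse pose and the all-atom partner share.  The whole
partner then moves rigidly, and the receptor is left bitwise untouched.
By default the rank-1 model is assembled; any rank can be selected,
since in practice partial knowledge of the binding site often picks a
different member of the top 10.  Instead of all-atom refinement the
package emits a clash report — every inter-chain residue pair with
minimum heavy-atom distance under 2.5 A — as the hook point where an
external refiner would start.

## Evaluation

All distances are heavy-atom minima over residue pairs, with strict `<`
at the cutoff (the convention is stated because printed cutoffs admit
both readings).  Contacts use 8 A; the motif interface is the peptide
plus receptor residues within 4.5 A of it, defined on the reference.
fNC is |native AND model| / |native|, an error (not NaN) when the
reference has no contacts.  iRMSD fits the model's interface CA set onto
the reference's by least squares and reports the minimized RMSD; the
fitting set is the interface CAs themselves, not the whole receptor
(the alternative is available via the same superposition primitives).
Residue correspondence is chain id + author number + insertion code;
there is no sequence-alignment fallback.

## Synthetic structures

The fixtures module builds everything the tests need.  The grooved
receptor is a three-strand fold: two rim strands 9.9 A apart joined by a
three-residue semicircular turn, and — after a one-residue connector — a
floor strand running beneath the groove's centre line.  The floor breaks
the mirror symmetry of a plain two-strand groove, which otherwise offers
an equally good binding site reflected through the strand plane; the
early two-strand design failed its own funnel test exactly that way.
All consecutive CA-CA distances are exactly 3.8 A (turn and connector
residues sit on circular arcs with 3.8 A chords).  Rim side chains tilt
up into the groove, all others point away.  Side chains are reduced to
CB plus one dummy CG heavy atom — enough to exercise every heavy-atom
rule without a rotamer library.

The designed peptide pose is a zig-zag CA trace along the groove axis at
the deepest essentially penalty-free height above the strand plane
(2.5 A; chosen by scanning the straight pose's energy against depth so
the designed pose sits at the potential's optimum rather than above it).
Groove-lining receptor residues are typed with the peptide's own letters
by x-position, so a contact table rewarding exactly the planted
residue-type pairs (-2 each) makes the designed registration the global
minimum: with all-distinct peptide letters, a reversed or shifted
placement loses almost all rewards.  Because contact energies are
type-level, a serine (untyped) residue participating in a planted
contact would reward serines everywhere; such fixtures are refused with
instructions to enlarge the receptor.  Every emitted complex is
self-verified before use: planted contacts are recomputed through the
metrics module, and any inter-chain residue pair under 2.5 A voids the
fixture.

What the toys do not emulate: rotamer statistics, realistic secondary
structure and packing, sequence-composition statistics, solvation.
Passing tests therefore demonstrate that the protocol's machinery —
sampling, bookkeeping, clustering, assembly, metrics — behaves as
specified, not that the surrogate force field predicts real complexes.
For real input the contact table should be replaced with a proper
statistical potential.

## Problem sizes and determinism

The test suite and the acceptance script use a 52-residue receptor with
a 13-mer motif for the full default-protocol run (10 x 1000 snapshots),
and a 37-residue receptor with an 8-mer motif, 1500 sweeps per replica
and exchange every 2 sweeps for the ten-seed funnel-recovery
experiment; both finish in minutes on one core.  Shorter motifs were
rejected for that experiment because a 6-mer's reward pattern is too
close to shift-degenerate: the bound basin is then wide enough that
cluster medoids can sit just outside a 5 A L-RMSD ball around the
designed pose even when the site is found.  Every
stochastic component takes a seed, and all derived streams come from
`numpy.random.SeedSequence` spawning, so reruns are bit-identical.

## Known limitations

- The surrogate contact table is a hydropathy heuristic; it orders
  hydrophobic burial sensibly but carries no pair-specific statistics.
- Receptor flexibility is local jitter under restraints; hinge or
  domain motion is out of scope, as is all-atom reconstruction and
  refinement of the models.
- k-medoids uses the alternating (Voronoi) iteration, a local optimiser;
  with k seeded medoids it can in principle miss the global partition on
  adversarial inputs (the suite checks exact recovery only on separated
  basins, and brute-force optimality on small instances).
- mmCIF, assemblies, insertion-code ranges spanning icode variants, and
  nucleic-acid chains are unsupported.
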