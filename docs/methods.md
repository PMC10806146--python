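# Methods

This note documents the models, numerical choices and limitations of
`ddhelix`.  Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model and PDB handling

Structures are chain → residue → atom hierarchies with Cartesian
coordinates in Å.  Author chain ids and author residue numbers are
authoritative throughout; residue identity is `(seq_id, insertion_code)`.
Reading goes through gemmi (first model only); waters are dropped by
default, and for altloc groups the highest-occupancy conformer is kept
(ties: first in file).  Writing emits fixed-column ATOM records to three
decimals with TER after every chain; structures beyond the 99,999-serial
limit of the format are refused.  mmCIF, NMR multi-model records and
BIOMT expansion are out of scope.

## Superposition

Rigid placement of one DD on another uses the closed-form Kabsch solution
on CA atoms: SVD of the cross-covariance of the centred point sets with
the determinant correction, so a reflection is never returned (for
near-collinear sets a warning is emitted and the best proper rotation
used).  Correspondence between homologous chains of different sequence
comes from a global Needleman–Wunsch alignment of the one-letter
sequences (Biopython `PairwiseAligner`, BLOSUM62, gap open −10 /
extend −1, defaults exposed in `ddhelix.superpose`); only aligned non-gap
columns become CA pairs, and superposition refuses to run on fewer than
20 pairs.  CA-only fitting is the standard fold-level choice for death
domains: it is insensitive to side-chain differences between homologues.
No outlier rejection or iterative trimming is applied, keeping placements
deterministic.

## Screw-axis analysis of the helical lattice

A single-start helical lattice is generated by one screw transform.  The
decomposition of a rigid motion takes the rotation axis and angle from
the rotation matrix (via rotation vectors), the rise as the translation
component along the axis, and the axis point as the minimum-norm solution
of `(I − R) c = t_perp` by pseudoinverse.  Sign convention, stated once
and tested: **the axis is oriented so the rise is nonnegative, and the
twist is the right-handed rotation angle about that direction** — a
left-handed helix therefore has negative twist with positive rise.  Pure
translations report zero twist with the axis along the translation; the
identity is flagged.  Placement at helix index `n` applies the
analytically scaled screw (n·twist, n·rise about the same axis), which
equals n-fold composition exactly.

The lattice generator of a template is estimated from every consecutive
subunit pair along an ordered chain path — Kabsch transforms averaged
with quaternion rotation means and arithmetic translation means — rather
than from a single pair, for robustness to local deviations.  On the
noise-free fixture this recovers the generating twist/rise to 1e-6; with
0.2 Å Gaussian coordinate noise, to 0.5° / 0.1 Å (seeded, asserted in
tests).

## Two-stage assembly construction

Stage 1 places one copy of the query DD on every subunit of the
template's two IRAK layers (8 targets in the standard 6:4:4 plan),
carrying the scaffold (MyD88-like) and adaptor (IRAK-4-like) layers into
the assembly unchanged.  Stage 2 computes a single joint CA-Kabsch
transform mapping the first four query copies (those riding the adaptor
layer) onto the template's bottom-layer chains, order-respecting, and
applies it to all eight copies: the octamer slides one layer down, the
template's own bottom layer is dropped, and the final model is 6 + 4
template subunits plus 8 query copies at helix indices 11–18 (query-local
1–8).  Helix indices increase down-helix, from the scaffold layer toward
the query layers.  Construction is deterministic; every placement records
its rmsd and pair count in the subunit provenance.

Which four chains anchor the re-positioning is a genuinely open choice;
the copies placed on the adaptor-layer targets (the tetramer directly
under that layer) are used.

### Threading stand-in

The original query homology model is not distributable, so the package
builds a documented stand-in: backbone (N, CA, C, O) and CB are copied
from a homologous template chain at sequence-aligned positions and side
chains are regrown with ideal internal coordinates (generic bond lengths
to ~0.01 Å, angles to ~1°, L-chirality fixed by the CB improper torsion
dihedral(C, N, CA, CB) = −122.7°) in the extended chi = 180° rotamer.
Where the query and template residue types match, the full template side
chain is copied instead, so identity threading reproduces the template
exactly.  Alignment must cover at least 80 % of the query sequence;
unaligned query positions are omitted and listed in the structure's
provenance.  The stand-in's title says what it is — it is not a homology
model: no loop building, no rotamer library, no energetic refinement.

## Clash detection and relief ("debumping")

A clash is a heavy-atom pair whose distance is below the sum of Bondi-type
van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å) minus a tolerance,
default 0.4 Å.  Neighbour search uses a k-d tree (never all-pairs).
Pairs within three covalent bonds (1-2, 1-3 and 1-4, including the
peptide link) are excluded: ideal covalent geometry places several 1-4
pairs (carbonyl O to the next CA; O to CB through the carbonyl) near
2.7–2.8 Å, inside the C/O radius sum minus tolerance, so counting 1-4
pairs would flag every residue of a perfect backbone — the same reason
bump checkers conventionally reduce or ignore 1-4 interactions.

Relief is a greedy, seeded, deterministic grid search: per iteration the
residue carrying the largest clash overlap (ties broken by seeded draw)
has its chi torsions scanned sequentially in 30° steps, and the move is
accepted only if the total overlap strictly decreases.  The backbone
never moves; proline rings are not rotated.  Termination: zero clashes,
the iteration cap, or no improving move (reported as non-convergence, not
an error — rigid-body lattices retain backbone–backbone contacts no side
chain can fix).  The per-iteration overlap sequence is strictly
decreasing by construction and asserted in tests.  No equivalence with
rotamer-library repacking is claimed.

## Interface analysis

Contacts are inter-subunit residue pairs whose minimum heavy-atom
distance is at or below 4.5 Å (stored canonically with the smaller helix
index first).  Offsets are `dn = n_partner − n_pivot`; classification:
|dn| = 1 → type I, |dn| ∈ {3, 4} → type II, anything else unclassified
(type III offsets are deliberately not guessed); the `a` face looks
up-helix (dn < 0), the `b` face down-helix.  Face-offset reports give,
per pivot residue and per query copy, the contact offsets plus —
separately — the nearest partner subunit by minimum heavy-atom distance
even when above the cutoff.

### Simplified energy model

The per-residue decomposition uses a single-conformation pairwise
potential over inter-subunit heavy-atom pairs within 10 Å:

* screened Coulomb `k·q_i·q_j / (ε(r)·r)` with `k = 332.0637`
  kcal·Å/(mol·e²) and the distance-dependent dielectric `ε(r) = 4r`;
  charges are a reduced model — one unit charge on the side-chain tip of
  the four ionizable residues (Lys NZ +1, Arg CZ +1, Asp CG −1, Glu CD
  −1), backbone and all else neutral;
* Lennard-Jones 12-6 with `r_min = r_i + r_j` from the vdW table and
  generic per-element well depths (C 0.11, N 0.17, O 0.21, S 0.25
  kcal/mol, geometric-mean combination).

Every pair energy is credited in full to both participating residues, so
over an assembly whose subunits are all query copies the residue terms
sum to exactly twice the total pair energy — an identity the tests
assert.  Per residue label, the eight copy energies are aggregated as the
**mean of the four lowest**; this package reads "four lowest" as spanning
the subunit copies (eight exist; four is half) rather than conformational
snapshots, of which there is only one.  With fewer than four copies all
are averaged and the record flagged.

This potential replaces ensemble-averaged MM/GBSA residue decomposition
over explicit-solvent MD, which is out of scope.  It has no solvation or
entropy terms and no kcal/mol accuracy claim: outputs are meaningful as
ranks and signs.  Whether the most favourable residues of a real
assembly would match an MM/GBSA ranking is therefore reported, not
asserted.

## Mutation scan

Mutations are applied homotypically (all eight query copies at once,
since the biological mutant oligomerizes with itself): the side chain is
regrown for the new residue type by the threading geometry rules,
backbone untouched, followed by clash relief restricted to the mutated
residues.  A self-mutation is an exact no-op.  Delta scores are
`E_mut − E_wt` over pairs involving the mutated position, reported per
partner offset and per interface class.  The sign property that anchors
the scan: with an acidic partner as nearest charged neighbour across the
type Ia interface, the lysine→glutamate flip strictly worsens
(raises) the Ia term.  No ΔΔG calibration is attempted.

## Synthetic fixture

The generator emulates the myddosome template architecture so the whole
pipeline is testable without any external structure: a left-handed
single-start lattice, default twist −98° (≈ 3.67 subunits/turn), rise
4.5 Å, centroid radius 18 Å, with 6 + 4 + 4 subunits in three layers and
optional seeded Gaussian coordinate noise.  The subunit is a compact
42-residue poly-alanine three-helix bundle (12-residue helices, two
frozen 3-residue turns).  Forty-two residues rather than a
death-domain-like ~90 is a deliberate choice: at these screw parameters a
larger three-helix bundle becomes elongated enough to touch the `n±2`
neighbour, destroying the {±1, ±3, ±4}-only contact-offset regime the
fixture exists to exhibit.

Marker residues sit at the positions that face each interface: Lys at
residue 2 (faces `n−1`; the type Ia pivot), Asp at 12 (faces `n+1`; the
Ia partner), Arg at 16 (faces `n+4`; the IIb pivot), Asp at 35 (faces
`n−4`; the IIb partner on the lower subunit, on the IIa side), Trp at 42
(faces `n−3`/`n−4`; the IIa pivot).  The fold's turn dihedrals, its
orientation in the lattice and the Lys/Arg marker rotamers (which form
~3 Å salt bridges with their designed partners without self-clashes) are
frozen constants of the packaged fixture, chosen once so that the σ = 0
lattice realizes the target geometry; tests treat them as ground truth.
The fixture has no sequence realism and no rotamer diversity — passing
tests demonstrate the correctness of the pipeline's geometry and
bookkeeping, not predictions about any real protein.

## Problem sizes and determinism

Default analyses run the 18-subunit assembly (~4,200 heavy atoms): build
≈ 1 s, full debump ≈ a few seconds, contact map and energy decomposition
well under a second on one core.  Every stochastic element (tie-breaks in
relief, fixture noise) is driven by an explicit seed; identical
configurations produce byte-identical output bundles, which the pipeline
manifest verifies by content hash.

## Known limitations

* The threading stand-in and ideal side-chain geometry make no claim of
  structural accuracy beyond rigid-body placement.
* The energy model is rank/sign-level; absolute values are not
  comparable across systems.
* Clash relief cannot resolve backbone–backbone overlaps inherent to
  rigid lattice placement and reports non-convergence honestly.
* Type III interfaces are never assigned; offsets outside {1, 3, 4} are
  labelled unclassified.
* The superposition correspondence is sequence-guided only; no
  structure-based alignment is attempted.
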