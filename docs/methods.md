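# Methods

This note records the models, conventions and numerical choices behind
`chewspace`, and what the synthetic test battery does and does not
demonstrate about real data.

## Data model and PDB conventions

A `Structure` is one conformation (column-oriented arrays of residue
number, residue name, atom name, element, chain, coordinates in Å); an
`Ensemble` is an ordered list of structures sharing one topology, validated
on construction (the error names the first mismatching atom).  Residue
numbers are taken verbatim from the PDB fields and never renumbered: every
published CheW residue selection assumes deposited numbering.

Reading multi-model PDB files is delegated to biotite; one `Structure` per
MODEL block, order preserved.  Heteroatoms and waters are dropped
(ligands/multi-chain assemblies are out of scope; the entries analysed here
are monomeric), hydrogens are kept but excluded by the `all_heavy` and
`backbone` atom classes, and alternate locations resolve to the
highest-occupancy conformer (first listed on a tie — NMR entries essentially
never carry altlocs, so this policy is a formality).  Multi-chain files are
an error unless a chain is selected explicitly.  Writing produces standard
fixed-width records at the format's 3-decimal precision, always with
MODEL/ENDMDL pairs (even for a single member), and can place one value per
residue in the B-factor column — the standard vehicle for colouring a
structure by a per-residue score in molecular viewers.  Round-trips preserve
coordinates to 1e-3 Å and identities exactly.

## Residue subsets

A subset is a named union of inclusive residue ranges plus an atom class.
Ranges are normalised (sorted, overlaps merged) so each residue counts once;
percentages are reported to one decimal.  `backbone` means {N, CA, C, O}:
the carbonyl oxygen is included because that is the standard four-atom
protein backbone; the choice is localised in `chewspace.subsets.BACKBONE_ATOMS`
for anyone preferring {N, CA, C}.

The CheW constants use the deposited chain lengths: 167 residues for the
*E. coli* protein and 151 for the *T. maritima* protein.  The α/β-consensus
percentages follow from those lengths (57/167 = 34.1 %, 61/151 = 40.4 %).

## Sequence statistics and alignment

Pairwise identity is defined over mutually non-gap columns; columns gapped
in either sequence count toward neither numerator nor denominator.  This is
the most common of several conventions and the one under which the
case-study sequence pair reproduces its published ~25.8 % identity; a pair
with no shared non-gap columns is an error, not 0 %.  Redundancy pruning is
a greedy single pass in input order (keep a sequence iff its identity to
every kept sequence is strictly below the threshold, default 98 %); the
output provably contains no kept pair at or above the threshold, which the
tests re-verify by re-scanning.

The pairwise aligner is Biopython's global Needleman–Wunsch with affine
gaps: a gap of length L costs `open + (L−1)·extend` (defaults 7 and 1 in
BLOSUM62 units) and terminal gaps are free, since homologous termini of
different length should not distort the alignment.  `X` is neutralised to
score 0 against everything; other unknown letters are errors.  Where
several optimal tracebacks exist the aligner's first path is taken — the
choice is deterministic, and scores (the tested quantity) are unaffected.
BLOSUM62 is the default scoring matrix; the per-residue similarity map
historically used a BLOSUM60-style matrix, which is not in common
distribution, so any matrix in NCBI format can be plugged in by path.
Per-residue similarity reports raw substitution scores (no normalisation);
residues aligned to a gap receive the matrix minimum by default.

## Superposition and RMSD

Superposition is the Kabsch algorithm via SVD of the covariance of
centroid-shifted point sets.  Reflections are excluded unconditionally by
correcting the sign of the smallest singular value: an improper rotation
can lower the RMSD of near-planar point sets but superposes a mirror image,
which is meaningless for chiral molecules.  At least 3 fit atoms are
required.  Atom correspondence across structures is by (residue number,
atom name) within the resolved subset; any unmatched atom is an error
rather than a silent drop.

`rmsd(a, b, spec, superpose=...)` optionally fits on a separate fit subset
then measures on the given subset.  The per-residue RMSD map performs ONE
global superposition (by default on a core/backbone subset) and then
measures each residue over its heavy atoms without refitting — refitting per
residue would erase exactly the signal the map exists to show (rigid cores
near zero, displaced segments inflated).  The per-residue values aggregate
exactly: the atom-weighted root-mean-square over residues equals the
whole-selection RMSD in the same frame, which is a test invariant.

## Ensemble and trajectory comparison

Cross matrices superpose every frame pair on the fit subset and measure on
the measure subset; "starting" is entry (0,0) — the two structures the
simulations started from, i.e. the static model-vs-experiment comparison —
and ties for the minimum resolve row-major.  Because the starting pair is
itself a matrix entry, `lowest ≤ starting` holds by construction; that
inequality is the formal core of the claim that sampling can only shrink
the apparent model–experiment gap, and the pipeline asserts it on every
run.  Frame striding is available for long trajectories (retained entries
are exact; the minimum over a strided grid is an upper bound on the full
minimum).  For comparisons too large to hold as m × n, a streaming variant
keeps running min/max/mean and histogram counts row by row and returns
bit-identical statistics, as verified against the dense path.

Histogram bin width defaults to 0.1 Å for RMSD distributions (0.25 Å in the
synthetic pipeline, whose spreads are small); both are configurable, and
within-ensemble distributions use unordered pairs (i < j) while cross
distributions use the full matrix.

## The Gō sampler

The sampler is a deliberately simple Cα-level structure-based model, used
as the ensemble-generation stage of the pipeline.  The analyses downstream
consume ensembles and are agnostic to how they were produced; an all-atom
MD or library-based MC engine could be substituted wherever an `Ensemble`
is accepted.

Potential: native contacts are bead pairs with |i−j| ≥ 3 whose reference
Cα distance is ≤ 8 Å (standard Gō conventions); a contact is formed while
its distance is within 1.2× its reference value and contributes −ε.
Non-bonded pairs (|i−j| ≥ 2) closer than 4.0 Å make the energy +∞ (hard
excluded volume; 4 Å is a conventional Cα hard-sphere diameter — note
consecutive Cα sit at ~3.8 Å, which is why bonded pairs are exempt).  A
stiff harmonic term (100 ε/Å²) on virtual bonds guards against corrupted
input; the move set preserves bond lengths exactly, so it contributes
nothing during sampling.  Energies are in units of ε and temperatures as
kT/ε throughout.

Moves: Ψ-torsion (rotate everything downstream of a virtual bond about that
bond — the Cα-trace analogue of a Ψ-dihedral change), crankshaft (rotate a
3-bead window about the axis of its flanking beads — a localised
rearrangement standing in for multi-peptide-plane swaps), and general pivot
(rotate downstream about a random axis through a bead, which also bends the
local virtual angle).  Per step the move type is drawn from configured
fractions (defaults: 10 % crankshaft, 30 % Ψ-only, remainder pivot) and the
rotation angle uniformly from ±max_angle.  Acceptance is Metropolis; the
proposal density is symmetric in each move class, so detailed balance holds,
which the tests verify empirically on an enumerable discrete-angle toy
(chi-square against Boltzmann weights) and on a two-state system against
the closed form exp(ΔE/kT).

Step-size tuning bisects max_angle in log space over short pilot runs until
the measured acceptance falls in the 20–25 % band (acceptance decreases
monotonically with angle in expectation; the iteration cap returns the best
angle found, with a warning).  The temperature scan runs short simulations
over a kT ladder and estimates the unfolding temperature as the lowest kT
whose mean Cα RMSD from native exceeds a threshold (default 5 Å on the toy
scale); production sampling is then placed slightly below it — kT/ε = 0.7
for the bundled fold, matching the case study's convention.  Runs are
bitwise reproducible under a fixed seed, saved-frame energies equal
from-scratch recomputation, and no saved frame ever violates excluded
volume.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical *shapes* the analysis depends on:

- an NMR-like ensemble — Gaussian jitter with a rigid core and floppy
  terminal tails (tail noise plus a rigid random swing of each tail);
- a homology-model-like ensemble — the same fold deformed coherently (a
  handful of random bond-axis pivots scaled by secant iteration to a target
  Cα RMSD, clash-checked) with a *tighter* spread than the NMR ensemble,
  mirroring the observation that model ensembles cluster more tightly than
  experimental ones;
- a two-class protein family whose identity histogram is bimodal, and a
  homolog pair at a requested identity (default setting 25.8 %, the
  case-study value);
- ideal-geometry folds: helix, extended chain, and a two-helix hairpin.
  The hairpin is the default pipeline fold because it has genuine tertiary
  (inter-helix) contacts and is thermally stable at kT/ε = 0.7, whereas a
  single helix has only local contacts and behaves as a floppy rod.

Defaults encode the case-study conditions: 20 models per ensemble, a static
model–experiment difference of ~3 Å Cα, kT/ε = 0.7, frames saved on a fixed
interval, 10 %/30 % move fractions, and a 20–25 % acceptance target.

Ensemble noise is Cartesian, not dihedral: adequate for exercising
selection, superposition and RMSD machinery, but it does not produce
physically valid backbones (bond geometry is mildly violated in jittered
copies).  Physically plausible ensembles come from the Gō sampler.  Passing
the synthetic battery therefore shows the *machinery* is correct and the
pipeline's orderings hold under the generated conditions; it does not by
itself validate claims about any particular experimental system — for that
the reference entries must be supplied (see `chewspace.refdata`), since
they are not redistributed with the package.

## Problem sizes

The bundled test battery and the acceptance script run on reduced problem
sizes chosen to keep a full run in minutes on one CPU while leaving every
statistical conclusion stable across seeds: 30–40-residue folds, ensembles
of 5–20 members, MC runs of 2,500–4,000 steps (plus a 10⁵-step two-state
chain, where the closed form makes the expected error explicit), 600-step
scan legs and 1,200-step tuning pilots.  All sizes are parameters; nothing
in the implementation assumes them.

## Known limitations

- Cross-organism per-residue maps require an externally supplied residue
  correspondence; sequence-based structure alignment of non-identical
  topologies is out of scope.
- The Gō sampler is a surrogate for all-atom dynamics: no side chains, no
  solvent, no force-field energetics; its crankshaft move is a declared
  stand-in for peptide-plane swap moves of library-based MC, not a claim of
  geometric equivalence.
- mmCIF, heteroatoms and multi-chain assemblies are unsupported.
- The unfolding-temperature estimate depends on the scan's RMSD threshold
  and run length; it is a placement heuristic for the sampling temperature,
  not a thermodynamic melting point.
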