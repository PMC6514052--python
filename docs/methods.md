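# Methods

This note documents the models and procedures implemented in lbdkit, the
parameters that matter, the design choices made where conventions genuinely
diverge, and what the synthetic-data validation does and does not show.

## Conventions

All internal lengths are nanometres and times picoseconds; PDB I/O converts
Å↔nm strictly at the file boundary, where coordinates are written with three
decimals in Å (Python's round-half-even float formatting). Author residue
numbering from input files is preserved verbatim — the nuclear-receptor
literature names residues (W755, E723, M909, …) by deposited-structure
numbers, so renumbering would silently break every selection. Everywhere a
distance is compared with a cutoff, the boundary is inclusive (≤).

## Two-reference ΔRMSD and state labels

A frame's conformational state is scored as
`ΔRMSD = RMSD(frame, closed reference) − RMSD(frame, open reference)`,
each RMSD Kabsch-optimal over a shared Cα correspondence. The operand order
is fixed closed-minus-open so that closed-like frames score negative and the
published closed criterion keeps its sign: a frame is **closed** when
ΔRMSD ≤ −0.1 nm. The **open** bound (+0.1 nm) is a symmetric choice of this
package — only the closed bound is quantified in the source literature — and
the band between the two is reported as **semi-open**, explicitly an
operational definition. Boundary inclusivity (≤ / ≥) is immaterial at float
resolution but documented and tested.

Kabsch superposition uses the SVD of the weighted cross-covariance with the
determinant correction that enforces a proper rotation; degenerate inputs
(fewer than 3 points, collinear or coincident point sets) are rejected
rather than silently fitted. The independent check in the test suite is a
quaternion (Horn) implementation, which agrees to 1e-8 nm on random point
sets.

Regional RMSDs follow the global-fit/regional-measure convention: frames are
superposed on the full Cα set and the deviation is measured over the region
mask without refitting. Both masks are configurable separately because the
per-region-refit convention also exists in the wild.

RMSF is measured about the iteratively converged mean structure (superpose →
re-average until the mean moves < 1e-6 nm RMS), not about frame 1; the
per-residue table uses each residue's Cα.

## PCA

Distance-matrix PCA uses the upper-triangle Cα–Cα distances (i < j,
row-major) as features, strided to the analysis cadence; because interatomic
distances are rigid-transform invariant, no superposition enters this route,
and projections of a rigidly transformed trajectory are identical to
1e-10. Cartesian PCA first superposes frames on their converged mean and
diagonalises the 3m-coordinate covariance; each eigenvector reshapes to
per-atom 3-vectors whose norms are the per-atom mode amplitudes used for
essential-dynamics visualisation. Both routes are plain covariance
eigendecompositions (thin SVD of the centred data, eigenvalues with the
1/(n−1) convention); eigenvector sign is fixed by making the
largest-magnitude loading positive so plots are reproducible. Note that
superposition removes net translation/rotation, so a mode driven by one atom
still carries counter-motion on the others (amplitude ratio (m−1):1 in the
single-driven-atom limit) — localisation claims should be read accordingly.

## Quasi-harmonic configurational entropy

The estimator builds the mass-weighted covariance σ of the Cartesian
coordinates of the selected atoms (units nm²·amu), diagonalises it, and
treats each eigenvalue λᵢ as a harmonic mode of frequency ωᵢ = √(k_B T/λᵢ).
The quasi-harmonic entropy is the quantum-oscillator sum

    S = R Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ],   xᵢ = ħωᵢ/k_B T,

and the Schlitter variant S = (R/2) Σᵢ ln(1 + k_B T e² λᵢ/ħ²) is computed
from the same spectrum; it is an upper bound and is asserted as such.
Quasi-harmonic is the default method. Modes with λᵢ < 1e-8 nm²·amu
(configurable) are discarded as rigid-body remnants or numerical nulls;
the discard rule is purely threshold-based so the reported
`n_modes_discarded` is exactly the count below tolerance.

Superposition: for real trajectories the frames are first aligned on their
converged mean (default `superpose=True`) to remove diffusive rigid-body
motion, which would otherwise dominate the spectrum. For ensembles generated
without rigid-body motion — the Gaussian validation ensembles — alignment
itself would perturb the spectrum, so the validation path uses
`superpose=False`. Fewer than 3m+1 frames leaves the covariance
rank-deficient; this warns rather than errors because rank-deficient spectra
are still well-defined (null modes fall below the discard tolerance).

Validation: the generator samples mean-zero Gaussians whose mass-weighted
covariance has a prescribed spectrum and returns the closed-form mode sum of
that spectrum. At 20,000 frames and 30 modes the estimate lands within 2% of
the closed form (typically within 0.1%), and inflating every mode variance
4× (an "apo-like" vs "bound-like" contrast) raises the estimate in 20 of 20
replicates. The published absolute entropies of the real receptor
(1529.86 vs 1230.43 J mol⁻¹ K⁻¹ for apo vs hormone-bound) come from μs-scale
all-atom ensembles and are not reproducible at toy scale; what the synthetic
validation establishes is the estimator's correctness and the robustness of
the apo > bound *ordering* under covariance inflation.

## gromos clustering

Pairwise Kabsch RMSDs over the analysis mask feed the greedy medoid scheme:
the frame with the most neighbours within the cutoff (inclusive) seeds a
cluster, it and its neighbours are removed, and the count-and-pick repeats
until no frames remain. Tie-break: among equal neighbour counts the lowest
frame index wins — the original algorithm description leaves this open, and
fixing it makes the assignment deterministic. Because removals can only
shrink neighbour counts, cluster sizes are non-increasing in formation
order. The default cutoff is 0.2 nm. An independent list-based
re-implementation (with quaternion RMSDs) reproduces assignments, medoids
and sizes exactly on 200-frame trajectories at 0.1/0.2/0.3 nm, including
engineered exact-tie cases.

## Solvation

The first hydration shell counts water *oxygens* within 0.5 nm (5 Å) of any
solute atom. The neighbour search is a cell list (cells no smaller than the
cutoff, 27-cell stencil, periodic wrapping for orthorhombic boxes) with a
brute-force all-pairs fallback; the two are asserted equal on every tested
configuration, including 1,000 waters × 100 frames. Whether "solute atoms"
means heavy atoms only is a mask-level decision left to the caller (the
default selections are heavy-atom because the toy systems carry no
hydrogens).

A bridging water is within 0.35 nm of both of two named protein atoms
simultaneously; for the progesterone-receptor case these are the Trp755
side-chain nitrogen NE1 and the Val912 backbone nitrogen N (standard PDB
nomenclature; the source text names only the elements). Residence intervals
are maximal runs of consecutive occupied frames; `gap_tolerance` (default 0,
the strict "continuous time" reading) can merge runs separated by short
absences, because frame striding fragments genuine residences. An interval's
duration is end − start plus one frame spacing, so a single-frame visit in a
2 ps-spaced trajectory lasts 2 ps.

Block averages emit one (mean time, mean value) point per non-overlapping
block; a trailing partial block is emitted and flagged in the series
metadata rather than dropped.

## Interactions and electrostatics

Hydrogen bonds use donor–acceptor distance ≤ 0.35 nm and, when an explicit
hydrogen is given, donor–H–acceptor angle ≥ 120°; these are
standard-practice geometric defaults (the source literature states none).
Occupancy is the fraction of frames satisfying the criterion and is exact on
planted schedules (50 of 100 frames → 0.500000).

Salt bridges report the per-frame minimum nitrogen–oxygen distance between
the basic side-chain nitrogens (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) and the
acidic carboxylate oxygens (Glu OE1/OE2; Asp OD1/OD2), with a 0.4 nm contact
flag.

Charge centers reduce each member residue to one representative side-chain
point — Lys NZ, Arg CZ, Glu/Asp carboxylate-oxygen midpoint — and take the
unweighted centroid. Two presets for the receptor's surface patches ship:
the helix-12 N-terminal acidic patch (E904/E907/E911, net −3) and the
helix-3 C-terminal basic patch (K733/R740, net +2); an alternative basic
preset (K731/K734/K740) from a methods-level residue list also exists
because the two published lists conflict — the Discussion-level pair is the
default. Which atoms "H12NT"/"H3CT" denote precisely (backbone vs side
chain) is unstated in the source; the side-chain charged-atom centroid is
this package's choice and is labelled as such.

Screened Coulomb energies default to the physical potential
E = k_C q₁ q₂ / (ε d), with k_C = e²N_A/(4πε₀) ≈ 138.935458 kJ mol⁻¹ nm e⁻²
derived from CODATA constants and ε = 80 for fully solvent-exposed charges.
A printed variant of this formula divides by d² — dimensionally a force law —
and is retained as an `as_printed_1_over_d2` mode for fidelity, flagged
non-standard in output metadata. The published "~2.5 kJ/mol" energy changes
are not used as validation values: the same number is quoted for two
different distance changes (1.5→0.3 nm and 3.6→2.0 nm), which no single
formula reproduces simultaneously; validation instead checks the
constant-based oracle value at 0.3 nm and the 1/d scaling law.

## Synthetic data

The generator emulates the *structure* of the real study at toy scale, with
exact ground truth, and deliberately not its physics (no force field, no
rotamers, no explicit hydrogens beyond the planted hydrogen-bond probe).

* **References**: a 60-residue, four-pseudo-helix Cα bundle (ideal helix:
  0.23 nm radius, 0.15 nm rise, 100°/residue; 1 nm inter-helix spacing).
  Residues number 711–770 so the two bridge pseudo-atoms land on Trp755
  (NE1) and Val756 (backbone N), echoing the receptor's W755/V912 pair; the
  pseudo-atoms sit on the midline between their Cαs, 0.3 nm apart, so a
  midpoint water bridges them in every state. The closed reference rotates
  the terminal helix ("helix 12") about a hinge through its first Cα,
  Kabsch-aligns it back onto the open structure, and scales the displacement
  field so the Cα RMSD equals the requested separation (default 0.6 nm)
  exactly. Because the closed structure is optimally aligned, the cross-
  covariance with the open structure is symmetric positive-definite, which
  makes linear interpolations have *exactly* linear RMSDs to both endpoints
  — ΔRMSD crosses zero exactly at the geometric midpoint, the property the
  contract tests exploit.
* **Transitions**: frames interpolate open→closed along a stage schedule
  with i.i.d. Gaussian positional noise (default σ = 0.02 nm). The default
  schedule mirrors the fast/fast/slow three-stage pattern of the real
  transition (3%, 5%, then the rest of the run). For acceptance scenarios a
  `crossing_frame` option replaces the schedule with a linear ramp whose
  noise-free ΔRMSD crosses the −0.1 nm threshold at the requested frame (the
  continuous crossing is placed half a frame early so float rounding cannot
  shift the first sub-threshold frame). Ground truth records the per-frame
  state fraction, the noise-free ΔRMSD and the crossing frame.
* **Solvent**: waters are single oxygens scripted per frame — at the bridge
  midpoint, 0.3 nm outside a surface Cα ("shell"), exactly at the shell
  cutoff biased inward by one part in 10¹² ("shell_boundary", so the
  inclusive rule holds under floating point), or far from the solute. The
  generator refuses schedules whose shell placements would accidentally
  satisfy the bridge criterion.
* **Gaussian ensembles**: per-coordinate variances λⱼ/mₐ give a mass-
  weighted covariance with exactly the prescribed spectrum; the closed-form
  entropies of that spectrum are returned for validation.

All generators are pure functions of spec + seed (bit-reproducible, asserted).

## Pipeline

`run_pipeline` validates the config before any computation, resolves the
input (synthetic bundle or PDB files matched by (chain, resid) Cα
correspondence), runs the configured stages in a fixed order, and emits a
JSON-serialisable report with provenance (config hash, seed, package and
numpy versions — no timestamps, so identical config + seed gives
byte-identical reports). Stages are independent: disabling one never changes
another's numbers (asserted). A failing stage raises an error naming the
stage; completed sections are still written when an output directory is
given.

## Problem sizes and limitations

The validation suite runs the full battery on 60-residue bundles with up to
1,000 frames and 1,000 scripted waters, and entropy recovery on 20,000-frame
ensembles of 10 atoms — sizes chosen so the complete pipeline and its
validation finish in seconds while exercising every code path at full
analysis cadence. Real μs-scale data is a streaming concern of the I/O layer
(use the MDAnalysis-backed reader), not of the analyses.

What passing tests do **not** show: agreement with the published absolute
entropies, occupancies or free-energy gaps of the real receptor (those
require μs atomistic sampling); correctness of the d² "as-printed" energy
form (retained for fidelity only); solvation behaviour with triclinic boxes
(minimum image is orthorhombic-only); or any force-field-level realism of
the synthetic trajectories, which are interpolations with noise, not
dynamics.
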