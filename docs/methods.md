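# Methods

This note documents the models, conventions and numerical choices behind
mdtrend, and what the synthetic-data validation does and does not show.

## Units and conventions

Internal units are nm, ps, kJ/mol and elementary charges (GROMACS
conventions); PDB files are read and written in Å, and contact-geometry
reports quote Å because that is how such distances are conventionally
published.  Atom indices are 0-based internally and 1-based in
human-facing reports.  Author residue numbering from the PDB is kept
verbatim and used in all selections and reports.  Alternate locations:
'A'/blank kept, others dropped with a logged warning.  When a topology
table omits the radius column, per-element intrinsic radii are applied
(H 0.12, C 0.17, N 0.155, O 0.15, S 0.18 nm).

## Superposition, RMSD, RMSF

Rigid-body fits use the Kabsch SVD solution on the weighted covariance,
with the reflection corrected by flipping the smallest singular
direction, so the rotation is always proper.  Weights are uniform by
default (mass weighting is a flag); the compared complexes share an atom
set, so uniform weights change nothing qualitative.

RMSD series fit each frame to the reference (first frame unless a
structure is supplied) over a fit selection and measure over a possibly
different calc selection; ligand RMSD defaults to protein-backbone fit,
which reports ligand motion relative to the fitted pocket.  A ligand
self-fit mode exists because either convention is defensible for
published ligand-RMSD curves.

RMSF is measured about the mean structure with one fit–average
iteration: frames are fitted to the plain frame average, the average is
recomputed from the fitted frames, and frames are refitted before the
per-atom root-mean-square displacement is taken.  Per-residue values use
the Cα atom (falling back to the residue mean) so that one value per
residue matches residue-level profiles.  A caveat the tests make
explicit: with a uniform-weight fit, a fluctuating residue in an
otherwise static system leaks a fraction ~n_moving/n_total of its motion
into the fit, biasing its RMSF low; recovery tests therefore use systems
where the moving fraction is small.

## Energies

Electrostatics: E = f·q1·q2/(ε_r·r) with f = 138.935458 kJ·mol⁻¹·nm·e⁻².
Lennard-Jones: 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combining.
Interaction energies between groups are full double sums (no exclusions —
the groups are different molecules); there is no cutoff by default
because the systems analysed here are desk-scale, and the optional cutoff
truncates hard, without switching.

The MM/GBSA composition is the single-trajectory end-point scheme: every
term is ΔX = X(complex) − X(receptor) − X(ligand) on the same frame,
averaged over the frame range.  ΔE_bonded is identically zero in this
scheme and the entropy term −TΔS is not estimated.  The identities
ΔG = ΔE_MM + ΔG_sol − TΔS, ΔE_MM = ΔE_vdw + ΔE_ele + ΔE_bonded and
ΔG_sol = ΔG_polar + ΔG_nonpolar are enforced at 1e-9 relative on every
EnergyBreakdown constructed.

Polar solvation is the Still-form generalized Born sum,
E = −½·f·(1/ε_in − 1/ε_out)·Σ_ij q_i q_j / f_GB,
f_GB = sqrt(r² + R_iR_j·exp(−r²/(4R_iR_j))), self terms included so a
single ion reproduces the Born formula exactly.  Defaults ε_in = 1,
ε_out = 78.4, no salt screening (ionic strength belongs to the MD force
field, not this post-hoc solvation model).  Effective radii follow the
Hawkins–Cramer–Truhlar pairwise-descreening integral with a dielectric
offset of 0.009 nm and per-element scale factors (H 0.85, C 0.72,
N 0.79, O 0.85, S 0.80) applied to the *reduced* neighbour radii, the
standard HCT convention; the analytic integral is validated in the tests
against direct spherical-shell quadrature of the descreened 1/r⁴ field.
Inverse radii are floored at a small positive value so pathological
overlaps stay finite; since descreening only increases radii, R ≥ ρ −
offset holds by construction.

The nonpolar term is γ·SASA + β with γ = 2.26778 kJ·mol⁻¹·nm⁻² and
β = 3.84928 kJ/mol (the common 0.00542 kcal·mol⁻¹·Å⁻² / 0.92 kcal/mol
parameterisation).  SASA is Shrake–Rupley with probe 0.14 nm and a
deterministic Fibonacci point set (default 960 points) rather than
random sampling, for bit-reproducibility; doubling the point count moves
totals by <0.5% on the fixtures, and an isolated sphere is within 1% of
its analytic area.  An independent Shrake–Rupley implementation
(biotite's) is used as a cross-check in the tests, never as the
implementation.

## Trend scoring

Window means are arithmetic means over frames with start ≤ t < end
(half-open, windows in ns, default 5–10/20–25/25–30).  For each residue
the between-complex difference c_w = mean_B[w] − mean_A[w] is reduced to
a sign; adjacent window pairs score +1 when the sign is conserved and
nonzero, −1 otherwise; the total for three windows is −2, 0 or +2, and
+2 flags a key residue.  Two deliberately resolved ambiguities:

- *Dead band.*  Only ±1 scores are defined by the statistic; numerically
  identical series would otherwise flip signs on rounding noise.  A
  delta with |c_w| < τ (default 1e-9, in series units) counts as sign 0
  and is never "consistent".  The dead band is far below any physical
  energy scale, so it only suppresses exact-tie artefacts.
- *Reading of "change".*  The default scores sign-consistency of the
  between-complex difference across window pairs, which is what makes
  "+2 = same trend throughout" well-defined; a within-complex reading
  (agreement of the two complexes' own window-to-window slopes) is
  available behind `mode="within"`.

Fold changes are magnitude ratios |B|/|A| (reference complex A in the
denominator), computed per window and averaged for per-residue
summaries; the RMSF variant reports A/B, matching the convention of
quoting how much more the reference complex fluctuates.  Scoring is
invariant under a common positive affine rescaling of both series, and
under swapping the complexes.

## Contacts

Hydrogen bonds use a donor–acceptor heavy-atom criterion (N/O/S within
3.6 Å) because deposited structures and generated fixtures usually lack
hydrogens; when explicit hydrogens are present a D–H…A ≥ 120° test is
applied automatically.  Hydrophobic contacts are carbon–carbon interface
pairs within 3.9 Å, reported as a deduplicated residue list.  Distance
series report the minimum N/O–N/O distance between ligand and residue
per frame, with per-window means — distances in Å throughout (tables of
such distances are Å-scale even when mislabelled otherwise).

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances in
Å), bond at E < −0.5.  Amide hydrogens are reconstructed 1.0 Å from N
opposite the bisector of the C(prev)–N and CA–N directions when absent;
the first residue of a segment has no donor.  Chains split at C–N gaps
over 2.5 Å or at sequence-number jumps.  Assignment uses a five-state
alphabet: two consecutive i→i+4 turns make H, i→i+3 analogously G,
hydrogen-bonded bridges (parallel or antiparallel patterns) make E,
turn-covered residues T, else C, with priority H > E > G > T on overlap.
This deliberately collapses the 8-state DSSP alphabet: π-helices,
isolated bridges vs ladders and bends are not distinguished, which is
sufficient for helix/turn/coil conversion analyses but not for β-bulge
topology work.

## Synthetic data: what it shows and what it does not

`make_toy_complex` builds an ideal poly-alanine helix (NeRF construction
from standard internal coordinates) with a rigid pseudo-ligand docked at
the middle residue, one planted polar contact (2.9 Å) and one planted
carbon–carbon contact (3.5 Å).  Charges and LJ parameters come from a
small documented table with per-residue neutrality; ligand σ values are
slightly soft so planted contact distances sit near the LJ minimum
rather than inside the repulsive wall.

`simulate_trajectory` adds iid Gaussian displacements with per-residue,
per-coordinate σ = amplitude/√3, so the planted amplitude *is* the target
RMSF, plus an optional random rigid roto-translation per frame to
exercise the fitting step.  iid noise (rather than an Ornstein–Uhlenbeck
process) is the default because every analysis under test consumes time
means and mean squares, which at fixed marginal variance are insensitive
to autocorrelation; the trade-off is that frame-to-frame displacements
are unphysically rough, so near-contact Lennard-Jones energies spike on
individual frames when amplitudes are large — demonstrations that
average LJ energies use gentle amplitudes.

`plant_trend_series` emulates the statistical structure the trend
statistic assumes: complex B is a per-residue baseline plus iid noise;
complex A has independent noise and is shifted by −offset_w on the key
residues in every window, while **all** other residues receive
sign-alternating window offsets of the same magnitude.  Independent
noise on the two complexes is what makes the recovery question
non-trivial (shared noise would cancel exactly); the alternating decoys
are what makes "exact recovery" a strong claim — without them any
residue whose window-mean noise happened to keep one sign (probability
1/4) would be flagged.  The defaults are 30 ns of frames every 8 ps,
three windows, a 10 kJ/mol offset and 2 kJ/mol per-frame noise
(offset/noise = 5); recovery is exact across 100 seeds at this contrast
and degrades gracefully as the contrast shrinks (the suite checks both).

`make_hinge_site_model` is a **synthetic stand-in** for the crystal-
structure hinge sites: three hinge residues as backbone templates spaced
so that the only interface polar pairs within the cutoff are the planted
ones, plus a three-residue hydrophobic shelf.  The planted distances are
the published hinge H-bond distances (crizotinib 2.96/3.02 Å to
Glu1197/Met1199; lorlatinib 2.96/2.81/3.58 Å).  Passing contact tests on
these models validates the detection machinery — element filtering,
cutoffs, minimum-distance logic, residue attribution — not
crystallographic reproduction.

What passing the suite does **not** show: recovery of any real
trajectory's observables (the published multi-nanosecond trajectories
are not reproducible at desk scale), force-field realism of the toy
parameters, or the behaviour of the trend statistic under strongly
autocorrelated noise (an OU stress mode is the natural extension).

## Problem sizes

The test and acceptance workloads are sized for interactive runs: RMSF
recovery uses 20,000 frames of a 30-residue system; trend recovery 100
seeds of 50 residues × 3,750 frames; the Kabsch brute-force oracle 100
six-point instances against 40,000 quasi-uniform rotations (~4°
resolution); MM/GBSA demonstrations a 10-residue complex over 4 frames
at 480–960 SASA points.  The full pytest suite runs in well under a
minute on one core.

## Pipeline determinism

`run_pipeline` executes load → rmsd → rmsf (+trend) → decompose/trend →
mmgbsa → contacts → secondary structure, failing fast with the stage
name.  Reports carry a config digest (output location excluded) and
seed; identical config and inputs give byte-identical `report.json`.
MM/GBSA inside the pipeline subsamples to a configurable number of
frames (default 5) since the frame-averaged terms converge quickly on
the synthetic systems.
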