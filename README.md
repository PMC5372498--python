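# mdtrend

Analysis toolkit for molecular-dynamics studies of kinase–inhibitor
binding, built around the question of how a resistance mutation changes
what a drug sees in the ATP pocket.  It implements the full post-MD
analysis layer for comparing two protein–ligand complexes (for example a
kinase bound to a first-generation versus a third-generation inhibitor):

- **Superposition observables** — Kabsch least-squares fitting, RMSD time
  series (backbone or ligand after backbone fit) and per-residue RMSF
  about the iteratively fitted mean structure.
- **Energy decomposition** — per-residue Coulomb and Lennard-Jones
  interaction energies with the ligand, per frame.
- **MM/GBSA binding energies** — the end-point composition
  ΔG = ΔE_MM + ΔG_sol − TΔS with ΔE_MM = ΔE_vdw + ΔE_ele,
  ΔG_sol = ΔG_polar + ΔG_nonpolar; ΔG_polar from a generalized Born model
  with Hawkins–Cramer–Truhlar pairwise-descreening radii, ΔG_nonpolar as
  γ·SASA + β with Shrake–Rupley areas on a deterministic Fibonacci sphere.
- **Windowed trend scoring** — the statistic used to flag *key residues*:
  for each residue, the between-complex difference of window-mean energy
  (or RMSF), c_w = mean_B[w] − mean_A[w], is reduced to its sign over the
  analysis windows (default 5–10, 20–25 and 25–30 ns); each adjacent
  window pair scores +1 if the sign is conserved and −1 otherwise, so for
  three windows the total is in {−2, 0, +2} and residues scoring +2 — a
  between-complex difference that never changes direction — are flagged.
  Magnitudes are summarised as window-averaged fold changes |B|/|A|.
- **Contact geometry** — hinge hydrogen bonds (N/O/S donor–acceptor
  distance criterion, 3.6 Å), hydrophobic carbon–carbon contacts (3.9 Å)
  and minimum polar ligand–residue distance series with window means.
- **Secondary structure** — Kabsch–Sander backbone H-bond energies with
  geometric amide-H reconstruction, a five-state (H/G/E/T/C) assignment,
  and per-window state-fraction comparison between complexes.
- **Synthetic data with ground truth** — helical toy complexes,
  trajectories with planted per-residue fluctuation amplitudes, paired
  energy series with planted key-residue offsets, and hinge-site contact
  models, so every stage can be validated against known answers without
  running an MD engine.

Internally everything is in GROMACS-style units (nm, ps, kJ/mol,
elementary charge); PDB I/O converts Å ↔ nm, contact reports quote Å.
Author residue numbering is preserved verbatim, so kinase-domain residues
keep their familiar numbers (Glu1197, Met1199, His1124, …).

## Worked example

Identify key residues from paired per-residue electrostatic-energy series
(here generated with a planted 10 kJ/mol offset on residues 10 and 42,
per-frame noise 2 kJ/mol):

```python
import mdtrend as mt

spec = mt.SyntheticSpec(seed=4)
series_a, series_b, truth = mt.plant_trend_series(spec)
report = mt.identify_key_residues(series_a, series_b, spec.windows)
print(report.key_residues)           # [10, 42]
fold = mt.relative_fold(25.9, 123.7)
print(round(fold.value, 1))          # 4.8
```

The two flagged residues are exactly the planted ones: their
between-complex energy difference keeps one sign across all three
analysis windows (trend score +2), while every other residue alternates.
The second number is the fold change between two binding energies of
25.9 and 123.7 kJ/mol — a 4.8-fold difference in magnitude.

Contact geometry on the bundled synthetic hinge-site models:

```text
crizotinib hinge model
  H-bond  N23 ... MET1199 N: 2.96 Å
  H-bond  N22 ... GLU1197 O: 3.02 Å
  hydrophobic residues: [1122, 1148, 1256]
```

Each line is an interface donor–acceptor pair within the 3.6 Å cutoff;
the hydrophobic list contains residues with at least one carbon–carbon
interface contact within 3.9 Å.

The `examples/` directory has one short script per capability
(`01_rmsd_rmsf.py` … `05_secondary_structure.py`); each builds a small
input, runs the method and prints annotated numbers.  A thin CLI mirrors
the stages (`mdtrend simulate|rmsd|rmsf|decompose|trend|mmgbsa|contacts|
ss|run`); `mdtrend run --config run.cfg` executes the whole pipeline on a
pair of complexes and writes TSV tables plus a deterministic
`report.json`.

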