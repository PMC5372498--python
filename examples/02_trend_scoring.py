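"""Key-residue identification by windowed trend scoring.

Generates paired per-residue electrostatic-energy series for two
complexes in which two residues carry a consistent 10 kJ/mol offset
across the 5-10, 20-25 and 25-30 ns windows (all other residues flip
sign between windows), then recovers exactly those residues.
"""

import mdtrend as mt

spec = mt.SyntheticSpec(seed=4)  # 50 residues, keys {10, 42}, offset/noise = 5
series_a, series_b, truth = mt.plant_trend_series(spec)

report = mt.identify_key_residues(series_a, series_b, spec.windows)
print(f"planted key residues : {truth['key_residues']}")
print(f"recovered key residues: {report.key_residues}")
# A residue is flagged when the between-complex energy difference keeps
# one sign across both adjacent window pairs (total trend score +2).

for r, total, fold in zip(report.residue_numbers, report.total_score,
                          report.fold):
    if r in report.key_residues:
        print(f"residue {r}: trend score {total:+d}, "
              f"window-averaged fold {fold:.2f}")

fold = mt.relative_fold(25.9, 123.7)
print(f"fold between binding energies 25.9 and 123.7 kJ/mol: "
      f"{fold.value:.1f}  (magnitude ratio, unitless)")
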