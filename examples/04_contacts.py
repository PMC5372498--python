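"""Hinge hydrogen bonds and hydrophobic contacts.

Uses the synthetic kinase hinge-site models (clearly-labelled stand-ins
whose contact geometry is planted at the distances reported for the
crizotinib and lorlatinib complexes) to demonstrate interface analysis.
"""

import numpy as np

import mdtrend as mt

for inhibitor, resname in (("crizotinib", "CRZ"), ("lorlatinib", "LOR")):
    system = mt.make_hinge_site_model(inhibitor)
    ligand = mt.select(system, f"resname {resname}")
    protein = mt.select(system, f"not resname {resname}")

    print(f"\n{inhibitor} hinge model")
    bonds = mt.detect_hbonds(system.positions, system, ligand, protein)
    for b in bonds:
        print(f"  H-bond {b.ligand_atom:>4s} ... {b.residue_name}{b.residue_number}"
              f" {b.protein_atom}: {b.distance:.2f} Å")
    # Crizotinib H-bonds the hinge through two nitrogens; lorlatinib
    # through three, one just inside the 3.6 Å cutoff.

    hydro = mt.hydrophobic_contacts(system.positions, system, ligand, protein)
    print(f"  hydrophobic residues: {hydro}")

    traj = mt.Trajectory(system.positions[None], np.zeros(1), system)
    ds = mt.distance_series(traj, ligand, 1197,
                            mt.WindowSpec(((0.0, 1.0), (1.0, 2.0))))
    print(f"  min polar distance ligand-Glu1197 at t=0: {ds.values[0]:.2f} Å")
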