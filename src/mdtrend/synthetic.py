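"""Synthetic complexes, trajectories and energy series with known truth.

Everything downstream — superposition, energy decomposition, trend
scoring, contacts, secondary structure — is exercised on data generated
here, so each planted quantity (per-residue fluctuation amplitudes,
between-complex energy offsets, contact distances) can be recovered and
checked without running an MD engine.

Geometry is built from ideal peptide internal coordinates (NeRF chain
construction); fluctuations are iid Gaussian displacements about the
reference with per-residue amplitudes expressed as the target RMSF
(sigma per coordinate = amplitude / sqrt(3)).  All generators are
deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import ResidueEnergySeries
from .model_io import ForceFieldParams, MolecularSystem, Trajectory
from .trend import WindowSpec

# Ideal backbone internal coordinates, Å / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_A_C_CA_CB, _D_N_C_CA_CB = 110.1, -122.6
_OMEGA = 180.0

#: Small documented nonbonded table for generated systems (charge e,
#: sigma nm, epsilon kJ/mol).  Charges sum to zero within each residue.
TOY_ATOM_PARAMS = {
    "N": (-0.40, 0.325, 0.711),
    "CA": (0.10, 0.340, 0.458),
    "C": (0.50, 0.340, 0.359),
    "O": (-0.50, 0.296, 0.879),
    "CB": (0.30, 0.340, 0.458),
}
#: Ligand sigmas are slightly soft so that planted contact distances
#: (2.9-3.5 Å) sit near the Lennard-Jones minimum instead of inside the
#: repulsive wall.
TOY_LIGAND_PARAMS = {
    "N": (-0.30, 0.26, 0.711),
    "C": (0.15, 0.30, 0.458),
    "O": (-0.30, 0.26, 0.879),
}

ALPHA_PHI, ALPHA_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted study conditions.

    Defaults emulate the analysed regime: 30 ns of frames saved every
    8 ps, three analysis windows (5-10, 20-25, 25-30 ns), a consistent
    between-complex offset of 10 kJ/mol on the key residues with 2 kJ/mol
    per-frame noise (offset/noise = 5), and 0.1 nm fluctuation amplitudes.
    """

    n_residues: int = 50
    ligand_atoms: int = 8
    key_residues: frozenset[int] = frozenset({10, 42})
    window_offsets: tuple[float, ...] = (10.0, 10.0, 10.0)   # kJ/mol per window
    noise_sigma: float = 2.0                                  # kJ/mol per frame
    rmsf_amplitudes: tuple[float, ...] | float = 0.1          # nm
    n_frames: int = 3750
    dt: float = 8.0                                           # ps
    seed: int = 0
    windows: WindowSpec = field(default_factory=WindowSpec)
    residue_start: int = 1

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        residues = set(range(self.residue_start, self.residue_start + self.n_residues))
        if not set(self.key_residues) <= residues:
            raise ValueError("key_residues outside the residue range")
        if len(self.window_offsets) != self.windows.n_windows:
            raise ValueError("one window offset per window required")
        signs = {np.sign(o) for o in self.window_offsets}
        if len(signs) > 1:
            raise ValueError("window offsets must share one sign")

    def amplitudes(self) -> np.ndarray:
        if np.isscalar(self.rmsf_amplitudes):
            return np.full(self.n_residues, float(self.rmsf_amplitudes))
        amps = np.asarray(self.rmsf_amplitudes, dtype=float)
        if len(amps) != self.n_residues:
            raise ValueError("rmsf_amplitudes length != n_residues")
        return amps


# ---------------------------------------------------------------------------
# Geometry construction (NeRF)
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from three predecessors and internal coordinates (Å)."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    n_residues: int,
    phi: float,
    psi: float,
    with_cb: bool = True,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Poly-peptide backbone (N, CA, C, O[, CB]) at fixed phi/psi, in nm.

    Returns coordinates (n_atoms, 3) and a parallel (residue_index,
    atom_name) list; residue indices are 0-based.
    """
    coords: list[np.ndarray] = []
    labels: list[tuple[int, str]] = []
    # seed the first three backbone atoms in the xy plane at the ideal angle
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])

    prev = {"N": n0, "CA": ca0, "C": c0}
    for res in range(n_residues):
        if res == 0:
            n, ca, c = n0, ca0, c0
        else:
            n = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
            ca = _nerf(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
            c = _nerf(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        coords += [n, ca, c]
        labels += [(res, "N"), (res, "CA"), (res, "C")]
        # carbonyl O: anti to the next amide nitrogen (dihedral psi + 180)
        o = _nerf(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        coords.append(o)
        labels.append((res, "O"))
        if with_cb:
            cb = _nerf(n, c, ca, _B_CA_CB, _A_C_CA_CB, _D_N_C_CA_CB)
            coords.append(cb)
            labels.append((res, "CB"))
        prev = {"N": n, "CA": ca, "C": c}
    return np.asarray(coords) / 10.0, labels


def _params_for(names, elements, is_ligand) -> ForceFieldParams:
    charge, sigma, epsilon, radius = [], [], [], []
    from .model_io import DEFAULT_ELEMENT_RADII_NM

    for name, element, lig in zip(names, elements, is_ligand):
        table = TOY_LIGAND_PARAMS if lig else TOY_ATOM_PARAMS
        key = element if lig else name
        q, s, e = table[key]
        charge.append(q)
        sigma.append(s)
        epsilon.append(e)
        radius.append(DEFAULT_ELEMENT_RADII_NM[element])
    return ForceFieldParams(
        charge=np.array(charge), lj_sigma=np.array(sigma),
        lj_epsilon=np.array(epsilon), intrinsic_radius=np.array(radius),
    )


def make_toy_complex(spec: SyntheticSpec) -> MolecularSystem:
    """Poly-alanine helix plus a rigid pseudo-ligand near a pocket residue.

    The ligand (residue name ``LIG``, numbered after the last protein
    residue) is a small deterministic cluster of N/C/O atoms docked 0.40 nm
    outside the CB of the middle (pocket) residue, with one polar atom
    planted 2.9 Å from the pocket backbone O and one carbon 3.5 Å from the
    pocket CB so that contact detection has known truth.  Charges/LJ
    parameters come from the documented toy tables; the charges sum to
    zero so the complex is neutral.
    """
    rng = np.random.default_rng(spec.seed)
    coords, labels = build_backbone(spec.n_residues, ALPHA_PHI, ALPHA_PSI)

    names = [name for _, name in labels]
    elements = [name[0] for name in names]  # N->N, CA/CB/C->C, O->O
    res_numbers = [spec.residue_start + r for r, _ in labels]
    res_names = ["ALA"] * len(labels)
    is_ligand = [False] * len(labels)

    # rigid pseudo-ligand: deterministic cluster docked at the pocket residue,
    # with one planted polar contact (N ... backbone O, 2.9 Å) and one planted
    # hydrophobic contact (C ... CB, 3.5 Å) so contact detection has truth
    pocket = spec.residue_start + spec.n_residues // 2
    cb_ix = [i for i, (r, n) in enumerate(zip(res_numbers, names))
             if r == pocket and n == "CB"][0]
    o_ix = [i for i, (r, n) in enumerate(zip(res_numbers, names))
            if r == pocket and n == "O"][0]
    axis = coords[cb_ix] - coords.mean(axis=0)
    axis /= np.linalg.norm(axis)
    centre = coords[cb_ix] + 0.40 * axis
    lig_elements = [("N", "C", "C", "O")[k % 4] for k in range(spec.ligand_atoms)]
    shell = rng.normal(size=(spec.ligand_atoms, 3))
    shell /= np.linalg.norm(shell, axis=1, keepdims=True)
    lig_coords = centre + 0.12 * shell
    lig_coords[0] = coords[o_ix] + 0.29 * axis     # planted H-bond partner
    if spec.ligand_atoms > 1:
        lig_coords[1] = coords[cb_ix] + 0.35 * axis  # planted C-C contact

    lig_number = spec.residue_start + spec.n_residues
    for k in range(spec.ligand_atoms):
        names.append(f"L{k + 1}")
        elements.append(lig_elements[k])
        res_numbers.append(lig_number)
        res_names.append("LIG")
        is_ligand.append(True)
    all_coords = np.vstack([coords, lig_coords])

    # neutralise the ligand: adjust the last carbon's charge
    params = _params_for(names, elements, is_ligand)
    lig_ix = np.array(is_ligand)
    resid_charge = params.charge[lig_ix].sum()
    carbons = np.flatnonzero(lig_ix & (np.array(elements) == "C"))
    params.charge[carbons[-1]] -= resid_charge

    return MolecularSystem(
        names=names, elements=elements, residue_numbers=res_numbers,
        residue_names=res_names,
        chain_ids=["A" if not lig else "B" for lig in is_ligand],
        positions=all_coords, params=params,
    )


def simulate_trajectory(
    system: MolecularSystem,
    spec: SyntheticSpec,
    rigid_motion: bool = False,
) -> Trajectory:
    """Frames fluctuating about the reference with planted per-residue RMSF.

    Each atom of protein residue k is displaced by iid Gaussian noise with
    per-coordinate sigma = amplitudes[k] / sqrt(3), so the recovered RMSF
    converges to the planted amplitude.  Ligand atoms stay at amplitude 0.
    With ``rigid_motion`` a random rigid roto-translation is applied to
    every frame on top, which a correct superposition step must remove.
    """
    rng = np.random.default_rng(spec.seed + 1)
    amps = spec.amplitudes()
    residue_order = system.residue_order
    amp_of = {int(r): (amps[k] if k < len(amps) else 0.0)
              for k, r in enumerate(residue_order)}
    sigma_atom = np.array(
        [amp_of.get(int(r), 0.0) for r in system.residue_numbers]
    ) / np.sqrt(3.0)

    frames = np.repeat(system.positions[None], spec.n_frames, axis=0)
    noise = rng.normal(size=frames.shape) * sigma_atom[None, :, None]
    frames = frames + noise

    if rigid_motion:
        for f in range(spec.n_frames):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0, np.radians(25.0))
            k = np.array([
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ])
            rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
            shift = rng.uniform(-0.5, 0.5, size=3)
            frames[f] = frames[f] @ rot.T + shift

    times = np.arange(spec.n_frames, dtype=float) * spec.dt
    return Trajectory(frames, times, system)


def plant_trend_series(
    spec: SyntheticSpec,
) -> tuple[ResidueEnergySeries, ResidueEnergySeries, dict]:
    """Paired per-residue energy series with a planted key-residue offset.

    Complex B (lorlatinib side) is a residue-specific baseline plus iid
    per-frame noise; complex A (crizotinib side) is the same baseline with
    independent noise, shifted by -offset_w on the key residues in every
    window (so the between-complex difference B - A keeps one sign
    throughout) and by sign-alternating window offsets of the same
    magnitude on every other residue (so their difference flips sign
    between windows — the decoys a correct trend score must never flag).

    Returns the two series and a ground-truth provenance dict.
    """
    rng = np.random.default_rng(spec.seed + 2)
    residues = np.arange(spec.residue_start, spec.residue_start + spec.n_residues)
    times = np.arange(spec.n_frames, dtype=float) * spec.dt
    times_ns = times / 1000.0

    baseline = rng.uniform(-60.0, -5.0, size=spec.n_residues)
    base = np.repeat(baseline[:, None], spec.n_frames, axis=1)
    noise_b = rng.normal(scale=spec.noise_sigma, size=base.shape) \
        if spec.noise_sigma > 0 else np.zeros_like(base)
    noise_a = rng.normal(scale=spec.noise_sigma, size=base.shape) \
        if spec.noise_sigma > 0 else np.zeros_like(base)

    offset = np.zeros((spec.n_residues, spec.n_frames))
    key_mask = np.isin(residues, list(spec.key_residues))
    for w, (a, b) in enumerate(spec.windows.windows):
        in_w = (times_ns >= a) & (times_ns < b)
        offset[np.ix_(key_mask, in_w)] = spec.window_offsets[w]
        sign = 1.0 if w % 2 == 0 else -1.0
        offset[np.ix_(~key_mask, in_w)] = sign * abs(spec.window_offsets[w])

    series_b = base + noise_b
    series_a = base - offset + noise_a

    zeros = np.zeros_like(base)
    a_series = ResidueEnergySeries(residues, times, ele=series_a, vdw=zeros)
    b_series = ResidueEnergySeries(residues, times, ele=series_b, vdw=zeros.copy())
    truth = {
        "seed": spec.seed,
        "key_residues": sorted(int(r) for r in spec.key_residues),
        "decoy_residues": sorted(int(r) for r in residues[~key_mask]),
        "window_offsets": list(spec.window_offsets),
        "noise_sigma": spec.noise_sigma,
        "windows": [list(w) for w in spec.windows.windows],
    }
    return a_series, b_series, truth


# ---------------------------------------------------------------------------
# Structure fixtures for contact / secondary-structure tests
# ---------------------------------------------------------------------------

def make_hinge_site_model(inhibitor: str = "crizotinib") -> MolecularSystem:
    """SYNTHETIC kinase hinge-site stand-in with planted contact geometry.

    A small model of the ALK hinge region (Glu1197, Phe1198, Met1199 on an
    extended backbone, plus Leu1122/Ala1148 side-chain carbons forming a
    hydrophobic shelf) with a pseudo-inhibitor whose polar atoms are placed
    at the hinge hydrogen-bond distances reported for the crizotinib
    (2.96/3.02 Å to Glu1197/Met1199) and lorlatinib (2.96/2.81/3.58 Å)
    complexes.  This is a constructed stand-in for the crystal structures,
    not crystallographic data; it exists so the contact-geometry code can
    be validated against exactly known distances.
    """
    if inhibitor not in ("crizotinib", "lorlatinib"):
        raise ValueError("inhibitor must be 'crizotinib' or 'lorlatinib'")
    # hinge residues as backbone templates spaced 6 Å apart along x so that
    # the only polar interface pairs within the cutoff are the planted ones
    template = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.46, 0.0, 0.0]),
        "C": np.array([2.0, 1.2, 0.0]),
        "O": np.array([2.0, 2.4, 0.0]),
    }
    hinge = [(1197, "GLU"), (1198, "PHE"), (1199, "MET")]
    names, elements, res_numbers, res_names, coords = [], [], [], [], []
    for k, (rnum, rname) in enumerate(hinge):
        for aname, pos in template.items():
            names.append(aname)
            elements.append(aname[0])
            res_numbers.append(rnum)
            res_names.append(rname)
            coords.append(pos + np.array([6.0 * k, 0.0, 0.0]))
    pos_of = {(r, n): c for r, n, c in zip(res_numbers, names, coords)}
    glu_o = pos_of[(1197, "O")]
    met_n = pos_of[(1199, "N")]
    met_o = pos_of[(1199, "O")]
    up = np.array([0.0, 0.0, 1.0])

    lig_names, lig_elements, lig_coords = [], [], []

    def add(name, element, pos):
        lig_names.append(name)
        lig_elements.append(element)
        lig_coords.append(np.asarray(pos, dtype=float))

    if inhibitor == "crizotinib":
        # N22...Glu1197 O at 3.02 Å, N23...Met1199 N at 2.96 Å
        add("N22", "N", glu_o + 3.02 * up)
        add("N23", "N", met_n + 2.96 * up)
        resname = "CRZ"
    else:
        # N3...Glu1197 O 2.81 Å, N17...Met1199 N 2.96 Å, N24...Met1199 O 3.58 Å
        add("N3", "N", glu_o + 2.81 * up)
        add("N17", "N", met_n + 2.96 * up)
        add("N24", "N", met_o + 3.58 * up)
        resname = "LOR"

    # carbon linker well above the strand plane
    for k, x in enumerate((4.0, 7.0, 10.0, 13.0)):
        add(f"C{k + 1}", "C", np.array([x, 1.0, 5.0]))

    # hydrophobic shelf: Leu1122 / Ala1148 side-chain carbons 3.5 Å from
    # the ligand linker carbons C1 and C3
    shelf = [
        ("LEU", 1122, "CD1", np.array([4.0, 4.5, 5.0])),
        ("ALA", 1148, "CB", np.array([10.0, 4.5, 5.0])),
        ("LEU", 1256, "CD1", np.array([13.0, 4.5, 5.0])),
    ]
    for rname, rnum, aname, pos in shelf:
        names.append(aname)
        elements.append("C")
        res_numbers.append(rnum)
        res_names.append(rname)
        coords.append(pos)

    names += lig_names
    elements += lig_elements
    res_numbers += [1] * len(lig_names)
    res_names += [resname] * len(lig_names)
    coords = np.vstack([np.asarray(coords), np.asarray(lig_coords)]) / 10.0  # Å -> nm

    params = _params_for(
        names,
        elements,
        [True] * len(names),  # element-keyed table covers N/C/O here
    )
    return MolecularSystem(
        names=names, elements=elements, residue_numbers=res_numbers,
        residue_names=res_names, chain_ids=["A"] * len(names),
        positions=coords, params=params,
    )


def make_helix_system(n_residues: int = 12, residue_start: int = 1) -> MolecularSystem:
    """Ideal poly-alanine alpha helix (phi=-57, psi=-47) with backbone+CB."""
    coords, labels = build_backbone(n_residues, ALPHA_PHI, ALPHA_PSI)
    names = [name for _, name in labels]
    return MolecularSystem(
        names=names,
        elements=[n[0] for n in names],
        residue_numbers=[residue_start + r for r, _ in labels],
        residue_names=["ALA"] * len(labels),
        chain_ids=["A"] * len(labels),
        positions=coords,
        params=_params_for(names, [n[0] for n in names], [False] * len(labels)),
    )


def make_sheet_system(n_residues: int = 8) -> MolecularSystem:
    """Two antiparallel extended strands with a hydrogen-bonded core.

    The second strand is the first rotated 180 deg about the y axis and
    offset so that backbone N-H...O=C pairs register across the interface;
    residues 1..n belong to strand one, 21..20+n to strand two.
    """
    coords, labels = build_backbone(n_residues, STRAND_PHI, STRAND_PSI)
    names = [name for _, name in labels]
    flip = np.diag([-1.0, 1.0, -1.0])
    strand2 = (coords - coords.mean(axis=0)) @ flip.T + coords.mean(axis=0)
    strand2 += np.array([-0.15, 0.40, 0.0])
    all_coords = np.vstack([coords, strand2])
    n_at = len(labels)
    return MolecularSystem(
        names=names * 2,
        elements=[n[0] for n in names] * 2,
        residue_numbers=[r + 1 for r, _ in labels] + [r + 21 for r, _ in labels],
        residue_names=["ALA"] * 2 * n_at,
        chain_ids=["A"] * n_at + ["B"] * n_at,
        positions=all_coords,
        params=_params_for(names * 2, [n[0] for n in names] * 2, [False] * 2 * n_at),
    )


def make_extended_system(n_residues: int = 12, residue_start: int = 1) -> MolecularSystem:
    """Fully extended single chain (beta dihedrals, no partner strand)."""
    coords, labels = build_backbone(n_residues, STRAND_PHI, STRAND_PSI)
    names = [name for _, name in labels]
    return MolecularSystem(
        names=names,
        elements=[n[0] for n in names],
        residue_numbers=[residue_start + r for r, _ in labels],
        residue_names=["ALA"] * len(labels),
        chain_ids=["A"] * len(labels),
        positions=coords,
        params=_params_for(names, [n[0] for n in names], [False] * len(labels)),
    )
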