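"""Protein–ligand hydrogen-bond and hydrophobic-contact geometry.

Hydrogen bonds are called on donor/acceptor heavy-atom distance alone by
default (N/O/S within 3.6 Å), the practical criterion when depositions
lack hydrogens; when explicit hydrogens are present a D-H...A angle test
(>= 120 deg) is applied as well.  Hydrophobic contacts are carbon–carbon
interface pairs within 3.9 Å.  Distances in this module are reported in Å,
the unit contact geometry is conventionally quoted in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ANGSTROM_PER_NM, MolecularSystem, Selection, Trajectory
from .trend import TrendError, WindowSpec, window_means

POLAR_ELEMENTS = ("N", "O", "S")
HBOND_CUTOFF_A = 3.6
HYDROPHOBIC_CUTOFF_A = 3.9
HBOND_ANGLE_MIN_DEG = 120.0


class ContactError(ValueError):
    """Raised on malformed contact-analysis input."""


@dataclass(frozen=True)
class HBond:
    """A donor–acceptor polar contact across the protein–ligand interface."""

    donor_index: int
    acceptor_index: int
    distance: float            # Å
    residue_number: int        # protein residue involved
    residue_name: str
    protein_atom: str
    ligand_atom: str


@dataclass(frozen=True)
class DistanceSeries:
    """Minimum ligand–residue polar distance over time, Å."""

    residue_number: int
    times: np.ndarray          # ps
    values: np.ndarray         # Å, per frame
    window_means: np.ndarray   # Å, one per window (plus t=0 handled by caller)
    window_labels: tuple[str, ...]


def _polar_mask(system: MolecularSystem, indices: np.ndarray) -> np.ndarray:
    return np.isin(system.elements[indices], POLAR_ELEMENTS)


def _angles_ok(
    frame: np.ndarray, system: MolecularSystem, donor: int, acceptor: int
) -> bool:
    """D-H...A angle test using any hydrogen bonded (< 1.3 Å) to the donor."""
    d_pos = frame[donor]
    h_mask = system.elements == "H"
    if not np.any(h_mask):
        return True
    h_ix = np.flatnonzero(h_mask)
    dist_h = np.linalg.norm(frame[h_ix] - d_pos, axis=1) * ANGSTROM_PER_NM
    attached = h_ix[dist_h < 1.3]
    if attached.size == 0:
        return True
    a_pos = frame[acceptor]
    for h in attached:
        hv = frame[h]
        v1 = d_pos - hv
        v2 = a_pos - hv
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= HBOND_ANGLE_MIN_DEG:
            return True
    return False


def detect_hbonds(
    frame: np.ndarray,
    system: MolecularSystem,
    ligand: Selection,
    protein: Selection,
    d_cut: float = HBOND_CUTOFF_A,
) -> list[HBond]:
    """All interface N/O/S polar-atom pairs within ``d_cut`` Å, by distance.

    Either partner may act as donor or acceptor — without hydrogens the
    roles cannot be assigned from geometry, so each close polar pair is
    reported once with the ligand atom listed as donor.  With explicit
    hydrogens present, pairs failing the D-H...A >= 120 deg test (in
    either direction) are rejected.
    """
    ligand.validate(system.n_atoms)
    protein.validate(system.n_atoms)
    li, pi = ligand.indices, protein.indices
    if np.intersect1d(li, pi).size:
        raise ContactError("ligand and protein selections overlap")
    lp = li[_polar_mask(system, li)]
    pp = pi[_polar_mask(system, pi)]
    if lp.size == 0 or pp.size == 0:
        return []
    diff = frame[lp][:, None, :] - frame[pp][None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2)) * ANGSTROM_PER_NM

    has_h = bool(np.any(system.elements == "H"))
    bonds: list[HBond] = []
    for a, b in zip(*np.nonzero(dist <= d_cut)):
        la, pa = int(lp[a]), int(pp[b])
        if has_h and not (
            _angles_ok(frame, system, la, pa) or _angles_ok(frame, system, pa, la)
        ):
            continue
        bonds.append(
            HBond(
                donor_index=la, acceptor_index=pa,
                distance=float(dist[a, b]),
                residue_number=int(system.residue_numbers[pa]),
                residue_name=str(system.residue_names[pa]),
                protein_atom=str(system.names[pa]),
                ligand_atom=str(system.names[la]),
            )
        )
    bonds.sort(key=lambda h: h.distance)
    return bonds


def hydrophobic_contacts(
    frame: np.ndarray,
    system: MolecularSystem,
    ligand: Selection,
    protein: Selection,
    c_cut: float = HYDROPHOBIC_CUTOFF_A,
) -> list[int]:
    """Residues with >= 1 carbon–carbon interface pair within ``c_cut`` Å.

    Returns deduplicated residue numbers sorted ascending.
    """
    ligand.validate(system.n_atoms)
    protein.validate(system.n_atoms)
    li, pi = ligand.indices, protein.indices
    if np.intersect1d(li, pi).size:
        raise ContactError("ligand and protein selections overlap")
    lc = li[system.elements[li] == "C"]
    pc = pi[system.elements[pi] == "C"]
    if lc.size == 0 or pc.size == 0:
        return []
    diff = frame[lc][:, None, :] - frame[pc][None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2)) * ANGSTROM_PER_NM
    close = np.any(dist <= c_cut, axis=0)
    residues = sorted({int(r) for r in system.residue_numbers[pc[close]]})
    return residues


def distance_series(
    traj: Trajectory,
    ligand: Selection,
    residue_number: int,
    spec: WindowSpec | None = None,
) -> DistanceSeries:
    """Minimum polar ligand–residue distance per frame, with window means.

    The per-frame value is the minimum distance between any ligand N/O atom
    and any N/O atom of the residue (backbone and side chain), in Å —
    the quantity behind hinge-distance tables.
    """
    spec = spec or WindowSpec()
    system = traj.system
    ligand.validate(system.n_atoms)
    res_ix = np.flatnonzero(system.residue_numbers == residue_number)
    res_ix = np.setdiff1d(res_ix, ligand.indices)
    if res_ix.size == 0:
        raise ContactError(f"residue {residue_number} not found")
    lp = ligand.indices[np.isin(system.elements[ligand.indices], ("N", "O"))]
    rp = res_ix[np.isin(system.elements[res_ix], ("N", "O"))]
    if lp.size == 0 or rp.size == 0:
        raise ContactError("no polar atoms available for distance series")

    diff = traj.frames[:, lp, None, :] - traj.frames[:, None, rp, :]
    dist = np.sqrt(np.sum(diff * diff, axis=3)) * ANGSTROM_PER_NM
    per_frame = dist.reshape(traj.n_frames, -1).min(axis=1)

    try:
        means = window_means(per_frame, traj.times, spec)
    except TrendError:
        means = np.full(spec.n_windows, np.nan)
    return DistanceSeries(
        residue_number=int(residue_number),
        times=traj.times.copy(),
        values=per_frame,
        window_means=np.asarray(means, dtype=float),
        window_labels=tuple(spec.labels()),
    )
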