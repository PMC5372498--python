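"""Interaction energies, per-residue decomposition, and MM/GBSA.

The binding free energy follows the end-point single-trajectory scheme

    dG      = dE_MM + dG_sol - TdS
    dE_MM   = dE_vdw + dE_ele + dE_bonded
    dG_sol  = dG_polar + dG_nonpolar

with dE_bonded fixed at zero (identical receptor/ligand conformations in
the single-trajectory approximation) and the entropy term TdS ignored.
The polar solvation term is a generalized Born model with Hawkins–Cramer–
Truhlar (HCT) pairwise-descreening effective radii; the nonpolar term is a
linear function of the solvent-accessible surface area (SASA) computed by
Shrake–Rupley sampling on a deterministic Fibonacci sphere.

Units: nm, kJ/mol, elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import ForceFieldParams, Selection, Trajectory

#: Coulomb constant 1/(4 pi eps0), kJ mol^-1 nm e^-2.
KE = 138.935458

#: GB dielectric defaults: solute interior and water.
EPS_IN = 1.0
EPS_OUT = 78.4

#: HCT dielectric offset subtracted from intrinsic radii, nm.
GB_OFFSET = 0.009

#: HCT per-element descreening scale factors.
HCT_SCALES = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.80}
HCT_SCALE_DEFAULT = 0.80

#: Linear SASA model: gamma in kJ mol^-1 nm^-2, beta in kJ/mol
#: (0.00542 kcal mol^-1 A^-2 and 0.92 kcal/mol in common GBSA parlance).
SASA_GAMMA = 2.26778
SASA_BETA = 3.84928


class EnergeticsError(ValueError):
    """Raised for ill-posed energy evaluations."""


@dataclass(frozen=True)
class EnergyBreakdown:
    """The terms of an end-point binding free energy, kJ/mol.

    ``dG_polar`` is the GB electrostatic solvation term (a.k.a. dE_GB) and
    ``dG_nonpolar`` the SASA term (a.k.a. dE_SUR).  The decomposition
    identities are enforced on construction.
    """

    dE_ele: float
    dE_vdw: float
    dG_polar: float
    dG_nonpolar: float
    dE_bonded: float = 0.0
    TdS: float = 0.0
    dE_MM: float = field(default=None)  # type: ignore[assignment]
    dG_sol: float = field(default=None)  # type: ignore[assignment]
    dG: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        mm = self.dE_vdw + self.dE_ele + self.dE_bonded
        sol = self.dG_polar + self.dG_nonpolar
        total = mm + sol - self.TdS
        for name, value in (("dE_MM", mm), ("dG_sol", sol), ("dG", total)):
            given = getattr(self, name)
            if given is None:
                object.__setattr__(self, name, value)
            else:
                scale = max(1.0, abs(value))
                if abs(given - value) > 1e-9 * scale:
                    raise EnergeticsError(
                        f"{name}={given} violates decomposition identity ({value})"
                    )

    def as_dict(self) -> dict[str, float]:
        return {
            "dG": self.dG, "dE_MM": self.dE_MM, "dE_ele": self.dE_ele,
            "dE_vdw": self.dE_vdw, "dE_bonded": self.dE_bonded,
            "dG_sol": self.dG_sol, "dG_polar": self.dG_polar,
            "dG_nonpolar": self.dG_nonpolar, "TdS": self.TdS,
        }


@dataclass(frozen=True)
class ResidueEnergySeries:
    """Per-residue, per-frame interaction energies with the ligand, kJ/mol."""

    residue_numbers: np.ndarray   # (R,)
    times: np.ndarray             # (F,) ps
    ele: np.ndarray               # (R, F)
    vdw: np.ndarray               # (R, F)

    def __post_init__(self):
        r, f = len(self.residue_numbers), len(self.times)
        if self.ele.shape != (r, f) or self.vdw.shape != (r, f):
            raise EnergeticsError("energy matrices must be (R, F)")
        if not (np.all(np.isfinite(self.ele)) and np.all(np.isfinite(self.vdw))):
            raise EnergeticsError("non-finite energies")

    @property
    def total(self) -> np.ndarray:
        return self.ele + self.vdw


# ---------------------------------------------------------------------------
# Pair potentials
# ---------------------------------------------------------------------------

def coulomb_pair(q1: float, q2: float, r: float, eps_r: float = 1.0) -> float:
    """Coulomb energy of a charge pair: KE * q1*q2 / (eps_r * r), kJ/mol."""
    if r <= 0:
        raise EnergeticsError("coulomb_pair: r must be positive")
    return KE * q1 * q2 / (eps_r * r)


def lj_pair(sigma: float, epsilon: float, r: float) -> float:
    """12-6 Lennard-Jones energy 4*eps*((s/r)^12 - (s/r)^6), kJ/mol."""
    if r <= 0:
        raise EnergeticsError("lj_pair: r must be positive")
    if sigma <= 0:
        raise EnergeticsError("lj_pair: sigma must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def lorentz_berthelot(
    sigma_i: np.ndarray, sigma_j: np.ndarray,
    eps_i: np.ndarray, eps_j: np.ndarray,
):
    """Combining rules: arithmetic-mean sigma, geometric-mean epsilon."""
    return 0.5 * (sigma_i + sigma_j), np.sqrt(eps_i * eps_j)


def interaction_energy(
    frame: np.ndarray,
    group_a: Selection,
    group_b: Selection,
    params: ForceFieldParams,
    cutoff: float | None = None,
    eps_r: float = 1.0,
) -> tuple[float, float]:
    """Total electrostatic and van der Waals energy between two atom groups.

    A plain double sum over all inter-group pairs (no exclusions — the
    groups are assumed to belong to different molecules).  An optional hard
    distance cutoff (nm) truncates the pair list without switching.

    Returns
    -------
    (ele, vdw) : tuple of float, kJ/mol
    """
    ia, ib = group_a.indices, group_b.indices
    if np.intersect1d(ia, ib).size:
        raise EnergeticsError("interaction groups overlap")
    if ia.size == 0 or ib.size == 0:
        return 0.0, 0.0
    diff = frame[ia][:, None, :] - frame[ib][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r <= 0):
        raise EnergeticsError("coincident atoms across groups")
    mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)

    qq = params.charge[ia][:, None] * params.charge[ib][None, :]
    ele = float(np.sum((KE * qq / (eps_r * r))[mask]))

    sig, eps = lorentz_berthelot(
        params.lj_sigma[ia][:, None], params.lj_sigma[ib][None, :],
        params.lj_epsilon[ia][:, None], params.lj_epsilon[ib][None, :],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
    vdw = float(np.sum((4.0 * eps * (sr6 * sr6 - sr6))[mask]))
    return ele, vdw


def per_residue_decomposition(
    traj: Trajectory,
    ligand: Selection,
    params: ForceFieldParams | None = None,
    eps_r: float = 1.0,
) -> ResidueEnergySeries:
    """Residue-by-residue interaction energy with the ligand, per frame.

    For every protein residue (all atoms not in the ligand selection) the
    electrostatic and van der Waals interaction with the ligand group is
    summed.  Rows add up to the whole protein–ligand interaction energy.
    """
    system = traj.system
    params = params if params is not None else system.params
    if params is None:
        raise EnergeticsError("no force-field parameters available")
    ligand.validate(system.n_atoms)
    lig = ligand.indices
    prot = np.setdiff1d(np.arange(system.n_atoms), lig)
    if lig.size == 0:
        raise EnergeticsError("empty ligand selection")
    if prot.size == 0:
        raise EnergeticsError("ligand selection covers every atom")

    res_of = system.residue_numbers[prot]
    residues = []
    seen = set()
    for r in res_of:
        if int(r) not in seen:
            seen.add(int(r))
            residues.append(int(r))
    res_pos = {r: k for k, r in enumerate(residues)}
    row = np.array([res_pos[int(r)] for r in res_of])

    q = params.charge
    sig, eps = lorentz_berthelot(
        params.lj_sigma[prot][:, None], params.lj_sigma[lig][None, :],
        params.lj_epsilon[prot][:, None], params.lj_epsilon[lig][None, :],
    )
    qq = q[prot][:, None] * q[lig][None, :]

    n_res, n_frames = len(residues), traj.n_frames
    ele = np.zeros((n_res, n_frames))
    vdw = np.zeros((n_res, n_frames))
    for f in range(n_frames):
        diff = traj.frames[f][prot][:, None, :] - traj.frames[f][lig][None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        if np.any(r <= 0):
            raise EnergeticsError(f"coincident atoms in frame {f}")
        e_pair = KE * qq / (eps_r * r)
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
        v_pair = 4.0 * eps * (sr6 * sr6 - sr6)
        ele[:, f] = np.bincount(row, weights=e_pair.sum(axis=1), minlength=n_res)
        vdw[:, f] = np.bincount(row, weights=v_pair.sum(axis=1), minlength=n_res)
    return ResidueEnergySeries(
        residue_numbers=np.asarray(residues, dtype=int),
        times=traj.times.copy(), ele=ele, vdw=vdw,
    )


# ---------------------------------------------------------------------------
# Generalized Born (HCT pairwise descreening)
# ---------------------------------------------------------------------------

def hct_scales(elements: np.ndarray) -> np.ndarray:
    """Per-atom HCT descreening scale factors from element symbols."""
    return np.array([HCT_SCALES.get(e, HCT_SCALE_DEFAULT) for e in elements])


def born_radii(
    frame: np.ndarray,
    params: ForceFieldParams,
    scales: np.ndarray | None = None,
    offset: float = GB_OFFSET,
) -> np.ndarray:
    """HCT effective Born radii, nm.

    Each atom's inverse radius starts from its reduced intrinsic radius
    ``rho_i - offset`` and is reduced by the analytic pairwise-descreening
    integral of every neighbour, evaluated with the neighbour's scaled
    reduced radius.  Descreening only ever increases the effective radius,
    so R_i >= rho_i - offset by construction; the inverse is floored at a
    small positive value to keep pathological overlaps finite.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    rho = params.intrinsic_radius - offset
    if np.any(rho <= 0):
        raise EnergeticsError("intrinsic radius smaller than GB offset")
    if scales is None:
        scales = np.full(n, HCT_SCALE_DEFAULT)
    scales = np.asarray(scales, dtype=float)

    diff = frame[:, None, :] - frame[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(r[off_diag] <= 0):
        raise EnergeticsError("coincident atoms")

    inv = 1.0 / rho
    sr = scales * rho                      # scaled reduced neighbour radii
    for i in range(n):
        rij = r[i]
        s = sr
        active = off_diag[i] & (rij + s > rho[i])
        if not np.any(active):
            continue
        rija, sa = rij[active], s[active]
        u = rija + sa
        l = np.maximum(rho[i], np.abs(rija - sa))
        term = (
            1.0 / l - 1.0 / u
            + 0.25 * (rija - sa * sa / rija) * (1.0 / (u * u) - 1.0 / (l * l))
            + 0.5 * np.log(l / u) / rija
        )
        engulfed = sa > rija + rho[i]      # atom i inside neighbour's sphere
        term = term + np.where(engulfed, 2.0 * (1.0 / rho[i] - 1.0 / l), 0.0)
        inv[i] -= 0.5 * np.sum(term)
    inv = np.maximum(inv, 1e-6)
    return 1.0 / inv


def gb_polar(
    frame: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    eps_in: float = EPS_IN,
    eps_out: float = EPS_OUT,
) -> float:
    """Generalized Born polar solvation energy (Still et al. form), kJ/mol.

    E = -1/2 * KE * (1/eps_in - 1/eps_out) * sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the i=j self terms
    are included, so a single ion reproduces the Born formula exactly.
    """
    if eps_in <= 0 or eps_out <= 0:
        raise EnergeticsError("dielectric constants must be positive")
    frame = np.asarray(frame, dtype=float)
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise EnergeticsError("Born radii must be positive")
    diff = frame[:, None, :] - frame[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    rr = radii[:, None] * radii[None, :]
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    qq = charges[:, None] * charges[None, :]
    prefactor = -0.5 * KE * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefactor * np.sum(qq / f_gb))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley on a Fibonacci sphere)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n_points, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n_points
    theta = 2.0 * np.pi * k / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    frame: np.ndarray,
    params: ForceFieldParams,
    probe: float = 0.14,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, nm^2.

    Shrake–Rupley: sample each atom's probe-inflated sphere with a
    deterministic Fibonacci point set and count points not buried inside
    any neighbour's inflated sphere.
    """
    if probe < 0:
        raise EnergeticsError("probe radius must be non-negative")
    if n_points < 50:
        raise EnergeticsError("n_points must be >= 50 for a meaningful area")
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    radii = params.intrinsic_radius + probe
    unit = fibonacci_sphere(n_points)

    diff = frame[:, None, :] - frame[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    areas = np.empty(n)
    for i in range(n):
        neighbours = np.flatnonzero(
            (dist[i] < radii[i] + radii) & (np.arange(n) != i)
        )
        pts = frame[i] + radii[i] * unit
        if neighbours.size == 0:
            accessible = n_points
        else:
            d = pts[:, None, :] - frame[neighbours][None, :, :]
            buried = np.any(
                np.sum(d * d, axis=2) < (radii[neighbours] ** 2)[None, :], axis=1
            )
            accessible = int(np.sum(~buried))
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points
    return areas


def nonpolar_energy(
    total_sasa: float, gamma: float = SASA_GAMMA, beta: float = SASA_BETA
) -> float:
    """Linear SASA nonpolar solvation model: gamma * SASA + beta, kJ/mol."""
    if total_sasa < 0:
        raise EnergeticsError("SASA must be non-negative")
    return gamma * total_sasa + beta


# ---------------------------------------------------------------------------
# MM/GBSA
# ---------------------------------------------------------------------------

def mmgbsa(
    traj: Trajectory,
    receptor: Selection,
    ligand: Selection,
    params: ForceFieldParams | None = None,
    frame_range: tuple[int, int] | None = None,
    eps_in: float = EPS_IN,
    eps_out: float = EPS_OUT,
    probe: float = 0.14,
    n_points: int = 960,
    sasa_gamma: float = SASA_GAMMA,
    sasa_beta: float = SASA_BETA,
) -> tuple[EnergyBreakdown, "object"]:
    """Single-trajectory MM/GBSA binding energy, frame-averaged.

    Every term is the complex-minus-parts difference
    ``dX = X(complex) - X(receptor) - X(ligand)`` evaluated on the same
    frame (single-trajectory approximation: dE_bonded = 0) and averaged
    over the frame range.  TdS is not estimated.

    Returns the averaged :class:`EnergyBreakdown` plus a pandas DataFrame
    with the per-frame terms.
    """
    import pandas as pd

    system = traj.system
    params = params if params is not None else system.params
    if params is None:
        raise EnergeticsError("no force-field parameters available")
    receptor.validate(system.n_atoms)
    ligand.validate(system.n_atoms)
    ri, li = receptor.indices, ligand.indices
    if np.intersect1d(ri, li).size:
        raise EnergeticsError("receptor and ligand selections overlap")
    if len(ri) + len(li) != system.n_atoms:
        raise EnergeticsError("receptor + ligand must cover every atom")

    lo, hi = frame_range if frame_range is not None else (0, traj.n_frames)
    if hi <= lo:
        raise EnergeticsError("empty frame range")

    scales = hct_scales(system.elements)
    q = params.charge

    def _sub_params(ix):
        return ForceFieldParams(
            charge=q[ix], lj_sigma=params.lj_sigma[ix],
            lj_epsilon=params.lj_epsilon[ix],
            intrinsic_radius=params.intrinsic_radius[ix],
        )

    p_r, p_l = _sub_params(ri), _sub_params(li)
    rows = []
    for f in range(lo, hi):
        frame = traj.frames[f]
        ele, vdw = interaction_energy(frame, receptor, ligand, params)

        # polar: GB of complex minus parts (radii recomputed per subsystem)
        def _gb(ix, sub):
            radii = born_radii(frame[ix], sub, scales[ix])
            return gb_polar(frame[ix], sub.charge, radii, eps_in, eps_out)

        all_ix = np.arange(system.n_atoms)
        gb_c = _gb(all_ix, _sub_params(all_ix))
        d_polar = gb_c - _gb(ri, p_r) - _gb(li, p_l)

        def _np_term(ix, sub):
            return nonpolar_energy(
                float(np.sum(sasa(frame[ix], sub, probe, n_points))),
                sasa_gamma, sasa_beta,
            )

        d_nonpolar = (
            _np_term(all_ix, _sub_params(all_ix))
            - _np_term(ri, p_r) - _np_term(li, p_l)
        )
        rows.append(
            {"frame": f, "time_ps": traj.times[f], "dE_ele": ele, "dE_vdw": vdw,
             "dG_polar": d_polar, "dG_nonpolar": d_nonpolar,
             "dG": ele + vdw + d_polar + d_nonpolar}
        )

    table = pd.DataFrame(rows)
    breakdown = EnergyBreakdown(
        dE_ele=float(table["dE_ele"].mean()),
        dE_vdw=float(table["dE_vdw"].mean()),
        dG_polar=float(table["dG_polar"].mean()),
        dG_nonpolar=float(table["dG_nonpolar"].mean()),
    )
    return breakdown, table
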