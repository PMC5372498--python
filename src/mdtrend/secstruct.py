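"""Backbone hydrogen-bond secondary-structure assignment and comparison.

Assignment follows the Kabsch–Sander electrostatic criterion: the
amide-to-carbonyl hydrogen-bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in Å]

with a bond called at E < -0.5 kcal/mol, followed by simplified pattern
rules over a five-state alphabet: H (alpha helix, consecutive i->i+4
turns), G (3-10 helix, i->i+3), E (bridge/ladder), T (isolated turn),
C (coil).  Amide hydrogens are reconstructed geometrically when absent,
as is typical for crystal structures and generated fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_io import ANGSTROM_PER_NM, MolecularSystem, Trajectory
from .trend import TrendError, WindowSpec

logger = logging.getLogger(__name__)

KS_Q = 0.084 * 332.0          # kcal/mol * Å
KS_BOND_CUTOFF = -0.5         # kcal/mol
NH_BOND_LENGTH_A = 1.0        # reconstructed N-H bond length, Å
CHAIN_BREAK_A = 2.5           # C(i)-N(i+1) distance beyond which the chain breaks

STATES = ("H", "G", "E", "T", "C")


class SecStructError(ValueError):
    """Raised on malformed secondary-structure input."""


@dataclass(frozen=True)
class SSTimeline:
    """Per-frame secondary-structure states for a set of residues."""

    residue_numbers: np.ndarray   # (R,)
    times: np.ndarray             # (F,) ps
    states: np.ndarray            # (F, R) single-character states

    def state_string(self, frame: int) -> str:
        return "".join(self.states[frame])

    def window_fractions(self, spec: WindowSpec) -> np.ndarray:
        """State occupancy fractions, shape (W, R, len(STATES)); rows sum to 1."""
        times_ns = self.times / 1000.0
        out = np.zeros((spec.n_windows, len(self.residue_numbers), len(STATES)))
        for w, (a, b) in enumerate(spec.windows):
            mask = (times_ns >= a) & (times_ns < b)
            if not np.any(mask):
                raise TrendError(f"window {a}-{b} ns contains no frames")
            sub = self.states[mask]
            for s, state in enumerate(STATES):
                out[w, :, s] = np.mean(sub == state, axis=0)
        return out


# ---------------------------------------------------------------------------
# Backbone extraction and hydrogen reconstruction
# ---------------------------------------------------------------------------

def _backbone_table(system: MolecularSystem):
    """Per-residue indices of N/CA/C/O (and H if present); None when missing."""
    residues = []
    for r in system.residue_order:
        ix = np.flatnonzero(system.residue_numbers == r)
        names = system.names[ix]
        entry = {}
        for name in ("N", "CA", "C", "O", "H"):
            hit = ix[names == name]
            entry[name] = int(hit[0]) if hit.size else None
        if all(entry[k] is not None for k in ("N", "CA", "C", "O")):
            entry["residue"] = int(r)
            residues.append(entry)
        else:
            # ligand/het residues and incomplete backbones are not assigned
            if np.any(names == "CA"):
                logger.warning("residue %s skipped: incomplete backbone", r)
    return residues


def _amide_positions(frame: np.ndarray, table, breaks: np.ndarray) -> np.ndarray:
    """Amide H position per residue (nan where undefined, e.g. segment start).

    When the structure has no explicit H, it is placed 1.0 Å from N along
    the direction opposite the bisector of the C(prev)-N and CA-N bonds.
    """
    n_res = len(table)
    h_pos = np.full((n_res, 3), np.nan)
    for k in range(n_res):
        if table[k]["H"] is not None:
            h_pos[k] = frame[table[k]["H"]]
            continue
        if k == 0 or breaks[k - 1]:
            continue  # no preceding carbonyl to orient the amide
        n = frame[table[k]["N"]]
        ca = frame[table[k]["CA"]]
        c_prev = frame[table[k - 1]["C"]]
        v1 = n - c_prev
        v2 = n - ca
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        d = v1 + v2
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        h_pos[k] = n + (NH_BOND_LENGTH_A / ANGSTROM_PER_NM) * d / norm
    return h_pos


def _segment_breaks(frame: np.ndarray, table) -> np.ndarray:
    """breaks[k] True when the chain is discontinuous between k and k+1."""
    n_res = len(table)
    breaks = np.zeros(max(n_res - 1, 0), dtype=bool)
    for k in range(n_res - 1):
        c = frame[table[k]["C"]]
        n = frame[table[k + 1]["N"]]
        gap = np.linalg.norm(n - c) * ANGSTROM_PER_NM
        seq_gap = table[k + 1]["residue"] - table[k]["residue"] != 1
        breaks[k] = gap > CHAIN_BREAK_A or seq_gap
    return breaks


def _ks_energy(frame, table, h_pos, donor_k: int, acceptor_k: int) -> float:
    """Kabsch–Sander energy (kcal/mol) of NH(donor) ... CO(acceptor)."""
    if np.any(np.isnan(h_pos[donor_k])):
        return 0.0
    n = frame[table[donor_k]["N"]]
    h = h_pos[donor_k]
    c = frame[table[acceptor_k]["C"]]
    o = frame[table[acceptor_k]["O"]]
    a = ANGSTROM_PER_NM
    r_on = np.linalg.norm(o - n) * a
    r_ch = np.linalg.norm(c - h) * a
    r_oh = np.linalg.norm(o - h) * a
    r_cn = np.linalg.norm(c - n) * a
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clashing atoms: treat as maximal bond, as DSSP does
    return KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def ks_hbond_energy(
    frame: np.ndarray,
    system: MolecularSystem,
    donor_res: int,
    acceptor_res: int,
) -> float:
    """Kabsch–Sander backbone H-bond energy between two residues, kcal/mol.

    ``donor_res`` contributes the amide N-H, ``acceptor_res`` the carbonyl
    C=O.  A hydrogen is reconstructed when the donor lacks one.  Residues
    with incomplete backbones raise :class:`SecStructError`.
    """
    table = _backbone_table(system)
    res_to_k = {e["residue"]: k for k, e in enumerate(table)}
    try:
        dk, ak = res_to_k[int(donor_res)], res_to_k[int(acceptor_res)]
    except KeyError as exc:
        raise SecStructError(f"residue {exc} lacks a complete backbone") from exc
    breaks = _segment_breaks(frame, table)
    h_pos = _amide_positions(frame, table, breaks)
    if np.any(np.isnan(h_pos[dk])):
        raise SecStructError(
            f"residue {donor_res}: amide hydrogen undefined (segment start)"
        )
    return float(_ks_energy(frame, table, h_pos, dk, ak))


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_ss(frame: np.ndarray, system: MolecularSystem) -> str:
    """Assign one of H/G/E/T/C to every complete-backbone residue.

    Simplified Kabsch–Sander rules: >= 2 consecutive i->i+4 turns make an
    alpha helix (H), i->i+3 analogously 3-10 (G), residues in hydrogen-
    bonded bridges are strand (E), residues covered by an isolated turn
    are T, everything else C.  Overlaps resolve with priority H > E > G > T.
    """
    table = _backbone_table(system)
    n_res = len(table)
    if n_res == 0:
        return ""
    breaks = _segment_breaks(frame, table)
    h_pos = _amide_positions(frame, table, breaks)

    # hb[i, j]: CO of residue i accepts the amide H of residue j
    hb = np.zeros((n_res, n_res), dtype=bool)
    coords = np.array([frame[e["CA"]] for e in table])
    for i in range(n_res):
        # prune by CA distance: KS energies are negligible past ~9 Å
        close = np.flatnonzero(
            np.linalg.norm(coords - coords[i], axis=1) * ANGSTROM_PER_NM < 9.0
        )
        for j in close:
            if abs(i - j) < 2:
                continue
            if _ks_energy(frame, table, h_pos, int(j), i) < KS_BOND_CUTOFF:
                hb[i, j] = True

    def same_segment(i, j):
        lo, hi = min(i, j), max(i, j)
        return not np.any(breaks[lo:hi])

    turn4 = np.zeros(n_res, dtype=bool)
    turn3 = np.zeros(n_res, dtype=bool)
    for i in range(n_res):
        if i + 4 < n_res and same_segment(i, i + 4) and hb[i, i + 4]:
            turn4[i] = True
        if i + 3 < n_res and same_segment(i, i + 3) and hb[i, i + 3]:
            turn3[i] = True

    states = np.full(n_res, "C", dtype="U1")

    # T: residues covered by any turn (will be overwritten by G/E/H)
    for i in np.flatnonzero(turn4):
        states[i + 1: i + 4] = "T"
    for i in np.flatnonzero(turn3):
        states[i + 1: i + 3] = "T"

    # G: two consecutive 3-turns
    for i in range(1, n_res):
        if turn3[i] and turn3[i - 1]:
            states[i: i + 3] = "G"

    # E: hydrogen-bonded bridges (parallel or antiparallel patterns)
    bridge = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 2, n_res - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or anti:
                bridge[i] = bridge[j] = True
    states[bridge] = "E"

    # H: two consecutive 4-turns mark the minimal helix i..i+3
    for i in range(1, n_res):
        if turn4[i] and turn4[i - 1]:
            states[i: i + 4] = "H"

    return "".join(states)


def assign_ss_timeline(traj: Trajectory) -> SSTimeline:
    """Run :func:`assign_ss` on every frame of a trajectory."""
    table = _backbone_table(traj.system)
    residues = np.array([e["residue"] for e in table], dtype=int)
    states = np.empty((traj.n_frames, len(residues)), dtype="U1")
    for f in range(traj.n_frames):
        s = assign_ss(traj.frames[f], traj.system)
        states[f] = list(s)
    return SSTimeline(residue_numbers=residues, times=traj.times.copy(), states=states)


def ss_window_compare(
    timeline_a: SSTimeline,
    timeline_b: SSTimeline,
    residue_range: tuple[int, int] | None = None,
    spec: WindowSpec | None = None,
):
    """Per-window state-fraction comparison of two timelines.

    Returns
    -------
    fractions_a, fractions_b : (W, R, S) arrays
        State occupancy fractions per window/residue/state.
    deltas : (W, R, S) array
        fractions_a - fractions_b.
    flagged : list of (window_index, residue_number)
        Residues whose dominant state differs between the complexes in a
        window.
    """
    spec = spec or WindowSpec()
    if not np.array_equal(timeline_a.residue_numbers, timeline_b.residue_numbers):
        raise SecStructError("timelines cover different residues")
    keep = np.ones(len(timeline_a.residue_numbers), dtype=bool)
    if residue_range is not None:
        lo, hi = residue_range
        keep = (timeline_a.residue_numbers >= lo) & (timeline_a.residue_numbers <= hi)
        if not np.any(keep):
            raise SecStructError(f"no residues in range {residue_range}")

    def _sub(t: SSTimeline) -> SSTimeline:
        return SSTimeline(t.residue_numbers[keep], t.times, t.states[:, keep])

    ta, tb = _sub(timeline_a), _sub(timeline_b)
    fa = ta.window_fractions(spec)
    fb = tb.window_fractions(spec)
    deltas = fa - fb
    flagged = []
    for w in range(spec.n_windows):
        dom_a = np.argmax(fa[w], axis=1)
        dom_b = np.argmax(fb[w], axis=1)
        for k in np.flatnonzero(dom_a != dom_b):
            flagged.append((w, int(ta.residue_numbers[k])))
    return fa, fb, deltas, flagged
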