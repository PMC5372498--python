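"""Structures, trajectories, force-field tables and atom selections.

Internal conventions follow GROMACS units: lengths in nm, times in ps,
energies in kJ/mol, charges in elementary charge units.  PDB I/O converts
between Å (file) and nm (memory).  Atom indices are 0-based internally;
author residue numbering from the PDB is preserved verbatim so that
kinase-domain residues keep their familiar numbers (His1124, Glu1197, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: Amino acids treated as polymer (ATOM) residues on write; everything else
#: is written as HETATM.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)

#: Default intrinsic (GB/SASA) radii per element, nm.  Used when a topology
#: table omits its radius column.
DEFAULT_ELEMENT_RADII_NM = {
    "H": 0.12,
    "C": 0.17,
    "N": 0.155,
    "O": 0.15,
    "S": 0.18,
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed."""


class StructureError(ValueError):
    """Raised on structurally inconsistent input (e.g. model size mismatch)."""


class TopologyError(ValueError):
    """Raised when a topology table does not align with the structure."""


class SelectionError(ValueError):
    """Raised on a malformed selection expression."""


@dataclass(frozen=True)
class Atom:
    """A single atom with author PDB metadata; position in nm."""

    index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.index}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class ForceFieldParams:
    """Per-atom nonbonded parameters plus an optional bond list.

    charge in e, lj_sigma in nm, lj_epsilon in kJ/mol, intrinsic_radius in nm
    (the GB/SASA radius).  All arrays share the atom ordering of the system
    they describe.
    """

    charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    intrinsic_radius: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.intrinsic_radius = np.asarray(self.intrinsic_radius, dtype=float)
        n = len(self.charge)
        for name in ("lj_sigma", "lj_epsilon", "intrinsic_radius"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"{name} length != charge length ({n})")
        if np.any(self.lj_epsilon < 0):
            raise TopologyError("lj_epsilon must be non-negative")
        if np.any(self.intrinsic_radius <= 0):
            raise TopologyError("intrinsic_radius must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)


class MolecularSystem:
    """Atoms of one molecular model plus (optionally) force-field parameters.

    Stores annotations as numpy arrays for vectorised analysis; the
    :attr:`atoms` property materialises :class:`Atom` records on demand.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        params: ForceFieldParams | None = None,
    ):
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray([e.upper() for e in elements], dtype="U2")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.chain_ids = np.asarray(chain_ids, dtype="U2")
        self.positions = np.asarray(positions, dtype=float)
        n = len(self.names)
        if self.positions.shape != (n, 3):
            raise StructureError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates")
        for arr, label in (
            (self.elements, "elements"),
            (self.residue_numbers, "residue_numbers"),
            (self.residue_names, "residue_names"),
            (self.chain_ids, "chain_ids"),
        ):
            if len(arr) != n:
                raise StructureError(f"{label} length != atom count {n}")
        if params is not None and params.n_atoms != n:
            raise TopologyError(
                f"topology has {params.n_atoms} rows for {n} atoms"
            )
        self.params = params

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(i, self.names[i], self.elements[i], int(self.residue_numbers[i]),
                 self.residue_names[i], self.chain_ids[i], self.positions[i])
            for i in range(self.n_atoms)
        ]

    @property
    def residue_index(self) -> dict[int, np.ndarray]:
        """Map author residue number -> sorted atom indices of that residue."""
        index: dict[int, list[int]] = {}
        for i, r in enumerate(self.residue_numbers):
            index.setdefault(int(r), []).append(i)
        return {r: np.asarray(ix, dtype=int) for r, ix in index.items()}

    @property
    def residue_order(self) -> np.ndarray:
        """Residue numbers in order of first appearance."""
        seen, order = set(), []
        for r in self.residue_numbers:
            if int(r) not in seen:
                seen.add(int(r))
                order.append(int(r))
        return np.asarray(order, dtype=int)

    def with_params(self, params: ForceFieldParams) -> "MolecularSystem":
        return MolecularSystem(
            self.names, self.elements, self.residue_numbers, self.residue_names,
            self.chain_ids, self.positions, params,
        )


class Trajectory:
    """Time-ordered coordinate frames (nm) over a fixed atom set."""

    def __init__(self, frames: np.ndarray, times: np.ndarray, system: MolecularSystem):
        self.frames = np.asarray(frames, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.system = system
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.frames.shape[1] != system.n_atoms:
            raise StructureError(
                f"frames have {self.frames.shape[1]} atoms, system has {system.n_atoms}"
            )
        if len(self.times) != self.frames.shape[0]:
            raise StructureError("times length != frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.frames[frame]


@dataclass(frozen=True)
class Selection:
    """A named, sorted, duplicate-free set of 0-based atom indices."""

    label: str
    indices: np.ndarray

    def __post_init__(self):
        ix = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", ix)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, n_atoms: int) -> None:
        if len(self.indices) and (self.indices[0] < 0 or self.indices[-1] >= n_atoms):
            raise SelectionError(
                f"selection '{self.label}' indices outside [0, {n_atoms})"
            )


# ---------------------------------------------------------------------------
# PDB I/O (via biotite; Å in file, nm in memory)
# ---------------------------------------------------------------------------

def read_pdb(source, dt_ps: float = 1.0) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL record (a single frame when there are none).
    HETATM ligand residues are retained.  Alternate locations: 'A' or blank
    kept, others dropped with a warning.  Frame times are ``k * dt_ps`` since
    the PDB format carries no time information.

    Parameters
    ----------
    source
        Path or file-like object with PDB text.
    dt_ps
        Time spacing assigned to successive models, ps.
    """
    try:
        if hasattr(source, "read"):
            pdb_file = pdb.PDBFile.read(source)
        else:
            pdb_file = pdb.PDBFile.read(str(source))
    except Exception as exc:  # biotite raises a range of parse errors
        raise PDBParseError(f"cannot parse PDB input: {exc}") from exc

    altlocs = {
        line[16] for line in pdb_file.lines
        if line.startswith(("ATOM", "HETATM")) and len(line) > 16
    }
    if altlocs - {" ", "A"}:
        logger.warning(
            "dropping alternate locations %s (keeping 'A'/blank)",
            sorted(altlocs - {" ", "A"}),
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = pdb_file.get_structure(model=None, altloc="first")
    except struc.BadStructureError as exc:
        raise StructureError(f"inconsistent models: {exc}") from exc
    except Exception as exc:
        raise PDBParseError(f"cannot parse PDB coordinates: {exc}") from exc

    system = MolecularSystem(
        names=stack.atom_name,
        elements=[e if e else "X" for e in stack.element],
        residue_numbers=stack.res_id,
        residue_names=stack.res_name,
        chain_ids=stack.chain_id,
        positions=stack.coord[0] / ANGSTROM_PER_NM,
    )
    frames = stack.coord / ANGSTROM_PER_NM
    times = np.arange(stack.stack_depth(), dtype=float) * dt_ps
    return Trajectory(frames, times, system)


def write_pdb(traj: Trajectory | MolecularSystem, path) -> None:
    """Write a trajectory (or single system) as a multi-model PDB file."""
    if isinstance(traj, MolecularSystem):
        system = traj
        frames = traj.positions[None, :, :]
    else:
        system = traj.system
        frames = traj.frames

    n = system.n_atoms
    array = struc.AtomArrayStack(frames.shape[0], n)
    array.coord = frames * ANGSTROM_PER_NM
    array.atom_name = system.names
    array.element = system.elements
    array.res_id = system.residue_numbers
    array.res_name = system.residue_names
    array.chain_id = np.where(system.chain_ids == "", "A", system.chain_ids)
    array.set_annotation(
        "hetero",
        np.array([rn not in STANDARD_RESIDUES for rn in system.residue_names]),
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    if hasattr(path, "write"):
        pdb_file.write(path)
    else:
        with open(path, "w") as fh:
            pdb_file.write(fh)


# ---------------------------------------------------------------------------
# Topology tables
# ---------------------------------------------------------------------------

def read_topology(source, system: MolecularSystem | None = None) -> ForceFieldParams:
    """Read the package's TSV force-field table.

    Expected layout: a header line ``index charge sigma epsilon [radius]``
    followed by one whitespace-separated row per atom, plus optional
    ``#bond i j`` lines.  When the radius column is omitted, per-element
    default radii (:data:`DEFAULT_ELEMENT_RADII_NM`) are applied, which
    requires ``system``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()

    header: list[str] | None = None
    rows: list[list[float]] = []
    bonds: list[tuple[int, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").split()
            if parts and parts[0] in ("bond", "bonds"):
                try:
                    bonds.append((int(parts[1]), int(parts[2])))
                except (IndexError, ValueError) as exc:
                    raise TopologyError(f"line {lineno}: malformed bond record") from exc
            continue
        if header is None:
            header = line.split()
            if header[:4] != ["index", "charge", "sigma", "epsilon"]:
                raise TopologyError(
                    "header must start with 'index charge sigma epsilon'"
                )
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise TopologyError(f"line {lineno}: malformed numeric field") from exc

    if header is None:
        raise TopologyError("empty topology table")
    has_radius = "radius" in header
    width = 5 if has_radius else 4
    for i, row in enumerate(rows):
        if len(row) != width:
            raise TopologyError(f"row {i}: expected {width} columns, got {len(row)}")

    data = np.asarray(rows, dtype=float)
    order = np.argsort(data[:, 0].astype(int))
    data = data[order]
    if not np.array_equal(data[:, 0].astype(int), np.arange(len(data))):
        raise TopologyError("index column must cover 0..N-1 exactly")

    if has_radius:
        radius = data[:, 4]
    else:
        if system is None:
            raise TopologyError(
                "radius column missing and no system given for element defaults"
            )
        try:
            radius = np.array(
                [DEFAULT_ELEMENT_RADII_NM[e] for e in system.elements]
            )
        except KeyError as exc:
            raise TopologyError(f"no default radius for element {exc}") from exc

    params = ForceFieldParams(
        charge=data[:, 1], lj_sigma=data[:, 2], lj_epsilon=data[:, 3],
        intrinsic_radius=radius, bonds=bonds,
    )
    if system is not None and params.n_atoms != system.n_atoms:
        raise TopologyError(
            f"topology has {params.n_atoms} rows, structure has {system.n_atoms} atoms"
        )
    return params


def write_topology(params: ForceFieldParams, path) -> None:
    """Write a :class:`ForceFieldParams` as the TSV dialect read_topology reads."""
    lines = ["index\tcharge\tsigma\tepsilon\tradius"]
    for i in range(params.n_atoms):
        lines.append(
            f"{i}\t{params.charge[i]:.6f}\t{params.lj_sigma[i]:.6f}"
            f"\t{params.lj_epsilon[i]:.6f}\t{params.intrinsic_radius[i]:.6f}"
        )
    for i, j in params.bonds:
        lines.append(f"#bond {i} {j}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"backbone", "calpha", "resid", "resname", "chain", "and", "or", "not",
             "all", "protein", "hetero"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelectionParser:
    """Recursive-descent parser for the small selection grammar.

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := "not" factor | "(" expr ")" | primary
    primary:= backbone | calpha | all | protein | hetero
            | resid A[-B] | resname NAME | chain ID
    """

    def __init__(self, system: MolecularSystem, tokens: list[str]):
        self.system = system
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token '{self.peek()}'")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        sys_ = self.system
        tok = self.take()
        if tok == "backbone":
            return np.isin(sys_.names, list(BACKBONE_NAMES)) & np.isin(
                sys_.residue_names, list(STANDARD_RESIDUES)
            )
        if tok == "calpha":
            return (sys_.names == "CA") & np.isin(
                sys_.residue_names, list(STANDARD_RESIDUES)
            )
        if tok == "all":
            return np.ones(sys_.n_atoms, dtype=bool)
        if tok == "protein":
            return np.isin(sys_.residue_names, list(STANDARD_RESIDUES))
        if tok == "hetero":
            return ~np.isin(sys_.residue_names, list(STANDARD_RESIDUES))
        if tok == "resid":
            spec = self.take()
            try:
                if "-" in spec[1:]:  # allow negative single ids
                    head, tail = spec.rsplit("-", 1)
                    lo, hi = int(head), int(tail)
                else:
                    lo = hi = int(spec)
            except ValueError as exc:
                raise SelectionError(f"bad resid range '{spec}'") from exc
            return (sys_.residue_numbers >= lo) & (sys_.residue_numbers <= hi)
        if tok == "resname":
            return sys_.residue_names == self.take()
        if tok == "chain":
            return sys_.chain_ids == self.take()
        raise SelectionError(f"unknown token '{tok}'")


def select(system: MolecularSystem, expression: str) -> Selection:
    """Evaluate a selection expression against a system.

    Grammar: ``backbone | calpha | all | protein | hetero | resid A-B |
    resname XXX | chain X`` combined with ``and``, ``or``, ``not`` and
    parentheses.  Residue numbers are author numbers.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelectionParser(system, tokens).parse()
    return Selection(label=expression, indices=np.flatnonzero(mask))
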