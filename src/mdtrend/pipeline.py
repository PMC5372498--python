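"""Orchestration of the full analysis workflow on a pair of complexes.

Given two trajectories (complex A, the crizotinib-side reference, and
complex B) with topologies, the pipeline runs, in dependency order:
RMSD curves, per-window RMSF profiles and their trend comparison,
per-residue energy decomposition and trend scoring, MM/GBSA binding
energies with relative folds, interface contacts, and secondary-structure
window comparison.  All outputs are TSV/JSON with units in headers;
identical config and inputs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import detect_hbonds, distance_series, hydrophobic_contacts
from .energetics import EPS_OUT, ResidueEnergySeries, mmgbsa, per_residue_decomposition
from .model_io import Trajectory, read_pdb, read_topology, select
from .secstruct import assign_ss_timeline, ss_window_compare
from .superpose import rmsd_series, rmsf, rmsf_difference
from .trend import (
    WindowSpec, average_fold, identify_key_residues, relative_fold, rmsf_trend,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run.

    ``series_a``/``series_b`` optionally point at precomputed per-residue
    energy series (TSV: residue, time_ps, value); when absent the energies
    are decomposed from the trajectories and topologies.
    """

    traj_a: str
    traj_b: str
    topology_a: str | None = None
    topology_b: str | None = None
    series_a: str | None = None
    series_b: str | None = None
    ligand_sel: str = "resname LIG"
    windows: WindowSpec = field(default_factory=WindowSpec)
    frame_dt_ps: float = 8.0
    eps_out: float = EPS_OUT
    sasa_points: int = 960
    mmgbsa_max_frames: int = 5
    run_mmgbsa: bool = True
    ss_residue_range: tuple[int, int] | None = None
    out_dir: str = "mdtrend_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` config file; CLI flags override it."""
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"config line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "windows":
                kwargs[key] = WindowSpec.parse(value)
            elif key == "ss_residue_range":
                lo, hi = value.split("-")
                kwargs[key] = (int(lo), int(hi))
            elif key in ("frame_dt_ps", "eps_out"):
                kwargs[key] = float(value)
            elif key in ("sasa_points", "mmgbsa_max_frames", "seed"):
                kwargs[key] = int(value)
            elif key == "run_mmgbsa":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        # where results land must not change what they contain
        payload = {
            k: (v.windows if isinstance(v, WindowSpec) else v)
            for k, v in sorted(vars(self).items())
            if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Series TSV I/O (residue, time_ps, value — long form)
# ---------------------------------------------------------------------------

def write_series_tsv(series: ResidueEnergySeries, path, component: str = "ele") -> None:
    values = {"ele": series.ele, "vdw": series.vdw, "total": series.total}[component]
    frames = []
    for k, r in enumerate(series.residue_numbers):
        frames.append(pd.DataFrame({
            "residue": int(r),
            "time_ps": series.times,
            "value_kJ_mol": values[k],
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_series_tsv(path) -> ResidueEnergySeries:
    df = pd.read_csv(path, sep="\t")
    residues = np.array(sorted(df["residue"].unique()))
    times = np.array(sorted(df["time_ps"].unique()))
    wide = df.pivot(index="residue", columns="time_ps", values="value_kJ_mol")
    wide = wide.loc[residues, times]
    values = wide.to_numpy()
    return ResidueEnergySeries(
        residue_numbers=residues, times=times,
        ele=values, vdw=np.zeros_like(values),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %-10s %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@dataclass
class AnalysisReport:
    """Everything one run produced, plus provenance."""

    provenance: dict
    rmsd: dict
    rmsf: dict
    trend: dict
    energy: dict
    contacts: dict
    secstruct: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return round(float(o), 6)
            if isinstance(o, np.ndarray):
                return [default(x) if isinstance(x, np.generic) else x
                        for x in o.tolist()]
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(f"not JSON serialisable: {type(o)}")
        return json.dumps(
            {"provenance": self.provenance, "rmsd": self.rmsd, "rmsf": self.rmsf,
             "trend": self.trend, "energy": self.energy, "contacts": self.contacts,
             "secstruct": self.secstruct},
            sort_keys=True, indent=2, default=default,
        )


def _load_complex(tag: str, traj_path, topo_path, dt) -> Trajectory:
    traj = read_pdb(traj_path, dt_ps=dt)
    if topo_path:
        params = read_topology(topo_path, traj.system)
        traj = Trajectory(traj.frames, traj.times, traj.system.with_params(params))
    logger.info("complex %s: %d frames, %d atoms", tag, traj.n_frames, traj.n_atoms)
    return traj


def _window_frame_ranges(traj: Trajectory, spec: WindowSpec):
    times_ns = traj.times / 1000.0
    for a, b in spec.windows:
        ix = np.flatnonzero((times_ns >= a) & (times_ns < b))
        if ix.size < 2:
            raise PipelineError(f"window {a}-{b} ns has < 2 frames")
        yield int(ix[0]), int(ix[-1]) + 1


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute every analysis stage and write TSV/JSON outputs.

    Returns the in-memory :class:`AnalysisReport`; files are written under
    ``config.out_dir`` (created if needed), with ``report.json`` as the
    machine-readable summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.traj_a, config.traj_b):
        if not Path(path).exists():
            raise PipelineError(f"config error: missing input {path}")

    spec = config.windows
    load = _stage("load")(_load_complex)
    traj = {
        "A": load("A", config.traj_a, config.topology_a, config.frame_dt_ps),
        "B": load("B", config.traj_b, config.topology_b, config.frame_dt_ps),
    }
    ligand = {k: select(t.system, config.ligand_sel) for k, t in traj.items()}
    backbone = {k: select(t.system, "backbone") for k, t in traj.items()}

    # --- RMSD -------------------------------------------------------------
    @_stage("rmsd")
    def _rmsd():
        result = {}
        for k, t in traj.items():
            bb = rmsd_series(t, 0, backbone[k], backbone[k])
            lig = rmsd_series(t, 0, backbone[k], ligand[k])
            pd.DataFrame({
                "time_ps": bb.times, "backbone_rmsd_nm": bb.values,
                "ligand_rmsd_nm": lig.values,
            }).to_csv(out / f"rmsd_{k}.tsv", sep="\t", index=False,
                      float_format="%.6f")
            result[k] = {
                "backbone_mean_nm": float(bb.values.mean()),
                "backbone_final_nm": float(bb.values[-1]),
                "ligand_mean_nm": float(lig.values.mean()),
            }
        return result

    # --- RMSF -------------------------------------------------------------
    @_stage("rmsf")
    def _rmsf():
        profiles, windows = {}, {}
        for k, t in traj.items():
            sel = select(t.system, "protein")
            profiles[k] = rmsf(t, sel)
            windows[k] = [
                rmsf(t, sel, frame_range=rng)
                for rng in _window_frame_ranges(t, spec)
            ]
            pd.DataFrame({
                "residue": profiles[k].residue_numbers,
                "rmsf_nm": profiles[k].values,
            }).to_csv(out / f"rmsf_{k}.tsv", sep="\t", index=False,
                      float_format="%.6f")
        deltas, ranked = rmsf_difference(profiles["A"], profiles["B"])
        trend_rep = rmsf_trend(windows["A"], windows["B"], spec)
        trend_rep.to_frame().to_csv(out / "rmsf_trend.tsv", sep="\t", index=False,
                                    float_format="%.6f")
        top = ranked[0]
        return {
            "largest_difference": {"residue": top[0], "delta_nm": top[1]},
            "trend_key_residues": trend_rep.key_residues,
            "per_residue": {
                str(r): {"A_nm": float(a), "B_nm": float(b)}
                for r, a, b in zip(profiles["A"].residue_numbers,
                                   profiles["A"].values, profiles["B"].values)
            },
        }

    # --- energy decomposition + trend -------------------------------------
    @_stage("trend")
    def _trend():
        if config.series_a and config.series_b:
            series = {"A": read_series_tsv(config.series_a),
                      "B": read_series_tsv(config.series_b)}
        else:
            series = {
                k: per_residue_decomposition(t, ligand[k])
                for k, t in traj.items()
            }
        report = identify_key_residues(series["A"], series["B"], spec)
        report.to_frame().to_csv(out / "trend.tsv", sep="\t", index=False,
                                 float_format="%.6f")
        key_folds = {
            str(int(r)): float(f)
            for r, f, flag in zip(report.residue_numbers, report.fold,
                                  report.key_flag)
            if flag
        }
        return {
            "key_residues": report.key_residues,
            "n_key": len(report.key_residues),
            "key_average_folds": key_folds,
        }

    # --- MM/GBSA ----------------------------------------------------------
    @_stage("mmgbsa")
    def _energy():
        if not config.run_mmgbsa:
            return {"skipped": True}
        result = {}
        for k, t in traj.items():
            if t.system.params is None:
                return {"skipped": True, "reason": "no topology provided"}
            receptor = select(t.system, f"not ({config.ligand_sel})")
            stride = max(1, t.n_frames // config.mmgbsa_max_frames)
            sub = Trajectory(t.frames[::stride], t.times[::stride], t.system)
            breakdown, table = mmgbsa(
                sub, receptor, ligand[k], eps_out=config.eps_out,
                n_points=config.sasa_points,
            )
            table.to_csv(out / f"mmgbsa_perframe_{k}.tsv", sep="\t",
                         index=False, float_format="%.6f")
            result[k] = breakdown.as_dict()
        for term in ("dG", "dE_ele"):
            if result["A"][term] != 0:
                result[f"fold_{term}_B_over_A"] = relative_fold(
                    result["A"][term], result["B"][term]).value
        (out / "mmgbsa.json").write_text(
            json.dumps(result, sort_keys=True, indent=2))
        return result

    # --- contacts ---------------------------------------------------------
    @_stage("contacts")
    def _contacts():
        result = {}
        for k, t in traj.items():
            prot = select(t.system, f"not ({config.ligand_sel})")
            hbonds = detect_hbonds(t.frames[0], t.system, ligand[k], prot)
            hydro = hydrophobic_contacts(t.frames[0], t.system, ligand[k], prot)
            pd.DataFrame([
                {"residue": h.residue_number, "residue_name": h.residue_name,
                 "protein_atom": h.protein_atom, "ligand_atom": h.ligand_atom,
                 "distance_A": h.distance} for h in hbonds
            ]).to_csv(out / f"hbonds_{k}.tsv", sep="\t", index=False,
                      float_format="%.3f")
            dist_rows = []
            for resnum in sorted({h.residue_number for h in hbonds}):
                ds = distance_series(t, ligand[k], resnum, spec)
                row = {"residue": resnum, "t0_A": float(ds.values[0])}
                for lab, mean in zip(ds.window_labels, ds.window_means):
                    row[f"{lab}_A"] = float(mean)
                dist_rows.append(row)
            if dist_rows:
                pd.DataFrame(dist_rows).to_csv(
                    out / f"distances_{k}.tsv", sep="\t", index=False,
                    float_format="%.2f")
            result[k] = {
                "hbonds": [
                    {"residue": h.residue_number, "ligand_atom": h.ligand_atom,
                     "distance_A": round(h.distance, 2)} for h in hbonds
                ],
                "hydrophobic_residues": hydro,
                "distances": dist_rows,
            }
        return result

    # --- secondary structure ----------------------------------------------
    @_stage("secstruct")
    def _ss():
        timelines = {k: assign_ss_timeline(t) for k, t in traj.items()}
        try:
            fa, fb, deltas, flagged = ss_window_compare(
                timelines["A"], timelines["B"], config.ss_residue_range, spec)
        except Exception as exc:
            return {"skipped": True, "reason": str(exc)}
        for k, tl in timelines.items():
            with open(out / f"ss_{k}.txt", "w") as fh:
                for f in range(tl.states.shape[0]):
                    fh.write(tl.state_string(f) + "\n")
        return {
            "flagged": [{"window": w, "residue": r} for w, r in flagged],
            "helix_fraction_A": float(np.mean(timelines["A"].states == "H")),
            "helix_fraction_B": float(np.mean(timelines["B"].states == "H")),
        }

    report = AnalysisReport(
        provenance={
            "package": "mdtrend", "version": __version__,
            "config_digest": config.digest(), "seed": config.seed,
            "windows_ns": [list(w) for w in spec.windows],
        },
        rmsd=_rmsd(), rmsf=_rmsf(), trend=_trend(),
        energy=_energy(), contacts=_contacts(), secstruct=_ss(),
    )
    tmp = out / "report.json.tmp"
    tmp.write_text(report.to_json())
    tmp.replace(out / "report.json")
    return report
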