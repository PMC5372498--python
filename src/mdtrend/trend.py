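"""Windowed trend scoring for key-residue identification.

The statistic compares two complexes (A, the crizotinib-side reference,
and B, the lorlatinib-side) over a set of simulation time windows
(default 5-10, 20-25 and 25-30 ns).  For every residue the between-complex
difference of the window-mean observable, c_w = mean_B[w] - mean_A[w], is
reduced to a sign; each adjacent window pair scores +1 when the sign is
conserved (and nonzero) and -1 otherwise.  With three windows the total is
in {-2, 0, +2}, and residues scoring +2 — the difference keeps the same
direction throughout the simulation — are flagged as key residues.

Magnitudes are summarised separately as fold changes |B|/|A| per window,
then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energetics import ResidueEnergySeries
from .superpose import RmsfProfile

#: Default dead-band below which a between-complex delta counts as "no
#: change" (sign 0, never consistent).  In series units (kJ/mol or nm).
DEADBAND = 1e-9


class TrendError(ValueError):
    """Raised on malformed trend-analysis input."""


@dataclass(frozen=True)
class WindowSpec:
    """Time windows in ns, half-open [start, end)."""

    windows: tuple[tuple[float, float], ...] = ((5.0, 10.0), (20.0, 25.0), (25.0, 30.0))

    def __post_init__(self):
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        if len(wins) < 2:
            raise TrendError("need at least 2 windows")
        for a, b in wins:
            if b <= a:
                raise TrendError(f"window ({a}, {b}) is empty or inverted")
        for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
            if a2 < b1:
                raise TrendError("windows must be non-overlapping and increasing")
        object.__setattr__(self, "windows", wins)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def labels(self) -> list[str]:
        return [f"{a:g}-{b:g}ns" for a, b in self.windows]

    @classmethod
    def parse(cls, text: str) -> "WindowSpec":
        """Parse '5-10,20-25,25-30' (ns) into a WindowSpec."""
        wins = []
        for chunk in text.split(","):
            a, b = chunk.strip().split("-")
            wins.append((float(a), float(b)))
        return cls(tuple(wins))


@dataclass(frozen=True)
class FoldChange:
    """Unitless magnitude ratio |numerator| / |denominator|."""

    numerator_label: str
    denominator_label: str
    value: float


@dataclass(frozen=True)
class TrendReport:
    """Per-residue window means, trend scores, key flags and folds."""

    residue_numbers: np.ndarray    # (R,)
    means_A: np.ndarray            # (R, W)
    means_B: np.ndarray            # (R, W)
    deltas: np.ndarray             # (R, W), B - A
    pair_scores: np.ndarray        # (R, W-1), each +-1
    total_score: np.ndarray        # (R,)
    key_flag: np.ndarray           # (R,) bool
    fold: np.ndarray               # (R,) unitless (nan when undefined)
    window_labels: tuple[str, ...] = ()

    @property
    def key_residues(self) -> list[int]:
        return [int(r) for r in self.residue_numbers[self.key_flag]]

    def to_frame(self):
        import pandas as pd

        labels = self.window_labels or tuple(
            f"w{k}" for k in range(self.means_A.shape[1])
        )
        data = {"residue": self.residue_numbers}
        for k, lab in enumerate(labels):
            data[f"mean_A_{lab}"] = self.means_A[:, k]
            data[f"mean_B_{lab}"] = self.means_B[:, k]
            data[f"delta_{lab}"] = self.deltas[:, k]
        for k in range(self.pair_scores.shape[1]):
            data[f"pair_score_{k}"] = self.pair_scores[:, k]
        data["total_score"] = self.total_score
        data["key_residue"] = self.key_flag
        data["fold"] = self.fold
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Window aggregation
# ---------------------------------------------------------------------------

def window_means(
    values: np.ndarray, times_ps: np.ndarray, spec: WindowSpec
) -> np.ndarray:
    """Arithmetic mean of ``values`` within each time window.

    ``values`` is (F,) or (R, F); times are in ps, windows in ns; a frame at
    time t belongs to window (a, b) when a <= t/1000 < b.
    """
    values = np.asarray(values, dtype=float)
    times_ns = np.asarray(times_ps, dtype=float) / 1000.0
    single = values.ndim == 1
    if single:
        values = values[None, :]
    if values.shape[1] != len(times_ns):
        raise TrendError("values and times length mismatch")
    out = np.empty((values.shape[0], spec.n_windows))
    for w, (a, b) in enumerate(spec.windows):
        mask = (times_ns >= a) & (times_ns < b)
        if not np.any(mask):
            raise TrendError(f"window {a}-{b} ns contains no frames")
        out[:, w] = values[:, mask].mean(axis=1)
    return out[0] if single else out


def series_window_means(
    series: ResidueEnergySeries, spec: WindowSpec, component: str = "ele"
) -> np.ndarray:
    """Window means (R, W) of one component of a residue energy series."""
    try:
        values = {"ele": series.ele, "vdw": series.vdw, "total": series.total}[component]
    except KeyError:
        raise TrendError(f"unknown component '{component}'") from None
    return window_means(values, series.times, spec)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _sign(x: np.ndarray, deadband: float) -> np.ndarray:
    s = np.sign(x)
    s[np.abs(x) < deadband] = 0
    return s


def trend_score(
    means_a: Sequence[float],
    means_b: Sequence[float],
    deadband: float = DEADBAND,
) -> tuple[np.ndarray, int]:
    """Sign-consistency score of the between-complex change across windows.

    c_w = means_b[w] - means_a[w].  Each adjacent window pair (w, w+1)
    scores +1 when sign(c_w) = sign(c_{w+1}) != 0 and -1 otherwise
    (a delta inside the dead-band counts as sign 0, never consistent).

    Returns
    -------
    (pair_scores, total) : ((W-1,) int array, int)
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise TrendError("means must be equal-length vectors, W >= 2")
    c = b - a
    s = _sign(c, deadband)
    pair = np.where((s[:-1] == s[1:]) & (s[:-1] != 0), 1, -1)
    return pair, int(pair.sum())


def _score_matrix(deltas: np.ndarray, deadband: float):
    s = _sign(deltas, deadband)
    pair = np.where((s[:, :-1] == s[:, 1:]) & (s[:, :-1] != 0), 1, -1)
    total = pair.sum(axis=1)
    return pair, total


def identify_key_residues(
    series_a: ResidueEnergySeries,
    series_b: ResidueEnergySeries,
    spec: WindowSpec | None = None,
    restrict: Sequence[int] | None = None,
    component: str = "ele",
    deadband: float = DEADBAND,
    mode: str = "between",
) -> TrendReport:
    """Score every residue's energy-change trend and flag key residues.

    A residue is a key residue when the between-complex energy difference
    keeps the same (nonzero) sign across all adjacent window pairs, i.e.
    its total score equals W-1 (+2 for the default three windows).

    Parameters
    ----------
    restrict
        Optional residue-number whitelist (e.g. a binding-site shortlist);
        residues outside it are dropped from the report.
    mode
        'between' (default): sign consistency of the B - A difference
        across window pairs.  'within': sign agreement of the two
        complexes' own window-to-window slopes.
    """
    spec = spec or WindowSpec()
    if not np.array_equal(series_a.residue_numbers, series_b.residue_numbers):
        raise TrendError("series cover different residues")
    means_a = series_window_means(series_a, spec, component)
    means_b = series_window_means(series_b, spec, component)
    return _build_report(
        series_a.residue_numbers, means_a, means_b, spec, restrict, deadband, mode,
        fold_direction="b_over_a",
    )


def _build_report(
    residues, means_a, means_b, spec, restrict, deadband, mode, fold_direction
) -> TrendReport:
    residues = np.asarray(residues, dtype=int)
    if restrict is not None:
        keep = np.isin(residues, np.asarray(list(restrict), dtype=int))
        residues = residues[keep]
        means_a, means_b = means_a[keep], means_b[keep]

    deltas = means_b - means_a
    if mode == "between":
        pair, total = _score_matrix(deltas, deadband)
    elif mode == "within":
        slope_a = np.diff(means_a, axis=1)
        slope_b = np.diff(means_b, axis=1)
        sa, sb = _sign(slope_a, deadband), _sign(slope_b, deadband)
        pair = np.where((sa == sb) & (sa != 0), 1, -1)
        total = pair.sum(axis=1)
    else:
        raise TrendError(f"unknown mode '{mode}'")

    w = means_a.shape[1]
    key = (total == w - 1) & np.all(pair == 1, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if fold_direction == "b_over_a":
            ratios = np.abs(means_b) / np.abs(means_a)
        else:
            ratios = np.abs(means_a) / np.abs(means_b)
    ratios = np.where(np.isfinite(ratios), ratios, np.nan)
    fold = np.nanmean(ratios, axis=1) if ratios.size else np.array([])

    return TrendReport(
        residue_numbers=residues, means_A=means_a, means_B=means_b,
        deltas=deltas, pair_scores=pair, total_score=total, key_flag=key,
        fold=fold, window_labels=tuple(spec.labels()),
    )


def relative_fold(value_a: float, value_b: float, label_a: str = "A",
                  label_b: str = "B") -> FoldChange:
    """Magnitude ratio |value_b| / |value_a| of two energies.

    Convention: A is the reference (crizotinib-side) energy, B the compared
    (lorlatinib-side) one, so a fold > 1 means B is larger in magnitude.
    """
    if value_a == 0:
        raise TrendError("relative_fold: reference value is zero")
    return FoldChange(
        numerator_label=label_b, denominator_label=label_a,
        value=abs(value_b) / abs(value_a),
    )


def average_fold(folds: Sequence[float]) -> float:
    """Arithmetic mean of a collection of fold values."""
    arr = np.asarray([f.value if isinstance(f, FoldChange) else f for f in folds],
                     dtype=float)
    if arr.size == 0:
        raise TrendError("average_fold: empty input")
    if not np.all(np.isfinite(arr)):
        raise TrendError("average_fold: non-finite fold")
    return float(arr.mean())


def rmsf_trend(
    profiles_a: Sequence[RmsfProfile],
    profiles_b: Sequence[RmsfProfile],
    spec: WindowSpec | None = None,
    deadband: float = DEADBAND,
    mode: str = "between",
) -> TrendReport:
    """Trend scoring applied to per-window RMSF profiles of two complexes.

    ``profiles_a[w]`` / ``profiles_b[w]`` are the RMSF profiles of complex
    A and B computed over window w.  The scoring machinery is identical to
    the energy variant; the fold is the window-averaged RMSF_A / RMSF_B
    ratio (complex A, the crizotinib side, in the numerator).
    """
    spec = spec or WindowSpec()
    if len(profiles_a) != spec.n_windows or len(profiles_b) != spec.n_windows:
        raise TrendError("need one RMSF profile per window for each complex")
    residues = profiles_a[0].residue_numbers
    for p in list(profiles_a) + list(profiles_b):
        if not np.array_equal(p.residue_numbers, residues):
            raise TrendError("RMSF profiles cover different residues")
    means_a = np.column_stack([p.values for p in profiles_a])
    means_b = np.column_stack([p.values for p in profiles_b])
    return _build_report(
        residues, means_a, means_b, spec, None, deadband, mode,
        fold_direction="a_over_b",
    )
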