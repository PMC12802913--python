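"""Thermal shift (differential scanning fluorimetry) melt-curve analysis.

Raw dye fluorescence vs temperature is min-max normalized per curve,
differentiated by a forward difference whose value is assigned to the
upper temperature of each interval, and melting temperatures are read
from the peaks of that derivative.  Nucleosome disassembly commonly shows
one or two transitions; replicates are aggregated transition-by-transition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "MeltCurve",
    "DerivativeCurve",
    "TmReport",
    "normalize_curve",
    "derivative_curve",
    "find_tm",
    "aggregate_replicates",
    "read_melt_curves",
    "write_melt_curves",
]


@dataclass
class MeltCurve:
    """Fluorescence vs temperature for one replicate."""

    temperatures: np.ndarray  # degC, strictly ascending
    rfu: np.ndarray
    replicate_id: int = 0
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.temperatures.size < 5:
            raise ValueError("melt curve needs at least 5 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.temperatures.shape != self.rfu.shape:
            raise ValueError("temperatures and rfu must have equal length")


@dataclass
class DerivativeCurve:
    """d(normalized fluorescence)/dT, assigned to the upper temperatures."""

    temperatures: np.ndarray
    values: np.ndarray
    replicate_id: int = 0


@dataclass
class TmReport:
    """Melting temperatures of one replicate, ascending, with prominences."""

    tm: list[float]
    prominence: list[float]
    replicate_id: int = 0


def normalize_curve(curve: MeltCurve) -> MeltCurve:
    """Min-max normalization: (RFU - RFU_min) / (RFU_max - RFU_min)."""
    lo, hi = float(curve.rfu.min()), float(curve.rfu.max())
    if hi <= lo:
        raise ValueError("flat melt curve cannot be normalized")
    return MeltCurve(
        curve.temperatures.copy(),
        (curve.rfu - lo) / (hi - lo),
        curve.replicate_id,
        normalized=True,
        metadata=dict(curve.metadata),
    )


def derivative_curve(norm: MeltCurve, smooth: bool = False) -> DerivativeCurve:
    """Forward difference of the normalized curve, assigned to T_{i+1}.

    The forward difference biases symmetric transitions by about half a
    grid step towards higher temperature; this is inherent to the
    definition and documented rather than corrected.  ``smooth`` applies an
    optional 3-point moving average for noisy data.
    """
    T, f = norm.temperatures, norm.rfu
    if T.size < 2:
        warnings.warn("single-point curve has no derivative", stacklevel=2)
        return DerivativeCurve(np.zeros(0), np.zeros(0), norm.replicate_id)
    d = np.diff(f) / np.diff(T)
    if smooth and d.size >= 3:
        d = np.convolve(d, np.ones(3) / 3.0, mode="same")
    return DerivativeCurve(T[1:], d, norm.replicate_id)


def find_tm(
    deriv: DerivativeCurve, max_peaks: int = 2, min_prominence: float = 0.05
) -> TmReport:
    """Peak temperatures of the derivative = melting temperatures.

    Peaks are ranked by topographic prominence; up to ``max_peaks`` are
    reported in ascending temperature order.  ``min_prominence`` is a
    fraction of the derivative's full range: attenuated transitions below
    it are omitted (some salt conditions render the second disassembly
    step too small to assign a Tm).
    """
    if deriv.values.size == 0:
        raise ValueError("empty derivative curve")
    span = float(deriv.values.max() - deriv.values.min())
    if span <= 0:
        return TmReport([], [], deriv.replicate_id)
    peaks, props = find_peaks(deriv.values, prominence=min_prominence * span)
    if peaks.size == 0:
        return TmReport([], [], deriv.replicate_id)
    order = np.argsort(props["prominences"])[::-1][:max_peaks]
    chosen = np.sort(peaks[order])
    prom_by_peak = dict(zip(peaks, props["prominences"]))
    return TmReport(
        tm=[float(deriv.temperatures[p]) for p in chosen],
        prominence=[float(prom_by_peak[p]) for p in chosen],
        replicate_id=deriv.replicate_id,
    )


def aggregate_replicates(
    reports: list[TmReport], match_window: float = 3.0
) -> pd.DataFrame:
    """Mean +/- sample sd of Tm per transition across replicates.

    Transitions are matched across replicates by nearest-temperature
    pairing within ``match_window`` degC (single-linkage clustering of the
    pooled peak list).  Replicates disagreeing on the transition count
    contribute only to the transitions they detected; sd is NaN for a
    single observation.
    """
    if not reports:
        raise ValueError("need at least one replicate report")
    pooled = sorted(
        (tm, rep.replicate_id) for rep in reports for tm in rep.tm
    )
    clusters: list[list[tuple[float, int]]] = []
    for tm, rid in pooled:
        if clusters and tm - clusters[-1][-1][0] <= match_window:
            clusters[-1].append((tm, rid))
        else:
            clusters.append([(tm, rid)])
    rows = []
    n_reps = len(reports)
    for k, cl in enumerate(clusters):
        values = [tm for tm, _ in cl]
        reps = {rid for _, rid in cl}
        if len(reps) < len(cl):
            warnings.warn(
                f"transition {k + 1}: a replicate contributed multiple peaks "
                "within the match window", stacklevel=2
            )
        rows.append(
            {
                "transition": k + 1,
                "tm_mean": float(np.mean(values)),
                "tm_sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
                "n_replicates": len(reps),
                "in_all_replicates": len(reps) == n_reps,
            }
        )
    return pd.DataFrame(rows)


def read_melt_curves(path) -> list[MeltCurve]:
    """Read a CSV with columns temperature_C, rfu, replicate."""
    df = pd.read_csv(path)
    curves = []
    for rid, grp in df.groupby("replicate"):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                grp["temperature_C"].to_numpy(),
                grp["rfu"].to_numpy(),
                replicate_id=int(rid),
            )
        )
    return curves


def write_melt_curves(curves: list[MeltCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "temperature_C": c.temperatures,
                "rfu": c.rfu,
                "replicate": c.replicate_id,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def analyze_melt(
    curves: list[MeltCurve],
    max_peaks: int = 2,
    min_prominence: float = 0.05,
    smooth: bool = False,
) -> tuple[list[TmReport], pd.DataFrame]:
    """Normalize, differentiate and extract Tm for each replicate, then aggregate."""
    reports = [
        find_tm(derivative_curve(normalize_curve(c), smooth=smooth), max_peaks, min_prominence)
        for c in curves
    ]
    return reports, aggregate_replicates(reports)
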