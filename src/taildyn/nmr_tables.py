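"""Experimental NMR table processing.

Chemical shift perturbations between two peak tables, single-exponential
fitting of intensity-vs-delay relaxation series, and the inversion of the
R2/R1 ratio into an effective rotational correlation time with standard
error propagation:

    CSP:    delta = sqrt((dH)^2 + (0.154*dN)^2)
    decay:  I(t)  = I0 * exp(-R*t)            (two parameters, no offset)
    tau_c:  tau_c = (1/(4*pi*nu_N)) * sqrt(6*R2/R1 - 7)

Peak tables are pandas DataFrames matched by residue_id, never by row
position; prolines and missing peaks carry an explicit missing flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import CSP_NITROGEN_WEIGHT

__all__ = [
    "PeakTable",
    "IntensitySeries",
    "RateFit",
    "TauCResult",
    "csp",
    "fit_decay",
    "tau_c_from_rates",
]

PEAK_COLUMNS = ["residue_id", "residue_name", "shift_H_ppm", "shift_N_ppm", "intensity", "missing_flag"]


@dataclass
class PeakTable:
    """Amide peak table: one row per residue; prolines flagged missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col, default in (
            ("residue_name", ""),
            ("intensity", np.nan),
            ("missing_flag", False),
        ):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in ("residue_id", "shift_H_ppm", "shift_N_ppm") if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if df["residue_id"].duplicated().any():
            dup = df.loc[df["residue_id"].duplicated(), "residue_id"].tolist()
            raise ValueError(f"duplicate residue ids in peak table: {dup}")
        df["missing_flag"] = df["missing_flag"].astype(bool)
        self.data = df[PEAK_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class IntensitySeries:
    """Peak intensity vs relaxation delay for one residue.

    Duplicate delays (e.g. the doubled points of a relaxation series) enter
    the fit as independent observations.
    """

    residue_id: int
    delays: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have equal length")
        if np.unique(self.delays).size < 4:
            raise ValueError("need at least 4 distinct delays to fit a decay")


@dataclass
class RateFit:
    """Fitted relaxation rate with uncertainty."""

    rate: float
    sigma: float
    I0: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    at_boundary: bool = False


@dataclass
class TauCResult:
    """tau_c from R2/R1; undefined (flagged) when the ratio <= 7/6."""

    tau_c: float
    sigma_tau_c: float
    ratio: float
    defined: bool


def csp(a: PeakTable, b: PeakTable, n_weight: float = CSP_NITROGEN_WEIGHT) -> pd.DataFrame:
    """Per-residue combined chemical shift perturbation between two tables.

    delta = sqrt((dH)^2 + (n_weight * dN)^2) with the conventional 15N
    weighting of 0.154.  Residues present in only one table, or flagged
    missing in either (prolines, unobserved peaks), are emitted with
    missing_flag=True and NaN delta rather than dropped.
    """
    merged = a.data.merge(b.data, on="residue_id", how="outer", suffixes=("_a", "_b"), sort=True)
    both = merged["shift_H_ppm_a"].notna() & merged["shift_H_ppm_b"].notna()
    flagged = merged["missing_flag_a"].fillna(True).astype(bool) | merged[
        "missing_flag_b"
    ].fillna(True).astype(bool)
    usable = both & ~flagged
    if not usable.any():
        raise ValueError("no shared, unflagged residues between the two peak tables")
    dH = merged["shift_H_ppm_b"] - merged["shift_H_ppm_a"]
    dN = merged["shift_N_ppm_b"] - merged["shift_N_ppm_a"]
    delta = np.sqrt(dH**2 + (n_weight * dN) ** 2)
    out = pd.DataFrame(
        {
            "residue_id": merged["residue_id"],
            "delta_ppm": np.where(usable, delta, np.nan),
            "missing_flag": ~usable,
        }
    )
    return out.reset_index(drop=True)


def fit_decay(series: IntensitySeries) -> RateFit:
    """Least-squares fit of I(t) = I0 exp(-R t), no offset.

    sigma_R is taken from the fit covariance scaled by the residual
    variance (scipy ``absolute_sigma=False``).  When replicate delays are
    present their scatter contributes to that residual variance, so the
    reported uncertainty reflects the measured repeatability.  A rate that
    converges to ~0 (constant intensities) is flagged ``at_boundary``.
    """
    t, I = series.delays, series.intensities
    if np.any(I <= 0):
        raise ValueError("intensities must be positive for exponential fitting")
    # log-linear start values
    slope, intercept = np.polyfit(t, np.log(I), 1)
    r0 = max(-slope, 1e-9)
    i0 = math.exp(intercept)

    def model(t, i0, r):
        return i0 * np.exp(-r * t)

    try:
        popt, pcov = curve_fit(
            model, t, I, p0=(i0, r0), bounds=((0, 0), (np.inf, np.inf)), maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit did not converge for residue {series.residue_id}; "
            f"delays={t.tolist()}, intensities={I.tolist()}"
        ) from exc
    i0_fit, rate = popt
    sigma = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    resid = I - model(t, *popt)
    at_boundary = rate < 1e-8 * max(1.0, 1.0 / (t.max() - t.min()))
    return RateFit(rate=float(rate), sigma=sigma, I0=float(i0_fit), residuals=resid, at_boundary=at_boundary)


def tau_c_from_rates(R1: RateFit, R2: RateFit, nu_N: float) -> TauCResult:
    """Invert the R2/R1 ratio into an effective correlation time.

    tau_c = (1/(4 pi nu_N)) sqrt(6 R2/R1 - 7).  Uncertainties propagate
    first to the ratio, sigma_ratio = ratio*sqrt((sR2/R2)^2 + (sR1/R1)^2),
    then sigma_tau = 3*sigma_ratio / (4 pi nu_N sqrt(6 ratio - 7)).
    Ratios <= 7/6 give an undefined (flagged) result, not an exception.
    """
    if R1.rate <= 0:
        raise ValueError("R1 must be positive")
    ratio = R2.rate / R1.rate
    if ratio <= 7.0 / 6.0:
        if math.isclose(ratio, 7.0 / 6.0, rel_tol=0, abs_tol=1e-12):
            return TauCResult(tau_c=0.0, sigma_tau_c=0.0, ratio=ratio, defined=True)
        return TauCResult(tau_c=float("nan"), sigma_tau_c=float("nan"), ratio=ratio, defined=False)
    radicand = 6.0 * ratio - 7.0
    tau_c = math.sqrt(radicand) / (4.0 * math.pi * nu_N)
    rel1 = (R1.sigma / R1.rate) if R1.rate else 0.0
    rel2 = (R2.sigma / R2.rate) if R2.rate else 0.0
    sigma_ratio = ratio * math.sqrt(rel1**2 + rel2**2)
    sigma_tau = 3.0 * sigma_ratio / (4.0 * math.pi * nu_N * math.sqrt(radicand))
    return TauCResult(tau_c=tau_c, sigma_tau_c=sigma_tau, ratio=ratio, defined=True)


def read_intensity_series(path) -> list[IntensitySeries]:
    """Read a long-format CSV (residue, delay_s, intensity) into series."""
    df = pd.read_csv(path)
    out = []
    for rid, grp in df.groupby("residue"):
        out.append(
            IntensitySeries(
                residue_id=int(rid),
                delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
            )
        )
    return out
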