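"""NMR spin-relaxation observables from bond-vector trajectories.

The chain implemented here turns a per-residue time series of N-H unit
vectors (with the overall tumbling removed by superposition) into R1, R2,
heteronuclear NOE and an effective rotational correlation time tau_c:

1. ``p2_autocorrelation``  — chunk-averaged orientational autocorrelation
   C(t) = <P2(u(t) . u(t+tau))>, with P2 the second Legendre polynomial.
2. ``fit_triexponential`` — constrained multi-exponential fit of C(t).
3. ``apply_tumbling``     — reintroduce overall tumbling by multiplying
   C(t) with exp(-t/tau_rot), i.e. 1/tau_eff = 1/tau_i + 1/tau_rot, and
   form the analytic spectral density
   J(w) = (2/5) * sum_i A_i * tau_eff_i / (1 + (w*tau_eff_i)^2).
4. ``relaxation_rates``   — standard dipolar + CSA expressions for R1, R2
   and NOE at the given field.
5. ``residue_tau_c``      — invert R2/R1 into tau_c.

The analytic transform of the fitted exponentials is the primary path to
J(w); ``spectral_density_fft`` provides a diagnostic numerical transform
of the raw correlation function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .constants import SpinSystemConstants

__all__ = [
    "VectorSeries",
    "CorrelationFunction",
    "TriExpFit",
    "SpectralDensityModel",
    "RelaxationRecord",
    "p2_autocorrelation",
    "fit_triexponential",
    "apply_tumbling",
    "spectral_density_fft",
    "relaxation_rates",
    "residue_tau_c",
    "compare_to_experiment",
]


@dataclass
class VectorSeries:
    """Time series of unit bond vectors for one residue.

    vectors are (n_frames, 3) and must be normalized; dt is the frame
    spacing in seconds.
    """

    residue_id: int
    vectors: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n_frames, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("vectors must be unit length to within 1e-6")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


@dataclass
class CorrelationFunction:
    """Chunk-averaged orientational autocorrelation C(t).

    lags in seconds; values dimensionless with C(0) = 1; stderr is the
    standard error across chunks (zero-length chunks axis -> NaN).
    """

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_chunks: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass
class TriExpFit:
    """Constrained sum-of-exponentials representation of C(t).

    C(t) = sum_i A_i exp(-t/tau_i) with A_i >= 0, sum A_i <= 1 and taus
    sorted ascending.  ``deficit`` = 1 - sum(A) is reported as an
    unresolved fast component.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    residual_norm: float
    deficit: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        order = np.argsort(self.taus)
        self.taus = self.taus[order]
        self.amplitudes = self.amplitudes[order]
        if np.any(self.amplitudes < -1e-9) or np.any(self.taus <= 0):
            raise ValueError("amplitudes must be >= 0 and taus > 0")
        if self.amplitudes.sum() > 1.0 + 1e-6:
            raise ValueError("sum of amplitudes exceeds 1")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        )


@dataclass
class SpectralDensityModel:
    """Analytic multi-Lorentzian spectral density.

    J(w) = (2/5) * sum_i A_i * tau_eff_i / (1 + (w*tau_eff_i)^2), where
    1/tau_eff_i = 1/tau_i + 1/tau_rot.
    """

    amplitudes: np.ndarray
    tau_eff: np.ndarray
    tau_rot: float

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.tau_eff = np.asarray(self.tau_eff, dtype=float)

    @classmethod
    def rigid_rotor(cls, tau: float) -> "SpectralDensityModel":
        """Single-Lorentzian J for a rigid isotropic rotor with time tau."""
        return cls(np.array([1.0]), np.array([tau]), tau_rot=tau)

    def J(self, omega: float | np.ndarray) -> float | np.ndarray:
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        out = 0.4 * np.sum(
            self.amplitudes[:, None]
            * self.tau_eff[:, None]
            / (1.0 + (omega[None, :] * self.tau_eff[:, None]) ** 2),
            axis=0,
        )
        return float(out[0]) if out.shape == (1,) else out


@dataclass
class RelaxationRecord:
    """Per-residue relaxation observables (computed or experimental)."""

    residue_id: int | None
    R1: float
    R2: float
    NOE: float | None
    tau_c: float | None = None
    sigma_R1: float = 0.0
    sigma_R2: float = 0.0
    sigma_NOE: float = 0.0
    sigma_tau_c: float = 0.0
    noe_defined: bool = True
    tau_c_defined: bool = True


def _p2_autocorr_fft(vectors: np.ndarray, max_lag: int) -> np.ndarray:
    """Exact P2 autocorrelation of one chunk via FFT.

    Uses P2(u.v) = (3/2)(u.v)^2 - 1/2 and expands the squared dot product
    into the 9 component products q_ab(t) = u_a(t)u_b(t), whose linear
    autocorrelations are computed with zero-padded FFTs.
    """
    n = vectors.shape[0]
    nfft = sp_fft.next_fast_len(2 * n)
    total = np.zeros(max_lag + 1)
    for a in range(3):
        for b in range(3):
            q = vectors[:, a] * vectors[:, b]
            f = sp_fft.rfft(q, nfft)
            ac = sp_fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
            total += ac
    counts = n - np.arange(max_lag + 1)
    return 1.5 * total / counts - 0.5


def p2_autocorrelation(
    series: VectorSeries,
    n_chunks: int = 20,
    max_lag_fraction: float = 0.5,
) -> CorrelationFunction:
    """Chunk-averaged P2 orientational autocorrelation function.

    The trajectory is split into ``n_chunks`` equal-length segments; C(t)
    is computed per segment over all valid time origins, averaged across
    segments, and the across-segment standard error is reported.  Lags are
    limited to ``max_lag_fraction`` of the segment length.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    n = series.n_frames
    if n < 2 * n_chunks:
        raise ValueError(f"need at least {2 * n_chunks} frames for {n_chunks} chunks")
    chunk_len = n // n_chunks
    max_lag = int(max_lag_fraction * (chunk_len - 1))
    if max_lag < 1:
        raise ValueError(
            f"chunk length {chunk_len} too short for requested max lag fraction"
        )
    per_chunk = np.empty((n_chunks, max_lag + 1))
    for k in range(n_chunks):
        seg = series.vectors[k * chunk_len : (k + 1) * chunk_len]
        per_chunk[k] = _p2_autocorr_fft(seg, max_lag)
    values = per_chunk.mean(axis=0)
    if n_chunks > 1:
        stderr = per_chunk.std(axis=0, ddof=1) / math.sqrt(n_chunks)
    else:
        stderr = np.full(max_lag + 1, np.nan)
    lags = np.arange(max_lag + 1) * series.dt
    return CorrelationFunction(lags, values, stderr, n_chunks)


class TriExpFitError(RuntimeError):
    """Raised when no multi-start converges; carries diagnostics."""


def _merge_close_components(amps: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge components whose time constants differ by < 1.5x.

    Near-degenerate exponentials are not identifiable; merging yields a
    canonical minimal representation (amplitude-weighted geometric-mean tau).
    """
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    merged_a: list[float] = []
    merged_t: list[float] = []
    for a, t in zip(amps, taus):
        if merged_t and t / merged_t[-1] < 1.5:
            a0, t0 = merged_a[-1], merged_t[-1]
            tot = a0 + a
            merged_t[-1] = math.exp((a0 * math.log(t0) + a * math.log(t)) / tot) if tot > 0 else t
            merged_a[-1] = tot
        else:
            merged_a.append(float(a))
            merged_t.append(float(t))
    return np.array(merged_a), np.array(merged_t)


def fit_triexponential(
    corr: CorrelationFunction,
    n_components: int = 3,
    amplitude_floor: float = 1e-4,
) -> TriExpFit:
    """Fit C(t) with up to three exponentials under physical constraints.

    Nonlinear least squares with A_i >= 0, sum A_i <= 1 (soft-constrained,
    then verified) and tau_i > 0.  Multiple starts from log-spaced initial
    time constants; the best start by residual wins, ties broken by the
    smallest sum |log tau_i|.  Components with amplitude below
    ``amplitude_floor`` are pruned; near-degenerate ones merged.
    """
    t = corr.lags
    y = corr.values
    if t.size < 10:
        raise ValueError("need at least 10 lag points to fit")
    finite_se = corr.stderr[np.isfinite(corr.stderr) & (corr.stderr > 0)]
    if finite_se.size >= t.size // 2:
        floor = np.median(finite_se) * 1e-3
        w = 1.0 / np.clip(np.nan_to_num(corr.stderr, nan=np.inf), max(floor, 1e-12), np.inf)
        w = np.clip(w, 0, np.median(w[w > 0]) * 100 if np.any(w > 0) else 1.0)
        if not np.all(np.isfinite(w)) or w.max() == 0:
            w = np.ones_like(y)
    else:
        w = np.ones_like(y)
    w = w / w.max()

    tmax = t[-1] if t[-1] > 0 else 1.0
    tmin = max(t[1] if t.size > 1 else tmax / 100, tmax * 1e-6)
    lo_log, hi_log = math.log10(tmin / 10), math.log10(tmax * 1e6)

    def residuals(p: np.ndarray) -> np.ndarray:
        amps = p[:n_components]
        taus = 10.0 ** p[n_components:]
        model = np.sum(amps[:, None] * np.exp(-t[None, :] / taus[None, :].T), axis=0)
        res = w * (model - y)
        penalty = 1e3 * max(0.0, amps.sum() - 1.0)
        return np.append(res, penalty)

    starts = []
    for scale in (0.01, 0.1, 1.0, 10.0, 1000.0):
        taus0 = np.geomspace(max(tmin, tmax * scale / 100), tmax * scale, n_components)
        starts.append(np.clip(np.log10(taus0), lo_log + 0.01, hi_log - 0.01))

    best = None
    diagnostics = []
    for logtau0 in starts:
        p0 = np.concatenate([np.full(n_components, 1.0 / n_components), logtau0])
        lb = np.concatenate([np.zeros(n_components), np.full(n_components, lo_log)])
        ub = np.concatenate([np.full(n_components, 1.0), np.full(n_components, hi_log)])
        try:
            sol = least_squares(residuals, p0, bounds=(lb, ub), max_nfev=2000)
        except Exception as exc:  # pragma: no cover - scipy rarely raises here
            diagnostics.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            diagnostics.append("non-finite solution")
            continue
        cost = float(np.sum(sol.fun[:-1] ** 2))
        tie = float(np.sum(np.abs(sol.x[n_components:])))
        key = (round(cost, 12), tie)
        if best is None or key < best[0]:
            best = (key, sol, cost)
    if best is None:
        raise TriExpFitError(f"no start converged; diagnostics: {diagnostics}")

    _, sol, cost = best
    amps = sol.x[:n_components]
    taus = 10.0 ** sol.x[n_components:]
    total = amps.sum()
    if total > 1.0:  # numerically enforce the soft constraint
        amps = amps / total * min(total, 1.0)
    # Components slower than the observation window are only constrained by
    # the (chunk-correlated) tail of C(t); keep them only when their
    # amplitude is significant against the tail uncertainty, otherwise they
    # inflate J(0) with pure noise.
    if finite_se.size >= t.size // 2:
        tail_se = float(np.nanmedian(corr.stderr[3 * t.size // 4 :]))
        beyond = taus > t[-1] / 2
        amps = np.where(beyond & (amps < 2.0 * tail_se), 0.0, amps)
    keep = amps >= amplitude_floor
    if not np.any(keep):
        keep = amps == amps.max()
    amps, taus = _merge_close_components(amps[keep], taus[keep])
    deficit = max(0.0, 1.0 - float(amps.sum()))
    return TriExpFit(amps, taus, residual_norm=math.sqrt(cost), deficit=deficit)


def apply_tumbling(fit: TriExpFit, tau_rot: float) -> SpectralDensityModel:
    """Reintroduce overall tumbling: multiply C(t) by exp(-t/tau_rot).

    Each internal time combines as 1/tau_eff = 1/tau_i + 1/tau_rot
    (amplitudes unchanged).  ``tau_rot=inf`` leaves internal motion only.
    """
    if not tau_rot > 0:
        raise ValueError("tau_rot must be positive")
    inv = 1.0 / fit.taus + (0.0 if math.isinf(tau_rot) else 1.0 / tau_rot)
    with np.errstate(divide="ignore"):
        tau_eff = np.where(inv > 0, 1.0 / inv, np.inf)
    return SpectralDensityModel(fit.amplitudes.copy(), tau_eff, tau_rot)


def spectral_density_fft(corr: CorrelationFunction, tau_rot: float = math.inf):
    """Diagnostic numerical J(w) from the raw C(t) via cosine transform.

    Returns (omega, J) arrays.  J(w) = (2/5) * 2 * Int_0^T C(t) cos(wt) dt
    evaluated by the trapezoid rule on the available lags after multiplying
    by the tumbling factor exp(-t/tau_rot).  Truncation at the maximum lag
    makes this a diagnostic, not the primary path to the rate formulas.
    """
    t = corr.lags
    c = corr.values * (np.exp(-t / tau_rot) if np.isfinite(tau_rot) else 1.0)
    dt = t[1] - t[0]
    n = t.size
    omega = 2.0 * math.pi * np.fft.rfftfreq(2 * n, d=dt)
    J = np.array(
        [0.4 * 2.0 * np.trapezoid(c * np.cos(w * t), t) for w in omega]
    )
    return omega, J


def relaxation_rates(
    J: SpectralDensityModel,
    constants: SpinSystemConstants | None = None,
    residue_id: int | None = None,
    include_high_frequency: bool = True,
) -> RelaxationRecord:
    """R1, R2 and NOE from a spectral density model.

    Standard dipolar + CSA expressions with d = (mu0/4pi) hbar gammaH gammaN
    / r_NH^3 and c = omegaN * delta_sigma / sqrt(3):

        R1 = (d^2/4)[J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)
        R2 = (d^2/8)[4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
             + (c^2/6)[4 J(0) + 3 J(wN)]
        NOE = 1 + (d^2/4)(gammaH/gammaN)[6 J(wH+wN) - J(wH-wN)] / R1

    ``include_high_frequency=False`` zeroes J(wH-wN), J(wH) and J(wH+wN);
    in that limit inverting R2/R1 for tau_c is an exact algebraic identity.
    """
    if constants is None:
        constants = SpinSystemConstants()
    wH, wN = constants.omega_H, constants.omega_N
    d2 = constants.dipolar_constant**2
    c2 = constants.csa_constant**2
    j0 = J.J(0.0)
    jN = J.J(wN)
    if include_high_frequency:
        j_hmn = J.J(abs(wH - wN))
        j_h = J.J(wH)
        j_hpn = J.J(wH + wN)
    else:
        j_hmn = j_h = j_hpn = 0.0
    R1 = (d2 / 4.0) * (j_hmn + 3.0 * jN + 6.0 * j_hpn) + c2 * jN
    R2 = (d2 / 8.0) * (4.0 * j0 + j_hmn + 3.0 * jN + 6.0 * j_h + 6.0 * j_hpn) + (
        c2 / 6.0
    ) * (4.0 * j0 + 3.0 * jN)
    if R1 > 0:
        noe = 1.0 + (d2 / 4.0) * (constants.gamma_H / constants.gamma_N) * (
            6.0 * j_hpn - j_hmn
        ) / R1
        noe_defined = True
    else:
        noe = None
        noe_defined = False
    return RelaxationRecord(
        residue_id=residue_id,
        R1=float(R1),
        R2=float(R2),
        NOE=noe,
        noe_defined=noe_defined,
    )


def residue_tau_c(
    record: RelaxationRecord, constants: SpinSystemConstants | None = None
) -> RelaxationRecord:
    """Effective rotational correlation time from R2/R1 for one record.

    Delegates to :func:`taildyn.nmr_tables.tau_c_from_rates`; ratios at or
    below 7/6 yield an undefined-tau_c flag rather than an exception.
    """
    from .nmr_tables import RateFit, tau_c_from_rates

    if constants is None:
        constants = SpinSystemConstants()
    res = tau_c_from_rates(
        RateFit(rate=record.R1, sigma=record.sigma_R1),
        RateFit(rate=record.R2, sigma=record.sigma_R2),
        nu_N=constants.nu_N_hz,
    )
    record.tau_c = res.tau_c if res.defined else None
    record.sigma_tau_c = res.sigma_tau_c
    record.tau_c_defined = res.defined
    return record


def compare_to_experiment(
    computed: dict[int, float], measured: dict[int, float]
):
    """Pairwise comparison of per-residue values (e.g. tau_c) with Pearson r.

    Residues missing from either side are excluded pairwise.  Returns a
    dict with 'residues', 'computed', 'measured', 'delta' arrays and the
    Pearson correlation 'r'.  Fewer than 3 shared residues is an error.
    """
    shared = sorted(set(computed) & set(measured))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared residues; need at least 3")
    x = np.array([computed[r] for r in shared], dtype=float)
    y = np.array([measured[r] for r in shared], dtype=float)
    r, _ = pearsonr(x, y)
    return {
        "residues": shared,
        "computed": x,
        "measured": y,
        "delta": x - y,
        "r": float(r),
    }
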