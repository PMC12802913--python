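"""Synthetic inputs with known ground truth for every pipeline stage.

Generators (all seeded, no global random state):

* unit bond vectors under isotropic rotational diffusion — the P2
  autocorrelation decays as exp(-t/tau_c), the oracle for the relaxometry
  chain;
* unit vectors restricted to a cone — implemented as a uniform-in-cap jump
  process whose correlation function is exactly
  C(t) = S^2 + (1 - S^2) exp(-t/tau_internal), with the wobbling-in-a-cone
  order parameter S = cos(theta0) (1 + cos(theta0)) / 2;
* two-state Markov bound/unbound timelines with known on/off rates;
* a toy pseudo-atom nucleosome (static DNA bead lattice + tail chain)
  whose scripted bound/unbound state is recoverable exactly by the contact
  pipeline;
* sigmoidal one- or two-transition melt curves with Gaussian noise;
* paired amide peak tables with prescribed chemical shift perturbations.

Ground-truth parameters are embedded in output metadata so tests never
re-derive them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import BoundStateSeries
from .melt import MeltCurve
from .nmr_tables import PeakTable
from .relaxometry import VectorSeries
from .trajectory import AtomRecord, Trajectory

__all__ = [
    "RotDiffSpec",
    "ConeSpec",
    "TwoStateSpec",
    "MeltSpec",
    "cone_order_parameter",
    "gen_rotdiff_vectors",
    "gen_cone_vectors",
    "gen_two_state_timeline",
    "gen_toy_nucleosome_traj",
    "gen_melt_curve",
    "gen_peak_tables",
]


@dataclass(frozen=True)
class RotDiffSpec:
    """Isotropic rotational diffusion of a unit vector.

    tau_c and dt in seconds; the angular diffusion coefficient is
    D = 1/(6 tau_c) so that <P2(u(0).u(t))> = exp(-t/tau_c).
    tau_c = inf means a static vector.
    """

    tau_c: float
    dt: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError("tau_c must be positive (inf allowed)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass(frozen=True)
class ConeSpec:
    """Restricted (cone) internal motion about a fixed axis.

    half_angle in degrees in (0, 90]; tau_internal and dt in seconds.
    """

    half_angle: float
    tau_internal: float
    dt: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.half_angle <= 90:
            raise ValueError("half_angle must be in (0, 90] degrees")
        if not self.tau_internal > 0 or not self.dt > 0:
            raise ValueError("tau_internal and dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass(frozen=True)
class TwoStateSpec:
    """Two-state Markov binding with rates per second; dt in seconds."""

    k_on: float
    k_off: float
    dt: float
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.k_on + self.k_off == 0:
            raise ValueError("rates must be >= 0 and not both zero")
        if not self.dt > 0 or self.n_frames < 2:
            raise ValueError("dt must be positive and n_frames >= 2")


@dataclass(frozen=True)
class MeltSpec:
    """Sum-of-logistic melt curve: transitions are (Tm degC, width degC, amplitude)."""

    transitions: tuple
    T_start: float = 25.0
    T_end: float = 95.0
    T_step: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_step <= 0:
            raise ValueError("T_step must be positive")
        for tm, w, a in self.transitions:
            if w <= 0 or a < 0:
                raise ValueError("transition widths must be > 0 and amplitudes >= 0")
        tms = sorted(tm for tm, _, _ in self.transitions)
        for a, b in zip(tms, tms[1:]):
            if b - a < 2 * self.T_step:
                warnings.warn(
                    f"transitions at {a} and {b} degC are closer than twice the "
                    "grid step; their derivative peaks may merge", stacklevel=2
                )


def cone_order_parameter(half_angle_deg: float) -> float:
    """Wobbling-in-a-cone generalized order parameter
    S = cos(theta0) (1 + cos(theta0)) / 2."""
    c = math.cos(math.radians(half_angle_deg))
    return c * (1.0 + c) / 2.0


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_rotdiff_vectors(spec: RotDiffSpec) -> VectorSeries:
    """Rotational random walk with the isotropic-diffusion P2 decay.

    Each step rotates the vector about a uniformly random perpendicular
    axis by an angle drawn from N(0, sqrt(4 D dt)), D = 1/(6 tau_c), then
    renormalizes — the correct small-step diffusion limit.  Refuses grids
    so coarse that the per-step angular variance 4 D dt exceeds 0.1 rad^2.
    """
    rng = np.random.default_rng(spec.seed)
    u0 = _random_unit_vector(rng)
    n = spec.n_frames
    if math.isinf(spec.tau_c):
        vectors = np.tile(u0, (n, 1))
        return VectorSeries(0, vectors, spec.dt, {"tau_c": spec.tau_c, "seed": spec.seed})
    D = 1.0 / (6.0 * spec.tau_c)
    step_var = 4.0 * D * spec.dt
    if step_var > 0.1:
        raise ValueError(
            f"dt too coarse: per-step angular variance {step_var:.3f} rad^2 > 0.1; "
            "reduce dt below 0.15*tau_c"
        )
    sigma = math.sqrt(step_var)
    alphas = rng.normal(0.0, sigma, n - 1)
    phis = rng.uniform(0.0, 2.0 * math.pi, n - 1)
    vectors = np.empty((n, 3))
    ux, uy, uz = u0
    vectors[0] = (ux, uy, uz)
    cos_a = np.cos(alphas)
    sin_a = np.sin(alphas)
    cos_p = np.cos(phis)
    sin_p = np.sin(phis)
    for i in range(n - 1):
        # orthonormal basis perpendicular to u
        if abs(uz) < 0.9:
            e1x, e1y, e1z = -uy, ux, 0.0
        else:
            e1x, e1y, e1z = 0.0, -uz, uy
        inv = 1.0 / math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x *= inv; e1y *= inv; e1z *= inv
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        # u' = cos(a) u + sin(a) m, with m uniform in the perpendicular plane
        mx = cos_p[i] * e1x + sin_p[i] * e2x
        my = cos_p[i] * e1y + sin_p[i] * e2y
        mz = cos_p[i] * e1z + sin_p[i] * e2z
        ux = cos_a[i] * ux + sin_a[i] * mx
        uy = cos_a[i] * uy + sin_a[i] * my
        uz = cos_a[i] * uz + sin_a[i] * mz
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux *= inv; uy *= inv; uz *= inv
        vectors[i + 1] = (ux, uy, uz)
    return VectorSeries(
        0, vectors, spec.dt, {"tau_c": spec.tau_c, "seed": spec.seed}
    )


def _uniform_in_cap(rng: np.random.Generator, cos_theta0: float, size: int) -> np.ndarray:
    """Uniform samples on the spherical cap around +z with cos(theta) >= cos_theta0."""
    c = rng.uniform(cos_theta0, 1.0, size)
    phi = rng.uniform(0.0, 2.0 * math.pi, size)
    s = np.sqrt(1.0 - c**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


def gen_cone_vectors(spec: ConeSpec) -> VectorSeries:
    """Unit vectors confined to a cone about +z.

    Jump dynamics: at each frame the orientation is resampled uniformly
    within the cap with probability 1 - exp(-dt/tau_internal), otherwise
    retained.  The resulting correlation function is exactly
    C(t) = S^2 + (1 - S^2) exp(-t/tau_internal), so the long-time plateau
    is the squared order parameter S^2.
    """
    rng = np.random.default_rng(spec.seed)
    cos0 = math.cos(math.radians(spec.half_angle))
    n = spec.n_frames
    p_jump = 1.0 - math.exp(-spec.dt / spec.tau_internal)
    jumps = rng.random(n) < p_jump
    jumps[0] = True  # initial orientation is the zeroth sample
    group = np.cumsum(jumps) - 1
    samples = _uniform_in_cap(rng, cos0, int(group[-1]) + 1)
    vectors = samples[group]
    S = cone_order_parameter(spec.half_angle)
    return VectorSeries(
        0,
        vectors,
        spec.dt,
        {
            "half_angle": spec.half_angle,
            "tau_internal": spec.tau_internal,
            "S": S,
            "S2": S * S,
            "seed": spec.seed,
        },
    )


def gen_two_state_timeline(spec: TwoStateSpec) -> BoundStateSeries:
    """Two-state Markov chain with per-step switching probability 1-exp(-k dt).

    Dwell lengths are geometric; the stationary bound fraction is
    k_on/(k_on + k_off).  Times in the returned series are nanoseconds.
    """
    rng = np.random.default_rng(spec.seed)
    p_on = 1.0 - math.exp(-spec.k_on * spec.dt)
    p_off = 1.0 - math.exp(-spec.k_off * spec.dt)
    p_bound = spec.k_on / (spec.k_on + spec.k_off)
    n = spec.n_frames
    bound = np.empty(n, dtype=bool)
    state = bool(rng.random() < p_bound)
    pos = 0
    while pos < n:
        p_leave = p_off if state else p_on
        dwell = int(rng.geometric(p_leave)) if p_leave > 0 else n - pos
        dwell = min(dwell, n - pos)
        bound[pos : pos + dwell] = state
        pos += dwell
        state = not state
    dt_ns = spec.dt * 1e9
    return BoundStateSeries(
        frame_times=np.arange(n) * dt_ns,
        bound=bound,
        metadata={
            "k_on": spec.k_on,
            "k_off": spec.k_off,
            "dt_s": spec.dt,
            "seed": spec.seed,
            "stationary_bound_fraction": p_bound,
        },
    )


def gen_toy_nucleosome_traj(
    timeline: BoundStateSeries, n_tail_beads: int = 12, seed: int = 0
) -> Trajectory:
    """Pseudo-atom tail + DNA system realizing a scripted binding timeline.

    A static lattice of DNA phosphate beads (chain D) lies along x; a tail
    chain (chain A) of one bead per residue sits either with ~30% of its
    beads within 4 Angstrom of DNA (bound frames) or entirely beyond
    6 Angstrom (unbound frames), with margins that make the contact
    pipeline's recovered state equal to the scripted state on every frame.
    The scripted states are stored in trajectory metadata.
    """
    if n_tail_beads < 10:
        raise ValueError(
            "n_tail_beads must be >= 10: the 10% unbound threshold is too "
            "coarse for fewer residues"
        )
    rng = np.random.default_rng(seed)
    n_frames = timeline.bound.size
    if n_frames == 0:
        raise ValueError("timeline is empty")
    n_dna = n_tail_beads + 4
    spacing = 6.0
    atoms: list[AtomRecord] = []
    for i in range(n_dna):
        atoms.append(
            AtomRecord(atom_id=i + 1, name="P", element="P", residue_id=i + 1,
                       residue_name="DA", chain_id="D", mass=30.974)
        )
    for i in range(n_tail_beads):
        atoms.append(
            AtomRecord(atom_id=n_dna + i + 1, name="CA", element="C",
                       residue_id=i + 1, residue_name="BEA", chain_id="A", mass=12.011)
        )
    dna_xyz = np.column_stack(
        [np.arange(n_dna) * spacing, np.zeros(n_dna), np.zeros(n_dna)]
    )
    n_contact = max(math.floor(0.1 * n_tail_beads) + 1, math.ceil(0.3 * n_tail_beads))
    tail_x = (np.arange(n_tail_beads) + 2) * spacing
    coords = np.empty((n_frames, n_dna + n_tail_beads, 3))
    coords[:, :n_dna, :] = dna_xyz
    jitter = rng.uniform(-0.3, 0.3, size=(n_frames, n_tail_beads))
    for f in range(n_frames):
        y = np.full(n_tail_beads, 8.0)
        if timeline.bound[f]:
            y[:n_contact] = 3.0
        coords[f, n_dna:, 0] = tail_x
        coords[f, n_dna:, 1] = y + jitter[f]
        coords[f, n_dna:, 2] = 0.0
    if timeline.frame_times.size >= 2:
        dt_ns = float(timeline.frame_times[1] - timeline.frame_times[0])
    else:
        dt_ns = 1.0
    return Trajectory(
        atoms,
        coords,
        frame_interval=dt_ns,
        origin_time=float(timeline.frame_times[0]) if timeline.frame_times.size else 0.0,
        metadata={
            "scripted_bound": timeline.bound.copy(),
            "n_contact_when_bound": n_contact,
            "seed": seed,
        },
    )


def _logistic_sum(T: np.ndarray, transitions) -> np.ndarray:
    f = np.zeros_like(T, dtype=float)
    for tm, w, a in transitions:
        f += a / (1.0 + np.exp(-(T - tm) / w))
    return f


def gen_melt_curve(spec: MeltSpec, n_replicates: int = 1) -> list[MeltCurve]:
    """Sum-of-logistic melt curves plus additive Gaussian noise.

    f(T) = sum_k A_k / (1 + exp(-(T - Tm_k)/w_k)) evaluated on the
    temperature grid; each replicate uses a distinct child seed.  The
    noiseless truth is stored in metadata.
    """
    T = np.arange(spec.T_start, spec.T_end + spec.T_step / 2, spec.T_step)
    truth = _logistic_sum(T, spec.transitions)
    seeds = np.random.SeedSequence(spec.seed).spawn(n_replicates)
    curves = []
    for rid, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, spec.noise_sd, T.size) if spec.noise_sd > 0 else 0.0
        curves.append(
            MeltCurve(
                T.copy(),
                truth + noise,
                replicate_id=rid,
                metadata={
                    "transitions": tuple(spec.transitions),
                    "noise_sd": spec.noise_sd,
                    "seed": spec.seed,
                },
            )
        )
    return curves


def gen_peak_tables(
    base: PeakTable, perturbations: dict[int, tuple[float, float]]
) -> tuple[PeakTable, PeakTable]:
    """Pair of peak tables differing by prescribed (dH, dN) shifts.

    The second table equals the first with the stated per-residue
    perturbations added; ground truth is recorded in the returned table's
    attrs for test bookkeeping.
    """
    df = base.data.copy()
    shifted = df.copy()
    for rid, (dH, dN) in perturbations.items():
        mask = shifted["residue_id"] == rid
        if not mask.any():
            raise ValueError(f"residue {rid} not in base peak table")
        shifted.loc[mask, "shift_H_ppm"] += dH
        shifted.loc[mask, "shift_N_ppm"] += dN
    out = PeakTable(shifted)
    out.data.attrs["true_perturbations"] = dict(perturbations)
    return PeakTable(df), out


def make_peak_table(residue_ids, rng: np.random.Generator | None = None) -> PeakTable:
    """Convenience random-but-plausible amide peak table for fixtures."""
    rng = rng or np.random.default_rng(0)
    n = len(residue_ids)
    df = pd.DataFrame(
        {
            "residue_id": list(residue_ids),
            "residue_name": ["ALA"] * n,
            "shift_H_ppm": rng.uniform(7.5, 9.0, n).round(4),
            "shift_N_ppm": rng.uniform(105.0, 130.0, n).round(4),
            "intensity": np.ones(n),
            "missing_flag": [False] * n,
        }
    )
    return PeakTable(df)
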