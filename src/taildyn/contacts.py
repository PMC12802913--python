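"""Histone tail-DNA contact timelines, binding kinetics and thermodynamics.

A tail residue is "in contact" with DNA in a frame when at least one of
its heavy atoms lies strictly within the cutoff (default 4 Angstrom) of a
DNA heavy atom.  The full tail is classified unbound in a frame when no
more than 10% of its residues are in contact (floor rule); bound episodes
shorter than a minimum residence time (default 50 ns) are treated as part
of the surrounding unbound stretch.  From frame counts in each state an
ensemble dissociation constant Kd = n_unbound/n_bound and a standard
binding free energy dG0 = RT ln Kd follow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import R_GAS_KCAL
from .trajectory import AtomSelection, Trajectory

__all__ = [
    "ContactTimeline",
    "BoundStateSeries",
    "Episode",
    "EventTable",
    "KineticsSummary",
    "BpContactMap",
    "residue_dna_contacts",
    "bound_fraction",
    "classify_bound_state",
    "extract_events",
    "binding_thermodynamics",
    "per_bp_contact_map",
]


@dataclass
class ContactTimeline:
    """Boolean and counted residue x frame tail-DNA contacts."""

    residues: list[int]
    frame_times: np.ndarray  # ns
    counts: np.ndarray  # (n_frames, n_residues) atom-pair contact counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.counts.shape != (self.frame_times.size, len(self.residues)):
            raise ValueError("counts must be (n_frames, n_residues)")

    @property
    def in_contact(self) -> np.ndarray:
        return self.counts >= 1

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass
class BoundStateSeries:
    """Per-frame bound/unbound state of the full tail (True = bound)."""

    frame_times: np.ndarray  # ns
    bound: np.ndarray  # bool per frame
    threshold_used: float = 0.10
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        if self.frame_times.shape != self.bound.shape:
            raise ValueError("frame_times and bound must have equal length")

    @property
    def dt(self) -> float:
        if self.frame_times.size < 2:
            raise ValueError("need at least 2 frames")
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass
class Episode:
    state: str  # 'bound' or 'unbound'
    start: float  # ns
    end: float  # ns (exclusive: start + n_frames * dt)
    duration: float  # ns
    truncated: bool = False  # runs into the end of the trajectory


@dataclass
class EventTable:
    episodes: list[Episode]
    n_binding: int
    n_unbinding: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.episodes])


@dataclass
class KineticsSummary:
    n_unbinding_events: int
    n_binding_events: int
    residence_times: np.ndarray  # ns, filtered
    frames_bound: int
    frames_unbound: int
    Kd: float | None = None
    deltaG0: float | None = None
    temperature: float = 310.0

    @property
    def mean_residence(self) -> float:
        return float(np.mean(self.residence_times)) if self.residence_times.size else float("nan")


@dataclass
class BpContactMap:
    """Mean tail contacts per DNA base pair (and optional residue-resolved map)."""

    bp_index: np.ndarray
    mean_contacts: np.ndarray
    residue_matrix: pd.DataFrame | None = None  # residues x bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bp_index": self.bp_index, "mean_contacts": self.mean_contacts})


def _analyzed_frames(traj: Trajectory, stride: float, burn_in: float) -> np.ndarray:
    if stride < traj.frame_interval:
        raise ValueError(
            f"stride {stride} ns is smaller than the frame interval "
            f"{traj.frame_interval} ns"
        )
    step = int(round(stride / traj.frame_interval))
    times = traj.times
    keep = np.nonzero(times >= burn_in)[0]
    return keep[::step]


def _contact_pairs(xa: np.ndarray, xb: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """All (i, j) with |xa_i - xb_j| strictly < cutoff (exact, tree-accelerated)."""
    tree_b = cKDTree(xb)
    pairs = []
    for i, neigh in enumerate(cKDTree(xa).query_ball_tree(tree_b, r=cutoff)):
        for j in neigh:
            if np.dot(xa[i] - xb[j], xa[i] - xb[j]) < cutoff * cutoff:
                pairs.append((i, j))
    return pairs


def _heavy_disjoint(traj: Trajectory, tail_sel: AtomSelection, dna_sel: AtomSelection):
    if len(tail_sel) == 0 or len(dna_sel) == 0:
        raise ValueError("tail and DNA selections must be non-empty")
    for sel, label in ((tail_sel, "tail"), (dna_sel, "DNA")):
        for i in sel.indices:
            if not traj.atoms[i].is_heavy:
                raise ValueError(f"{label} selection contains hydrogen atoms; use heavy-only")
    if set(tail_sel.indices) & set(dna_sel.indices):
        raise ValueError("tail and DNA selections overlap")


def residue_dna_contacts(
    traj: Trajectory,
    tail_sel: AtomSelection,
    dna_sel: AtomSelection,
    cutoff: float = 4.0,
    stride: float = 1.0,
    burn_in: float = 200.0,
) -> ContactTimeline:
    """Per-residue tail-DNA heavy-atom contact counts over analyzed frames.

    Contacts use a strict distance inequality (< cutoff).  Frames earlier
    than ``burn_in`` ns are discarded; ``stride`` ns subsampling is applied
    to the retained frames.
    """
    _heavy_disjoint(traj, tail_sel, dna_sel)
    frames = _analyzed_frames(traj, stride, burn_in)
    tail_idx = tail_sel.indices
    dna_idx = dna_sel.indices
    residues = sorted({traj.atoms[i].residue_id for i in tail_idx})
    res_pos = {r: k for k, r in enumerate(residues)}
    atom_res = np.array([res_pos[traj.atoms[i].residue_id] for i in tail_idx])
    counts = np.zeros((frames.size, len(residues)), dtype=int)
    for fi, f in enumerate(frames):
        pairs = _contact_pairs(traj.coords[f, tail_idx], traj.coords[f, dna_idx], cutoff)
        for i, _ in pairs:
            counts[fi, atom_res[i]] += 1
    return ContactTimeline(residues, traj.times[frames], counts)


def bound_fraction(timeline: ContactTimeline) -> np.ndarray:
    """Per-frame fraction of tail residues having at least one DNA contact."""
    if timeline.n_frames == 0:
        raise ValueError("empty timeline")
    return timeline.in_contact.sum(axis=1) / len(timeline.residues)


def classify_bound_state(
    timeline: ContactTimeline, unbound_threshold: float = 0.10
) -> BoundStateSeries:
    """Classify each frame: unbound iff <= floor(threshold * n_residues)
    residues are in contact, bound otherwise."""
    if not 0 < unbound_threshold < 1:
        raise ValueError("unbound_threshold must be in (0, 1)")
    n_res = len(timeline.residues)
    limit = math.floor(unbound_threshold * n_res)
    n_contact = timeline.in_contact.sum(axis=1)
    return BoundStateSeries(
        frame_times=timeline.frame_times,
        bound=n_contact > limit,
        threshold_used=unbound_threshold,
    )


def _run_length_encode(bound: np.ndarray) -> list[tuple[bool, int, int]]:
    """(state, start_index, length) runs of the boolean series."""
    runs = []
    start = 0
    for i in range(1, bound.size + 1):
        if i == bound.size or bound[i] != bound[start]:
            runs.append((bool(bound[start]), start, i - start))
            start = i
    return runs


def extract_events(
    states: BoundStateSeries,
    min_residence: float = 50.0,
    count_short_events: bool = False,
) -> tuple[EventTable, KineticsSummary]:
    """Run-length encode the state series into episodes and kinetics.

    An unbinding event is a bound->unbound transition.  Bound episodes
    shorter than ``min_residence`` ns are excluded from residence-time
    statistics and, unless ``count_short_events``, merged into the flanking
    unbound time before transitions are counted so that a single consistent
    state sequence underlies both statistics.  The final episode is
    censored by the trajectory end: flagged and excluded from residence
    statistics.  Episode durations are n_frames * dt.
    """
    if states.bound.size < 2:
        raise ValueError("need at least 2 frames to extract events")
    dt = states.dt
    t0 = states.frame_times[0]

    effective = states.bound.copy()
    if not count_short_events and min_residence > 0:
        for is_bound, start, length in _run_length_encode(states.bound):
            # the final episode is censored, not short: leave it alone
            if is_bound and length * dt < min_residence and start + length < states.bound.size:
                effective[start : start + length] = False

    episodes: list[Episode] = []
    runs = _run_length_encode(effective)
    for k, (is_bound, start, length) in enumerate(runs):
        truncated = k == len(runs) - 1
        episodes.append(
            Episode(
                state="bound" if is_bound else "unbound",
                start=t0 + start * dt,
                end=t0 + (start + length) * dt,
                duration=length * dt,
                truncated=truncated,
            )
        )
    n_unbinding = sum(
        1 for a, b in zip(runs, runs[1:]) if a[0] and not b[0]
    )
    n_binding = sum(1 for a, b in zip(runs, runs[1:]) if not a[0] and b[0])

    residences = np.array(
        [
            e.duration
            for e in episodes
            if e.state == "bound" and not e.truncated and e.duration >= min_residence
        ]
    )
    if residences.size == 0:
        warnings.warn("no bound episode passes the residence filter", stacklevel=2)
    summary = KineticsSummary(
        n_unbinding_events=n_unbinding,
        n_binding_events=n_binding,
        residence_times=residences,
        frames_bound=int(states.bound.sum()),
        frames_unbound=int((~states.bound).sum()),
    )
    return EventTable(episodes, n_binding, n_unbinding), summary


def binding_thermodynamics(
    states: BoundStateSeries, temperature: float = 310.0
) -> KineticsSummary:
    """Ensemble Kd and standard binding free energy from frame counts.

    Kd = frames_unbound / frames_bound; dG0 = R*T*ln(Kd) in kcal/mol
    (negative when the bound state dominates).  Frame counts use every
    analyzed frame, before any residence-time filtering.
    """
    nb = int(states.bound.sum())
    nu = int((~states.bound).sum())
    summary = KineticsSummary(
        n_unbinding_events=0,
        n_binding_events=0,
        residence_times=np.zeros(0),
        frames_bound=nb,
        frames_unbound=nu,
        temperature=temperature,
    )
    if nb == 0 or nu == 0:
        warnings.warn(
            f"Kd undefined: frames_bound={nb}, frames_unbound={nu}", stacklevel=2
        )
        return summary
    summary.Kd = nu / nb
    summary.deltaG0 = R_GAS_KCAL * temperature * math.log(summary.Kd)
    return summary


def default_bp_pairing(n_bp: int, resids_strand1: list[int], resids_strand2: list[int]) -> dict[int, int]:
    """Duplex pairing i <-> 2N+1-i mapped onto actual residue ids.

    ``resids_strand1`` run 5'->3' on strand one, ``resids_strand2`` 5'->3'
    on the complementary strand; nucleotide k of strand one pairs with
    nucleotide N+1-k of strand two, both assigned bp index k.
    """
    if len(resids_strand1) != n_bp or len(resids_strand2) != n_bp:
        raise ValueError("strand residue lists must each have n_bp entries")
    pairing = {}
    for k in range(n_bp):
        pairing[resids_strand1[k]] = k + 1
        pairing[resids_strand2[n_bp - 1 - k]] = k + 1
    return pairing


def per_bp_contact_map(
    traj: Trajectory,
    tail_sel: AtomSelection,
    dna_sel: AtomSelection,
    bp_pairing: dict[int, int],
    cutoff: float = 4.0,
    stride: float = 1.0,
    burn_in: float = 200.0,
    residue_resolved: bool = False,
) -> BpContactMap:
    """Mean tail-DNA atomic contacts per DNA base pair.

    Atom-pair contacts are aggregated onto the base-pair index of the DNA
    atom (both strands of a pair share one index), then averaged over the
    analyzed frames.
    """
    _heavy_disjoint(traj, tail_sel, dna_sel)
    frames = _analyzed_frames(traj, stride, burn_in)
    tail_idx, dna_idx = tail_sel.indices, dna_sel.indices
    for j in dna_idx:
        rid = traj.atoms[j].residue_id
        if rid not in bp_pairing:
            raise ValueError(f"DNA residue {rid} absent from bp pairing map")
    bp_values = sorted(set(bp_pairing.values()))
    bp_pos = {bp: k for k, bp in enumerate(bp_values)}
    dna_bp = np.array([bp_pos[bp_pairing[traj.atoms[j].residue_id]] for j in dna_idx])
    tail_res = sorted({traj.atoms[i].residue_id for i in tail_idx})
    res_pos = {r: k for k, r in enumerate(tail_res)}
    atom_res = np.array([res_pos[traj.atoms[i].residue_id] for i in tail_idx])

    totals = np.zeros(len(bp_values))
    res_matrix = np.zeros((len(tail_res), len(bp_values))) if residue_resolved else None
    for f in frames:
        pairs = _contact_pairs(traj.coords[f, tail_idx], traj.coords[f, dna_idx], cutoff)
        for i, j in pairs:
            totals[dna_bp[j]] += 1
            if res_matrix is not None:
                res_matrix[atom_res[i], dna_bp[j]] += 1
    n = max(frames.size, 1)
    residue_df = (
        pd.DataFrame(res_matrix / n, index=tail_res, columns=bp_values)
        if res_matrix is not None
        else None
    )
    return BpContactMap(np.array(bp_values), totals / n, residue_df)
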