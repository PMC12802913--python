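"""Intra-tail conformational ensemble descriptors.

Dynamic cross-correlation matrices of residue displacement vectors,
radius of gyration, residue-residue contact-probability maps (distance or
geometric hydrogen-bond criterion), and node degrees over interaction
edge tables (sums of per-edge occurrence probabilities).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import _contact_pairs
from .trajectory import AtomSelection, Trajectory

__all__ = [
    "DCCMatrix",
    "RgSeries",
    "dccm",
    "radius_of_gyration",
    "contact_probability_map",
    "node_degree",
    "read_edge_table",
    "write_edge_table",
]


@dataclass
class DCCMatrix:
    """Symmetric normalized cross-correlation matrix, entries in [-1, 1].

    Zero-variance residues produce NaN rows/columns (flagged, not errors);
    the diagonal is exactly 1 where defined.
    """

    residues: list[int]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class RgSeries:
    values: np.ndarray  # Angstrom per frame
    selection: str
    mass_weighted: bool


def dccm(traj: Trajectory, selection: AtomSelection) -> DCCMatrix:
    """Dynamic cross-correlation matrix over one representative atom per residue.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr = r - <r>
    computed per selected atom across frames.  The selection must contain
    exactly one atom per residue (conventionally the C-alpha, or the
    pseudo-bead of a coarse model); the trajectory should be superposed.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for a meaningful DCCM")
    idx = selection.indices
    residues = [traj.atoms[i].residue_id for i in idx]
    if len(set(residues)) != len(residues):
        raise ValueError("selection must contain one representative atom per residue")
    X = traj.coords[:, idx, :]  # (F, R, 3)
    D = X - X.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", D, D) / traj.n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(
            f"zero-variance residues in DCCM: {[r for r, z in zip(residues, zero) if z]}",
            stacklevel=2,
        )
        var[zero] = np.nan
    denom = np.sqrt(np.outer(var, var))
    M = cov / denom
    np.fill_diagonal(M, np.where(zero, np.nan, 1.0))
    return DCCMatrix(residues, M)


def radius_of_gyration(
    traj: Trajectory, selection: AtomSelection, mass_weighted: bool = True
) -> RgSeries:
    """Per-frame radius of gyration of the selection.

    Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i); unweighted mode sets all
    masses to 1.
    """
    idx = selection.indices
    if idx.size == 0:
        raise ValueError("empty selection")
    m = (
        np.array([traj.atoms[i].mass for i in idx])
        if mass_weighted
        else np.ones(idx.size)
    )
    X = traj.coords[:, idx, :]
    com = np.einsum("fia,i->fa", X, m) / m.sum()
    d2 = np.sum((X - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("fi,i->f", d2, m) / m.sum())
    return RgSeries(rg, selection.expression, mass_weighted)


def _find_bonded_h(traj: Trajectory, frame0: np.ndarray) -> dict[int, list[int]]:
    """Heavy atom index -> attached hydrogen indices, by a 1.3 A distance rule
    within the same residue (frame 0 geometry)."""
    bonded: dict[int, list[int]] = {}
    h_idx = [i for i, a in enumerate(traj.atoms) if not a.is_heavy]
    heavy_idx = [i for i, a in enumerate(traj.atoms) if a.is_heavy]
    for h in h_idx:
        hr = traj.atoms[h].residue_id
        best, best_d = None, 1.3
        for j in heavy_idx:
            if traj.atoms[j].residue_id != hr:
                continue
            d = float(np.linalg.norm(frame0[h] - frame0[j]))
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            bonded.setdefault(best, []).append(h)
    return bonded


def contact_probability_map(
    traj: Trajectory,
    tail_selection: AtomSelection,
    criterion: str = "distance",
    cutoff: float = 4.0,
    hbond_distance: float = 3.5,
    hbond_angle: float = 120.0,
    min_sequence_separation: int = 2,
) -> pd.DataFrame:
    """Residue-residue contact probabilities within the tail.

    ``criterion='distance'``: a pair is in contact in a frame when any
    heavy-atom pair lies within ``cutoff``.  ``criterion='hbond'`` uses a
    geometric proxy: donor(N/O with attached H) to acceptor(N/O) heavy
    distance < ``hbond_distance`` and donor-H...acceptor angle >
    ``hbond_angle`` degrees.  Pairs with |i-j| < ``min_sequence_separation``
    (adjacent residues) are masked to NaN.  Probability = fraction of
    frames in contact.
    """
    idx = tail_selection.indices
    residues = sorted({traj.atoms[i].residue_id for i in idx})
    rpos = {r: k for k, r in enumerate(residues)}
    n = len(residues)
    hits = np.zeros((n, n))

    if criterion == "distance":
        heavy = np.array([i for i in idx if traj.atoms[i].is_heavy], dtype=int)
        if heavy.size == 0:
            raise ValueError("no heavy atoms in selection")
        atom_res = np.array([rpos[traj.atoms[i].residue_id] for i in heavy])
        for f in range(traj.n_frames):
            X = traj.coords[f, heavy]
            seen = set()
            for i, j in _contact_pairs(X, X, cutoff):
                ri, rj = atom_res[i], atom_res[j]
                if ri != rj:
                    seen.add((min(ri, rj), max(ri, rj)))
            for ri, rj in seen:
                hits[ri, rj] += 1
                hits[rj, ri] += 1
    elif criterion == "hbond":
        if all(traj.atoms[i].is_heavy for i in range(len(traj.atoms))):
            raise ValueError(
                "no hydrogen atoms present; use the distance criterion instead"
            )
        bonded = _find_bonded_h(traj, traj.coords[0])
        polar = [
            i
            for i in idx
            if traj.atoms[i].element.upper() in ("N", "O")
        ]
        donors = [i for i in polar if bonded.get(i)]
        cos_lim = math.cos(math.radians(hbond_angle))
        for f in range(traj.n_frames):
            X = traj.coords[f]
            seen = set()
            for d in donors:
                for a in polar:
                    if a == d or traj.atoms[a].residue_id == traj.atoms[d].residue_id:
                        continue
                    if np.linalg.norm(X[d] - X[a]) >= hbond_distance:
                        continue
                    for h in bonded[d]:
                        v1 = X[d] - X[h]
                        v2 = X[a] - X[h]
                        cosang = float(
                            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        )
                        # angle > hbond_angle <=> cos(angle) < cos(hbond_angle)
                        if cosang < cos_lim:
                            ri = rpos[traj.atoms[d].residue_id]
                            rj = rpos[traj.atoms[a].residue_id]
                            seen.add((min(ri, rj), max(ri, rj)))
                            break
            for ri, rj in seen:
                hits[ri, rj] += 1
                hits[rj, ri] += 1
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    prob = hits / traj.n_frames
    for a in range(n):
        for b in range(n):
            if abs(residues[a] - residues[b]) < min_sequence_separation:
                prob[a, b] = np.nan
    return pd.DataFrame(prob, index=residues, columns=residues)


EDGE_COLUMNS = ["residue_a", "residue_b", "probability", "interaction_class"]


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    if "interaction_class" not in df.columns:
        df["interaction_class"] = "any"
    return df[EDGE_COLUMNS]


def write_edge_table(df: pd.DataFrame, path) -> None:
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def edges_from_probability_map(
    prob: pd.DataFrame, threshold: float = 0.0, interaction_class: str = "contact"
) -> pd.DataFrame:
    """Threshold a contact-probability matrix into an edge table."""
    rows = []
    res = list(prob.index)
    for i, a in enumerate(res):
        for b in res[i + 1 :]:
            p = prob.loc[a, b]
            if np.isfinite(p) and p > threshold:
                rows.append((a, b, float(p), interaction_class))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def node_degree(edges: pd.DataFrame, classes: list[str] | None = None) -> pd.Series:
    """Sum of edge probability scores incident to each residue.

    Edges may optionally be filtered to the given interaction classes.
    Duplicate (pair, class) rows are rejected: silent double counting is a
    data error, not a convention.
    """
    df = edges.copy()
    if "interaction_class" not in df.columns:
        df["interaction_class"] = "any"
    if classes is not None:
        df = df[df["interaction_class"].isin(classes)]
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        raise ValueError("edge probabilities must lie in [0, 1]")
    if (df["residue_a"] == df["residue_b"]).any():
        raise ValueError("self-edges are not allowed")
    key = df.apply(
        lambda r: (min(r.residue_a, r.residue_b), max(r.residue_a, r.residue_b), r.interaction_class),
        axis=1,
    )
    if key.duplicated().any():
        dups = key[key.duplicated()].tolist()
        raise ValueError(f"duplicate edge rows: {dups}")
    nodes = sorted(set(df["residue_a"]) | set(df["residue_b"]))
    deg = pd.Series(0.0, index=nodes, dtype=float)
    for _, row in df.iterrows():
        deg[row.residue_a] += row.probability
        deg[row.residue_b] += row.probability
    return deg
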