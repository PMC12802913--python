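"""Minimal trajectory data model, I/O, atom selection and superposition.

Coordinates are in Angstrom and times at the API surface are nanoseconds.
Binary formats (DCD/XTC) and PDB files are read through MDAnalysis; the
plain-text fixture format (header: n_atoms n_frames frame_interval_ns,
then whitespace-separated xyz per atom per frame) is this package's own
diffable interchange format.  Internal timestamps of binary trajectories
are ignored in favour of an explicit frame interval so that fixtures and
real data behave identically.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .relaxometry import VectorSeries

__all__ = [
    "AtomRecord",
    "Trajectory",
    "AtomSelection",
    "TrajectoryIOError",
    "SelectionError",
    "infer_element",
    "read_structure",
    "read_frames",
    "write_fixture",
    "read_fixture",
    "select",
    "superpose",
    "extract_nh_vectors",
]

# Approximate atomic masses (Da) for the elements that occur in
# protein/nucleic systems; fallback 12.0 for unknowns.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "SE": 78.971, "FE": 55.845,
    "ZN": 65.38, "MG": 24.305, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


class TrajectoryIOError(RuntimeError):
    pass


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    mass: float = 12.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Trajectory:
    """Atoms plus an ordered (frame x atom x xyz) coordinate array in Angstrom."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_interval: float  # ns
    origin_time: float = 0.0  # ns
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"{len(self.atoms)} atom records"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in ns."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval


@dataclass
class AtomSelection:
    expression: str
    resolved_ids: frozenset[int]
    indices: np.ndarray  # positional indices into trajectory.atoms, sorted

    def __len__(self) -> int:
        return len(self.indices)


# -- element inference ------------------------------------------------------

_TWO_LETTER = {"FE", "ZN", "MG", "NA", "CL", "SE", "BR", "MN", "CU", "CA2"}


def infer_element(name: str, residue_name: str = "") -> str:
    """Infer the element from a PDB atom name.

    Follows the PDB convention for polymer residues: strip digits and
    primes, take the leading letter (so " CA " in a protein residue is
    carbon, not calcium).  Names beginning with a digit (e.g. 1H5') are
    hydrogens or carbons per the remaining letters.
    """
    stripped = re.sub(r"[0-9'\"*]", "", name.strip()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped in _TWO_LETTER and residue_name.strip().upper() == stripped:
        return stripped.capitalize()
    return stripped[0]


def _mass_for(element: str) -> float:
    return _MASSES.get(element.upper(), 12.0)


# -- PDB / binary readers (MDAnalysis behind the surface) -------------------

def _scan_pdb_for_malformed(path: Path) -> None:
    with open(path) as fh:
        n_atom_lines = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atom_lines += 1
                if len(line.rstrip("\n")) < 54:
                    raise TrajectoryIOError(
                        f"{path}: malformed record at line {lineno}: too short"
                    )
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise TrajectoryIOError(
                        f"{path}: malformed coordinates at line {lineno}"
                    ) from None
    if n_atom_lines == 0:
        raise TrajectoryIOError(f"{path}: no ATOM/HETATM records found")


def _atoms_from_universe(u) -> list[AtomRecord]:
    ag = u.atoms
    try:
        elements = [str(e) for e in ag.elements]
        if any(not e.strip() for e in elements):
            raise ValueError
    except Exception:
        elements = [
            infer_element(name, resname)
            for name, resname in zip(ag.names, ag.resnames)
        ]
    try:
        chains = [str(c) for c in ag.chainIDs]
    except Exception:
        try:
            chains = [str(s) for s in ag.segids]
        except Exception:
            chains = ["A"] * len(ag)
    records = []
    for i in range(len(ag)):
        el = elements[i].strip().upper() or infer_element(ag.names[i], ag.resnames[i])
        records.append(
            AtomRecord(
                atom_id=int(ag.ids[i]) if hasattr(ag, "ids") else i + 1,
                name=str(ag.names[i]),
                element=el.capitalize() if len(el) > 1 else el,
                residue_id=int(ag.resids[i]),
                residue_name=str(ag.resnames[i]),
                chain_id=chains[i].strip() or "A",
                mass=_mass_for(el),
            )
        )
    return records


def read_structure(path) -> tuple[list[AtomRecord], np.ndarray]:
    """Read a PDB topology; returns (atoms, coordinates of the first model)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise TrajectoryIOError(f"{path}: empty or missing file")
    _scan_pdb_for_malformed(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = _atoms_from_universe(u)
    return atoms, np.array(u.atoms.positions, dtype=float)


def read_frames(
    path,
    frame_interval: float,
    topology=None,
    origin_time: float = 0.0,
) -> Trajectory:
    """Read a multi-model PDB, DCD, XTC or text fixture into a Trajectory.

    ``frame_interval`` (ns) is mandatory for binary/PDB inputs; internal
    timestamps are ignored.  For the text fixture the header value is used
    and checked against the argument when both are given.
    """
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fix", ".txt", ".dat"):
        traj = read_fixture(path, atoms=None if topology is None else read_structure(topology)[0])
        if frame_interval is not None and not math.isclose(
            traj.frame_interval, frame_interval, rel_tol=1e-9
        ):
            raise TrajectoryIOError(
                f"{path}: fixture frame interval {traj.frame_interval} ns "
                f"disagrees with requested {frame_interval} ns"
            )
        return replace(traj, origin_time=origin_time)
    if not path.exists() or path.stat().st_size == 0:
        raise TrajectoryIOError(f"{path}: empty or missing file")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if suffix in (".dcd", ".xtc", ".trr"):
                if topology is None:
                    raise TrajectoryIOError(f"{path}: binary trajectory requires a topology")
                u = mda.Universe(str(topology), str(path))
            else:
                u = mda.Universe(str(path))
        except TrajectoryIOError:
            raise
        except Exception as exc:
            raise TrajectoryIOError(f"{path}: failed to open trajectory: {exc}") from exc
        atoms = _atoms_from_universe(u)
        frames = []
        try:
            for _ in u.trajectory:
                if u.atoms.positions.shape[0] != len(atoms):
                    raise TrajectoryIOError(
                        f"{path}: frame has {u.atoms.positions.shape[0]} atoms, "
                        f"topology has {len(atoms)}"
                    )
                frames.append(np.array(u.atoms.positions, dtype=float))
        except TrajectoryIOError:
            raise
        except Exception as exc:
            raise TrajectoryIOError(
                f"{path}: truncated or unreadable trajectory after "
                f"{len(frames)} frames: {exc}"
            ) from exc
    if not frames:
        raise TrajectoryIOError(f"{path}: no frames read")
    return Trajectory(atoms, np.stack(frames), frame_interval, origin_time)


def write_pdb(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as a minimal PDB (topology companion to the fixture)."""
    with open(path, "w") as fh:
        for a, xyz in zip(traj.atoms, traj.coords[frame]):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.atom_id % 100000:5d} {name[:4]}{a.residue_name[:4]:>4s} "
                f"{a.chain_id[:1]}{a.residue_id % 10000:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {a.element[:2]:>2s}\n"
            )
        fh.write("END\n")


# -- text fixture -----------------------------------------------------------

def write_fixture(traj: Trajectory, path) -> None:
    """Write the plain-text fixture: full-precision, diffable, atoms-per-line."""
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames} {float(traj.frame_interval)!r}\n")
        for frame in traj.coords:
            for xyz in frame:
                fh.write(f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")


def _default_atoms(n: int) -> list[AtomRecord]:
    return [
        AtomRecord(atom_id=i + 1, name="C", element="C", residue_id=i + 1,
                   residue_name="BEA", chain_id="A", mass=12.011)
        for i in range(n)
    ]


def read_fixture(path, atoms: list[AtomRecord] | None = None) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise TrajectoryIOError(f"{path}: bad fixture header")
        n_atoms, n_frames, dt = int(header[0]), int(header[1]), float(header[2])
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (n_atoms * n_frames, 3):
        raise TrajectoryIOError(
            f"{path}: expected {n_atoms * n_frames} coordinate rows "
            f"({n_atoms} atoms x {n_frames} frames), found {data.shape[0]}"
        )
    if atoms is None:
        atoms = _default_atoms(n_atoms)
    elif len(atoms) != n_atoms:
        raise TrajectoryIOError(
            f"{path}: fixture has {n_atoms} atoms but topology has {len(atoms)}"
        )
    coords = data.reshape(n_frames, n_atoms, 3)
    return Trajectory(atoms, coords, dt)


# -- selection mini-language ------------------------------------------------

_KEYWORDS = {"and", "or", "not", "chain", "resid", "name", "heavy", "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    """Recursive-descent parser: or < and < not < primary."""

    def __init__(self, tokens: list[str], atoms: list[AtomRecord], expression: str):
        self.tokens = tokens
        self.pos = 0
        self.atoms = atoms
        self.expression = expression

    def _err(self, msg: str):
        raise SelectionError(f"selection syntax error at token {self.pos} "
                             f"({self._peek()!r}) in {self.expression!r}: {msg}")

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.parse_or()
        if self._peek() is not None:
            self._err("unexpected trailing tokens")
        return result

    def parse_or(self) -> set[int]:
        left = self.parse_and()
        while self._peek() == "or":
            self._next()
            left = left | self.parse_and()
        return left

    def parse_and(self) -> set[int]:
        left = self.parse_not()
        while self._peek() == "and":
            self._next()
            left = left & self.parse_not()
        return left

    def parse_not(self) -> set[int]:
        if self._peek() == "not":
            self._next()
            return set(range(len(self.atoms))) - self.parse_not()
        return self.parse_primary()

    def _collect_args(self) -> list[str]:
        args = []
        while self._peek() is not None and self._peek() not in _KEYWORDS:
            args.append(self._next())
        if not args:
            self._err("expected at least one argument")
        return args

    def parse_primary(self) -> set[int]:
        tok = self._next()
        if tok == "(":
            inner = self.parse_or()
            if self._next() != ")":
                self._err("expected ')'")
            return inner
        if tok == "all":
            return set(range(len(self.atoms)))
        if tok == "heavy":
            return {i for i, a in enumerate(self.atoms) if a.is_heavy}
        if tok == "chain":
            chains = set(self._collect_args())
            return {i for i, a in enumerate(self.atoms) if a.chain_id in chains}
        if tok == "name":
            names = {n.upper() for n in self._collect_args()}
            return {i for i, a in enumerate(self.atoms) if a.name.strip().upper() in names}
        if tok == "resid":
            ids: set[int] = set()
            for arg in self._collect_args():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", arg)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    ids.update(range(lo, hi + 1))
                elif re.fullmatch(r"-?\d+", arg):
                    ids.add(int(arg))
                else:
                    self._err(f"bad resid argument {arg!r}")
            return {i for i, a in enumerate(self.atoms) if a.residue_id in ids}
        self._err(f"unknown keyword {tok!r}")


def select(traj: Trajectory, expression: str) -> AtomSelection:
    """Resolve a selection expression deterministically.

    Mini-language: ``chain A``, ``resid 1-36`` (ranges/lists), ``name N H``,
    ``heavy``, ``all``, combined with ``and``/``or``/``not`` and parentheses.
    Empty selections are allowed but warned about.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    idx = _Parser(tokens, traj.atoms, expression).parse()
    indices = np.array(sorted(idx), dtype=int)
    if indices.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    resolved = frozenset(traj.atoms[i].atom_id for i in indices)
    return AtomSelection(expression=expression, resolved_ids=resolved, indices=indices)


# -- superposition ----------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation matrix + translation mapping mobile onto reference.

    Proper rotation enforced via the determinant sign fix (no reflections).
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def superpose(
    traj: Trajectory,
    reference_frame: int,
    selection: AtomSelection,
) -> tuple[Trajectory, np.ndarray]:
    """Rigid-body superposition of every frame onto a reference frame.

    The Kabsch rotation+translation is computed on the selection (e.g. the
    histone-core C-alpha atoms) and applied to all atoms.  Returns the
    superposed trajectory and the per-frame RMSD over the selection.
    """
    idx = selection.indices
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = traj.coords[reference_frame, idx]
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection is collinear/degenerate; cannot superpose")
    out = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t = _kabsch(traj.coords[f, idx], ref)
        out[f] = traj.coords[f] @ R.T + t
        diff = out[f, idx] - ref
        rmsd[f] = math.sqrt(np.mean(np.sum(diff**2, axis=1)))
    meta = dict(traj.metadata)
    meta["superposed"] = True
    new = Trajectory(traj.atoms, out, traj.frame_interval, traj.origin_time, meta)
    return new, rmsd


# -- N-H bond vectors -------------------------------------------------------

def extract_nh_vectors(
    traj: Trajectory,
    residues: list[int],
    amide_h_names: tuple[str, ...] = ("H", "HN"),
    require_superposed: bool = True,
) -> tuple[dict[int, VectorSeries], list[int]]:
    """Per-residue unit H-N bond vectors, one series per residue.

    The trajectory must already be superposed (internal-motion frame);
    this is asserted via the trajectory metadata flag unless
    ``require_superposed=False``.  Prolines in the residue list are
    reported as skipped, not an error; a missing amide H elsewhere is.
    Returns (series by residue_id, skipped proline ids).
    """
    if require_superposed and not traj.metadata.get("superposed", False):
        raise ValueError(
            "trajectory is not flagged as superposed; superpose first or pass "
            "require_superposed=False"
        )
    by_res: dict[int, dict[str, int]] = {}
    res_names: dict[int, str] = {}
    for i, a in enumerate(traj.atoms):
        by_res.setdefault(a.residue_id, {})[a.name.strip().upper()] = i
        res_names[a.residue_id] = a.residue_name.strip().upper()
    series: dict[int, VectorSeries] = {}
    skipped: list[int] = []
    dt_seconds = traj.frame_interval * 1e-9
    for rid in residues:
        if rid not in by_res:
            raise ValueError(f"residue {rid} not present in trajectory")
        if res_names[rid] == "PRO":
            skipped.append(rid)
            continue
        atom_map = by_res[rid]
        if "N" not in atom_map:
            raise ValueError(f"residue {rid} has no backbone N atom")
        h_idx = next((atom_map[h] for h in amide_h_names if h in atom_map), None)
        if h_idx is None:
            raise ValueError(f"residue {rid} ({res_names[rid]}) is missing an amide H")
        vec = traj.coords[:, h_idx, :] - traj.coords[:, atom_map["N"], :]
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError(f"residue {rid}: coincident N and H positions")
        series[rid] = VectorSeries(rid, vec / norms, dt_seconds)
    return series, skipped
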