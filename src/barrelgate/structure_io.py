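"""Structures, trajectories, selections and domain segmentation.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Atom` records (author residue numbering, one annotation
``score`` slot that maps onto the PDB B-factor column), and a
:class:`Trajectory` is a fixed atom template plus a ``(n_frames, n_atoms, 3)``
coordinate array.  The reference on-disk format is multi-model PDB, read and
written through biotite so fixed-width compliance is not our problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .exceptions import (
    PDBParseError,
    ScoreRangeError,
    SelectionError,
    TrajectoryConsistencyError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "DomainMap",
    "GFCD_DOMAINS",
    "read_pdb",
    "write_annotated_pdb",
    "write_trajectory_pdb",
    "select",
    "segment_domains",
]

# B-factor is a fixed-width %6.2f column.
SCORE_MIN = -9.99
SCORE_MAX = 999.99


@dataclass
class Atom:
    """One atom record.

    ``resid`` is the author numbering from the file (1-based); ``score`` is a
    free annotation slot that occupies the B-factor column on output.
    """

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    coords: np.ndarray
    score: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")
        if self.resid < 1:
            raise ValueError(f"atom {self.serial}: resid must be >= 1, got {self.resid}")


@dataclass
class Structure:
    """An ordered, fixed set of atoms."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.resid, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom identity {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def resids(self) -> np.ndarray:
        return np.array([a.resid for a in self.atoms], dtype=int)

    @property
    def scores(self) -> np.ndarray:
        return np.array([a.score for a in self.atoms], dtype=float)

    def with_scores(self, scores: Sequence[float]) -> "Structure":
        """Return a copy carrying the given per-atom scores."""
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (self.n_atoms,):
            raise ValueError("one score per atom required")
        atoms = [
            Atom(a.serial, a.name, a.resname, a.resid, a.chain, a.element,
                 a.coords.copy(), float(s))
            for a, s in zip(self.atoms, scores)
        ]
        return Structure(atoms, self.title)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.resname, a.resid, a.chain, a.element,
                 c.copy(), a.score)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.title)


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom template.

    ``frames`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom.  ``times``
    (ns) must be strictly increasing when present.  Topology is immutable:
    every frame covers exactly the template's atoms.
    """

    atom_template: Structure
    frames: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.atom_template.n_atoms, 3):
            raise TrajectoryConsistencyError(
                f"frames shape {self.frames.shape} does not match "
                f"{self.atom_template.n_atoms} template atoms"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise TrajectoryConsistencyError("one time per frame required")
            if np.any(np.diff(self.times) <= 0):
                raise TrajectoryConsistencyError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int) -> Structure:
        """The template carrying the coordinates of one frame."""
        return self.atom_template.with_coords(self.frames[index])


@dataclass(frozen=True)
class DomainMap:
    """Named inclusive residue ranges, in declaration order.

    Ranges may overlap (a C-terminal plug folded back into its own barrel is
    the expected case).
    """

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.ranges:
            if lo > hi or lo < 1:
                raise ValueError(f"domain {name!r}: bad range {lo}-{hi}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.ranges)

    def range_of(self, name: str) -> tuple[int, int]:
        for n, lo, hi in self.ranges:
            if n == name:
                return lo, hi
        raise KeyError(name)


#: Default GfcD segmentation: signal peptide, N-terminal 12-stranded barrel,
#: periplasmic middle domain, C-terminal 13-stranded barrel, and the
#: C-terminal plug folded back into the GfcD-C channel.
GFCD_DOMAINS = DomainMap((
    ("signal", 1, 18),
    ("GfcD-N", 19, 278),
    ("GfcD-M", 279, 423),
    ("GfcD-C", 424, 698),
    ("plug", 674, 698),
))


def segment_domains(resid: int, domain_map: DomainMap = GFCD_DOMAINS) -> list[str]:
    """All domain names whose range contains ``resid``, in map order.

    A residue outside every range yields an empty list.
    """
    return [name for name, lo, hi in domain_map.ranges if lo <= resid <= hi]


def _first_bad_line(path: Path) -> tuple[int, str] | None:
    """Locate the first ATOM/HETATM record with an unparseable fixed-width field."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                int(line[22:26])
                for sl in (slice(30, 38), slice(38, 46), slice(46, 54)):
                    float(line[sl])
            except (ValueError, IndexError):
                return i, line.rstrip("\n")
    return None


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    The atom template comes from the first model; later models contribute
    coordinates only and must cover the identical atom set.  Files without
    MODEL records yield a single frame.  First altloc is kept; insertion
    codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(
            model=None, altloc="first", extra_fields=["b_factor", "atom_id"]
        )
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg and "model" in msg.lower():
            raise TrajectoryConsistencyError(
                f"{path}: {msg} (all models must share one atom set)"
            ) from exc
        bad = _first_bad_line(path)
        if bad is not None:
            raise PDBParseError(
                f"{path}: malformed record at line {bad[0]}: {bad[1]!r}"
            ) from exc
        raise PDBParseError(f"{path}: {msg}") from exc
    if np.any(stack.ins_code != ""):
        bad_res = stack.res_id[stack.ins_code != ""][0]
        raise PDBParseError(
            f"{path}: insertion codes are not supported (first at residue {bad_res})"
        )
    first = stack[0]
    atoms = [
        Atom(
            serial=int(first.atom_id[i]),
            name=str(first.atom_name[i]),
            resname=str(first.res_name[i]),
            resid=int(first.res_id[i]),
            chain=str(first.chain_id[i]),
            element=str(first.element[i]),
            coords=np.asarray(first.coord[i], dtype=float),
            score=float(first.b_factor[i]),
        )
        for i in range(first.array_length())
    ]
    template = Structure(atoms, title=path.stem)
    return Trajectory(template, np.asarray(stack.coord, dtype=float))


def _to_atom_array(structure: Structure) -> struc.AtomArray:
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = structure.resids
    arr.res_name = np.array([a.resname for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([False] * n)
    arr.set_annotation("b_factor", structure.scores)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    return arr


def write_annotated_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure with per-atom scores in the B-factor column.

    Scores must fit the fixed-width %6.2f column, i.e. lie in
    [-9.99, 999.99]; coordinates survive a round-trip to 3 decimals and
    scores to 2 decimals.
    """
    scores = structure.scores
    if not np.all(np.isfinite(scores)):
        raise ScoreRangeError("scores must be finite")
    if np.any(scores < SCORE_MIN) or np.any(scores > SCORE_MAX):
        bad = scores[(scores < SCORE_MIN) | (scores > SCORE_MAX)][0]
        raise ScoreRangeError(
            f"score {bad} outside B-factor column range [{SCORE_MIN}, {SCORE_MAX}]"
        )
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(Path(path))


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    arr = _to_atom_array(traj.atom_template)
    arrays = []
    for f in range(traj.n_frames):
        a = arr.copy()
        a.coord = traj.frames[f]
        arrays.append(a)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(Path(path))


_SELECT_FIELDS = {"chain", "resid", "resname", "name", "element"}


def _match_str(value: str, criterion) -> bool:
    if isinstance(criterion, str):
        return value == criterion
    return value in criterion


def _match_resid(resid: int, criterion) -> bool:
    if isinstance(criterion, int):
        return resid == criterion
    if isinstance(criterion, tuple) and len(criterion) == 2:
        lo, hi = criterion
        return lo <= resid <= hi
    return resid in criterion


def select(structure: Structure, **criteria) -> np.ndarray:
    """Resolve a selection to atom indices in template order.

    Supported fields: ``chain``, ``resname``, ``name``, ``element`` (a string
    or an iterable of strings) and ``resid`` (an int, an inclusive
    ``(lo, hi)`` tuple, or an iterable of ints).  Criteria combine with AND.
    An empty result is legal but warned about.
    """
    unknown = set(criteria) - _SELECT_FIELDS
    if unknown:
        raise SelectionError(
            f"unknown selection field(s) {sorted(unknown)}; "
            f"allowed: {sorted(_SELECT_FIELDS)}"
        )
    out = []
    for i, a in enumerate(structure.atoms):
        ok = True
        for key, crit in criteria.items():
            if key == "resid":
                ok = _match_resid(a.resid, crit)
            else:
                ok = _match_str(getattr(a, key), crit)
            if not ok:
                break
        if ok:
            out.append(i)
    if not out:
        warnings.warn(f"selection {criteria!r} matched no atoms", stacklevel=2)
    return np.array(out, dtype=int)
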