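"""Anchored-lipid observables: gate plane, head-vector tilt, membrane insertion.

The membrane-insertion criterion is deliberately geometric: an oriented plane
is least-squares fitted through the Cα atoms lining the lateral gate, with
its normal pointing away from the barrel axis, and a tail atom counts as
membrane-inserted once its signed distance to that plane is positive
(outward side).  The reported quantity is an atom-count fraction, declared
as such in every output — a deterministic, monotone proxy for the area
fraction sometimes used to quantify lipid egress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, SelectionError
from .structure_io import Structure, Trajectory, select

__all__ = [
    "GatePlane",
    "LipidDefinition",
    "TiltSeries",
    "InsertionSeries",
    "EgressReport",
    "fit_gate_plane",
    "tilt_series",
    "insertion_series",
    "egress_order",
]

_MIN_VECTOR_NORM = 1e-6  # Å; below this PA/PB are treated as coincident


@dataclass(frozen=True)
class GatePlane:
    """An oriented plane: a point on it and an outward unit normal.

    "Outward" means away from the barrel axis; orientation is fixed at fit
    time by a declared axis reference point.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-8:
            raise DegenerateGeometryError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, coords: np.ndarray) -> np.ndarray:
        """Signed point-plane distances; positive on the outward side."""
        return (np.asarray(coords, dtype=float) - self.point) @ self.normal


@dataclass(frozen=True)
class LipidDefinition:
    """Atom indices describing the anchored lipid.

    ``pa_atom``/``pb_atom`` are the two head phosphorus atoms; ``tails`` is
    one disjoint atom-index list per aliphatic tail (six for lipid A).
    """

    pa_atom: int
    pb_atom: int
    tails: tuple[tuple[int, ...], ...]
    head_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.pa_atom == self.pb_atom:
            raise ValueError("PA and PB must be distinct atoms")
        object.__setattr__(
            self, "tails", tuple(tuple(int(i) for i in t) for t in self.tails)
        )
        object.__setattr__(self, "head_atoms", tuple(int(i) for i in self.head_atoms))
        flat = [i for t in self.tails for i in t]
        if any(len(t) == 0 for t in self.tails):
            raise ValueError("every tail must contain at least one atom")
        if len(set(flat)) != len(flat):
            raise ValueError("tail atom lists must be disjoint")

    @property
    def n_tails(self) -> int:
        return len(self.tails)


@dataclass(frozen=True)
class TiltSeries:
    """Head-vector tilt angle per frame, degrees in [0, 180].

    Frames with a degenerate (near-zero) PA→PB vector carry NaN.  The
    attached histogram covers [0, 180] and counts finite angles only.
    """

    angles: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    times: np.ndarray | None = None


@dataclass(frozen=True)
class InsertionSeries:
    """Membrane-inserted atom fractions per frame, overall and per tail."""

    overall: np.ndarray          # (n_frames,)
    per_tail: np.ndarray         # (n_frames, n_tails)
    tail_sizes: np.ndarray       # atoms per tail
    times: np.ndarray | None = None


@dataclass(frozen=True)
class EgressReport:
    """First-exit frames per tail and the resulting exit order.

    ``first_exit[t]`` is the first frame whose per-tail inserted fraction
    reaches the exit threshold, or None if the tail never exits; ``order``
    lists the exited tails sorted by that frame (ties by tail index).
    """

    first_exit: tuple[int | None, ...]
    order: tuple[int, ...]
    exit_threshold: float


def fit_plane_points(points: np.ndarray, axis_point: Sequence[float]) -> GatePlane:
    """Least-squares plane through a point cloud, oriented away from an axis point.

    The normal is the direction of smallest positional variance, flipped so
    that it points from ``axis_point`` (a point on the barrel axis) toward
    the point centroid — i.e. outward, into the membrane.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(f"need >= 3 points to fit a plane, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sv, Vt = np.linalg.svd(centered)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = Vt[2] / np.linalg.norm(Vt[2])
    outward = centroid - np.asarray(axis_point, dtype=float)
    if float(outward @ normal) < 0:
        normal = -normal
    return GatePlane(point=centroid, normal=normal)


def fit_gate_plane(
    structure: Structure,
    flank_resids: Sequence[int],
    axis_point: Sequence[float],
) -> GatePlane:
    """Least-squares plane through the gate-flanking Cα atoms.

    See :func:`fit_plane_points` for the fit and orientation convention.
    """
    idx = select(structure, name="CA", resid=list(flank_resids))
    if idx.size < 3:
        raise DegenerateGeometryError(
            f"need >= 3 flank CA atoms, found {idx.size}"
        )
    return fit_plane_points(structure.coords[idx], axis_point)


def tilt_series(
    traj: Trajectory,
    lipid: LipidDefinition,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    bin_width: float = 2.5,
    flip_vector: bool = False,
) -> TiltSeries:
    """Angle between the PA→PB head vector and a reference axis, per frame.

    The default axis is the membrane normal (+Z of the simulation box) and
    the default bin width of 2.5° resolves a 112.5° histogram boundary
    exactly.  ``flip_vector`` measures PB→PA instead (θ → 180° − θ).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    v = traj.frames[:, lipid.pb_atom] - traj.frames[:, lipid.pa_atom]
    if flip_vector:
        v = -v
    norms = np.linalg.norm(v, axis=1)
    angles = np.full(traj.n_frames, np.nan)
    ok = norms >= _MIN_VECTOR_NORM
    cosang = np.clip((v[ok] @ axis) / norms[ok], -1.0, 1.0)
    angles[ok] = np.degrees(np.arccos(cosang))
    n_bins = int(round(180.0 / bin_width))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles[np.isfinite(angles)], bins=edges)
    return TiltSeries(angles=angles, bin_edges=edges, counts=counts, times=traj.times)


def insertion_series(
    traj: Trajectory,
    lipid: LipidDefinition,
    plane: GatePlane,
) -> InsertionSeries:
    """Fraction of tail atoms on the membrane (outward) side of the gate plane.

    Per frame and per tail: inserted atoms / tail atoms; the overall fraction
    pools all tail atoms, i.e. it is the atom-count-weighted mean of the
    per-tail fractions.
    """
    if lipid.n_tails == 0:
        raise ValueError("lipid has no tails defined")
    sizes = np.array([len(t) for t in lipid.tails], dtype=int)
    per_tail = np.empty((traj.n_frames, lipid.n_tails))
    inserted_total = np.zeros(traj.n_frames)
    for t, tail in enumerate(lipid.tails):
        sd = plane.signed_distance(traj.frames[:, list(tail)].reshape(-1, 3))
        inserted = (sd.reshape(traj.n_frames, len(tail)) > 0).sum(axis=1)
        per_tail[:, t] = inserted / len(tail)
        inserted_total += inserted
    overall = inserted_total / sizes.sum()
    return InsertionSeries(
        overall=overall, per_tail=per_tail, tail_sizes=sizes, times=traj.times
    )


def egress_order(series: InsertionSeries, exit_threshold: float = 0.9) -> EgressReport:
    """First frame each tail reaches the exit threshold, and the exit order.

    A threshold of 0 makes every tail "exit" at frame 0 (fractions are
    non-negative); tails that never reach the threshold are reported as
    not-exited (None).
    """
    n_frames, n_tails = series.per_tail.shape
    if n_frames == 0:
        raise ValueError("empty insertion series")
    first_exit: list[int | None] = []
    for t in range(n_tails):
        hits = np.nonzero(series.per_tail[:, t] >= exit_threshold)[0]
        first_exit.append(int(hits[0]) if hits.size else None)
    order = sorted(
        (t for t in range(n_tails) if first_exit[t] is not None),
        key=lambda t: (first_exit[t], t),
    )
    return EgressReport(
        first_exit=tuple(first_exit), order=tuple(order), exit_threshold=exit_threshold
    )
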