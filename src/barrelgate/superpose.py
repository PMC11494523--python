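"""Least-squares rigid-body superposition and the RMSD/RMSF observables.

The fit is the classic SVD solution to the orthogonal Procrustes problem
restricted to proper rotations: reflections are resolved by flipping the
sign of the smallest singular direction, so the returned rotation always has
determinant +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, SelectionError
from .structure_io import Structure, Trajectory

__all__ = [
    "Superposition",
    "RmsfProfile",
    "BACKBONE_ATOMS",
    "kabsch",
    "rmsd_series",
    "rmsf",
]

#: Backbone atom names used for protein fits.  Carbonyl O is excluded, which
#: matches the conventional MD "backbone" group; pass your own set to widen it.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C")

_COLLINEAR_RTOL = 1e-8


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> R x + t`` and its minimized RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue root-mean-square fluctuations (Å)."""

    resids: np.ndarray
    values: np.ndarray


def _check_nondegenerate(centered: np.ndarray, label: str) -> None:
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= _COLLINEAR_RTOL * max(sv[0], 1.0):
        raise DegenerateGeometryError(f"{label} point set is collinear or degenerate")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal proper rigid fit of ``mobile`` onto ``reference``.

    Both arguments are ``(n, 3)`` arrays with equal ``n >= 3``.  The returned
    transform minimizes the RMSD over all rotations+translations, and
    ``rmsd`` is that minimum.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share an (n, 3) shape")
    if P.shape[0] < 3:
        raise DegenerateGeometryError("at least 3 points required for a rigid fit")
    p_cent = P.mean(axis=0)
    q_cent = Q.mean(axis=0)
    Pc = P - p_cent
    Qc = Q - q_cent
    _check_nondegenerate(Pc, "mobile")
    _check_nondegenerate(Qc, "reference")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    t = q_cent - R @ p_cent
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame minimized RMSD (Å) of a selection onto a reference frame.

    Every frame is independently superposed onto ``reference_frame`` over the
    selection before the deviation is measured.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("rmsd_series: empty selection")
    ref = traj.frames[reference_frame][selection]
    return np.array(
        [kabsch(traj.frames[f][selection], ref).rmsd for f in range(traj.n_frames)]
    )


def rmsf(
    traj: Trajectory,
    selection: Sequence[int] | np.ndarray,
    align_selection: Sequence[int] | np.ndarray | None = None,
    per_residue: bool = True,
) -> RmsfProfile:
    """Root-mean-square fluctuation about the mean structure.

    Frames are first aligned to frame 0 on ``align_selection``, the mean
    structure is formed, and the original frames are re-aligned to that mean
    (one iteration).  The per-atom RMSF is the root-mean-square displacement
    from the mean position; with ``per_residue`` the values are averaged over
    each residue's selected atoms and keyed by resid.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf requires at least 2 frames")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("rmsf: empty selection")
    if align_selection is None:
        align_selection = selection
    align_selection = np.asarray(align_selection, dtype=int)

    def _aligned_to(target_align: np.ndarray) -> np.ndarray:
        out = np.empty_like(traj.frames)
        for f in range(traj.n_frames):
            sup = kabsch(traj.frames[f][align_selection], target_align)
            out[f] = sup.apply(traj.frames[f])
        return out

    pass1 = _aligned_to(traj.frames[0][align_selection])
    mean_align = pass1.mean(axis=0)[align_selection]
    aligned = _aligned_to(mean_align)
    mean = aligned.mean(axis=0)
    disp2 = np.sum((aligned[:, selection] - mean[selection]) ** 2, axis=2)
    per_atom = np.sqrt(disp2.mean(axis=0))
    if not per_residue:
        resids = traj.atom_template.resids[selection]
        return RmsfProfile(resids=resids, values=per_atom)
    resids = traj.atom_template.resids[selection]
    uniq = []
    for r in resids:
        if r not in uniq:
            uniq.append(r)
    uniq_arr = np.array(uniq, dtype=int)
    values = np.array([per_atom[resids == r].mean() for r in uniq_arr])
    return RmsfProfile(resids=uniq_arr, values=values)
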