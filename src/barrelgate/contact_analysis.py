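"""Lipid–protein contact frequencies and the cross-replica geometric score.

A residue is "in contact" in a frame iff any of its heavy atoms lies within
the cutoff (default 4.0 Å) of any lipid heavy atom — a binary per-frame
criterion, so the per-replica frequency is a fraction of frames in [0, 1].
The replica-level score of a residue is the geometric mean of its
frequencies across independent replicas: one replica without contact zeroes
the score, which is exactly the "reproducible contact" semantics wanted
when averaging replicas that should agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import MappingError
from .structure_io import Structure, Trajectory

__all__ = [
    "ContactTable",
    "heavy_atom_mask",
    "protein_atoms_by_resid",
    "frame_contacts",
    "contact_frequencies",
    "geometric_score",
    "annotate_scores",
]


def heavy_atom_mask(structure: Structure) -> np.ndarray:
    """Boolean mask of non-hydrogen atoms.

    Uses the element field; when it is blank the atom name is consulted
    instead (leading digits stripped, then a leading H means hydrogen) with
    a warning, since name-based inference is a heuristic.
    """
    mask = np.empty(structure.n_atoms, dtype=bool)
    warned = False
    for i, a in enumerate(structure.atoms):
        el = a.element.strip()
        if el:
            mask[i] = el.upper() != "H"
        else:
            if not warned:
                warnings.warn(
                    "element fields missing; inferring hydrogens from atom names",
                    stacklevel=2,
                )
                warned = True
            mask[i] = not a.name.lstrip("0123456789").upper().startswith("H")
    return mask


def protein_atoms_by_resid(
    structure: Structure,
    indices: Sequence[int] | np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Heavy-atom indices grouped by residue number, in template order."""
    if indices is None:
        indices = np.arange(structure.n_atoms)
    indices = np.asarray(indices, dtype=int)
    heavy = heavy_atom_mask(structure)
    out: dict[int, list[int]] = {}
    for i in indices:
        if heavy[i]:
            out.setdefault(structure.atoms[i].resid, []).append(int(i))
    return {r: np.array(v, dtype=int) for r, v in out.items()}


def frame_contacts(
    coords: np.ndarray,
    lipid_atoms: Sequence[int] | np.ndarray,
    atoms_by_resid: Mapping[int, np.ndarray],
    cutoff: float = 4.0,
) -> set[int]:
    """Residues with any heavy atom within ``cutoff`` of any lipid heavy atom.

    Callers are expected to pass heavy-atom index sets (see
    :func:`protein_atoms_by_resid` / :func:`heavy_atom_mask`); the distance
    test itself is a KD-tree nearest-neighbour query per residue.
    """
    lipid_atoms = np.asarray(lipid_atoms, dtype=int)
    if lipid_atoms.size == 0:
        raise ValueError("frame_contacts: empty lipid atom set")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords[lipid_atoms])
    hits: set[int] = set()
    for resid, idx in atoms_by_resid.items():
        dmin, _ = tree.query(coords[np.asarray(idx, dtype=int)], k=1)
        if np.min(dmin) <= cutoff:
            hits.add(int(resid))
    return hits


def contact_frequencies(
    traj: Trajectory,
    lipid_atoms: Sequence[int] | np.ndarray,
    atoms_by_resid: Mapping[int, np.ndarray],
    cutoff: float = 4.0,
) -> dict[int, float]:
    """Fraction of frames in which each residue contacts the lipid."""
    if traj.n_frames == 0:
        raise ValueError("contact_frequencies: empty trajectory")
    counts: dict[int, int] = {int(r): 0 for r in atoms_by_resid}
    for f in range(traj.n_frames):
        for r in frame_contacts(traj.frames[f], lipid_atoms, atoms_by_resid, cutoff):
            counts[r] += 1
    return {r: c / traj.n_frames for r, c in counts.items()}


def geometric_score(frequencies: Sequence[float]) -> float:
    """Geometric mean of per-replica contact frequencies, in [0, 1].

    Exactly zero when any replica frequency is zero; the identity for a
    single replica.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("at least one replica frequency required")
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(freqs == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(freqs))))


@dataclass(frozen=True)
class ContactTable:
    """Per-residue contact frequencies for each replica plus the geometric score."""

    resids: np.ndarray               # (R,)
    frequencies: np.ndarray          # (R, K) in [0, 1]
    scores: np.ndarray               # (R,) geometric means

    @classmethod
    def from_replicas(cls, replica_freqs: Sequence[Mapping[int, float]]) -> "ContactTable":
        """Combine per-replica frequency mappings; missing residues count as 0."""
        if not replica_freqs:
            raise ValueError("at least one replica required")
        resids = sorted({int(r) for m in replica_freqs for r in m})
        freq = np.array(
            [[float(m.get(r, 0.0)) for m in replica_freqs] for r in resids]
        ).reshape(len(resids), len(replica_freqs))
        scores = np.array([geometric_score(row) for row in freq])
        return cls(resids=np.array(resids, dtype=int), frequencies=freq, scores=scores)

    @property
    def n_replicas(self) -> int:
        return self.frequencies.shape[1]

    def score_of(self, resid: int) -> float:
        pos = np.nonzero(self.resids == resid)[0]
        return float(self.scores[pos[0]]) if pos.size else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"resid": self.resids})
        for k in range(self.n_replicas):
            df[f"freq_rep{k}"] = self.frequencies[:, k]
        df["score"] = self.scores
        return df


def annotate_scores(structure: Structure, table: ContactTable) -> Structure:
    """Copy of the structure with each residue's score on all its atoms.

    Residues absent from the table are scored 0; a table residue absent from
    the structure is an error (the annotation would silently vanish).
    """
    present = set(int(r) for r in structure.resids)
    missing = [int(r) for r in table.resids if int(r) not in present]
    if missing:
        raise MappingError(f"table residues absent from structure: {missing}")
    by_resid = {int(r): float(s) for r, s in zip(table.resids, table.scores)}
    scores = np.array([by_resid.get(a.resid, 0.0) for a in structure.atoms])
    return structure.with_scores(scores)
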