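"""Lateral-gate aperture metrics and membrane-lipid flicker depth.

The aperture is tracked as Cα–Cα distances across residue pairs that span
the opening between the first and last barrel strands; the defaults are
three pairs evenly distributed along the GfcD-C gate.  "Flicker" measures
how deep membrane-lipid atoms transiently reach past the gate plane into the
channel, restricted to atoms near the gate-flanking residues so that lipids
elsewhere in the bilayer cannot register.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import MappingError, SelectionError
from .lipid_analysis import GatePlane
from .structure_io import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GateDefinition",
    "ApertureSeries",
    "ClosureReport",
    "gfcd_gate",
    "aperture_series",
    "closure_report",
    "flicker_depth_series",
]


@dataclass(frozen=True)
class GateDefinition:
    """Residue pairs and flanking residues defining the lateral aperture.

    Distances are measured Cα to Cα.  ``closure_threshold`` (Å) is the
    distance below which a pair counts as closed; the gate is never declared
    closed silently — reports always carry the per-pair below-threshold
    fractions so the threshold choice stays visible.
    """

    pairs: tuple[tuple[int, int], ...]
    flank_resids: tuple[int, ...] = ()
    closure_threshold: float = 6.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one gate pair required")
        object.__setattr__(
            self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs)
        )
        object.__setattr__(self, "flank_resids", tuple(int(r) for r in self.flank_resids))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in self.pairs)


def gfcd_gate(closure_threshold: float = 6.0) -> GateDefinition:
    """The default GfcD-C gate: three Cα pairs along the β1/β13 opening.

    Pairs are identified by residue number only (437–668, 433–666, 427–663);
    the residue names found in the structure are logged, not checked.
    """
    return GateDefinition(
        pairs=((437, 668), (433, 666), (427, 663)),
        closure_threshold=closure_threshold,
    )


@dataclass(frozen=True)
class ApertureSeries:
    """Per-pair aperture distance time series (Å) with summary statistics."""

    pair_labels: tuple[str, ...]
    distances: np.ndarray            # (n_frames, n_pairs)
    times: np.ndarray | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.distances.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.distances.std(axis=0, ddof=0)

    @property
    def min(self) -> np.ndarray:
        return self.distances.min(axis=0)


@dataclass(frozen=True)
class ClosureReport:
    """Fraction of frames below the closure threshold, per pair."""

    pair_labels: tuple[str, ...]
    below_fraction: np.ndarray
    closure_threshold: float
    stayed_open: bool


def _ca_index(traj: Trajectory, resid: int) -> int:
    for i, a in enumerate(traj.atom_template.atoms):
        if a.resid == resid and a.name == "CA":
            logger.debug("gate residue %d resolved to %s CA", resid, a.resname)
            return i
    raise MappingError(f"no CA atom found for residue {resid}")


def aperture_series(traj: Trajectory, gate: GateDefinition) -> ApertureSeries:
    """Euclidean Cα–Cα distance per gate pair per frame."""
    idx = np.array([[_ca_index(traj, a), _ca_index(traj, b)] for a, b in gate.pairs])
    diff = traj.frames[:, idx[:, 0]] - traj.frames[:, idx[:, 1]]
    distances = np.linalg.norm(diff, axis=2)
    return ApertureSeries(pair_labels=gate.labels, distances=distances, times=traj.times)


def closure_report(series: ApertureSeries, gate: GateDefinition) -> ClosureReport:
    """Below-threshold frame fractions and the "gate stayed open" verdict.

    The gate stayed open iff no pair ever dipped below the closure threshold.
    """
    if series.distances.shape[0] == 0:
        raise ValueError("empty aperture series")
    below = (series.distances < gate.closure_threshold).mean(axis=0)
    return ClosureReport(
        pair_labels=series.pair_labels,
        below_fraction=below,
        closure_threshold=gate.closure_threshold,
        stayed_open=bool(np.all(below == 0.0)),
    )


def flicker_depth_series(
    traj: Trajectory,
    gate_plane: GatePlane,
    membrane_atoms: Sequence[int] | np.ndarray,
    flank_ca_atoms: Sequence[int] | np.ndarray,
    gate_region_radius: float = 8.0,
) -> np.ndarray:
    """Maximum inward penetration depth (Å) of membrane atoms, per frame.

    Only membrane atoms within ``gate_region_radius`` of the nearest
    gate-flank Cα count; for those, the depth is the distance past the gate
    plane on the inward (channel) side, clamped at zero.  A frame with no
    membrane atom inward of the plane scores 0.
    """
    membrane_atoms = np.asarray(membrane_atoms, dtype=int)
    flank_ca_atoms = np.asarray(flank_ca_atoms, dtype=int)
    if membrane_atoms.size == 0:
        raise SelectionError("flicker_depth_series: empty membrane selection")
    if flank_ca_atoms.size == 0:
        raise SelectionError("flicker_depth_series: empty gate-flank selection")
    depths = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        mem = traj.frames[f][membrane_atoms]
        flank = traj.frames[f][flank_ca_atoms]
        d2 = ((mem[:, None, :] - flank[None, :, :]) ** 2).sum(axis=2)
        in_region = np.sqrt(d2.min(axis=1)) <= gate_region_radius
        if not np.any(in_region):
            continue
        sd = gate_plane.signed_distance(mem[in_region])
        depths[f] = max(0.0, float(np.max(-sd)))
    return depths
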