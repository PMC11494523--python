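"""Toy barrel structures and trajectories with exactly known ground truth.

The generator emulates, at desk scale, the observables of a microsecond
membrane simulation of a lateral-gate β-barrel: a Cα-only barrel of
``n_strands`` strands placed on a cylinder with one strand slot left vacant
(the lateral opening), per-residue Gaussian positional fluctuations, a
surrogate two-phosphorus lipid head whose tilt follows a prescribed
schedule, tail pseudo-atoms crossing the construction's gate plane on a
prescribed per-frame schedule, probe atoms realizing prescribed per-residue
contact frame-fractions, and membrane pseudo-atoms sitting outside the gate.

Every schedule is realized exactly by construction, so the generator's
:class:`GroundTruth` record is the oracle for the analysis modules.  There
is no physics here: no force field, no membrane thermodynamics, no water.

Determinism: all randomness flows from ``(seed, replica, stage)``-scoped
numpy generators, so the same spec and seed give bit-identical trajectories
and adding a generator stage never perturbs another stage's stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gate_analysis import GateDefinition
from .lipid_analysis import GatePlane, LipidDefinition, fit_plane_points
from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "build_toy_barrel",
    "generate_trajectory",
    "default_spec",
    "stable_gate_spec",
]

_STAGE_FLUCT = 1

# fixed geometry constants of the construction
_HEAD_LENGTH = 9.0       # Å, PA-PB distance of the surrogate head
_CONTACT_NEAR = 3.0      # Å, probe-to-Cα distance in contact frames
_CONTACT_FAR = 40.0      # Å, radial probe offset out of contact
_TAIL_PLANE_OFFSET = 1.5  # Å, tail atoms sit this far on either side of the plane
_MEMBRANE_OFFSET = 2.0   # Å, membrane pseudo-atoms outside the plane

_LIPID_RESID = 900
_TAIL_RESID0 = 901
_PROBE_RESID0 = 910
_DECOY_H_RESID = 930
_MEMBRANE_RESID0 = 950


@dataclass
class SyntheticSpec:
    """Everything that defines one synthetic system and its schedules.

    Schedules are optional; a spec with none of them is an "uncomplexed"
    barrel (protein + membrane pseudo-atoms only).  ``fluct_sigma`` is the
    per-coordinate Gaussian σ (Å), either a scalar for all residues or a
    mapping resid → σ (unlisted residues get 0).
    """

    n_strands: int = 13
    strand_length: int = 19
    barrel_radius: float = 15.0
    n_frames: int = 200
    fluct_sigma: float | Mapping[int, float] = 0.3
    tilt_schedule: Sequence[float] | None = None
    egress_schedule: np.ndarray | None = None          # (n_frames, n_tails) atom counts
    contact_pattern: Mapping[int, Sequence[float]] | None = None  # resid -> per-replica fractions
    gate_pair_schedule: Mapping[tuple[int, int], Sequence[float]] | None = None
    gate_pairs: tuple[tuple[int, int], ...] = ((437, 668), (433, 666), (427, 663))
    resid_start: int = 424
    rise: float = 3.4            # Å per residue along the strand
    tail_atoms: int = 4          # pseudo-atoms per aliphatic tail
    n_tails: int = 6
    dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 3:
            raise ValueError("a barrel needs at least 3 strands")
        if self.barrel_radius <= 0:
            raise ValueError("barrel_radius must be positive")
        if self.strand_length < 1 or self.n_frames < 1:
            raise ValueError("strand_length and n_frames must be >= 1")
        if self.tilt_schedule is not None:
            self.tilt_schedule = np.asarray(self.tilt_schedule, dtype=float)
            if self.tilt_schedule.shape != (self.n_frames,):
                raise ValueError("tilt_schedule must have one angle per frame")
        if self.egress_schedule is not None:
            self.egress_schedule = np.asarray(self.egress_schedule, dtype=int)
            if self.egress_schedule.shape != (self.n_frames, self.n_tails):
                raise ValueError(
                    "egress_schedule must be (n_frames, n_tails) inserted-atom counts"
                )
            if (self.egress_schedule.min() < 0
                    or self.egress_schedule.max() > self.tail_atoms):
                raise ValueError("egress counts must lie in [0, tail_atoms]")
        if self.contact_pattern is not None:
            for r, fr in self.contact_pattern.items():
                if any(f < 0 or f > 1 for f in fr):
                    raise ValueError(f"contact fractions for residue {r} not in [0, 1]")
                if not (self.resid_start <= r < self.resid_start + self.n_residues):
                    raise ValueError(f"contact residue {r} outside the toy barrel")
        if self.gate_pair_schedule is not None:
            for pair, sched in self.gate_pair_schedule.items():
                if len(sched) != self.n_frames:
                    raise ValueError(f"schedule for pair {pair} must cover every frame")

    # ------------------------------------------------------------------ geometry
    @property
    def n_residues(self) -> int:
        return self.n_strands * self.strand_length

    @property
    def n_slots(self) -> int:
        # one extra angular slot stays vacant: the lateral opening
        return self.n_strands + 1

    def slot_angle(self, slot: int) -> float:
        return 2.0 * np.pi * slot / self.n_slots

    @property
    def gap_angle(self) -> float:
        return self.slot_angle(self.n_strands)

    @property
    def z_mid(self) -> float:
        return 0.5 * (self.strand_length - 1) * self.rise

    def strand_of(self, resid: int) -> int:
        """1-based strand index of a residue."""
        return (resid - self.resid_start) // self.strand_length + 1

    def strand_resids(self, strand: int) -> range:
        lo = self.resid_start + (strand - 1) * self.strand_length
        return range(lo, lo + self.strand_length)

    @property
    def flank_resids(self) -> tuple[int, ...]:
        return tuple(self.strand_resids(1)) + tuple(self.strand_resids(self.n_strands))

    def ca_position(self, resid: int) -> np.ndarray:
        s = self.strand_of(resid)
        j = (resid - self.resid_start) % self.strand_length
        if s % 2 == 0:  # antiparallel: even strands run downward
            j = self.strand_length - 1 - j
        phi = self.slot_angle(s - 1)
        return np.array([
            self.barrel_radius * np.cos(phi),
            self.barrel_radius * np.sin(phi),
            j * self.rise,
        ])

    def gate_plane(self) -> GatePlane:
        """The construction's gate plane: least-squares fit of the base flank
        Cα positions, oriented away from the barrel axis.

        Using the fitted plane (rather than the cylinder tangent at the vacant
        slot) makes the construction's plane the same one an analysis recovers
        from the flank residues, so scheduled insertions stay classifiable with
        a clean margin.
        """
        pts = np.array([self.ca_position(r) for r in self.flank_resids])
        return fit_plane_points(pts, np.array([0.0, 0.0, self.z_mid]))

    def gate_definition(self, closure_threshold: float = 6.0) -> GateDefinition:
        return GateDefinition(
            pairs=self.gate_pairs,
            flank_resids=self.flank_resids,
            closure_threshold=closure_threshold,
        )

    def sigma_of(self, resid: int) -> float:
        if isinstance(self.fluct_sigma, Mapping):
            return float(self.fluct_sigma.get(resid, 0.0))
        return float(self.fluct_sigma)

    @property
    def pinned_resids(self) -> frozenset[int]:
        """Residues excluded from positional noise so schedules stay exact.

        Contact-pattern residues (and their strand neighbours, which would
        otherwise fluctuate into the probe cutoff) and gate-pair residues
        under an explicit distance schedule.
        """
        pinned: set[int] = set()
        if self.contact_pattern:
            for r in self.contact_pattern:
                pinned.update((r - 1, r, r + 1))
        if self.gate_pair_schedule:
            for a, b in self.gate_pair_schedule:
                pinned.update((a, b))
        lo = self.resid_start
        return frozenset(r for r in pinned if lo <= r < lo + self.n_residues)


@dataclass
class GroundTruth:
    """The schedules a synthetic trajectory realizes, plus atom bookkeeping."""

    replica: int
    seed: int
    gate_plane_point: np.ndarray
    gate_plane_normal: np.ndarray
    gate_pairs: tuple[tuple[int, int], ...]
    flank_resids: tuple[int, ...]
    pinned_resids: tuple[int, ...]
    tilt: np.ndarray | None = None
    egress_counts: np.ndarray | None = None      # (n_frames, n_tails)
    egress_fractions: np.ndarray | None = None   # counts / tail_atoms
    contact_fractions: dict[int, float] | None = None  # realized, this replica
    pair_distance_schedule: dict[str, np.ndarray] | None = None
    atom_groups: dict = field(default_factory=dict)

    def lipid_definition(self) -> LipidDefinition:
        g = self.atom_groups
        if "pa" not in g or "tails" not in g:
            raise ValueError("this trajectory carries no complete surrogate lipid")
        return LipidDefinition(
            pa_atom=g["pa"],
            pb_atom=g["pb"],
            tails=tuple(tuple(t) for t in g["tails"]),
            head_atoms=(g["pa"], g["pb"]),
        )

    def plane(self) -> GatePlane:
        return GatePlane(point=self.gate_plane_point, normal=self.gate_plane_normal)

    def to_json(self, path: str | Path) -> None:
        def _conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer, np.floating)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): _conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_conv(v) for v in x]
            return x

        payload = {k: _conv(v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def build_toy_barrel(spec: SyntheticSpec) -> Structure:
    """The Cα-only barrel at its base geometry (no lipid, no membrane).

    Strands sit on a cylinder of ``barrel_radius`` with one angular slot
    vacant between the first and last strand — the lateral opening.
    Deterministic given the spec.
    """
    atoms = []
    serial = 1
    for r in range(spec.resid_start, spec.resid_start + spec.n_residues):
        atoms.append(Atom(
            serial=serial, name="CA", resname="ALA", resid=r, chain="A",
            element="C", coords=spec.ca_position(r),
        ))
        serial += 1
    return Structure(atoms, title="toy barrel")


def _tangent(spec: SyntheticSpec, normal: np.ndarray) -> np.ndarray:
    """In-plane horizontal direction across the gap (exactly ⊥ the plane normal)."""
    g = spec.gap_angle
    t = np.array([-np.sin(g), np.cos(g), 0.0])
    t = t - (t @ normal) * normal
    return t / np.linalg.norm(t)


def _decoy_target(spec: SyntheticSpec) -> int:
    """A mid-barrel residue used to park the decoy hydrogen."""
    mid_strand = spec.n_strands // 2
    return spec.strand_resids(mid_strand)[spec.strand_length // 2]


def generate_trajectory(
    spec: SyntheticSpec, replica: int = 0
) -> tuple[Trajectory, GroundTruth]:
    """Build a trajectory realizing every schedule of the spec exactly.

    The atom template is the toy barrel plus, when the respective schedule is
    present, the surrogate lipid head (PA/PB), tail pseudo-atoms, contact
    probe atoms (with one decoy hydrogen to exercise heavy-atom filtering),
    and always a handful of membrane pseudo-atoms outside the gate plane.
    """
    protein = build_toy_barrel(spec)
    atoms = list(protein.atoms)
    serial = len(atoms) + 1
    F = spec.n_frames
    plane = spec.gate_plane()
    tangent = _tangent(spec, plane.normal)
    zhat = np.array([0.0, 0.0, 1.0])
    groups: dict = {"protein_ca": list(range(len(atoms)))}

    def _add(name, resname, resid, element, coords) -> int:
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, resname=resname, resid=resid,
                          chain="L" if resname != "MEM" else "M",
                          element=element, coords=coords))
        serial += 1
        return len(atoms) - 1

    pa_base = np.array([0.0, 0.0, spec.z_mid])
    has_lipid = spec.tilt_schedule is not None or spec.egress_schedule is not None
    if has_lipid:
        groups["pa"] = _add("PA", "LPA", _LIPID_RESID, "P", pa_base.copy())
        groups["pb"] = _add("PB", "LPA", _LIPID_RESID, "P",
                            pa_base + np.array([0.0, 0.0, _HEAD_LENGTH]))

    tail_bases: list[list[np.ndarray]] = []
    if spec.egress_schedule is not None:
        groups["tails"] = []
        for t in range(spec.n_tails):
            tail_idx, bases = [], []
            off_t = (t - (spec.n_tails - 1) / 2.0) * 2.0
            for a in range(spec.tail_atoms):
                base = (plane.point + tangent * off_t
                        + zhat * (-spec.z_mid - 10.0 - 1.5 * a))
                bases.append(base)
                tail_idx.append(_add(f"C{a + 1}", "LPT", _TAIL_RESID0 + t, "C", base))
            groups["tails"].append(tail_idx)
            tail_bases.append(bases)

    probe_idx: dict[int, int] = {}
    contact_frames: dict[int, int] = {}
    if spec.contact_pattern is not None:
        reps = {r: len(fr) for r, fr in spec.contact_pattern.items()}
        if any(replica >= k for k in reps.values()):
            raise ValueError(
                f"replica {replica} not covered by the contact pattern "
                f"(fractions per residue: {reps})"
            )
        for i, (r, fracs) in enumerate(sorted(spec.contact_pattern.items())):
            m = int(round(float(fracs[replica]) * F))
            contact_frames[r] = m
            ca = spec.ca_position(r)
            rhat = np.array([*(ca[:2] / np.linalg.norm(ca[:2])), 0.0])
            probe_idx[r] = _add("C1", "LIG", _PROBE_RESID0 + i, "C",
                                ca + _CONTACT_FAR * rhat)
        target = _decoy_target(spec)
        tca = spec.ca_position(target)
        trhat = np.array([*(tca[:2] / np.linalg.norm(tca[:2])), 0.0])
        groups["decoy_h"] = _add("H1", "LIG", _DECOY_H_RESID, "H", tca + 2.5 * trhat)
        groups["probes"] = dict(probe_idx)

    groups["membrane"] = []
    for k, (dx, dz) in enumerate([(-2.0, -2.0), (-2.0, 2.0), (2.0, -2.0), (2.0, 2.0)]):
        pos = plane.point + plane.normal * _MEMBRANE_OFFSET + tangent * dx + zhat * dz
        groups["membrane"].append(_add("C1", "MEM", _MEMBRANE_RESID0 + k, "C", pos))

    template = Structure(atoms, title=f"synthetic replica {replica}")
    base = template.coords
    frames = np.repeat(base[None, :, :], F, axis=0)

    # stage 1: per-residue Gaussian fluctuations on non-pinned protein atoms
    pinned = spec.pinned_resids
    n_prot = spec.n_residues
    sigma = np.array([
        0.0 if template.atoms[i].resid in pinned else spec.sigma_of(template.atoms[i].resid)
        for i in range(n_prot)
    ])
    rng = np.random.default_rng([int(spec.seed), int(replica), _STAGE_FLUCT])
    noise = rng.standard_normal((F, n_prot, 3)) * sigma[None, :, None]
    frames[:, :n_prot] += noise

    # gate-pair distance schedule: residue b slides along the base a->b direction
    pair_sched: dict[str, np.ndarray] | None = None
    if spec.gate_pair_schedule is not None:
        pair_sched = {}
        ca_of = {a.resid: i for i, a in enumerate(template.atoms[:n_prot])}
        for (ra, rb), sched in spec.gate_pair_schedule.items():
            sched = np.asarray(sched, dtype=float)
            ia, ib = ca_of[ra], ca_of[rb]
            u = base[ib] - base[ia]
            u = u / np.linalg.norm(u)
            frames[:, ib] = base[ia] + sched[:, None] * u[None, :]
            pair_sched[f"{ra}-{rb}"] = sched

    # tilt schedule: PB orbits PA in the xz-plane at the scheduled angle from +Z
    if spec.tilt_schedule is not None:
        th = np.radians(spec.tilt_schedule)
        frames[:, groups["pb"]] = pa_base + _HEAD_LENGTH * np.stack(
            [np.sin(th), np.zeros(F), np.cos(th)], axis=1
        )

    # egress schedule: the first `count` atoms of each tail sit outward
    egress_fracs = None
    if spec.egress_schedule is not None:
        for t in range(spec.n_tails):
            for a in range(spec.tail_atoms):
                inserted = spec.egress_schedule[:, t] > a
                side = np.where(inserted, _TAIL_PLANE_OFFSET, -_TAIL_PLANE_OFFSET)
                frames[:, groups["tails"][t][a]] = (
                    tail_bases[t][a][None, :] + side[:, None] * plane.normal[None, :]
                )
        egress_fracs = spec.egress_schedule / float(spec.tail_atoms)

    # contact pattern: probe sits 3 Å from its residue's Cα in the first m frames
    realized_contacts = None
    if spec.contact_pattern is not None:
        realized_contacts = {}
        for r, idx in probe_idx.items():
            m = contact_frames[r]
            ca = spec.ca_position(r)
            rhat = np.array([*(ca[:2] / np.linalg.norm(ca[:2])), 0.0])
            near = ca + _CONTACT_NEAR * rhat
            far = ca + _CONTACT_FAR * rhat
            frames[:m, idx] = near
            frames[m:, idx] = far
            realized_contacts[r] = m / F

    times = np.arange(F, dtype=float) * spec.dt_ns + spec.dt_ns
    traj = Trajectory(template, frames, times=times)
    truth = GroundTruth(
        replica=replica,
        seed=spec.seed,
        gate_plane_point=plane.point,
        gate_plane_normal=plane.normal,
        gate_pairs=spec.gate_pairs,
        flank_resids=spec.flank_resids,
        pinned_resids=tuple(sorted(pinned)),
        tilt=None if spec.tilt_schedule is None else np.asarray(spec.tilt_schedule),
        egress_counts=spec.egress_schedule,
        egress_fractions=egress_fracs,
        contact_fractions=realized_contacts,
        pair_distance_schedule=pair_sched,
        atom_groups=groups,
    )
    return traj, truth


def _staircase_egress(n_frames: int, n_tails: int, tail_atoms: int,
                      start_step: int = 20, atoms_per_step: int = 5) -> np.ndarray:
    """Sequential tail exit: tail t starts at frame ``start_step * t`` and
    gains one inserted atom every ``atoms_per_step`` frames."""
    f = np.arange(n_frames)[:, None]
    t = np.arange(n_tails)[None, :]
    return np.clip((f - start_step * t) // atoms_per_step, 0, tail_atoms).astype(int)


def default_spec(seed: int = 0, n_frames: int = 200, n_replicas: int = 3) -> SyntheticSpec:
    """The complexed study system at toy scale: all schedules active.

    Constant 135° head tilt (inside the stabilized range a tilted anchored
    lipid adopts), a sequential six-tail egress staircase, and a contact
    pattern concentrated on gate-flank residues across ``n_replicas``
    replicas, with one deliberately irreproducible residue (zero in one
    replica) to exercise the zero-propagation of the geometric score.
    """
    def _reps(*vals: float) -> tuple[float, ...]:
        if len(vals) < n_replicas:
            vals = tuple(vals) + tuple(vals[-1] for _ in range(n_replicas - len(vals)))
        return tuple(vals[:n_replicas])

    spec = SyntheticSpec(
        n_frames=n_frames,
        fluct_sigma=0.3,
        tilt_schedule=np.full(n_frames, 135.0),
        egress_schedule=_staircase_egress(n_frames, 6, 4),
        contact_pattern={
            437: _reps(0.9, 0.8, 0.85),
            668: _reps(0.7, 0.75, 0.8),
            663: _reps(0.5, 0.6, 0.55),
            427: _reps(0.3, 0.4, 0.35),
            545: _reps(0.2, 0.0, 0.3),
        },
        seed=seed,
    )
    return spec


def stable_gate_spec(seed: int = 0, n_frames: int = 200,
                     fluct_sigma: float = 0.3) -> SyntheticSpec:
    """The uncomplexed system: no lipid, only thermal-like Cα fluctuations.

    Gate-pair distances then fluctuate only through the per-residue noise,
    which is the regime in which a stable lateral gate "barely fluctuates
    and does not close"."""
    return SyntheticSpec(n_frames=n_frames, fluct_sigma=fluct_sigma, seed=seed)
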