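"""Per-replica orchestration and cross-replica aggregation.

Every number written here is produced by a module operation — this layer
only resolves selections, routes arrays, and serializes CSV tables.  Output
files are deterministic: fixed float formatting, no timestamps, and a config
hash in the header so tables can be traced to the exact thresholds that
produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import contact_analysis, gate_analysis, lipid_analysis, superpose
from .contact_analysis import ContactTable
from .exceptions import ConfigError
from .structure_io import (
    Structure,
    Trajectory,
    read_pdb,
    select,
    write_annotated_pdb,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReplicaResult",
    "AggregateResult",
    "run_replica",
    "aggregate",
    "load_replica_result",
]

FLOAT_FMT = "%.6f"


def _normalize_criteria(raw: Mapping[str, Any]) -> dict:
    """YAML selection block -> keyword criteria for :func:`select`.

    A ``resid`` entry may be an int, a list of ints, or ``{range: [lo, hi]}``.
    """
    crit = {}
    for key, val in raw.items():
        if key == "resid" and isinstance(val, Mapping) and "range" in val:
            lo, hi = val["range"]
            crit[key] = (int(lo), int(hi))
        elif isinstance(val, list):
            crit[key] = tuple(val)
        else:
            crit[key] = val
    return crit


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from a YAML file.

    Paths are resolved relative to the config file's directory.  All
    thresholds have defaults mirroring the package-wide conventions; the
    ``config init`` CLI subcommand prints them.
    """

    reference: Path
    trajectories: tuple[Path, ...]
    output_dir: Path
    seed: int = 0
    backbone_atoms: tuple[str, ...] = superpose.BACKBONE_ATOMS
    protein_selection: dict = field(default_factory=lambda: {"chain": "A"})
    membrane_selection: dict = field(default_factory=lambda: {"resname": "MEM"})
    gate_pairs: tuple[tuple[int, int], ...] = ((437, 668), (433, 666), (427, 663))
    gate_flank_resids: tuple[int, ...] = ()
    closure_threshold: float = 6.0
    gate_region_radius: float = 8.0
    axis_point: tuple[float, float, float] | None = None
    lipid: dict | None = None      # pa/pb/tails/contact_selection criteria blocks
    contact_cutoff: float = 4.0
    exit_threshold: float = 0.9
    histogram_bin_width: float = 2.5

    def __post_init__(self) -> None:
        self.reference = Path(self.reference)
        self.trajectories = tuple(Path(p) for p in self.trajectories)
        self.output_dir = Path(self.output_dir)
        if not self.trajectories:
            raise ConfigError("at least one replica trajectory required")

    def validate_paths(self) -> None:
        missing = [str(p) for p in (self.reference, *self.trajectories) if not p.exists()]
        if missing:
            raise ConfigError(f"input file(s) not found: {missing}")

    # ---------------------------------------------------------------- yaml io
    def to_dict(self) -> dict:
        return {
            "reference": str(self.reference),
            "trajectories": [str(p) for p in self.trajectories],
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "backbone_atoms": list(self.backbone_atoms),
            "protein_selection": dict(self.protein_selection),
            "membrane_selection": dict(self.membrane_selection),
            "gate": {
                "pairs": [list(p) for p in self.gate_pairs],
                "flank_resids": list(self.gate_flank_resids),
                "closure_threshold": self.closure_threshold,
            },
            "gate_region_radius": self.gate_region_radius,
            "axis_point": list(self.axis_point) if self.axis_point else None,
            "lipid": self.lipid,
            "contact_cutoff": self.contact_cutoff,
            "exit_threshold": self.exit_threshold,
            "histogram_bin_width": self.histogram_bin_width,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], base_dir: Path | None = None) -> "RunConfig":
        base = Path(base_dir) if base_dir else Path(".")
        gate = d.get("gate", {})
        try:
            return cls(
                reference=base / d["reference"],
                trajectories=tuple(base / p for p in d["trajectories"]),
                output_dir=base / d.get("output_dir", "results"),
                seed=int(d.get("seed", 0)),
                backbone_atoms=tuple(d.get("backbone_atoms", superpose.BACKBONE_ATOMS)),
                protein_selection=dict(d.get("protein_selection", {"chain": "A"})),
                membrane_selection=dict(d.get("membrane_selection", {"resname": "MEM"})),
                gate_pairs=tuple(tuple(p) for p in gate.get(
                    "pairs", [[437, 668], [433, 666], [427, 663]])),
                gate_flank_resids=tuple(gate.get("flank_resids", ())),
                closure_threshold=float(gate.get("closure_threshold", 6.0)),
                gate_region_radius=float(d.get("gate_region_radius", 8.0)),
                axis_point=tuple(d["axis_point"]) if d.get("axis_point") else None,
                lipid=d.get("lipid"),
                contact_cutoff=float(d.get("contact_cutoff", 4.0)),
                exit_threshold=float(d.get("exit_threshold", 0.9)),
                histogram_bin_width=float(d.get("histogram_bin_width", 2.5)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        if not isinstance(d, Mapping):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(d, base_dir=path.parent)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        settings hash identically wherever the files live)."""
        d = self.to_dict()
        for key in ("reference", "trajectories", "output_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self, extra: str = "") -> list[str]:
        line = (
            f"# config_hash={self.config_hash()} contact_cutoff={self.contact_cutoff} "
            f"closure_threshold={self.closure_threshold} exit_threshold={self.exit_threshold} "
            f"gate_region_radius={self.gate_region_radius} "
            f"histogram_bin_width={self.histogram_bin_width}"
        )
        out = ["# barrelgate analysis output" + (f" ({extra})" if extra else ""), line]
        return out


@dataclass
class ReplicaResult:
    """All per-replica outputs needed downstream of a single-trajectory run."""

    replica_id: int
    times: np.ndarray
    pair_labels: tuple[str, ...]
    aperture: np.ndarray                    # (n_frames, n_pairs)
    rmsd: np.ndarray | None = None
    rmsf: superpose.RmsfProfile | None = None
    closure: gate_analysis.ClosureReport | None = None
    flicker: np.ndarray | None = None
    tilt: lipid_analysis.TiltSeries | None = None
    insertion: lipid_analysis.InsertionSeries | None = None
    egress: lipid_analysis.EgressReport | None = None
    contact_freqs: dict[int, float] | None = None
    output_dir: Path | None = None

    @property
    def n_frames(self) -> int:
        return self.aperture.shape[0]


@dataclass
class AggregateResult:
    """Cross-replica summaries: mean aperture curves and contact scores."""

    n_replicas: int
    times: np.ndarray
    pair_labels: tuple[str, ...]
    mean_aperture: np.ndarray               # (n_frames, n_pairs)
    contact_table: ContactTable | None = None
    annotated_structure_path: Path | None = None


def _require(indices: np.ndarray, what: str) -> np.ndarray:
    if np.asarray(indices).size == 0:
        raise ConfigError(f"selection {what!r} resolved to no atoms")
    return np.asarray(indices, dtype=int)


def _resolve(template: Structure, raw: Mapping[str, Any], what: str) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idx = select(template, **_normalize_criteria(raw))
    return _require(idx, what)


def _write_csv(df: pd.DataFrame, path: Path, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _resolve_lipid(template: Structure, lipid_cfg: Mapping[str, Any]):
    pa = _resolve(template, lipid_cfg["pa"], "lipid.pa")
    pb = _resolve(template, lipid_cfg["pb"], "lipid.pb")
    if pa.size != 1 or pb.size != 1:
        raise ConfigError("lipid.pa and lipid.pb must each resolve to exactly one atom")
    tails = tuple(
        tuple(_resolve(template, t, f"lipid.tails[{i}]"))
        for i, t in enumerate(lipid_cfg.get("tails", []))
    )
    if not tails:
        raise ConfigError("lipid.tails must define at least one tail")
    return lipid_analysis.LipidDefinition(
        pa_atom=int(pa[0]), pb_atom=int(pb[0]), tails=tails,
        head_atoms=(int(pa[0]), int(pb[0])),
    )


def run_replica(config: RunConfig, replica_id: int) -> ReplicaResult:
    """Analyze one replica trajectory and write its tables.

    Runs, in order: backbone RMSD/RMSF, gate aperture + closure report,
    gate-plane fit, membrane flicker depth, and — when a lipid block is
    configured — head tilt, tail insertion, egress order, and per-residue
    contact frequencies.  Outputs land in ``output_dir/replica_<id>/``.
    """
    config.validate_paths()
    traj_path = config.trajectories[replica_id]
    traj = read_pdb(traj_path)
    template = traj.atom_template
    times = traj.times if traj.times is not None else np.arange(traj.n_frames, dtype=float)
    out = Path(config.output_dir) / f"replica_{replica_id}"
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header_lines(f"replica {replica_id}")

    protein_idx = _resolve(template, config.protein_selection, "protein_selection")
    backbone = _resolve(
        template,
        {**config.protein_selection, "name": list(config.backbone_atoms)},
        "backbone",
    )

    rmsd = superpose.rmsd_series(traj, 0, backbone)
    _write_csv(pd.DataFrame({"time_ns": times, "rmsd_A": rmsd}), out / "rmsd.csv", hdr)

    profile = superpose.rmsf(traj, backbone, backbone)
    _write_csv(
        pd.DataFrame({"resid": profile.resids, "rmsf_A": profile.values}),
        out / "rmsf.csv", hdr,
    )

    gate = gate_analysis.GateDefinition(
        pairs=config.gate_pairs,
        flank_resids=config.gate_flank_resids,
        closure_threshold=config.closure_threshold,
    )
    aperture = gate_analysis.aperture_series(traj, gate)
    long = pd.DataFrame({
        "time_ns": np.repeat(times, len(gate.pairs)),
        "pair": list(aperture.pair_labels) * traj.n_frames,
        "distance_A": aperture.distances.ravel(),
    })
    _write_csv(long, out / "aperture.csv", hdr)
    closure = gate_analysis.closure_report(aperture, gate)
    _write_csv(
        pd.DataFrame({
            "pair": aperture.pair_labels,
            "mean_A": aperture.mean,
            "sd_A": aperture.sd,
            "min_A": aperture.min,
            "below_fraction": closure.below_fraction,
            "stayed_open": [closure.stayed_open] * len(gate.pairs),
        }),
        out / "aperture_summary.csv", hdr,
    )

    flank = config.gate_flank_resids
    flicker = None
    if flank:
        axis_point = config.axis_point
        if axis_point is None:
            ca_idx = select(template, name="CA")
            axis_point = tuple(template.coords[ca_idx].mean(axis=0))
        plane = lipid_analysis.fit_gate_plane(template, flank, axis_point)
        flank_ca = _resolve(template, {"name": "CA", "resid": list(flank)}, "gate flank CA")
        membrane = _resolve(template, config.membrane_selection, "membrane_selection")
        flicker = gate_analysis.flicker_depth_series(
            traj, plane, membrane, flank_ca, config.gate_region_radius
        )
        _write_csv(
            pd.DataFrame({"time_ns": times, "flicker_depth_A": flicker}),
            out / "flicker.csv", hdr,
        )
    else:
        logger.info("no gate flank residues configured; skipping plane-based stages")
        plane = None

    tilt = insertion = egress = None
    contact_freqs = None
    if config.lipid is not None:
        lipid = _resolve_lipid(template, config.lipid)
        tilt = lipid_analysis.tilt_series(
            traj, lipid, bin_width=config.histogram_bin_width
        )
        _write_csv(
            pd.DataFrame({"time_ns": times, "tilt_deg": tilt.angles}),
            out / "tilt.csv", hdr,
        )
        _write_csv(
            pd.DataFrame({
                "bin_lo_deg": tilt.bin_edges[:-1],
                "bin_hi_deg": tilt.bin_edges[1:],
                "count": tilt.counts,
            }),
            out / "tilt_hist.csv", hdr,
        )
        if plane is not None:
            insertion = lipid_analysis.insertion_series(traj, lipid, plane)
            wide = pd.DataFrame({"time_ns": times, "overall": insertion.overall})
            for t in range(insertion.per_tail.shape[1]):
                wide[f"tail_{t}"] = insertion.per_tail[:, t]
            _write_csv(wide, out / "insertion.csv", hdr)
            egress = lipid_analysis.egress_order(insertion, config.exit_threshold)
            rank = {t: k for k, t in enumerate(egress.order)}
            _write_csv(
                pd.DataFrame({
                    "tail_id": np.arange(lipid.n_tails),
                    "first_exit_frame": [
                        -1 if f is None else f for f in egress.first_exit
                    ],
                    "exit_rank": [rank.get(t, -1) for t in range(lipid.n_tails)],
                }),
                out / "egress.csv", hdr,
            )
        contact_sel = config.lipid.get("contact_selection")
        if contact_sel is not None:
            lipid_atoms = _resolve(template, contact_sel, "lipid.contact_selection")
            heavy = contact_analysis.heavy_atom_mask(template)
            lipid_atoms = lipid_atoms[heavy[lipid_atoms]]
            by_resid = contact_analysis.protein_atoms_by_resid(template, protein_idx)
            contact_freqs = contact_analysis.contact_frequencies(
                traj, lipid_atoms, by_resid, config.contact_cutoff
            )
            _write_csv(
                pd.DataFrame({
                    "resid": sorted(contact_freqs),
                    "frequency": [contact_freqs[r] for r in sorted(contact_freqs)],
                }),
                out / "contacts.csv", hdr,
            )
    else:
        logger.info("replica %d: no lipid configured; lipid/contact stages skipped",
                    replica_id)

    return ReplicaResult(
        replica_id=replica_id,
        times=times,
        pair_labels=aperture.pair_labels,
        aperture=aperture.distances,
        rmsd=rmsd,
        rmsf=profile,
        closure=closure,
        flicker=flicker,
        tilt=tilt,
        insertion=insertion,
        egress=egress,
        contact_freqs=contact_freqs,
        output_dir=out,
    )


def load_replica_result(replica_dir: str | Path) -> ReplicaResult:
    """Reconstruct the aggregation-relevant parts of a replica from its tables."""
    replica_dir = Path(replica_dir)
    ap = pd.read_csv(replica_dir / "aperture.csv", comment="#")
    labels = tuple(dict.fromkeys(ap["pair"]))
    n_pairs = len(labels)
    distances = ap["distance_A"].to_numpy().reshape(-1, n_pairs)
    times = ap["time_ns"].to_numpy().reshape(-1, n_pairs)[:, 0]
    contact_freqs = None
    contacts_path = replica_dir / "contacts.csv"
    if contacts_path.exists():
        cf = pd.read_csv(contacts_path, comment="#")
        contact_freqs = dict(zip(cf["resid"].astype(int), cf["frequency"]))
    rep_id = int(str(replica_dir.name).rsplit("_", 1)[-1])
    return ReplicaResult(
        replica_id=rep_id,
        times=times,
        pair_labels=labels,
        aperture=distances,
        contact_freqs=contact_freqs,
        output_dir=replica_dir,
    )


def aggregate(
    results: Sequence[ReplicaResult],
    config: RunConfig,
    reference: Structure | None = None,
) -> AggregateResult:
    """Cross-replica mean aperture curves and geometric contact scores.

    Replicas must share the gate definition; unequal frame counts are
    truncated to the shortest with a warning.  When contact frequencies are
    present, the geometric-mean score table is computed and mapped onto the
    reference structure (B-factor column of ``annotated.pdb``).
    """
    if not results:
        raise ValueError("at least one replica result required")
    labels = results[0].pair_labels
    for r in results[1:]:
        if r.pair_labels != labels:
            raise ConfigError(
                f"mixed gate definitions across replicas: {labels} vs {r.pair_labels}"
            )
    n_frames = min(r.n_frames for r in results)
    if any(r.n_frames != n_frames for r in results):
        warnings.warn(
            f"replicas differ in length; truncating to {n_frames} frames", stacklevel=2
        )
    mean_ap = np.mean([r.aperture[:n_frames] for r in results], axis=0)
    times = results[0].times[:n_frames]

    out = Path(config.output_dir) / "aggregate"
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header_lines(f"aggregate of {len(results)} replicas")
    wide = pd.DataFrame({"time_ns": times})
    for j, lab in enumerate(labels):
        wide[f"mean_{lab}_A"] = mean_ap[:, j]
    _write_csv(wide, out / "aperture_mean.csv", hdr)

    table = None
    annotated_path = None
    freq_maps = [r.contact_freqs for r in results if r.contact_freqs is not None]
    if freq_maps:
        if len(freq_maps) != len(results):
            warnings.warn("some replicas lack contact data; scoring the ones that have it",
                          stacklevel=2)
        table = ContactTable.from_replicas(freq_maps)
        _write_csv(table.to_dataframe(), out / "contact_scores.csv", hdr)
        if reference is None and config.reference.exists():
            reference = read_pdb(config.reference).atom_template
        if reference is not None:
            annotated = contact_analysis.annotate_scores(reference, table)
            annotated_path = out / "annotated.pdb"
            write_annotated_pdb(annotated, annotated_path)

    manifest = {
        "n_replicas": len(results),
        "n_frames": int(n_frames),
        "pair_labels": list(labels),
        "config_hash": config.config_hash(),
        "has_contact_table": table is not None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return AggregateResult(
        n_replicas=len(results),
        times=times,
        pair_labels=labels,
        mean_aperture=mean_ap,
        contact_table=table,
        annotated_structure_path=annotated_path,
    )
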