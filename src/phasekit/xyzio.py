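"""File formats: the extended-XYZ configuration dialect, TSV tables, JSON fits.

The configuration interchange format is a dialect of XYZ:

    <n_atoms>
    box_edge_nm=<float> frame_time=<float>
    <element> <x> <y> <z> <radius_nm> <peptide_id> <species> <donor_h_index> <is_acceptor>

Coordinates and radii are in nm; ``donor_h_index`` is the global atom index
of the donor's bonded hydrogen (-1 for none); ``is_acceptor`` is 0/1.
Frames may be concatenated; a multi-frame file reads back as a trajectory
ordered by appearance with strictly increasing ``frame_time``.

TSV tables use a single header line and '.' decimal separators regardless
of locale.  Nested fit results are serialized as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError
from .kinetics import CoalescenceEvent, FrapTrace, KineticTrace, TurbidityCurve, PhaseDiagram
from .structure import Configuration, HBond, PhaseMetrics, Trajectory

XYZ_COLUMNS = (
    "element", "x", "y", "z", "radius_nm", "peptide_id",
    "species", "donor_h_index", "is_acceptor",
)


# --------------------------------------------------------------------------
# extended XYZ


def _format_frame(config: Configuration, frame_time: float) -> str:
    lines = [str(config.n_atoms)]
    header = []
    if config.box_edge is not None:
        header.append(f"box_edge_nm={config.box_edge:.9g}")
    header.append(f"frame_time={frame_time:.9g}")
    lines.append(" ".join(header))
    for i in range(config.n_atoms):
        x, y, z = config.positions[i]
        lines.append(
            f"{config.elements[i]} {x:.9f} {y:.9f} {z:.9f} "
            f"{config.radii[i]:.6f} {config.peptide_ids[i]} {config.species[i]} "
            f"{config.donor_h_index[i]} {int(config.is_acceptor[i])}"
        )
    return "\n".join(lines) + "\n"


def write_configuration(config: Configuration, path: str | Path, frame_time: float = 0.0) -> None:
    Path(path).write_text(_format_frame(config, frame_time))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(_format_frame(frame, float(t)))


def _parse_header(line: str, lineno: int) -> dict:
    out: dict[str, float] = {}
    for token in line.split():
        if "=" not in token:
            raise ParseError(f"line {lineno}: header token {token!r} is not key=value")
        key, val = token.split("=", 1)
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric header value {token!r}") from exc
    return out


def read_configuration(path: str | Path) -> Configuration | Trajectory:
    """Read one frame as a Configuration, several as a Trajectory."""
    lines = Path(path).read_text().splitlines()
    frames: list[Configuration] = []
    times: list[float] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_start = i + 1  # 1-based line number of the count line
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {frame_start}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 >= len(lines):
            raise ParseError(f"line {frame_start}: truncated frame (missing header)")
        header = _parse_header(lines[i + 1], frame_start + 1)
        body = lines[i + 2: i + 2 + n_atoms]
        if len(body) < n_atoms or any(_looks_like_count(b) for b in body):
            raise ParseError(
                f"line {frame_start}: atom count {n_atoms} disagrees with frame body"
            )
        (positions, radii, elements, pids, species, donors, acceptors) = (
            [], [], [], [], [], [], []
        )
        for j, raw in enumerate(body):
            lineno = frame_start + 2 + j
            parts = raw.split()
            if len(parts) != len(XYZ_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(XYZ_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
                radius = float(parts[4])
                pid = int(parts[5])
                donor = int(parts[7])
                acceptor = int(parts[8])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field in {raw!r}") from exc
            if radius <= 0:
                raise ParseError(f"line {lineno}: non-positive radius {radius}")
            if pid < 0:
                raise ParseError(f"line {lineno}: negative peptide_id {pid}")
            positions.append(xyz)
            radii.append(radius)
            elements.append(parts[0])
            pids.append(pid)
            species.append(parts[6])
            donors.append(donor)
            acceptors.append(bool(acceptor))
        frames.append(
            Configuration(
                positions=np.array(positions),
                radii=np.array(radii),
                elements=np.array(elements, dtype=object),
                peptide_ids=np.array(pids),
                species=np.array(species, dtype=object),
                donor_h_index=np.array(donors),
                is_acceptor=np.array(acceptors),
                box_edge=header.get("box_edge_nm"),
            )
        )
        times.append(header.get("frame_time", float(len(times))))
        i = i + 2 + n_atoms
    if not frames:
        raise ParseError("file contains no frames")
    if len(frames) == 1:
        return frames[0]
    if not all(b > a for a, b in zip(times, times[1:])):
        raise ParseError("frame_time values must be strictly increasing across frames")
    return Trajectory(frames=frames, times=np.array(times))


def _looks_like_count(line: str) -> bool:
    parts = line.split()
    return len(parts) == 1 and parts[0].isdigit()


# --------------------------------------------------------------------------
# TSV tables


def write_phase_metrics_tsv(rows: list[tuple[str, PhaseMetrics]], path: str | Path) -> None:
    records = []
    for name, m in rows:
        rec = {
            "name": name,
            "ap": m.ap,
            "relative_sasa": m.relative_sasa,
            "cd": m.cd,
            "n_hbonds_total": m.n_hbonds_total,
        }
        rec["hbonds_by_pair"] = ";".join(
            f"{a}-{b}:{v:g}" for (a, b), v in sorted(m.n_hbonds_by_pair.items())
        )
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_phase_metrics_tsv(path: str | Path) -> list[tuple[str, PhaseMetrics]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        pairs: dict[tuple[str, str], float] = {}
        cell = row.get("hbonds_by_pair")
        if isinstance(cell, str) and cell:
            for item in cell.split(";"):
                key, val = item.rsplit(":", 1)
                a, b = key.split("-", 1)
                pairs[(a, b)] = float(val)
        out.append(
            (
                str(row["name"]),
                PhaseMetrics(
                    ap=float(row["ap"]),
                    relative_sasa=float(row["relative_sasa"]),
                    cd=float(row["cd"]),
                    n_hbonds_total=float(row["n_hbonds_total"]),
                    n_hbonds_by_pair=pairs,
                ),
            )
        )
    return out


def write_hbonds_tsv(bonds: list[HBond], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "donor": b.donor_index,
                "hydrogen": b.hydrogen_index,
                "acceptor": b.acceptor_index,
                "distance_nm": b.distance_da,
                "angle_deg": b.angle_deg,
                "species_pair": "-".join(b.species_pair),
            }
            for b in bonds
        ],
        columns=["donor", "hydrogen", "acceptor", "distance_nm", "angle_deg", "species_pair"],
    ).to_csv(path, sep="\t", index=False)


def write_frap_tsv(trace: FrapTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "intensity": trace.intensity})
    df["bleach_index"] = trace.bleach_index
    df.to_csv(path, sep="\t", index=False)


def read_frap_tsv(path: str | Path) -> FrapTrace:
    df = pd.read_csv(path, sep="\t")
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        bleach_index=int(df["bleach_index"].iloc[0]),
    )


def write_events_tsv(events: list[CoalescenceEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"tau_s": [e.tau for e in events], "l_um": [e.l for e in events]}
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[CoalescenceEvent]:
    df = pd.read_csv(path, sep="\t")
    return [CoalescenceEvent(tau=float(t), l=float(l)) for t, l in zip(df["tau_s"], df["l_um"])]


def write_kinetic_tsv(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time": trace.times, "signal": trace.signal, "model_hint": trace.model_hint}
    ).to_csv(path, sep="\t", index=False)


def read_kinetic_tsv(path: str | Path) -> KineticTrace:
    df = pd.read_csv(path, sep="\t")
    hint = str(df["model_hint"].iloc[0]) if "model_hint" in df else "linear"
    return KineticTrace(
        times=df["time"].to_numpy(), signal=df["signal"].to_numpy(), model_hint=hint
    )


def write_turbidity_tsv(curve: TurbidityCurve, path: str | Path) -> None:
    df = pd.DataFrame({"time": curve.times, "a600": curve.absorbance})
    df.to_csv(path, sep="\t", index=False)
    if curve.cycle_boundaries:
        Path(str(path) + ".cycles.json").write_text(json.dumps(curve.cycle_boundaries))


def read_turbidity_tsv(path: str | Path) -> TurbidityCurve:
    df = pd.read_csv(path, sep="\t")
    cyc = None
    side = Path(str(path) + ".cycles.json")
    if side.exists():
        cyc = [tuple(p) for p in json.loads(side.read_text())]
    return TurbidityCurve(
        times=df["time"].to_numpy(), absorbance=df["a600"].to_numpy(), cycle_boundaries=cyc
    )


def write_grid_tsv(grid: PhaseDiagram, path: str | Path) -> None:
    rows = []
    for i, ph in enumerate(grid.ph_values):
        for j, salt in enumerate(grid.nacl_values):
            rec = {"ph": ph, "nacl_mm": salt, "a600": grid.turbidity[i, j]}
            if grid.phase_separated is not None:
                rec["phase_separated"] = int(grid.phase_separated[i, j])
            rows.append(rec)
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)


def read_grid_tsv(path: str | Path) -> PhaseDiagram:
    df = pd.read_csv(path, sep="\t")
    ph = np.unique(df["ph"].to_numpy())
    salt = np.unique(df["nacl_mm"].to_numpy())
    turb = np.full((len(ph), len(salt)), np.nan)
    for _, row in df.iterrows():
        i = int(np.searchsorted(ph, row["ph"]))
        j = int(np.searchsorted(salt, row["nacl_mm"]))
        turb[i, j] = row["a600"]
    return PhaseDiagram(ph_values=ph, nacl_values=salt, turbidity=turb)


# --------------------------------------------------------------------------
# JSON fit records


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fit_json(fit, path: str | Path, model: str, input_digest: str | None = None) -> None:
    record = {"model": model, "parameters": dataclasses.asdict(fit)}
    if input_digest is not None:
        record["input_sha256"] = input_digest
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --------------------------------------------------------------------------
# run configuration


_RUNCONFIG_DEFAULTS = {
    "preset": "all_atom_revised",
    "contact_cutoff": 0.5,
    "hbond_d_max": 0.35,
    "hbond_angle_max": 30.0,
    "sasa_probe_radius": 0.14,
    "sasa_n_points": 960,
    "segmentation_method": "otsu",
    "segmentation_min_area": 20,
    "seed": 0,
    "n_peptides": 64,
    "n_frames": 2,
    "tail_frames": 1,
}


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline configuration; unknown keys are rejected."""

    preset: str = "all_atom_revised"
    contact_cutoff: float = 0.5
    hbond_d_max: float = 0.35
    hbond_angle_max: float = 30.0
    sasa_probe_radius: float = 0.14
    sasa_n_points: int = 960
    segmentation_method: str = "otsu"
    segmentation_min_area: int = 20
    seed: int = 0
    n_peptides: int = 64
    n_frames: int = 2
    tail_frames: int = 1

    def __post_init__(self) -> None:
        for name in (
            "contact_cutoff", "hbond_d_max", "hbond_angle_max",
            "sasa_probe_radius", "sasa_n_points", "segmentation_min_area",
            "n_peptides", "n_frames", "tail_frames",
        ):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be positive")
        if self.seed < 0:
            raise ArgumentError("seed must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_RUNCONFIG_DEFAULTS)
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{**_RUNCONFIG_DEFAULTS, **data})

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
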