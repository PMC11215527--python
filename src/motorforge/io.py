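"""File formats: trace text tables, track CSVs, PDB structures.

Trap traces are two-column delimited text (time_s, force_pN) preceded by
``# key=value`` metadata lines (spring_constant_pN_per_nm, sample_rate_hz,
label); programmed ground truth goes to a sidecar CSV
(start_s, end_s, kind, level_pN).  Tracks are CSV
(track_id, microtubule_id, time_s, position_nm).  Structures and
trajectories use PDB / multi-model PDB via biotite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from biotite.structure.io.pdb import PDBFile

from .motility import Track
from .structures import from_biotite, to_biotite
from .synthetic_data import GroundTruthInterval, TrapTrace


def write_trace(path: str | Path, trace: TrapTrace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spring_constant_pN_per_nm={trace.spring_constant}\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate}\n")
        fh.write(f"# label={trace.label}\n")
        for t, f in zip(trace.times, trace.force):
            fh.write(f"{t:.6f}\t{f:.6f}\n")
    if trace.ground_truth:
        rows = [
            {"start_s": iv.start, "end_s": iv.end, "kind": iv.kind,
             "level_pN": iv.level}
            for iv in trace.ground_truth
        ]
        pd.DataFrame(rows).to_csv(path.with_suffix(".truth.csv"), index=False)


def read_trace(path: str | Path) -> TrapTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    times, force = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            t, f = line.split()
            times.append(float(t))
            force.append(float(f))
    truth = None
    sidecar = path.with_suffix(".truth.csv")
    if sidecar.exists():
        df = pd.read_csv(sidecar)
        truth = [
            GroundTruthInterval(kind=row.kind, start=row.start_s,
                                end=row.end_s, level=row.level_pN)
            for row in df.itertuples()
        ]
    return TrapTrace(
        times=np.array(times), force=np.array(force),
        spring_constant=float(meta["spring_constant_pN_per_nm"]),
        sample_rate=float(meta["sample_rate_hz"]),
        label=meta.get("label", path.stem), ground_truth=truth)


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "track_id": tr.track_id, "microtubule_id": tr.microtubule_id,
            "time_s": tr.times, "position_nm": tr.positions}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for (tid, mid), grp in df.groupby(["track_id", "microtubule_id"],
                                      sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if t.size > 1 else 0.5
        tracks.append(Track(times=t,
                            positions=grp["position_nm"].to_numpy(),
                            frame_interval=dt, track_id=str(tid),
                            microtubule_id=str(mid)))
    return tracks


def write_structure(path: str | Path, atoms) -> None:
    """Write a StructureFrame (PDB) or Trajectory (multi-model PDB)."""
    pdb = PDBFile()
    pdb.set_structure(to_biotite(atoms))
    pdb.write(str(path))


def read_structure(path: str | Path):
    """Read a PDB file; multi-model files return a Trajectory."""
    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() == 1:
        return from_biotite(pdb.get_structure(model=1))
    return from_biotite(pdb.get_structure())


def write_angles(path: str | Path, angles: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(angles)),
                  "angle_deg": angles}).to_csv(path, index=False)
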