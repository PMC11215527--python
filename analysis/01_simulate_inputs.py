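#!/usr/bin/env python
"""Generate the synthetic raw inputs for the downstream analyses.

Writes to results/inputs/: 20 wild-type-like and 20 mutant-like trap traces
(5 kHz, with ground-truth sidecars), one high-bandwidth unbound calibration
trace, a 200-track TIRF-like cohort, and rigid-body MD-like trajectories
(reference PDB + multi-model PDB + programmed angle ground truth).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from motorforge import io as mfio
from motorforge.synthetic_data import (
    MotorTrapParams,
    SyntheticTrackParams,
    SyntheticTrajectoryParams,
    mutant_motor_params,
    simulate_mtbd_trajectory,
    simulate_track,
    simulate_trap_trace,
    wt_motor_params,
)
from motorforge.motility import Track

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for label, fn in (("wt", wt_motor_params), ("mutant", mutant_motor_params)):
        d = OUT / f"traces_{label}"
        d.mkdir(exist_ok=True)
        for i in range(20):
            mfio.write_trace(d / f"trace_{i:03d}.txt",
                             simulate_trap_trace(fn(seed=SEED + i)))
        print(f"wrote 20 {label} traces to {d}")

    calib = simulate_trap_trace(MotorTrapParams(
        initially_bound=False, reattach_rate=0.0, sample_rate=50_000.0,
        duration=20.0, seed=SEED + 99))
    mfio.write_trace(OUT / "calibration_trace.txt", calib)
    print("wrote calibration trace (20 s unbound bead at 50 kHz)")

    tracks = []
    composition = [("processive", 120, dict(velocity=500.0)),
                   ("static", 60, {}),
                   ("diffusive", 20, dict(diffusion_coeff=5.0e4))]
    i = 0
    for mode, n, kw in composition:
        for j in range(n):
            tr = simulate_track(SyntheticTrackParams(
                mode=mode, seed=SEED + 200 + i, frame_interval=0.1,
                duration=3.0, localization_noise_sd=20.0, **kw))
            tracks.append(Track(times=tr.times, positions=tr.positions,
                                track_id=f"{mode[:4]}_{j:03d}",
                                microtubule_id=f"mt{i % 5}",
                                ground_truth_mode=mode))
            i += 1
    mfio.write_tracks(OUT / "tracks.csv", tracks)
    truth = pd.DataFrame({"track_id": [t.track_id for t in tracks],
                          "mode": [t.ground_truth_mode for t in tracks]})
    truth.to_csv(OUT / "tracks_truth.csv", index=False)
    print(f"wrote {len(tracks)} tracks (120 processive / 60 static / "
          f"20 diffusive)")

    traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
        angle_components=((0.5, 11.5, 4.0), (0.5, -7.9, 4.0)),
        n_frames=300, seed=SEED + 500))
    mfio.write_structure(OUT / "reference.pdb", traj.reference)
    mfio.write_structure(OUT / "trajectory_mutantlike.pdb", traj.frames)
    mfio.write_angles(OUT / "trajectory_mutantlike_truth_angles.csv",
                      traj.ground_truth_angles_deg)
    wt_traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
        angle_components=((1.0, 0.0, 4.0),), n_frames=300, seed=SEED + 501))
    mfio.write_structure(OUT / "trajectory_wtlike.pdb", wt_traj.frames)
    mfio.write_angles(OUT / "trajectory_wtlike_truth_angles.csv",
                      wt_traj.ground_truth_angles_deg)
    print("wrote reference.pdb and two 300-frame multi-model trajectories")


if __name__ == "__main__":
    main()
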