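#!/usr/bin/env python
"""Force-velocity curves from the 5 kHz stall-containing traces.

Median filter (200-point window), 1-pN bins centered on 2-5 pN, velocity
per passage = delta F / (k * delta t), non-negative passages only.
Writes results/fv_<construct>.csv.
"""

from pathlib import Path

import pandas as pd

from motorforge import io as mfio
from motorforge.force_velocity import FVParams, force_velocity_curve

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for label in ("wt", "mutant"):
        traces = [mfio.read_trace(p) for p in
                  sorted((ROOT / "inputs" / f"traces_{label}").glob("*.txt"))]
        curve = force_velocity_curve(traces, FVParams())
        df = pd.DataFrame({"bin_center_pN": curve.bin_centers,
                           "mean_velocity_nm_s": curve.mean_velocity,
                           "sem": curve.sem, "n_events": curve.n_events})
        df.to_csv(ROOT / f"fv_{label}.csv", index=False)
        shown = ", ".join(
            f"{c:.0f} pN: {v:.0f} nm/s (n={n})"
            for c, v, n in zip(curve.bin_centers, curve.mean_velocity,
                               curve.n_events) if n > 0)
        print(f"{label}: {shown}")


if __name__ == "__main__":
    main()
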