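#!/usr/bin/env python
"""Recover trap stiffness from the thermal spectrum of the unbound bead.

Reads results/inputs/calibration_trace.txt, fits the Lorentzian, and
writes results/calibration.json with the corner frequency, diffusion
coefficient, Lorentzian stiffness and the equipartition cross-check.
"""

import json
from dataclasses import asdict
from pathlib import Path

from motorforge import io as mfio
from motorforge.calibration import fit_lorentzian, power_spectrum

ROOT = Path(__file__).resolve().parent.parent / "results"
DRAG = 9.4e-6  # pN.s/nm, the generator's bead drag


def main() -> None:
    trace = mfio.read_trace(ROOT / "inputs" / "calibration_trace.txt")
    psd = power_spectrum(trace)
    result = fit_lorentzian(psd, (100.0, 4000.0), drag=DRAG)
    (ROOT / "calibration.json").write_text(
        json.dumps(asdict(result), indent=2))
    print(f"corner frequency {result.corner_frequency:.0f} Hz, "
          f"Lorentzian stiffness {result.stiffness:.4f} pN/nm, "
          f"equipartition {result.stiffness_equipartition:.4f} pN/nm "
          f"(programmed 0.0600)")


if __name__ == "__main__":
    main()
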