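# motorforge

Analysis pipeline for single-molecule dynein force-sensitivity studies:
optical-trap stall and force–velocity analysis, TIRF kymograph track
classification, and geometric/contact analysis of MD trajectories of the
microtubule-binding domain (MTBD) on tubulin — together with synthetic-data
generators that emulate each raw input class with exact ground truth, so
every stage is testable end to end.

It is aimed at single-molecule biophysicists who need the bespoke parts of
such studies — the stall detector, the binned force–velocity estimator,
the kymograph counting rules, the microtubule-referenced angle analysis —
as reusable, tested code rather than one-off scripts.

## The quantities at the core

* **Stall force / stall time.** A stall is a stationary interval of the
  bead-force record F(t) = k·x(t) above a preset threshold (wild type:
  >2.5 pN for >100 ms; mutant: >1 pN for >150 ms, both at 250 Hz after
  block-mean downsampling from 5 kHz), terminated by the bead snapping
  back to the trap center.  Stall force is ⟨F⟩ over the last 20% of the
  event; stall time is the dwell at F ≥ 0.8·F_stall ending at detachment.
  Stall-time populations are fit on the empirical survival (1-CDF) with
  A·e^(−t/τ_fast) + (1−A)·e^(−t/τ_slow).
* **Trap calibration.** The thermal position spectrum of a trapped bead is
  Lorentzian, S(f) = D/(2π²(f_c²+f²)); the corner frequency gives the
  stiffness k = 2πγf_c, cross-checked by equipartition k = k_BT/var(x).
* **Force–velocity.** Median-filtered (200-point) 5 kHz traces are cut
  into maximal passages through 1-pN bins centered on 2–5 pN; each
  passage's velocity is ΔF/(k·Δt), non-negative passages only, averaged
  per bin.
* **Motility classes.** Kymograph tracks count only if ≥1.5 s; processive
  if they contain a ≥500 nm directed segment; static if their range stays
  ≤250 nm; diffusive otherwise.  Velocities are means over piecewise-linear
  segments; run length is net displacement.
* **MD geometry and contacts.** Tubulin principal axes (PA1 long, PA2
  radial toward the dynein anchors, PA3 = PA1×PA2); the MTBD vector's
  signed angle about the long axis; the stalk vector's angle to PA1;
  per-residue RMSF after tubulin alignment; salt-bridge (≤4 Å),
  hydrogen-bond (≤3.5 Å, ≤30°) and hydrophobic (≤8 Å side-chain C–C)
  contact occupancies.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs (each writes tables under `results/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_calibrate_trap.py
python analysis/03_stall_forces.py
```

Output of steps 02 and 03:

```
corner frequency 1025 Hz, Lorentzian stiffness 0.0605 pN/nm, equipartition 0.0600 pN/nm (programmed 0.0600)
wt: 59 stalls, 4.26 +/- 0.01 pN, mean stall time 0.56 s
mutant: 53 stalls, 2.89 +/- 0.00 pN, mean stall time 0.70 s
stall-force reduction (wt -> mutant): 0.322 (~one-third)
```

The calibration recovers the programmed 0.06 pN/nm stiffness from the
bead's thermal spectrum alone; the stall pipeline recovers the programmed
4.3 and 2.9 pN stall forces from noisy traces and reports the
approximately one-third force reduction of the mutant-like motor.
Continuing:

```bash
python analysis/04_force_velocity.py   # fv_wt.csv: 424 nm/s at 2 pN, 224 at 3 pN ...
python analysis/05_motility.py        # 200/200 tracks match ground truth; 60/30/10% classes
python analysis/06_md_geometry.py     # MTBD peaks -7.7 and +12.0 deg; stalk 59.9 / 46.3 deg; RMSF +16.7%
python analysis/07_md_contacts.py     # salt-bridge occupancy 62.5% vs 8.5%
```

A `motorforge` command-line interface wraps the same library for ad-hoc
use, e.g.:

```bash
motorforge simulate --preset wt --n-traces 5 --out traces/
motorforge analyze-trap stalls --traces traces/ --preset wt --out events.csv
motorforge calibrate --trace traces/wt_trace_0000.txt --drag 9.4e-6 --band 100:2000
```

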