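# Methods

`motorforge` re-implements, as a tested pipeline, the quantitative analyses
used in single-molecule studies of dynein force sensitivity: optical-trap
stall detection and force–velocity analysis, TIRF kymograph track
classification, and geometric/contact analysis of MD trajectories of the
microtubule-binding domain (MTBD) docked on tubulin.  Because the raw
experimental recordings are not available, every stage is exercised against
a synthetic-data module that emulates the raw inputs with exact, seedable
ground truth.  This note documents the models, the parameters that matter,
the numerical choices, and what passing tests do and do not establish.

## Trapped-bead simulator

A bead in a harmonic trap of stiffness *k* (default 0.06 pN/nm, the value
used for stall-force measurements) with drag *γ* (default 9.4×10⁻⁶
pN·s/nm, a ~1 µm bead in water) is driven by a single motor with the
linear force–velocity law v(F) = v₀(1 − F/F_s), clipped at zero.  The
recorded force is

F(t) = F_m(t) + k·δ(t),

where F_m is the load the motor has built against the trap and δ is the
bead's thermal Ornstein–Uhlenbeck (OU) fluctuation with relaxation time
τ = γ/k and stationary variance k_BT/k (k_BT = 4.114 pN·nm at 298 K,
configurable).  Two deliberate modelling choices:

* **Exact discretization, no integration step.**  Both components have
  closed-form transition densities: δ is an AR(1) process sampled exactly
  at the output rate, and F_m relaxes exponentially toward F_s with time
  constant F_s/(k·v₀).  Euler–Maruyama integration at a fixed small step
  followed by block-average decimation was rejected: block averaging over
  a 5 kHz output grid (window ≈ 1.3 τ at the stated stiffness and drag)
  attenuates the recorded force variance to ≈0.68·k·k_BT, which would
  break equipartition of the recorded trace (var F = k·k_BT ≈ 0.247 pN²,
  SD ≈ 0.50 pN) — the property the detector's noise thresholds and the
  spectral calibration are designed around.  Instantaneous sampling keeps
  equipartition and the OU autocorrelation exact at any rate.
* **The motor feels its mean load, not the instantaneous fluctuation.**
  With a v(F) law clipped at zero, coupling the motor to the thermally
  fluctuating force rectifies noise into a spurious upward force creep
  (~2 pN/s at these parameters) during stalls.  Real motors average load
  over many steps; decoupling F_m from δ removes the artifact and makes
  the programmed stall force exactly the plateau of the noise-free trace.

Kinetics: the detachment hazard (default 2.5 s⁻¹ wild-type-like,
1.5 s⁻¹ mutant-like) switches on when F_m ≥ 0.97·F_s; the 0.97 gate was
chosen from the closed form E[F(T_detach)] so that the exponential
approach to the plateau does not itself bias the recovered stall force by
more than a few hundredths of a pN.  Mutant-like pausing is a force-gated
two-state switch: entry at 2 s⁻¹ while 1 pN ≤ F_m < 0.9·F_s, exit at
8 s⁻¹ (mean pause ≈ 125 ms, i.e. mostly below the 150 ms counting
threshold), with 10% of exits detaching instead of resuming — reproducing
the qualitative behavior that paused mutant motors either detach or move
on.  Detachment snaps F_m to 0; rebinding at 1 s⁻¹.  Programmed stall /
pause / unbound intervals are recorded as ground truth.  The pause-exit
rate, pause gate force and the unbound-start option are simulator
parameters beyond the minimal published description; their defaults are
stated here and in the dataclass.

Default trace conditions: 5 kHz sampling, 5 s duration, stall forces 4.3
(wild-type-like) and 2.9 pN (mutant-like), unloaded velocity 800 nm/s.
Calibration traces use an unbound bead sampled at 50 kHz for 20 s — at
5 kHz the corner frequency (~1 kHz) sits near Nyquist and spectral
aliasing of the OU tail would bias a Lorentzian fit; high-bandwidth
acquisition is also what instruments do in practice.

## Calibration

`power_spectrum` is a Welch-style segment-averaged one-sided periodogram
(non-overlapping boxcar segments, default 2¹³ samples, DC bin dropped) of
bead position x = F/k; boxcar windows keep the estimate
Parseval-consistent.  `fit_lorentzian` fits S(f) = D/(2π²(f_c² + f²)) in
log-density space with uniform weights (so high-frequency bins do not
dominate), default band 100–4000 Hz.  Stiffness is 2πγf_c when the drag
is supplied; the equipartition estimate k_BT/∫S df is always reported as
a cross-check.  A fitted corner outside the band, or a spectrum with no
decay, is an error, not a clamped value.

## Stall analysis

Traces are block-mean downsampled to 250 Hz (block means preserve the
trace mean exactly).  "Stationary" — undefined in the source description —
is operationalized as a centered rolling SD ≤ 0.35 pN over a 40 ms
window: the thermal floor is ≈0.5 pN SD at 5 kHz and ≈0.14 pN after
250 Hz block averaging, so the default sits between the two.  A stall
event is a maximal stationary interval with force above the preset
threshold (wild type: >2.5 pN for >100 ms; mutant: >1 pN for >150 ms).
Outcomes: *detach* if the force falls by ≥50% of the stall force within
20 ms after the interval (the lookahead includes half a rolling window,
which the centered SD necessarily shaves off the interval end; for detach
events the end is extended through the samples still at ≥80% of the stall
force so the event terminates at the snap), *censored* at the trace end,
*resume* otherwise.  Stall force is the mean of the last ⌈20%⌉ of event
samples; stall time is the contiguous run at ≥80% of the stall force
ending at the event end (the "followed by snapping" reading; total
supra-threshold time is available by flag).  Censored events are excluded
from population statistics.  Where the original analysis relied on manual
review of every event, this implementation substitutes the explicit
parameters above.

## Population statistics

Force histograms pool all samples of all traces (0.2 pN bins, edges on a
fixed grid) and normalize to unit mass.  The three-Gaussian fit is a
nonlinear least-squares *curve fit* to (bin center, probability) pairs —
not an EM fit to samples — with deterministic initialization: means at
the largest local maxima of the smoothed histogram, SDs at 0.5 pN, equal
weights.  The component nearest 0 pN is the unbound (untethered) peak;
subtraction removes its predicted per-bin mass, floors at zero, and does
not renormalize unless asked.

Stall-time survival is fit on the empirical 1-CDF evaluated at the event
times (no binning, uniform weights) with
A·exp(−t/τ_fast) + (1−A)·exp(−t/τ_slow), τ_fast ≤ τ_slow enforced by
parameterization.  Because a second exponential is ill-conditioned on
single-exponential data (the fit splits one τ into two to chase sampling
noise), the routine first fits a single exponential; if that already fits
to within the binomial sampling noise of an empirical survival curve
(rms ≤ 1.6·√(1/6n), a bound with clear empirical separation between the
two regimes at n = 500), the collapsed solution (τ_fast = τ_slow,
A = 1) is returned.  Parameter SEMs come from the fit covariance.

## Force–velocity

5 kHz traces are median filtered (200-point window, odd-adjusted to 201,
edges truncated so length is preserved), then maximal contiguous passages
through 1-pN-wide bins centered on 2, 3, 4 and 5 pN are extracted
(half-open membership [c−0.5, c+0.5); passages shorter than 25 samples =
5 ms are dropped as single-crossing noise).  The published velocity
prescription divides the force change by the spring constant only; the
only dimensionally consistent reading divides by the passage duration as
well, v = ΔF/(k·Δt), and that is what is implemented.  Passages with
negative average velocity (detachments) are excluded per event, before
averaging.  Traces are processed individually and pooled so passages
never span concatenation joints.  Note the measured bin velocity is a
transit-time average over the bin and therefore sits slightly below
v₀(1 − F_c/F_s) evaluated at the bin center; at the default parameters
the discrepancy is ≤5%, well inside the recovery tolerances used.

## Motility

Tracks shorter than 1.5 s are not counted.  A counted track is
*processive* if it contains a directed displacement segment ≥500 nm
(inclusive thresholds, matching the printed "≥" rules).  Strict
monotonicity is undefined under localization noise, and running-max
relaxations admit far too many Brownian excursions, so "directed segment"
is operationalized statistically: some window whose net displacement is
≥500 nm *and* whose frame-increment mean dominates its standard error
(t ≥ 6 over ≥10 increments; noise-free directed motion has zero increment
SD and always qualifies).  At the cohort defaults (500 nm/s drift vs
D = 5×10⁴ nm²/s wander, 20 nm localization noise, 10 Hz frames) this
leaves both false-processive and missed-processive rates below ~0.3%.
The cost is insensitivity to marginal tracks (e.g. exactly 500 nm spread
over 3 s in heavy noise); those are rare in the emulated regime and the
threshold behavior is exact in the noise-free limit.  Non-processive
tracks are *static* if their positional range is ≤250 nm (≈2.4 pixels at
the 105 nm pixel size — sub-pixel wander indistinguishable from
localization noise), else *diffusive*.

Mean velocity of a processive track is the unweighted mean over
piecewise-linear velocity segments (bottom-up merging while the merged
segment's RMS residual stays ≤50 nm; slope by least squares), matching
the segment-based averaging used for motors that change speed mid-run.
Run length is net displacement from first to last point (total path
length by flag).  Summaries are per microtubule; fractions are over
counted tracks and sum to 1.

## MD geometry

Structures live in a float64 container (`StructureFrame` /
`Trajectory`); PDB input/output converts through biotite at the boundary.
Double precision is kept end to end because the angle operations are
validated to 10⁻⁶ degrees on rigid-rotation fixtures, below the
resolution of float32 coordinates.

The tubulin frame: PA1 is the smallest-inertia principal axis of the
tubulin Cα coordinates (the protofilament long axis), signed to match the
reference; PA2 is the component of (stalk-base anchor center − tubulin
center of mass) orthogonal to PA1; PA3 = PA1×PA2.  Axes are computed once
from the reference structure; each frame is first superposed onto the
reference via the tubulin selection (in-package Kabsch with the proper
rotation enforced, cross-checked against biotite in tests).  The MTBD
vector runs from the 3295/3395 Cα center to the 3288/3402 Cα center
(human dynein heavy-chain numbering).  Its signed angle is measured by
default in the PA2–PA3 plane — the plane perpendicular to the long axis,
which is the stated *goal* of the published angle even though the text
names the PA1/PA2 plane; the literal PA1–PA2 projection is available as
an option, and positive angles mean rotation from PA2 toward +PA3 viewed
down +PA1 ("clockwise").  The wild-type peak is an explicit
reference-zero parameter.  The stalk vector is obtained by superposing a
full-length structure onto the frame's stalk-base Cα anchors and runs
from the 3295/3395 center to the 3191/3501 center; its angle is against
PA1, in [0°, 180°).

Angle histograms (1° bins) are fit with 1 or 2 Gaussians, deterministic
mode-based initialization; a 2-component fit whose peaks collapse (closer
than 2°, closer than their mean SD, or with a component weight below 0.1)
is reported as an error.  RMSF is per-residue Cα
√⟨|r−⟨r⟩|²⟩ after tubulin alignment, with percent change between
profiles = mean over residues of 100·(B−A)/A, optionally restricted to a
residue range (the helix-3-to-coiled-coil-2 region is a user-supplied
range, as the field names regions, not residue bounds).

The rigid-body trajectory generator rotates the dynein chain about a
chosen axis by angles drawn from a Gaussian mixture and adds isotropic
per-atom noise — by default to the mobile chain only, mirroring source
simulations in which tubulin is harmonically restrained; this also keeps
the tubulin alignment exact so the RMSF of σ-noise equals √3σ without an
alignment-jitter correction.  The synthetic reference uses a tubulin rod
of antipodal atom pairs on a helix with whole turns, making the Cα
inertia tensor exactly diagonal and the reference axes exactly (z, x, y).

## MD contacts

Salt bridge: minimum basic-N (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2 —
histidine counts by default since "basic nitrogen" is not enumerated, and
can be excluded) to acidic-O (Asp OD1/OD2; Glu OE1/OE2; any OXT) distance
≤4.0 Å.  Hydrogen bond: donor–acceptor heavy-atom distance ≤3.5 Å and
hydrogen–donor–acceptor angle ≤30°, explicit hydrogens required (no
placement inference — all-atom trajectories carry them).  Hydrophobic:
any side-chain carbon pair ≤8.0 Å, backbone C/CA excluded; a glycine
partner is an error.  All boundaries are closed (exactly the cutoff
counts).  Occupancy reports both per-trajectory fractions and the pooled
per-frame fraction, since "% of simulations" can be read either way.

## What the synthetic data does and does not establish

The generators reproduce the statistical structure the analyses key on —
OU thermal noise at the correct stiffness, exponential dwell mixtures,
drift/wander/noise track classes, rigid-body angular mixtures, exact
contact schedules — with known ground truth, so the recovery suites
demonstrate that the pipeline measures what it claims at realistic noise.
They do not emulate instrument artifacts (detector nonlinearity, drift,
aliasing filters), discrete 8-nm stepping, motor back-slipping,
photophysics, or genuine all-atom dynamics; passing tests therefore
validate the *analysis chain*, not any biological claim about real
recordings.

## Problem sizes

The recovery suites use 150 traces per construct (≈450–500 stalls each),
50 calibration seeds, 500 survival events, 2×10⁵ histogram samples, a
200-track motility cohort, 5000-frame angle series, 10⁴-frame RMSF
trajectories and ≥1200 randomized contact frames.  The acceptance script
uses the same sizes except 20 calibration seeds and 4000-frame RMSF runs.
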