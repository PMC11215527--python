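"""Synthetic generators for every input class the pipeline consumes.

Three generators with exact, seedable ground truth:

* :func:`simulate_trap_trace` — a bead held in a harmonic optical trap and
  driven by a single motor with a linear force–velocity law, programmable
  stalls, force-gated pausing, detachment and reattachment.  Thermal motion
  of the bead is an Ornstein–Uhlenbeck (OU) process with relaxation time
  ``bead_drag / trap_stiffness``; it is sampled with the *exact* discrete
  transition density, so recorded traces satisfy equipartition
  (``var(F) = trap_stiffness * thermal_energy``) and the OU autocorrelation
  to machine precision, with no integration-step error.
* :func:`simulate_track` — single-particle (time, position) tracks in
  processive / static / diffusive modes, emulating TIRF kymograph tracks.
* :func:`simulate_mtbd_trajectory` — rigid-body pseudo-MD trajectories of a
  motor domain docked on a microtubule, with rotation angles drawn from a
  Gaussian mixture, per-atom positional noise, and an optional programmed
  on/off contact schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .structures import StructureFrame, Trajectory

BOLTZMANN_PN_NM_298K = 4.114
"""k_B T at 298 K in pN.nm."""

# Fraction of the stall force above which the motor is considered stalled:
# the detachment hazard switches on and the interval is annotated "stall".
STALL_GATE_FRACTION = 0.97

# Pause entry is only allowed below this fraction of the stall force so that
# pause and stall ground-truth intervals can never overlap.
PAUSE_GATE_MAX_FRACTION = 0.90


class SyntheticDataError(ValueError):
    """Invalid generator parameters."""


# ---------------------------------------------------------------------------
# Trap traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorTrapParams:
    """Parameters of the trapped-bead / single-motor simulator.

    Units: forces pN, lengths nm, times s, rates 1/s, stiffness pN/nm,
    drag pN.s/nm, energies pN.nm.
    """

    trap_stiffness: float = 0.06
    bead_drag: float = 9.4e-6          # ~1 um bead in water
    thermal_energy: float = BOLTZMANN_PN_NM_298K
    unloaded_velocity: float = 800.0
    stall_force: float = 4.3
    detach_rate_at_stall: float = 2.5
    pause_entry_rate: float = 0.0      # force-gated; >0 for mutant-like motors
    pause_exit_rate: float = 8.0
    pause_exit_detach_prob: float = 0.0
    pause_min_force: float = 1.0
    reattach_rate: float = 1.0
    sample_rate: float = 5000.0
    duration: float = 5.0
    initially_bound: bool = True
    seed: int = 0

    def validate(self) -> None:
        finite = all(
            math.isfinite(getattr(self, name))
            for name in (
                "trap_stiffness", "bead_drag", "thermal_energy",
                "unloaded_velocity", "stall_force", "detach_rate_at_stall",
                "pause_entry_rate", "pause_exit_rate",
                "pause_exit_detach_prob", "pause_min_force",
                "reattach_rate", "sample_rate", "duration",
            )
        )
        if not finite:
            raise SyntheticDataError("non-finite trap parameter")
        if self.trap_stiffness <= 0:
            raise SyntheticDataError("trap_stiffness must be > 0")
        if self.bead_drag <= 0:
            raise SyntheticDataError("bead_drag must be > 0")
        if self.sample_rate <= 0:
            raise SyntheticDataError("sample_rate must be > 0")
        if self.duration <= 0:
            raise SyntheticDataError("duration must be > 0")
        if self.stall_force <= 0:
            raise SyntheticDataError("stall_force must be > 0")
        if not 0.0 <= self.pause_exit_detach_prob <= 1.0:
            raise SyntheticDataError("pause_exit_detach_prob must be in [0, 1]")
        for name in ("detach_rate_at_stall", "pause_entry_rate",
                     "pause_exit_rate", "reattach_rate"):
            if getattr(self, name) < 0:
                raise SyntheticDataError(f"{name} must be >= 0")
        if self.thermal_energy < 0:
            raise SyntheticDataError("thermal_energy must be >= 0")


@dataclass(frozen=True)
class GroundTruthInterval:
    """A programmed event interval in a synthetic trace."""

    kind: str          # "stall" | "pause" | "unbound"
    start: float       # s (inclusive)
    end: float         # s (exclusive)
    level: float       # force level in pN associated with the event


@dataclass
class TrapTrace:
    """Uniformly sampled force record of a trapped bead.

    ``force`` is positive when the load opposes the motor (bead displaced
    from the trap center).
    """

    times: np.ndarray
    force: np.ndarray
    spring_constant: float
    sample_rate: float
    label: str = ""
    ground_truth: Optional[list[GroundTruthInterval]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.times.shape != self.force.shape:
            raise SyntheticDataError("times/force length mismatch")
        if not np.all(np.isfinite(self.force)):
            raise SyntheticDataError("non-finite force values")

    def __len__(self) -> int:
        return self.force.size


def wt_motor_params(seed: int = 0, **overrides) -> MotorTrapParams:
    """Wild-type-like motor: 4.3 pN stall, no low-force pausing."""
    return replace(MotorTrapParams(seed=seed), **overrides)


def mutant_motor_params(seed: int = 0, **overrides) -> MotorTrapParams:
    """Mutant-like motor: 2.9 pN stall with force-gated pausing; on pause
    exit the motor either detaches or resumes moving."""
    base = MotorTrapParams(
        stall_force=2.9,
        detach_rate_at_stall=1.5,
        pause_entry_rate=2.0,
        pause_exit_rate=8.0,
        pause_exit_detach_prob=0.1,
        seed=seed,
    )
    return replace(base, **overrides)


def _ou_fluctuation(n: int, dt: float, tau: float, sigma_x: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Exact stationary OU sample path (positions, nm) of length n."""
    if sigma_x == 0.0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    innov_sd = sigma_x * math.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n) * innov_sd
    noise[0] = rng.standard_normal() * sigma_x   # stationary start
    # AR(1) recursion x[i] = a*x[i-1] + noise[i]
    return signal.lfilter([1.0], [1.0, -a], noise)


def simulate_trap_trace(params: MotorTrapParams) -> TrapTrace:
    """Simulate the force record of a bead driven by a single motor.

    The recorded force is ``F(t) = F_motor(t) + k * delta(t)`` where
    ``F_motor`` is the load built up by the motor walking against the trap
    (``dF/dt = k * v0 * (1 - F/F_stall)``, clipped at zero, integrated
    exactly) and ``delta`` is the bead's thermal OU fluctuation around its
    mean position.  Detachment snaps the motor load to zero; ground-truth
    ``stall`` / ``pause`` / ``unbound`` intervals are annotated.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    k = params.trap_stiffness
    fs = params.sample_rate
    dt = 1.0 / fs
    n = int(round(params.duration * fs))
    if n < 1:
        raise SyntheticDataError("duration shorter than one sample")

    tau_bead = params.bead_drag / k
    sigma_x = math.sqrt(params.thermal_energy / k) if params.thermal_energy else 0.0
    delta = _ou_fluctuation(n, dt, tau_bead, sigma_x, rng)

    f_stall = params.stall_force
    stall_gate = STALL_GATE_FRACTION * f_stall
    pause_gate_hi = PAUSE_GATE_MAX_FRACTION * f_stall
    # Exact relaxation factor for dF/dt = (k v0 / Fs) (Fs - F)
    if params.unloaded_velocity > 0:
        decay = math.exp(-dt * k * params.unloaded_velocity / f_stall)
    else:
        decay = 1.0

    p_detach = 1.0 - math.exp(-params.detach_rate_at_stall * dt)
    p_pause = 1.0 - math.exp(-params.pause_entry_rate * dt)
    p_unpause = 1.0 - math.exp(-params.pause_exit_rate * dt)
    p_reattach = 1.0 - math.exp(-params.reattach_rate * dt)

    u = rng.random(n)
    u2 = rng.random(n)

    MOVING, PAUSED, UNBOUND = 0, 1, 2
    state = MOVING if params.initially_bound else UNBOUND
    f_motor = 0.0
    motor = np.empty(n)
    annot = np.zeros(n, dtype=np.int8)   # 0 none, 1 stall, 2 pause, 3 unbound
    level = np.zeros(n)

    for i in range(n):
        if state == MOVING:
            f_motor = f_stall - (f_stall - f_motor) * decay
            if f_motor >= stall_gate:
                annot[i] = 1
                level[i] = f_stall
                if u[i] < p_detach:
                    state = UNBOUND
                    f_motor_next = 0.0
                else:
                    f_motor_next = f_motor
            elif params.pause_min_force <= f_motor < pause_gate_hi \
                    and u[i] < p_pause:
                state = PAUSED
                f_motor_next = f_motor
            else:
                f_motor_next = f_motor
            motor[i] = f_motor
            f_motor = f_motor_next
        elif state == PAUSED:
            annot[i] = 2
            level[i] = f_motor
            motor[i] = f_motor
            if u[i] < p_unpause:
                if u2[i] < params.pause_exit_detach_prob:
                    state = UNBOUND
                    f_motor = 0.0
                else:
                    state = MOVING
        else:  # UNBOUND
            annot[i] = 3
            level[i] = 0.0
            motor[i] = 0.0
            f_motor = 0.0
            if u[i] < p_reattach:
                state = MOVING

    force = motor + k * delta
    times = np.arange(n) / fs

    intervals: list[GroundTruthInterval] = []
    kinds = {1: "stall", 2: "pause", 3: "unbound"}
    i = 0
    while i < n:
        a = annot[i]
        j = i
        while j < n and annot[j] == a:
            j += 1
        if a != 0:
            intervals.append(GroundTruthInterval(
                kind=kinds[a], start=i * dt, end=j * dt,
                level=float(np.mean(level[i:j])),
            ))
        i = j

    return TrapTrace(times=times, force=force, spring_constant=k,
                     sample_rate=fs, label=f"sim-seed{params.seed}",
                     ground_truth=intervals)


# ---------------------------------------------------------------------------
# TIRF-like tracks
# ---------------------------------------------------------------------------

TRACK_MODES = ("processive", "static", "diffusive")


@dataclass(frozen=True)
class SyntheticTrackParams:
    """Parameters for a single synthetic kymograph track.

    ``velocity`` in nm/s (minus-end-positive), ``diffusion_coeff`` in nm^2/s,
    ``frame_interval`` in s, ``localization_noise_sd`` in nm.
    """

    mode: str = "processive"
    velocity: float = 400.0
    diffusion_coeff: float = 3.0e4
    duration: float = 3.0
    frame_interval: float = 0.5
    localization_noise_sd: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in TRACK_MODES:
            raise SyntheticDataError(f"unknown track mode {self.mode!r}")
        if self.duration <= 0:
            raise SyntheticDataError("duration must be > 0")
        if self.frame_interval <= 0:
            raise SyntheticDataError("frame_interval must be > 0")
        if self.localization_noise_sd < 0:
            raise SyntheticDataError("localization noise must be >= 0")
        if self.diffusion_coeff < 0:
            raise SyntheticDataError("diffusion_coeff must be >= 0")


def simulate_track(params: "SyntheticTrackParams"):
    """Generate a (time, position) track on a uniform frame grid.

    Returns a :class:`motorforge.motility.Track`.  Modes: ``processive``
    (constant drift + noise), ``static`` (noise only), ``diffusive``
    (1-D Brownian steps with the stated diffusion coefficient + noise).
    """
    from .motility import Track  # local import to avoid a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(math.floor(params.duration / params.frame_interval)) + 1
    t = np.arange(n) * params.frame_interval

    if params.mode == "processive":
        x = params.velocity * t
    elif params.mode == "static":
        x = np.zeros(n)
    else:
        step_sd = math.sqrt(2.0 * params.diffusion_coeff * params.frame_interval)
        steps = rng.standard_normal(n - 1) * step_sd
        x = np.concatenate([[0.0], np.cumsum(steps)])

    if params.localization_noise_sd > 0:
        x = x + rng.standard_normal(n) * params.localization_noise_sd

    return Track(times=t, positions=x, frame_interval=params.frame_interval,
                 ground_truth_mode=params.mode)


# ---------------------------------------------------------------------------
# Rigid-body pseudo-MD trajectories
# ---------------------------------------------------------------------------

TUBULIN_CHAIN = "A"
DYNEIN_CHAIN = "D"

# synthetic geometry (Angstrom)
_ANCHOR_BASE_CENTER = np.array([40.0, 0.0, 0.0])   # center of res 3295/3395 CA
_ANCHOR_TIP_CENTER = np.array([55.0, 0.0, 0.0])    # center of res 3288/3402 CA
_STALK_TIP_ANGLE_DEG = 60.0                        # stalk vector vs +z (PA1)
_STALK_LENGTH = 80.0


def make_reference_structure(stalk_angle_deg: float = _STALK_TIP_ANGLE_DEG
                             ) -> StructureFrame:
    """Build the synthetic MTBD-on-tubulin reference coordinate set.

    Chain ``A`` is a "tubulin" rod of CA pseudo-atoms on a shallow helix
    along z (the protofilament long axis) plus an ARG 402 side-chain
    nitrogen near the interface; chain ``D`` carries the dynein stalk-base
    anchor residues (3295/3395 and 3288/3402 CA), the stalk tip anchors
    (3191/3501 CA, at ``stalk_angle_deg`` to the long axis), a GLU 3306
    side-chain oxygen facing R402, and a spread of MTBD CA atoms for RMSF
    profiling.

    The helix closes an integer number of turns, so the tubulin CA inertia
    tensor is exactly axisymmetric about z and the principal-axis frame of
    the reference is exactly (z, x, y).  The MTBD vector (3295/3395 center
    -> 3288/3402 center) points along +x, which maps to PA2, so the
    reference MTBD angle is exactly 0.
    """
    records: list[tuple[str, int, str, str, str, list[float]]] = []

    def add(chain, res_id, res_name, atom_name, element, xyz):
        records.append((chain, res_id, res_name, atom_name, element,
                        [float(v) for v in xyz]))

    # tubulin rod: antipodal atom pairs on a helix, whole turns -> the CA
    # inertia tensor is exactly diagonal in (x, y, z), so PA1 is exactly z
    n_levels = 24
    zs = np.linspace(-100.0, 100.0, n_levels)
    rid = 1
    for i, z in enumerate(zs):
        phi = 2.0 * math.pi * i / 12.0
        for phase in (phi, phi + math.pi):
            add(TUBULIN_CHAIN, rid, "ALA", "CA", "C",
                [8.0 * math.cos(phase), 8.0 * math.sin(phase), z])
            rid += 1
    # alpha-tubulin R402 basic nitrogen near the dynein interface
    add(TUBULIN_CHAIN, 402, "ARG", "NH1", "N", [12.0, 0.0, 8.0])

    # dynein stalk-base anchors
    add(DYNEIN_CHAIN, 3295, "ALA", "CA", "C", _ANCHOR_BASE_CENTER + [0.0, 0.0, 4.0])
    add(DYNEIN_CHAIN, 3395, "TRP", "CA", "C", _ANCHOR_BASE_CENTER - [0.0, 0.0, 4.0])
    add(DYNEIN_CHAIN, 3288, "ALA", "CA", "C", _ANCHOR_TIP_CENTER + [0.0, 0.0, 4.0])
    add(DYNEIN_CHAIN, 3402, "TYR", "CA", "C", _ANCHOR_TIP_CENTER - [0.0, 0.0, 4.0])

    # stalk tip anchors: center at base + L*(sin(theta) x + cos(theta) z)
    theta = math.radians(stalk_angle_deg)
    tip_center = _ANCHOR_BASE_CENTER + _STALK_LENGTH * np.array(
        [math.sin(theta), 0.0, math.cos(theta)])
    add(DYNEIN_CHAIN, 3191, "ARG", "CA", "C", tip_center + [0.0, 3.0, 0.0])
    add(DYNEIN_CHAIN, 3501, "SER", "CA", "C", tip_center - [0.0, 3.0, 0.0])

    # E3306 acidic oxygen facing R402 (contact-schedule handle)
    add(DYNEIN_CHAIN, 3306, "GLU", "OE1", "O", [18.0, 0.0, 8.0])

    # MTBD body CA atoms for RMSF reporting
    rng = np.random.default_rng(20240601)
    for res_id in range(3300, 3380, 4):
        xyz = _ANCHOR_BASE_CENTER + rng.uniform(-10.0, 10.0, size=3)
        add(DYNEIN_CHAIN, res_id, "GLY", "CA", "C", xyz)

    chain, rid, rname, aname, elem, xyz = zip(*records)
    return StructureFrame(chain_id=np.array(chain), res_id=np.array(rid),
                          res_name=np.array(rname),
                          atom_name=np.array(aname),
                          element=np.array(elem), coord=np.array(xyz))


@dataclass(frozen=True)
class ContactSchedule:
    """Programmed per-frame on/off positioning of one atom pair.

    On "on" frames the second atom is placed ``on_distance`` A from the
    first (along +x in the lab frame); on "off" frames ``off_distance`` A.
    """

    pattern: Sequence[bool]
    atom_a: tuple[str, int, str] = (TUBULIN_CHAIN, 402, "NH1")
    atom_b: tuple[str, int, str] = (DYNEIN_CHAIN, 3306, "OE1")
    on_distance: float = 3.0
    off_distance: float = 12.0


@dataclass(frozen=True)
class SyntheticTrajectoryParams:
    """Parameters of the rigid-body MTBD trajectory generator.

    ``angle_components`` is a list of ``(weight, mean_deg, sd_deg)``; each
    frame rotates the mobile (dynein) chain about ``axis`` (through the
    origin) by an angle drawn from this Gaussian mixture.  Isotropic
    Gaussian noise of ``positional_noise_sd`` A is added per atom — by
    default to the mobile chain only, mirroring source simulations in
    which the tubulin dimer is harmonically restrained.
    """

    reference: Optional[StructureFrame] = None
    angle_components: tuple = ((1.0, 0.0, 0.0),)
    positional_noise_sd: float = 0.0
    n_frames: int = 100
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    mobile_chain: str = DYNEIN_CHAIN
    noise_mobile_only: bool = True
    contact_schedule: Optional[ContactSchedule] = None
    frame_interval_ns: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise SyntheticDataError("n_frames must be >= 1")
        w = sum(c[0] for c in self.angle_components)
        if not math.isclose(w, 1.0, rel_tol=0, abs_tol=1e-9):
            raise SyntheticDataError("component weights must sum to 1")
        if any(c[2] < 0 for c in self.angle_components):
            raise SyntheticDataError("component sd must be >= 0")
        if self.positional_noise_sd < 0:
            raise SyntheticDataError("positional noise must be >= 0")
        if np.linalg.norm(self.axis) == 0:
            raise SyntheticDataError("degenerate rotation axis")


@dataclass
class SyntheticTrajectory:
    """Frames plus the programmed per-frame rotation angles."""

    reference: StructureFrame
    frames: Trajectory
    ground_truth_angles_deg: np.ndarray


def simulate_mtbd_trajectory(params: SyntheticTrajectoryParams
                             ) -> SyntheticTrajectory:
    """Generate a rigid-body trajectory with known rotation ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    ref = params.reference if params.reference is not None \
        else make_reference_structure()
    if len(ref) == 0:
        raise SyntheticDataError("reference coordinates are empty")

    axis = np.asarray(params.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    weights = np.array([c[0] for c in params.angle_components])
    means = np.array([c[1] for c in params.angle_components])
    sds = np.array([c[2] for c in params.angle_components])
    comp = rng.choice(len(weights), size=params.n_frames, p=weights)
    angles = means[comp] + sds[comp] * rng.standard_normal(params.n_frames)

    mobile = ref.chain_id == params.mobile_chain
    coords = np.repeat(ref.coord[None, :, :], params.n_frames, axis=0)

    for f in range(params.n_frames):
        rot = Rotation.from_rotvec(math.radians(angles[f]) * axis)
        coords[f, mobile, :] = rot.apply(coords[f, mobile, :])

    if params.positional_noise_sd > 0:
        noise = rng.standard_normal(coords.shape) * params.positional_noise_sd
        if params.noise_mobile_only:
            noise[:, ~mobile, :] = 0.0
        coords += noise

    if params.contact_schedule is not None:
        sched = params.contact_schedule
        ia = _atom_index(ref, *sched.atom_a)
        ib = _atom_index(ref, *sched.atom_b)
        pattern = np.asarray(sched.pattern, dtype=bool)
        for f in range(params.n_frames):
            on = pattern[f % pattern.size]
            d = sched.on_distance if on else sched.off_distance
            coords[f, ib, :] = coords[f, ia, :] + np.array([d, 0.0, 0.0])

    traj = Trajectory(topology=ref, coords=coords,
                      frame_interval_ns=params.frame_interval_ns)
    return SyntheticTrajectory(reference=ref, frames=traj,
                               ground_truth_angles_deg=angles)


def _atom_index(arr: StructureFrame, chain: str, res_id: int,
                atom_name: str) -> int:
    mask = (arr.chain_id == chain) & (arr.res_id == res_id) \
        & (arr.atom_name == atom_name)
    idx = np.flatnonzero(mask)
    if idx.size != 1:
        raise SyntheticDataError(
            f"atom ({chain},{res_id},{atom_name}) resolves to {idx.size} atoms")
    return int(idx[0])
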