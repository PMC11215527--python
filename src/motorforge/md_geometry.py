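"""Microtubule-referenced geometry of MD trajectories.

The tubulin dimer defines an orthonormal frame: PA1 is the protofilament
long axis (smallest-inertia principal axis of the tubulin atoms), PA2 is
the radial axis pointing from the tubulin center of mass toward the dynein
stalk-base anchor center (component orthogonal to PA1), and PA3 = PA1 x PA2
is the tangential axis.  Axes are computed from the reference structure and
held fixed, per-frame structures being superposed onto the reference via
the tubulin selection first.

The MTBD vector runs from the center of the 3295/3395 CA atoms to the
center of the 3288/3402 CA atoms; its signed angle about the long axis is
measured in a configurable projection plane (default the PA2-PA3 plane,
i.e. the plane perpendicular to the long axis; the literal PA1-PA2 reading
is available).  The stalk vector is obtained by superposing a full-length
structure onto the stalk-base CA atoms of each frame and runs from the
3295/3395 center to the 3191/3501 center; its angle is measured against
PA1 in [0, 180).

Also provided: Kabsch superposition, per-residue RMSF after tubulin
alignment, and deterministic 1- or 2-Gaussian fits of angle histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize

from .structures import StructureFrame, Trajectory
from .synthetic_data import DYNEIN_CHAIN, TUBULIN_CHAIN


class GeometryError(ValueError):
    pass


MTBD_BASE_ANCHORS = (3295, 3395)   # stalk-base CA pair (vector origin)
MTBD_TIP_ANCHORS = (3288, 3402)    # MTBD-side CA pair (vector tip)
STALK_TIP_ANCHORS = (3191, 3501)   # stalk tip CA pair in the full structure


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch) of point sets.

    Returns the proper rotation (det = +1 enforced) and translation mapping
    ``mobile`` onto ``reference``, with the post-fit RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise GeometryError("need >= 3 paired atoms for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise GeometryError("collinear/degenerate selection")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    rmsd = float(np.sqrt(np.mean(np.sum(
        (a @ rot.T - b) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


# ---------------------------------------------------------------------------
# Principal axes
# ---------------------------------------------------------------------------

@dataclass
class PrincipalAxes:
    origin: np.ndarray
    pa1: np.ndarray
    pa2: np.ndarray
    pa3: np.ndarray

    def check(self) -> None:
        m = np.vstack([self.pa1, self.pa2, self.pa3])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise GeometryError("axes not orthonormal")


def _ca_center(arr: StructureFrame, chain: str, res_ids: Iterable[int]
               ) -> np.ndarray:
    coords = []
    for rid in res_ids:
        mask = (arr.chain_id == chain) & (arr.res_id == rid) \
            & (arr.atom_name == "CA")
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise GeometryError(f"CA of {chain}/{rid} resolves to "
                                f"{idx.size} atoms")
        coords.append(arr.coord[idx[0]])
    return np.mean(coords, axis=0)


def principal_axes(reference: StructureFrame,
                   tubulin_chain: str = TUBULIN_CHAIN,
                   anchor_chain: str = DYNEIN_CHAIN,
                   anchor_res_ids: Sequence[int] = MTBD_BASE_ANCHORS,
                   reference_pa1: Optional[np.ndarray] = None,
                   ) -> PrincipalAxes:
    """Microtubule frame from the tubulin inertia tensor and the anchors.

    PA1 is the smallest-inertia (long) axis, its sign chosen to match
    ``reference_pa1`` (or +z by default); PA2 is the unit component of
    (anchor center - tubulin COM) orthogonal to PA1; PA3 = PA1 x PA2.
    """
    tub = reference[(reference.chain_id == tubulin_chain)
                    & (reference.atom_name == "CA")]
    if len(tub) == 0:
        raise GeometryError("empty tubulin selection")
    origin = tub.coord.mean(axis=0)
    rel = tub.coord - origin
    # inertia tensor with unit masses
    r2 = np.sum(rel ** 2, axis=1)
    inertia = np.eye(3) * r2.sum() - rel.T @ rel
    evals, evecs = np.linalg.eigh(inertia)
    if evals[0] > 0.9 * evals[1]:
        raise GeometryError("near-degenerate inertia tensor: long axis "
                            "ambiguous")
    pa1 = evecs[:, 0]
    ref_dir = np.asarray(reference_pa1, dtype=float) \
        if reference_pa1 is not None else np.array([0.0, 0.0, 1.0])
    if np.dot(pa1, ref_dir) < 0:
        pa1 = -pa1

    anchor = _ca_center(reference, anchor_chain, anchor_res_ids)
    radial = anchor - origin
    radial = radial - np.dot(radial, pa1) * pa1
    norm = np.linalg.norm(radial)
    if norm < 1e-9:
        raise GeometryError("anchor center lies on the long axis")
    pa2 = radial / norm
    pa3 = np.cross(pa1, pa2)
    axes = PrincipalAxes(origin=origin, pa1=pa1, pa2=pa2, pa3=pa3)
    axes.check()
    return axes


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

ProjectionPlane = Literal["PA2PA3", "PA1PA2"]


def _signed_plane_angle(v: np.ndarray, axes: PrincipalAxes,
                        plane: ProjectionPlane) -> float:
    """Signed angle (deg) between the projection of v and PA2.

    Positive = rotation from PA2 toward +PA3 viewed down +PA1 ("clockwise"
    in the published convention) for the PA2PA3 plane; for the PA1PA2
    plane the sign follows the plane normal PA3.
    """
    if plane == "PA2PA3":
        a = float(np.dot(v, axes.pa2))
        b = float(np.dot(v, axes.pa3))
    elif plane == "PA1PA2":
        a = float(np.dot(v, axes.pa2))
        b = -float(np.dot(v, axes.pa1))
    else:
        raise GeometryError(f"unknown projection plane {plane!r}")
    if math.hypot(a, b) < 1e-9:
        raise GeometryError("projected vector is near zero")
    return math.degrees(math.atan2(b, a))


def mtbd_vector(frame: StructureFrame, chain: str = DYNEIN_CHAIN
                ) -> np.ndarray:
    base = _ca_center(frame, chain, MTBD_BASE_ANCHORS)
    tip = _ca_center(frame, chain, MTBD_TIP_ANCHORS)
    return tip - base


def mtbd_angle(frame: StructureFrame, axes: PrincipalAxes,
               plane: ProjectionPlane = "PA2PA3",
               reference_zero: float = 0.0,
               chain: str = DYNEIN_CHAIN) -> float:
    """Signed MTBD orientation angle (deg) relative to the reference zero."""
    angle = _signed_plane_angle(mtbd_vector(frame, chain), axes, plane)
    angle -= reference_zero
    return (angle + 180.0) % 360.0 - 180.0


def stalk_angle(frame: StructureFrame, axes: PrincipalAxes,
                full_structure: StructureFrame,
                chain: str = DYNEIN_CHAIN,
                base_res_ids: Sequence[int] = MTBD_BASE_ANCHORS + MTBD_TIP_ANCHORS,
                rmsd_max: float = 5.0) -> float:
    """Angle (deg, in [0, 180)) between the stalk vector and PA1.

    ``full_structure`` is superposed onto the frame's stalk-base CA atoms;
    the stalk vector runs from the frame's 3295/3395 CA center to the
    superposed structure's 3191/3501 CA center.
    """
    mob = np.array([_ca_center(full_structure, chain, [rid])
                    for rid in base_res_ids])
    ref = np.array([_ca_center(frame, chain, [rid])
                    for rid in base_res_ids])
    tf = superpose(mob, ref)
    if tf.rmsd > rmsd_max:
        raise GeometryError(
            f"stalk-base superposition RMSD {tf.rmsd:.2f} A exceeds "
            f"{rmsd_max} A")
    tip_full = _ca_center(full_structure, chain, STALK_TIP_ANCHORS)
    tip = tf.apply(tip_full[None, :])[0]
    base = _ca_center(frame, chain, MTBD_BASE_ANCHORS)
    v = tip - base
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise GeometryError("zero-length stalk vector")
    cosang = np.clip(np.dot(v / nv, axes.pa1), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def _align_frame(frame: StructureFrame, reference: StructureFrame,
                 align_mask: np.ndarray) -> StructureFrame:
    tf = superpose(frame.coord[align_mask], reference.coord[align_mask])
    out = frame.copy()
    out.coord = tf.apply(frame.coord)
    return out


def mtbd_angle_series(frames: Trajectory,
                      reference: StructureFrame,
                      plane: ProjectionPlane = "PA2PA3",
                      reference_zero: float = 0.0,
                      align: bool = True,
                      tubulin_chain: str = TUBULIN_CHAIN,
                      chain: str = DYNEIN_CHAIN) -> np.ndarray:
    """Per-frame MTBD angles with the axes fixed from the reference."""
    axes = principal_axes(reference, tubulin_chain=tubulin_chain,
                          anchor_chain=chain)
    align_mask = reference.chain_id == tubulin_chain
    out = np.empty(frames.n_frames)
    for i, frame in enumerate(frames):
        fr = _align_frame(frame, reference, align_mask) if align else frame
        out[i] = mtbd_angle(fr, axes, plane=plane,
                            reference_zero=reference_zero, chain=chain)
    return out


def stalk_angle_series(frames: Trajectory,
                       reference: StructureFrame,
                       full_structure: StructureFrame,
                       align: bool = True,
                       tubulin_chain: str = TUBULIN_CHAIN,
                       chain: str = DYNEIN_CHAIN) -> np.ndarray:
    axes = principal_axes(reference, tubulin_chain=tubulin_chain,
                          anchor_chain=chain)
    align_mask = reference.chain_id == tubulin_chain
    out = np.empty(frames.n_frames)
    for i, frame in enumerate(frames):
        fr = _align_frame(frame, reference, align_mask) if align else frame
        out[i] = stalk_angle(fr, axes, full_structure, chain=chain)
    return out


# ---------------------------------------------------------------------------
# Angle histogram fits
# ---------------------------------------------------------------------------

@dataclass
class AngleHistogramFit:
    n_components: int
    peaks: list[tuple[float, float]]   # (mean deg, sd deg), ascending mean
    weights: list[float]
    residual_rms: float
    reference_zero: float = 0.0


def angle_histogram_fit(angles: np.ndarray, n_components: int = 1,
                        bin_width: float = 1.0,
                        reference_zero: float = 0.0,
                        min_separation: float = 2.0) -> AngleHistogramFit:
    """Fit a normalized angle histogram with 1 or 2 Gaussians.

    Initialization is deterministic (histogram modes); for two components
    a fit whose peaks collapse closer than ``min_separation`` degrees is
    reported as an error.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 100:
        raise GeometryError(f"need >= 100 angle samples, got {angles.size}")
    if n_components not in (1, 2):
        raise GeometryError("n_components must be 1 or 2")
    lo = math.floor(angles.min() / bin_width) * bin_width
    hi = math.ceil(angles.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    prob = counts / counts.sum()
    x = 0.5 * (edges[:-1] + edges[1:])

    order = np.argsort(prob)[::-1]
    mu0 = [float(x[order[0]])]
    if n_components == 2:
        # second initial mean: highest bin at least 5 deg from the first
        for idx in order[1:]:
            if abs(x[idx] - mu0[0]) >= 5.0:
                mu0.append(float(x[idx]))
                break
        else:
            mu0.append(mu0[0] + 5.0)

    pars = Parameters()
    for i in range(n_components):
        pars.add(f"w{i}", value=1.0 / n_components, min=1e-6, max=1.0)
        pars.add(f"mu{i}", value=mu0[i], min=lo - bin_width,
                 max=hi + bin_width)
        pars.add(f"sd{i}", value=max(2.0, bin_width), min=bin_width / 4.0,
                 max=(hi - lo))

    def model(p):
        out = np.zeros_like(x)
        for i in range(n_components):
            out += p[f"w{i}"] * np.exp(
                -0.5 * ((x - p[f"mu{i}"]) / p[f"sd{i}"]) ** 2) \
                / (p[f"sd{i}"] * math.sqrt(2 * math.pi))
        return out * bin_width

    out = minimize(lambda p: model(p) - prob, pars, method="leastsq")
    rms = float(np.sqrt(np.mean(out.residual ** 2)))
    if not out.success:
        raise GeometryError(f"angle histogram fit failed (rms {rms:.3g})")
    comps = sorted(
        ((float(out.params[f"mu{i}"].value) - reference_zero,
          float(out.params[f"sd{i}"].value),
          float(out.params[f"w{i}"].value))
         for i in range(n_components)),
        key=lambda c: c[0])
    if n_components == 2:
        sep = abs(comps[1][0] - comps[0][0])
        collapsed = (sep < min_separation
                     or sep < 0.5 * (comps[0][1] + comps[1][1])
                     or min(c[2] for c in comps) < 0.1)
        if collapsed:
            raise GeometryError("two-component fit collapsed onto one mode")
    return AngleHistogramFit(
        n_components=n_components,
        peaks=[(c[0], c[1]) for c in comps],
        weights=[c[2] for c in comps],
        residual_rms=rms, reference_zero=reference_zero)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    res_ids: np.ndarray
    rmsf: np.ndarray   # Angstrom


def rmsf(frames: Trajectory, reference: StructureFrame,
         align_mask: np.ndarray, report_mask: np.ndarray) -> RMSFProfile:
    """Per-residue CA RMSF after rigid alignment onto the reference.

    Every frame is superposed on the reference via ``align_mask`` atoms;
    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames for each reported atom,
    reported per residue (mean over that residue's reported atoms).
    """
    n = frames.n_frames
    if n < 2:
        raise GeometryError("RMSF undefined for a single frame")
    coords = np.empty((n, int(report_mask.sum()), 3))
    for i, frame in enumerate(frames):
        tf = superpose(frame.coord[align_mask], reference.coord[align_mask])
        coords[i] = tf.apply(frame.coord[report_mask])
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))

    res_ids = reference.res_id[report_mask]
    uniq = np.unique(res_ids)
    prof = np.array([per_atom[res_ids == rid].mean() for rid in uniq])
    return RMSFProfile(res_ids=uniq, rmsf=prof)


def rmsf_percent_change(profile_a: RMSFProfile, profile_b: RMSFProfile,
                        res_range: Optional[tuple[int, int]] = None) -> float:
    """Mean over residues of 100 * (B - A) / A, optionally restricted to an
    inclusive residue range."""
    if not np.array_equal(profile_a.res_ids, profile_b.res_ids):
        raise GeometryError("profiles cover different residues")
    sel = np.ones(profile_a.res_ids.size, dtype=bool)
    if res_range is not None:
        sel = (profile_a.res_ids >= res_range[0]) \
            & (profile_a.res_ids <= res_range[1])
        if not sel.any():
            raise GeometryError("empty residue range")
    a = profile_a.rmsf[sel]
    b = profile_b.rmsf[sel]
    if np.any(a <= 0):
        raise GeometryError("zero RMSF in denominator profile")
    return float(np.mean(100.0 * (b - a) / a))
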