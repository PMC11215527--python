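"""Frame-wise contact detection and occupancy statistics.

Fixed-cutoff criteria on explicit-atom structures:

* salt bridge — any basic nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2,
  optional) within 4.0 A of any acidic oxygen (Asp OD1/OD2; Glu OE1/OE2;
  C-terminal OXT); closed boundary (exactly 4.0 A counts);
* hydrogen bond — donor–acceptor heavy-atom distance <= 3.5 A and the
  hydrogen–donor–acceptor angle <= 30 deg; hydrogens must be explicit;
* hydrophobic contact — any side-chain carbon pair within 8.0 A
  (backbone C, CA and carbonyl O excluded from "side chain").

Occupancy is the fraction of frames in which a contact is present,
reported per trajectory and pooled over all frames of all trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structures import StructureFrame, Trajectory


class ContactError(ValueError):
    pass


BASIC_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

ACIDIC_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


@dataclass(frozen=True)
class ContactCriteria:
    salt_bridge_cutoff: float = 4.0    # A
    hydrophobic_cutoff: float = 8.0    # A
    hbond_distance_cutoff: float = 3.5  # A, donor-acceptor heavy atoms
    hbond_angle_cutoff: float = 30.0   # deg, H-donor-acceptor
    include_histidine: bool = True

    def validate(self) -> None:
        for name in ("salt_bridge_cutoff", "hydrophobic_cutoff",
                     "hbond_distance_cutoff", "hbond_angle_cutoff"):
            if getattr(self, name) <= 0:
                raise ContactError(f"{name} must be > 0")


@dataclass(frozen=True)
class ResidueSpec:
    chain: str
    res_id: int


@dataclass(frozen=True)
class ContactPair:
    kind: str                 # "salt_bridge" | "hbond" | "hydrophobic"
    residue_a: ResidueSpec
    residue_b: ResidueSpec
    # hbond only: donor heavy atom, its hydrogen, acceptor heavy atom
    donor_atom: str = ""
    hydrogen_atom: str = ""
    acceptor_atom: str = ""


def _residue(frame: StructureFrame, spec: ResidueSpec) -> StructureFrame:
    sub = frame[(frame.chain_id == spec.chain) & (frame.res_id == spec.res_id)]
    if len(sub) == 0:
        raise ContactError(f"residue {spec.chain}/{spec.res_id} not found")
    return sub


def _coords_of(res: StructureFrame, names: Sequence[str]) -> np.ndarray:
    mask = np.isin(res.atom_name, list(names))
    return res.coord[mask]


def _basic_n_coords(res: StructureFrame, include_his: bool) -> np.ndarray:
    name = res.res_name[0]
    table = dict(BASIC_NITROGENS)
    if not include_his:
        table.pop("HIS", None)
    if name not in table:
        raise ContactError(f"{name} has no basic nitrogen")
    coords = _coords_of(res, table[name])
    if coords.size == 0:
        raise ContactError(f"basic nitrogens of {name} missing from frame")
    return coords


def _acidic_o_coords(res: StructureFrame) -> np.ndarray:
    name = res.res_name[0]
    names: tuple[str, ...] = ACIDIC_OXYGENS.get(name, ())
    names = names + ("OXT",)
    coords = _coords_of(res, names)
    if coords.size == 0:
        raise ContactError(f"acidic oxygens of {name} missing from frame")
    return coords


def detect_salt_bridge(frame: StructureFrame, pair: ContactPair,
                       criteria: ContactCriteria = ContactCriteria()) -> bool:
    """Minimum basic-N to acidic-O distance <= cutoff (closed boundary).

    ``residue_a`` is the basic partner, ``residue_b`` the acidic one.
    """
    criteria.validate()
    n = _basic_n_coords(_residue(frame, pair.residue_a),
                        criteria.include_histidine)
    o = _acidic_o_coords(_residue(frame, pair.residue_b))
    return bool(cdist(n, o).min() <= criteria.salt_bridge_cutoff)


def detect_hbond(frame: StructureFrame, pair: ContactPair,
                 criteria: ContactCriteria = ContactCriteria()) -> bool:
    """Donor-acceptor distance and H-donor-acceptor angle criterion.

    The donor hydrogen must be an explicit atom; no hydrogen positions are
    inferred.
    """
    criteria.validate()
    don_res = _residue(frame, pair.residue_a)
    acc_res = _residue(frame, pair.residue_b)
    for label, res, name in (("donor", don_res, pair.donor_atom),
                             ("hydrogen", don_res, pair.hydrogen_atom),
                             ("acceptor", acc_res, pair.acceptor_atom)):
        if not name:
            raise ContactError(f"hbond pair missing {label} atom name")
    d = _coords_of(don_res, [pair.donor_atom])
    h = _coords_of(don_res, [pair.hydrogen_atom])
    a = _coords_of(acc_res, [pair.acceptor_atom])
    if h.size == 0:
        raise ContactError(
            f"explicit hydrogen {pair.hydrogen_atom} missing from donor "
            f"residue (no hydrogen inference is performed)")
    if d.size == 0 or a.size == 0:
        raise ContactError("donor or acceptor heavy atom missing")
    d, h, a = d[0], h[0], a[0]
    if np.linalg.norm(a - d) > criteria.hbond_distance_cutoff:
        return False
    v1 = h - d
    v2 = a - d
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return angle <= criteria.hbond_angle_cutoff


def _sidechain_carbons(res: StructureFrame) -> np.ndarray:
    mask = (res.element == "C") & ~np.isin(res.atom_name, BACKBONE_ATOMS)
    coords = res.coord[mask]
    if coords.size == 0:
        raise ContactError(
            f"{res.res_name[0]} {res.res_id[0]} has no side-chain carbon")
    return coords


def detect_hydrophobic(frame: StructureFrame, pair: ContactPair,
                       criteria: ContactCriteria = ContactCriteria()) -> bool:
    """Any side-chain C–C distance <= cutoff (backbone carbons excluded)."""
    criteria.validate()
    ca = _sidechain_carbons(_residue(frame, pair.residue_a))
    cb = _sidechain_carbons(_residue(frame, pair.residue_b))
    return bool(cdist(ca, cb).min() <= criteria.hydrophobic_cutoff)


_DETECTORS = {
    "salt_bridge": detect_salt_bridge,
    "hbond": detect_hbond,
    "hydrophobic": detect_hydrophobic,
}


def detect(frame: StructureFrame, pair: ContactPair,
           criteria: ContactCriteria = ContactCriteria()) -> bool:
    try:
        fn = _DETECTORS[pair.kind]
    except KeyError:
        raise ContactError(f"unknown contact kind {pair.kind!r}") from None
    return fn(frame, pair, criteria)


@dataclass
class OccupancyResult:
    per_trajectory: list[float]
    pooled: float
    n_frames: int
    n_trajectories: int


def occupancy(trajectories: "Trajectory | list[Trajectory]",
              pair: ContactPair,
              criteria: ContactCriteria = ContactCriteria()
              ) -> OccupancyResult:
    """Fraction of contact-positive frames, per trajectory and pooled."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ContactError("no trajectories supplied")
    per = []
    hits = 0
    total = 0
    for stack in trajectories:
        n = stack.n_frames
        if n == 0:
            raise ContactError("empty trajectory")
        h = sum(1 for frame in stack if detect(frame, pair, criteria))
        per.append(h / n)
        hits += h
        total += n
    return OccupancyResult(per_trajectory=per, pooled=hits / total,
                           n_frames=total, n_trajectories=len(per))
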