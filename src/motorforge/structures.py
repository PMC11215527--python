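"""In-memory containers for structures and trajectories.

A :class:`StructureFrame` is a flat table of atom records (chain, residue
id/name, atom name, element, xyz in Angstrom) with float64 coordinates —
geometric analyses here resolve angles far below the float32 resolution
that typical structure containers use, so coordinates are kept in double
precision end to end.  PDB input/output converts to and from biotite's
``AtomArray`` at the boundary (see :mod:`motorforge.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

import biotite.structure as struc


class StructureError(ValueError):
    pass


@dataclass
class StructureFrame:
    """One conformation: parallel annotation arrays plus (n, 3) coords."""

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coord = np.asarray(self.coord, dtype=np.float64)
        n = self.chain_id.size
        if self.coord.shape != (n, 3):
            raise StructureError(f"coord shape {self.coord.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return self.chain_id.size

    def __getitem__(self, mask) -> "StructureFrame":
        return StructureFrame(
            chain_id=self.chain_id[mask], res_id=self.res_id[mask],
            res_name=self.res_name[mask], atom_name=self.atom_name[mask],
            element=self.element[mask], coord=self.coord[mask])

    def copy(self) -> "StructureFrame":
        return StructureFrame(
            chain_id=self.chain_id.copy(), res_id=self.res_id.copy(),
            res_name=self.res_name.copy(), atom_name=self.atom_name.copy(),
            element=self.element.copy(), coord=self.coord.copy())

    def with_coord(self, coord: np.ndarray) -> "StructureFrame":
        return StructureFrame(
            chain_id=self.chain_id, res_id=self.res_id,
            res_name=self.res_name, atom_name=self.atom_name,
            element=self.element, coord=coord)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; coords shape (m, n, 3)."""

    topology: StructureFrame
    coords: np.ndarray
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != \
                (len(self.topology), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.topology)}-atom topology")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureFrame:
        return self.topology.with_coord(self.coords[i])

    def __iter__(self) -> Iterator[StructureFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# biotite conversion (PDB I/O boundary)
# ---------------------------------------------------------------------------

def from_biotite(atoms) -> "StructureFrame | Trajectory":
    """Convert a biotite AtomArray / AtomArrayStack."""
    topo = StructureFrame(
        chain_id=atoms.chain_id, res_id=atoms.res_id,
        res_name=atoms.res_name, atom_name=atoms.atom_name,
        element=atoms.element,
        coord=(atoms.coord if isinstance(atoms, struc.AtomArray)
               else atoms.coord[0]))
    if isinstance(atoms, struc.AtomArray):
        return topo
    return Trajectory(topology=topo, coords=atoms.coord)


def to_biotite(obj: "StructureFrame | Trajectory"):
    if isinstance(obj, Trajectory):
        topo = obj.topology
        out = struc.AtomArrayStack(obj.n_frames, len(topo))
        coord = obj.coords
    else:
        topo = obj
        out = struc.AtomArray(len(topo))
        coord = obj.coord
    out.chain_id = topo.chain_id.astype("U4")
    out.res_id = topo.res_id
    out.res_name = topo.res_name.astype("U5")
    out.atom_name = topo.atom_name.astype("U6")
    out.element = topo.element.astype("U2")
    out.hetero = np.zeros(len(topo), dtype=bool)
    out.coord = coord.astype(np.float32)
    return out
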