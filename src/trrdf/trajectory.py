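"""Trajectory container, file loading, particle groups and time windows.

Coordinates are stored in nm and times in ps (the GROMACS convention, in
which the distance thresholds used throughout this package — the 0.70 nm
ion cutoff, the 0.5 nm contact cutoff — are naturally expressed).  File
formats (XTC, TRR, DCD, multi-model PDB, GRO topologies) are read through
MDTraj and converted into plain NumPy arrays plus a pandas topology table;
a lossless JSON trajectory format is also supported for bit-exact fixture
round-trips.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CellError, FormatError, TopologyError
from .pbc import UnitCell

__all__ = [
    "Trajectory",
    "ParticleGroups",
    "WindowScheme",
    "Window",
    "load_trajectory",
    "partition_windows",
    "read_index_file",
]

log = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = ["name", "element", "resname", "resid", "chain"]


@dataclass
class Trajectory:
    """An MD trajectory as dense arrays.

    Attributes
    ----------
    xyz : (n_frames, n_atoms, 3) float64, nm
    time : (n_frames,) float64, ps, strictly increasing
    cells : (n_frames, 3, 3) float64 or None
        Per-frame cell-vector matrices (rows = cell vectors, nm).  ``None``
        means no periodic boundary information; analyses that need the
        minimum-image convention will then raise :class:`CellError` unless
        explicitly run without PBC.
    topology : pandas.DataFrame
        One row per atom with columns ``name, element, resname, resid,
        chain``; ``resid`` is a 0-based residue index.
    """

    xyz: np.ndarray
    time: np.ndarray
    cells: np.ndarray | None
    topology: pd.DataFrame

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise TopologyError(f"xyz must be (frames, atoms, 3), got {self.xyz.shape}")
        if len(self.time) != self.n_frames:
            raise TopologyError("time array length != number of frames")
        if self.n_frames > 1 and not np.all(np.diff(self.time) > 0):
            raise TopologyError("frame times must be strictly increasing")
        if len(self.topology) != self.n_atoms:
            raise TopologyError(
                f"topology has {len(self.topology)} atoms, coordinates have {self.n_atoms}"
            )
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise TopologyError(f"topology missing columns {missing}")
        if self.cells is not None:
            self.cells = np.asarray(self.cells, dtype=np.float64)
            if self.cells.shape == (3, 3):  # constant cell broadcast to all frames
                self.cells = np.broadcast_to(self.cells, (self.n_frames, 3, 3)).copy()
            if self.cells.shape != (self.n_frames, 3, 3):
                raise CellError(f"cells must be (frames, 3, 3), got {self.cells.shape}")
            vols = np.linalg.det(self.cells)
            if np.any(vols <= 0):
                raise CellError("every cell must have positive volume")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def cell(self, frame: int) -> UnitCell | None:
        """The unit cell of one frame, or None when no cell data exist."""
        if self.cells is None:
            return None
        return UnitCell(self.cells[frame])

    def slice_frames(self, frames) -> "Trajectory":
        frames = np.asarray(frames, dtype=np.intp)
        return Trajectory(
            xyz=self.xyz[frames],
            time=self.time[frames],
            cells=None if self.cells is None else self.cells[frames],
            topology=self.topology,
        )

    # -- conversion to/from MDTraj -----------------------------------------

    @classmethod
    def from_mdtraj(cls, traj) -> "Trajectory":
        rows = []
        for atom in traj.topology.atoms:
            rows.append(
                (
                    atom.name,
                    atom.element.symbol if atom.element is not None else "",
                    atom.residue.name,
                    atom.residue.index,
                    atom.residue.chain.index,
                )
            )
        topo = pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS)
        time = np.asarray(traj.time, dtype=np.float64)
        if len(time) > 1 and not np.all(np.diff(time) > 0):
            # some writers emit all-zero times; fall back to frame index
            time = np.arange(traj.n_frames, dtype=np.float64)
        return cls(
            xyz=np.asarray(traj.xyz, dtype=np.float64),
            time=time,
            cells=None
            if traj.unitcell_vectors is None
            else np.asarray(traj.unitcell_vectors, dtype=np.float64),
            topology=topo,
        )

    def to_mdtraj(self):
        import mdtraj as md

        top = md.Topology()
        chains: dict[int, object] = {}
        residues: dict[tuple[int, int], object] = {}
        for _, row in self.topology.iterrows():
            ch = chains.setdefault(row["chain"], None) or top.add_chain()
            chains[row["chain"]] = ch
            key = (row["chain"], row["resid"])
            res = residues.get(key)
            if res is None:
                res = top.add_residue(str(row["resname"]), ch, resSeq=int(row["resid"]))
                residues[key] = res
            try:
                elem = md.element.get_by_symbol(str(row["element"]))
            except KeyError:
                elem = md.element.virtual
            top.add_atom(str(row["name"]), elem, res)
        traj = md.Trajectory(
            xyz=self.xyz.astype(np.float32),
            topology=top,
            time=self.time,
        )
        if self.cells is not None:
            traj.unitcell_vectors = self.cells.astype(np.float32)
        return traj

    # -- lossless JSON round-trip ------------------------------------------

    def save_json(self, path) -> None:
        """Write the trajectory as lossless JSON (full float precision)."""
        payload = {
            "xyz": self.xyz.tolist(),
            "time": self.time.tolist(),
            "cells": None if self.cells is None else self.cells.tolist(),
            "topology": {c: self.topology[c].tolist() for c in TOPOLOGY_COLUMNS},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_json(cls, path) -> "Trajectory":
        try:
            payload = json.loads(Path(path).read_text())
            return cls(
                xyz=np.asarray(payload["xyz"], dtype=np.float64),
                time=np.asarray(payload["time"], dtype=np.float64),
                cells=None
                if payload["cells"] is None
                else np.asarray(payload["cells"], dtype=np.float64),
                topology=pd.DataFrame(payload["topology"]),
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"not a valid JSON trajectory: {path}") from exc


def load_trajectory(trajectory_path, topology_path=None, stride: int = 1) -> Trajectory:
    """Load a trajectory file (XTC/TRR/DCD/PDB/GRO or lossless JSON).

    Coordinate-only formats (XTC, TRR, DCD) require ``topology_path`` (PDB
    or GRO).  ``stride`` keeps every stride-th frame, starting at frame 0.
    A constant cell in the topology is broadcast to all retained frames.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(trajectory_path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".json":
        traj = Trajectory.load_json(path)
        if stride > 1:
            traj = traj.slice_frames(np.arange(0, traj.n_frames, stride))
        return traj

    import mdtraj as md

    kwargs = {}
    if topology_path is not None:
        tpath = Path(topology_path)
        if not tpath.exists():
            raise FormatError(f"no such topology file: {tpath}")
        kwargs["top"] = str(tpath)
    try:
        mdt = md.load(str(path), stride=stride, **kwargs)
    except (OSError, IOError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    except ValueError as exc:
        msg = str(exc)
        if "atom" in msg.lower() or "topology" in msg.lower():
            raise TopologyError(f"topology mismatch for {path}: {msg}") from exc
        raise FormatError(f"cannot read {path}: {msg}") from exc
    return Trajectory.from_mdtraj(mdt)


@dataclass(frozen=True)
class ParticleGroups:
    """Named reference (species a) and target (species b) atom-index groups."""

    reference_groups: dict[str, np.ndarray]
    target_groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for kind, groups in (
            ("reference", self.reference_groups),
            ("target", self.target_groups),
        ):
            if not groups:
                raise ValueError(f"at least one {kind} group is required")
            clean = {}
            for name, idx in groups.items():
                arr = np.asarray(idx, dtype=np.intp)
                if arr.size == 0:
                    raise ValueError(f"{kind} group {name!r} is empty")
                if len(np.unique(arr)) != len(arr):
                    raise ValueError(f"{kind} group {name!r} has duplicate indices")
                if np.any(arr < 0):
                    raise ValueError(f"{kind} group {name!r} has negative indices")
                clean[name] = np.sort(arr)
            object.__setattr__(
                self,
                "reference_groups" if kind == "reference" else "target_groups",
                clean,
            )

    def validate_against(self, trajectory: Trajectory) -> None:
        n = trajectory.n_atoms
        for groups in (self.reference_groups, self.target_groups):
            for name, idx in groups.items():
                if idx.max() >= n:
                    raise TopologyError(
                        f"group {name!r} references atom {int(idx.max())} "
                        f"but the trajectory has {n} atoms"
                    )

    @property
    def ref_names(self) -> list[str]:
        return list(self.reference_groups)

    @property
    def target_names(self) -> list[str]:
        return list(self.target_groups)


@dataclass(frozen=True)
class WindowScheme:
    """Contiguous, non-overlapping blocks of frames used as time windows.

    ``stride`` first thins the frame range (keeping every stride-th frame);
    the retained frames are then grouped into blocks of
    ``frames_per_window``.  A trailing block shorter than a full window is
    dropped by default, because a partial window has a different frame
    count in the per-window normalisation and would silently carry a
    different noise level; ``policy="keep-partial"`` keeps it, flagged.
    """

    frames_per_window: int
    stride: int = 1
    policy: str = "drop"

    def __post_init__(self) -> None:
        if self.frames_per_window < 1:
            raise ValueError("frames_per_window must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.policy not in ("drop", "keep-partial"):
            raise ValueError("policy must be 'drop' or 'keep-partial'")


@dataclass(frozen=True)
class Window:
    """One time window: an ordered block of original frame indices."""

    index: int
    frames: np.ndarray
    partial: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def partition_windows(n_frames: int, scheme: WindowScheme) -> list[Window]:
    """Partition a frame range into time windows according to a scheme."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    used = np.arange(0, n_frames, scheme.stride, dtype=np.intp)
    fpw = scheme.frames_per_window
    windows: list[Window] = []
    for w, start in enumerate(range(0, len(used), fpw)):
        block = used[start : start + fpw]
        if len(block) < fpw:
            if scheme.policy == "drop":
                break
            windows.append(Window(index=w, frames=block, partial=True))
        else:
            windows.append(Window(index=w, frames=block, partial=False))
    if not windows:
        msg = (
            f"frames_per_window={fpw} exceeds the {len(used)} available "
            f"(strided) frames; no windows produced"
        )
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return windows


def read_index_file(path) -> np.ndarray:
    """Read a whitespace/comma-separated list of 0-based atom indices."""
    text = Path(path).read_text()
    tokens = text.replace(",", " ").split()
    try:
        idx = np.array([int(t) for t in tokens], dtype=np.intp)
    except ValueError as exc:
        raise FormatError(f"non-integer token in index file {path}") from exc
    return np.unique(idx)
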