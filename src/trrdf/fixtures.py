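"""Synthetic trajectories with analytically known pair statistics.

Every generator returns an in-memory :class:`Trajectory` and is fully
determined by its seed.  The menagerie:

* **ideal gas** — i.i.d. uniform positions each frame; g(r) = 1 exactly
  in expectation at every radius, the canonical null for normalisation.
* **lattices** — frozen simple-cubic or fcc crystals with known
  coordination shells (sc: 6/12/8 at a, a*sqrt(2), a*sqrt(3); fcc: 12 at
  a/sqrt(2)), pinning the running coordination number exactly.
* **two-particle** — one reference at the cell centre, one target at a
  scripted per-frame separation (optionally wrapped across the periodic
  boundary), for closed-form single-bin RDF values and window switching.
* **random-walk ions** — wrapped Gaussian random walks around a frozen
  set of "protein" sites, emulating ions wandering in and out of the
  0.70 nm shell; shell occupancy is countable by brute force.

Generators can be written to disk as GRO (topology + first frame) plus
XTC (all frames) to exercise the binary reader path, or as lossless JSON
for bit-exact round-trips (XTC stores single-precision coordinates,
so its round-trip tolerance is ~1e-3 nm).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CellError
from .trajectory import TOPOLOGY_COLUMNS, Trajectory

__all__ = [
    "generate_ideal_gas",
    "generate_lattice",
    "generate_two_particle",
    "generate_random_walk_ions",
    "generate_frozen",
    "random_reduced_cell",
    "write_gro_xtc",
]


def _as_cell_matrix(cell) -> np.ndarray:
    cell = np.asarray(cell, dtype=np.float64)
    if cell.ndim == 0:
        cell = np.diag(np.full(3, float(cell)))
    elif cell.shape == (3,):
        cell = np.diag(cell)
    if cell.shape != (3, 3):
        raise CellError("cell must be an edge length, 3 edges, or a 3x3 matrix")
    if np.linalg.det(cell) <= 0:
        raise CellError("degenerate cell")
    return cell


def _wrap(xyz: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Wrap cartesian coordinates into the primary cell."""
    frac = xyz @ np.linalg.inv(cell)
    frac -= np.floor(frac)
    return frac @ cell


def _particle_topology(n: int, resname: str = "GAS", name: str = "P", element: str = "Ar"):
    return pd.DataFrame(
        {
            "name": [name] * n,
            "element": [element] * n,
            "resname": [resname] * n,
            "resid": np.arange(n),
            "chain": np.zeros(n, dtype=np.int64),
        },
        columns=TOPOLOGY_COLUMNS,
    )


def generate_ideal_gas(
    n_particles: int,
    n_frames: int,
    cell,
    seed: int,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Uniform i.i.d. particle positions per frame — exact g(r) = 1."""
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    h = _as_cell_matrix(cell)
    rng = np.random.default_rng(seed)
    frac = rng.random((n_frames, n_particles, 3))
    xyz = frac @ h
    return Trajectory(
        xyz=xyz,
        time=np.arange(n_frames) * dt_ps,
        cells=np.broadcast_to(h, (n_frames, 3, 3)).copy(),
        topology=_particle_topology(n_particles),
    )


def generate_lattice(
    kind: str,
    n_cells: int,
    lattice_constant: float = 1.0,
    n_frames: int = 1,
    dt_ps: float = 1.0,
) -> Trajectory:
    """A frozen perfect lattice filling a cubic box of n_cells^3 unit cells.

    kind "sc": one atom per unit cell, first shells at a (6 neighbours),
    a*sqrt(2) (12) and a*sqrt(3) (8).  kind "fcc": four atoms per
    conventional cell, first shell of 12 at a/sqrt(2).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 unit cells per edge for distinct images")
    a = float(lattice_constant)
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    ii, jj, kk = np.meshgrid(*(np.arange(n_cells),) * 3, indexing="ij")
    corners = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64) * a
    if kind == "sc":
        xyz0 = corners
    elif kind == "fcc":
        basis = np.array(
            [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
        ) * a
        xyz0 = (corners[:, np.newaxis, :] + basis[np.newaxis, :, :]).reshape(-1, 3)
    else:
        raise ValueError("kind must be 'sc' or 'fcc'")
    edge = n_cells * a
    h = np.diag([edge, edge, edge])
    xyz = np.broadcast_to(xyz0, (n_frames, len(xyz0), 3)).copy()
    return Trajectory(
        xyz=xyz,
        time=np.arange(n_frames) * dt_ps,
        cells=np.broadcast_to(h, (n_frames, 3, 3)).copy(),
        topology=_particle_topology(len(xyz0), resname="LAT", name="L", element="Ar"),
    )


def generate_two_particle(
    separations,
    cell,
    direction=(1.0, 0.0, 0.0),
    across_boundary: bool = False,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Reference at the cell centre, target at scripted separations.

    ``separations`` is one minimum-image distance per frame, placed along
    ``direction``.  With ``across_boundary`` the reference is moved next
    to a cell face so the pair wraps through the periodic boundary while
    the minimum-image distance still equals the script value.
    """
    h = _as_cell_matrix(cell)
    seps = np.asarray(separations, dtype=np.float64)
    if seps.ndim != 1 or len(seps) == 0:
        raise ValueError("separations must be a non-empty 1-D sequence")
    u = np.asarray(direction, dtype=np.float64)
    u = u / np.linalg.norm(u)
    if across_boundary:
        # reference sits 0.05 nm inside the face the direction points at
        ref = 0.5 * h.sum(axis=0) + (0.5 * np.diag(h).min() - 0.05) * u
    else:
        ref = 0.5 * h.sum(axis=0)
    n_frames = len(seps)
    xyz = np.empty((n_frames, 2, 3))
    for f, s in enumerate(seps):
        xyz[f, 0] = ref
        xyz[f, 1] = _wrap((ref + s * u)[np.newaxis, :], h)[0]
    topo = pd.DataFrame(
        {
            "name": ["REF", "TGT"],
            "element": ["C", "Cl"],
            "resname": ["SIT", "ION"],
            "resid": [0, 1],
            "chain": [0, 0],
        },
        columns=TOPOLOGY_COLUMNS,
    )
    return Trajectory(
        xyz=xyz,
        time=np.arange(n_frames) * dt_ps,
        cells=np.broadcast_to(h, (n_frames, 3, 3)).copy(),
        topology=topo,
    )


def generate_random_walk_ions(
    n_ions: int,
    n_frames: int,
    cell,
    step_nm: float,
    seed: int,
    site_positions=None,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Gaussian-step random-walk ions around frozen single-carbon sites.

    Sites are one-atom residues (name CA, element C, resname GLY) so the
    ion-site machinery applies directly; ions are chloride-like single
    atoms.  ``step_nm`` = 0 freezes the ions.  Starting positions and
    steps are drawn from the seeded generator; all coordinates are kept
    wrapped inside the cell.
    """
    if n_ions < 1:
        raise ValueError("need at least one ion")
    h = _as_cell_matrix(cell)
    rng = np.random.default_rng(seed)
    if site_positions is None:
        site_positions = 0.5 * h.sum(axis=0)[np.newaxis, :]
    sites = np.atleast_2d(np.asarray(site_positions, dtype=np.float64))
    n_sites = len(sites)

    ions = np.empty((n_frames, n_ions, 3))
    pos = _wrap(rng.random((n_ions, 3)) @ h, h)
    for f in range(n_frames):
        ions[f] = pos
        if step_nm > 0:
            pos = _wrap(pos + rng.normal(0.0, step_nm, size=(n_ions, 3)), h)

    xyz = np.concatenate(
        [np.broadcast_to(sites, (n_frames, n_sites, 3)), ions], axis=1
    )
    topo = pd.DataFrame(
        {
            "name": ["CA"] * n_sites + ["CL"] * n_ions,
            "element": ["C"] * n_sites + ["Cl"] * n_ions,
            "resname": ["GLY"] * n_sites + ["CL"] * n_ions,
            "resid": list(range(n_sites)) + list(range(n_sites, n_sites + n_ions)),
            "chain": [0] * (n_sites + n_ions),
        },
        columns=TOPOLOGY_COLUMNS,
    )
    return Trajectory(
        xyz=xyz,
        time=np.arange(n_frames) * dt_ps,
        cells=np.broadcast_to(h, (n_frames, 3, 3)).copy(),
        topology=topo,
    )


def generate_frozen(base: Trajectory, n_frames: int) -> Trajectory:
    """Repeat a trajectory's first frame n_frames times (static dynamics)."""
    return Trajectory(
        xyz=np.broadcast_to(base.xyz[0], (n_frames, base.n_atoms, 3)).copy(),
        time=np.arange(n_frames, dtype=np.float64),
        cells=None
        if base.cells is None
        else np.broadcast_to(base.cells[0], (n_frames, 3, 3)).copy(),
        topology=base.topology,
    )


def random_reduced_cell(rng: np.random.Generator, min_edge: float = 1.0, max_edge: float = 2.0) -> np.ndarray:
    """A random valid reduced triclinic cell matrix (GROMACS bounds)."""
    diag = rng.uniform(min_edge, max_edge, size=3)
    m = np.diag(diag)
    m[1, 0] = rng.uniform(-0.5, 0.5) * diag[0]
    m[2, 0] = rng.uniform(-0.5, 0.5) * diag[0]
    m[2, 1] = rng.uniform(-0.5, 0.5) * diag[1]
    return m


def write_gro_xtc(trajectory: Trajectory, basename) -> tuple[Path, Path]:
    """Write topology+frame0 as GRO and all frames as XTC; returns the paths."""
    base = Path(basename)
    mdt = trajectory.to_mdtraj()
    gro = base.with_suffix(".gro")
    xtc = base.with_suffix(".xtc")
    mdt[0].save_gro(str(gro))
    mdt.save_xtc(str(xtc))
    return gro, xtc
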