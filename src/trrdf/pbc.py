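"""Minimum-image geometry under periodic boundary conditions.

Distances are measured with the minimum-image convention: the reported
separation of two particles is the smallest distance between one particle
and any periodic image of the other.  Cells are general triclinic
parallelepipeds stored in the reduced (GROMACS) convention — first cell
vector along x, second in the xy-plane — which also covers rhombic
dodecahedral boxes in their triclinic representation.

For a reduced cell, converting the separation vector to fractional
coordinates and rounding each component to the nearest integer is not by
itself sufficient for strongly skewed cells; the rounded image is therefore
refined by searching the surrounding 3x3x3 block of neighbour images, which
is exhaustive for reduced cells whenever the distance of interest is below
half the minimal cell width.  Histograms beyond that radius are ambiguous
and are refused upstream (see :func:`half_min_width`).

All lengths are in nm.
"""

from __future__ import annotations

import itertools

import numpy as np

from .errors import CellError

__all__ = [
    "UnitCell",
    "minimum_image_distance",
    "min_image_distance_matrix",
    "pairwise_distance_matrix",
    "DistanceBlock",
    "shell_volume",
    "half_min_width",
]

# the 27 integer image shifts searched around the rounded image
_NEIGHBOR_SHIFTS = np.array(
    list(itertools.product((-1.0, 0.0, 1.0), repeat=3)), dtype=np.float64
)

_ORTHO_TOL = 1e-10


class UnitCell:
    """A triclinic simulation cell in reduced form.

    Parameters
    ----------
    vectors : array-like
        Either a length-3 vector of box edges (interpreted as an
        orthorhombic cell) or a 3x3 matrix whose *rows* are the cell
        vectors in nm.  Cells not already in reduced triclinic form are
        brought into it by lattice-preserving row operations (and, if
        needed, a rigid rotation), which leave all pair distances
        unchanged.
    """

    __slots__ = ("vectors",)

    def __init__(self, vectors) -> None:
        v = np.asarray(vectors, dtype=np.float64)
        if v.shape == (3,):
            v = np.diag(v)
        if v.shape != (3, 3):
            raise CellError(f"cell must be a 3-vector or 3x3 matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise CellError("cell contains non-finite entries")
        det = np.linalg.det(v)
        scale = np.abs(v).max()
        if scale == 0 or abs(det) < 1e-12 * scale**3:
            raise CellError("singular cell (zero volume)")
        v = _reduce_cell(v)
        if np.linalg.det(v) <= 0:
            raise CellError("cell is not right-handed (negative volume)")
        self.vectors = v

    # -- derived quantities -------------------------------------------------

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.vectors))

    @property
    def is_orthorhombic(self) -> bool:
        v = self.vectors
        off = np.abs(v[~np.eye(3, dtype=bool)]).max()
        return off <= _ORTHO_TOL * np.abs(np.diag(v)).max()

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def __repr__(self) -> str:  # pragma: no cover
        kind = "orthorhombic" if self.is_orthorhombic else "triclinic"
        return f"UnitCell({kind}, volume={self.volume:.4g} nm^3)"


def _reduce_cell(v: np.ndarray) -> np.ndarray:
    """Bring a cell-vector matrix into the reduced triclinic form.

    First rotates the lattice so the matrix is lower triangular (a along x,
    b in the xy-plane), then shifts b by multiples of a and c by multiples
    of a and b so that every off-diagonal element is at most half the
    corresponding diagonal.  Both steps preserve the lattice (hence all
    minimum-image distances).
    """
    upper = np.abs(np.triu(v, k=1)).max()
    if upper > _ORTHO_TOL * np.abs(v).max():
        # QR of the transpose yields v = L @ Q with L lower triangular
        q, r = np.linalg.qr(v.T)
        v = r.T @ np.eye(3)
        # enforce positive diagonal (QR sign freedom)
        signs = np.sign(np.diag(v))
        signs[signs == 0] = 1.0
        v = v * signs[np.newaxis, :]
        v = np.tril(v)
    else:
        v = np.tril(v)
    if np.any(np.diag(v) <= 0):
        raise CellError("reduced cell has non-positive diagonal")
    b, c = v[1].copy(), v[2].copy()
    c -= v[1] * np.round(c[1] / v[1, 1])
    c -= v[0] * np.round(c[0] / v[0, 0])
    b -= v[0] * np.round(b[0] / v[0, 0])
    out = np.array([v[0], b, c])
    return out


def half_min_width(cell: UnitCell) -> float:
    """Half the smallest distance between opposite faces of the cell.

    Minimum-image distances are unambiguous only below this radius; the
    histogram engines refuse larger ranges.
    """
    v = cell.vectors
    vol = abs(np.linalg.det(v))
    widths = [
        vol / np.linalg.norm(np.cross(v[(i + 1) % 3], v[(i + 2) % 3]))
        for i in range(3)
    ]
    return 0.5 * min(widths)


def shell_volume(r_inner, r_outer):
    """Volume of the spherical shell between two radii, (4pi/3)(r_o^3 - r_i^3)."""
    r_inner = np.asarray(r_inner, dtype=np.float64)
    r_outer = np.asarray(r_outer, dtype=np.float64)
    if np.any(r_inner < 0) or np.any(r_inner > r_outer):
        raise ValueError("require 0 <= r_inner <= r_outer")
    return (4.0 * np.pi / 3.0) * (r_outer**3 - r_inner**3)


def _min_image_diff_norms(diff: np.ndarray, cell: UnitCell | None) -> np.ndarray:
    """Minimum-image norms of an (..., 3) array of separation vectors."""
    if cell is None:
        return np.linalg.norm(diff, axis=-1)
    h = cell.vectors
    if cell.is_orthorhombic:
        box = np.diag(h)
        diff = diff - box * np.round(diff / box)
        return np.linalg.norm(diff, axis=-1)
    s = diff @ np.linalg.inv(h)
    s -= np.round(s)
    d2_min = None
    for shift in _NEIGHBOR_SHIFTS:
        cart = (s + shift) @ h
        d2 = np.einsum("...i,...i->...", cart, cart)
        d2_min = d2 if d2_min is None else np.minimum(d2_min, d2)
    return np.sqrt(d2_min)


def minimum_image_distance(x1, x2, cell: UnitCell | None) -> float:
    """Minimum-image distance between two points (nm)."""
    diff = np.asarray(x1, dtype=np.float64) - np.asarray(x2, dtype=np.float64)
    return float(_min_image_diff_norms(diff, cell))


def min_image_distance_matrix(
    ref_xyz: np.ndarray,
    tgt_xyz: np.ndarray,
    cell: UnitCell | None,
    chunk_pairs: int = 1 << 21,
) -> np.ndarray:
    """Dense N_ref x N_tgt matrix of minimum-image distances for one frame.

    Reference rows are processed in chunks so memory stays bounded by
    ``chunk_pairs`` separation vectors regardless of group sizes.
    """
    ref_xyz = np.asarray(ref_xyz, dtype=np.float64)
    tgt_xyz = np.asarray(tgt_xyz, dtype=np.float64)
    n_ref, n_tgt = len(ref_xyz), len(tgt_xyz)
    out = np.empty((n_ref, n_tgt), dtype=np.float64)
    rows = max(1, chunk_pairs // max(n_tgt, 1))
    for start in range(0, n_ref, rows):
        stop = min(start + rows, n_ref)
        diff = ref_xyz[start:stop, np.newaxis, :] - tgt_xyz[np.newaxis, :, :]
        out[start:stop] = _min_image_diff_norms(diff, cell)
    return out


class DistanceBlock:
    """Per-frame reference x target minimum-image distance matrix.

    Attributes
    ----------
    values : (N_ref, N_tgt) float array, nm
    frame_index : int
    ref_indices, tgt_indices : atom indices of the two groups, used to flag
        identical-atom pairs for self-exclusion during binning.
    """

    __slots__ = ("values", "frame_index", "ref_indices", "tgt_indices")

    def __init__(self, values, frame_index, ref_indices, tgt_indices) -> None:
        self.values = np.asarray(values, dtype=np.float64)
        self.frame_index = int(frame_index)
        self.ref_indices = np.asarray(ref_indices, dtype=np.intp)
        self.tgt_indices = np.asarray(tgt_indices, dtype=np.intp)

    @property
    def self_pair_mask(self) -> np.ndarray:
        """Boolean (N_ref, N_tgt) mask of identical-atom pairs."""
        return self.ref_indices[:, np.newaxis] == self.tgt_indices[np.newaxis, :]


def pairwise_distance_matrix(trajectory, frame, groups, pair) -> DistanceBlock:
    """Distance matrix for one (reference group, target group) pair at a frame.

    Parameters
    ----------
    trajectory : Trajectory
    frame : int
    groups : ParticleGroups
    pair : (ref_group_name, target_group_name)
    """
    ref_name, tgt_name = pair
    ref = groups.reference_groups[ref_name]
    tgt = groups.target_groups[tgt_name]
    cell = trajectory.cell(frame)
    xyz = trajectory.xyz[frame]
    values = min_image_distance_matrix(xyz[ref], xyz[tgt], cell)
    return DistanceBlock(values, frame, ref, tgt)
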