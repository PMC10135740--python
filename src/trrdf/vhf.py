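"""Distinct-part van Hove correlation function G_d(r, tau).

The distinct van Hove function generalises g(r) in time: it is the
relative density of target particles at distance r from where a reference
particle sat a lag tau earlier.  At tau = 0 it reduces exactly to the RDF
over the origin frames.  The standard (Hansen–McDonald) distinct-part
normalisation is used: per lag, the time-origin-averaged cross histogram
is divided by V_shell(r) * rho_b * N_a * n_origins, so an uncorrelated
(ideal-gas) system gives G_d = 1 at every lag.

Cross-time distances are measured with the minimum-image convention under
the *origin* frame's cell.  In constant-volume simulations this choice is
immaterial; for fluctuating boxes a ``strict_cells`` mode refuses lags
across which any cell entry changes by more than 1%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CellError
from .pbc import DistanceBlock, min_image_distance_matrix
from .rdf import (
    BulkDensity,
    RadialGrid,
    bin_distances,
    check_pbc_range,
    estimate_bulk_density,
)
from .trajectory import ParticleGroups, Trajectory

__all__ = ["VHFResult", "compute_vhf"]


@dataclass
class VHFResult:
    """G_d values, dense over (ref group, target group, lag, bin)."""

    G: np.ndarray  # (R, T, L, B)
    counts: np.ndarray  # (R, T, L, B) int64
    grid: RadialGrid
    lags_frames: np.ndarray
    lags_ps: np.ndarray
    origins_per_lag: np.ndarray
    ref_names: list[str]
    target_names: list[str]


def compute_vhf(
    trajectory: Trajectory,
    groups: ParticleGroups,
    grid: RadialGrid | None = None,
    lags: list[int] | None = None,
    origin_stride: int = 1,
    density: BulkDensity | str = "auto",
    pbc: bool = True,
    strict_cells: bool = False,
) -> VHFResult:
    """Distinct van Hove function for the given frame lags.

    Parameters
    ----------
    lags : list of non-negative frame offsets (default [0, 1]).
    origin_stride : every origin_stride-th frame serves as a time origin.
    strict_cells : error if cells differ by >1% within any lag span.
    """
    grid = grid or RadialGrid()
    lags = [0, 1] if lags is None else [int(l) for l in lags]
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    if any(l < 0 for l in lags):
        raise ValueError("lags must be non-negative")
    if max(lags) >= trajectory.n_frames:
        raise ValueError(
            f"lag {max(lags)} out of range for {trajectory.n_frames} frames"
        )
    groups.validate_against(trajectory)
    if pbc:
        check_pbc_range(trajectory, np.arange(trajectory.n_frames), grid)

    R = len(groups.reference_groups)
    T = len(groups.target_groups)
    L = len(lags)
    B = grid.n_bins
    G = np.zeros((R, T, L, B))
    counts = np.zeros((R, T, L, B), dtype=np.int64)
    origins_per_lag = np.zeros(L, dtype=np.int64)
    lags_ps = np.zeros(L)

    ref_items = list(groups.reference_groups.items())
    tgt_items = list(groups.target_groups.items())
    for li, lag in enumerate(lags):
        origins = np.arange(0, trajectory.n_frames - lag, origin_stride, dtype=np.intp)
        origins_per_lag[li] = len(origins)
        lags_ps[li] = (
            trajectory.time[lag] - trajectory.time[0] if lag < trajectory.n_frames else 0.0
        )
        if strict_cells and trajectory.cells is not None and lag > 0:
            _check_cell_drift(trajectory, origins, lag)
        for j, (tgt_name, tgt_idx) in enumerate(tgt_items):
            if isinstance(density, BulkDensity):
                rho = density
            else:
                rho = estimate_bulk_density(trajectory, origins, len(tgt_idx))
            for i, (ref_name, ref_idx) in enumerate(ref_items):
                c = np.zeros(B, dtype=np.int64)
                for t0 in origins:
                    cell = trajectory.cell(int(t0)) if pbc else None
                    d = min_image_distance_matrix(
                        trajectory.xyz[t0, ref_idx],
                        trajectory.xyz[t0 + lag, tgt_idx],
                        cell,
                    )
                    block = DistanceBlock(d, t0, ref_idx, tgt_idx)
                    # at lag 0 the identical-atom pair is the self part and
                    # is excluded; at lag > 0 the same particle at a later
                    # time is also "self" in the distinct-part sense
                    c += bin_distances(block, grid, exclude_self=True)
                counts[i, j, li] = c
                # dividing by the origin count first keeps a frozen
                # trajectory's G bit-identical across lags
                per_origin = c / len(origins)
                norm = grid.shell_volumes * rho.value * len(ref_idx)
                G[i, j, li] = per_origin / norm

    return VHFResult(
        G=G,
        counts=counts,
        grid=grid,
        lags_frames=np.asarray(lags, dtype=np.int64),
        lags_ps=lags_ps,
        origins_per_lag=origins_per_lag,
        ref_names=[n for n, _ in ref_items],
        target_names=[n for n, _ in tgt_items],
    )


def _check_cell_drift(trajectory: Trajectory, origins: np.ndarray, lag: int) -> None:
    cells = trajectory.cells
    for t0 in origins:
        a, b = cells[t0], cells[t0 + lag]
        scale = np.abs(a).max()
        if np.abs(b - a).max() > 0.01 * scale:
            raise CellError(
                f"cells differ by >1% between frames {int(t0)} and {int(t0) + lag}; "
                "refusing cross-time minimum image in strict mode"
            )
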