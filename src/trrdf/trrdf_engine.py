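"""Time-resolved RDFs and running coordination numbers.

A TRRDF is an RDF computed separately over consecutive, user-defined
blocks of frames ("time windows"), so that transient structure — an ion
dwelling near a binding site for a few tens of ps — is not washed out by
averaging over the whole trajectory.  For window W with N_W frames,

    g_ab(r, W) = counts_W(r) / ( V_shell(r) * rho_b * N_a * N_W ),

i.e. exactly the whole-trajectory estimator restricted to the window's
frames.  In auto-density mode each window uses its own mean cell volume,
so constant-pressure volume fluctuations do not couple the windows.

The running coordination number integrates the pair histogram,

    n_ab(r, W) = cumsum_k<=r counts_W(k) / ( N_a * N_W ),

which requires no bulk density at all and is therefore the primary
product for dilute species in fluctuating boxes.  For dilute targets n is
typically fractional and reads as the likelihood of finding a target
within radius r of a reference during the window.  The same quantity is
recoverable from g by multiplying back the shell volumes and density;
both routes agree to rounding and are cross-checked in the test suite.

Windows are processed one at a time and pair by pair: the full
frames x pairs distance tensor is never resident in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rdf import (
    BulkDensity,
    RadialGrid,
    RDFProfile,
    check_pbc_range,
    estimate_bulk_density,
    _accumulate_counts,
)
from .trajectory import ParticleGroups, Trajectory, Window, WindowScheme, partition_windows

__all__ = [
    "TRRDFResult",
    "CoordinationProfile",
    "compute_trrdf",
    "running_coordination",
    "window_average_rdf",
]


@dataclass
class TRRDFResult:
    """Windowed RDFs, dense over (ref group, target group, window, bin).

    ``densities[j, w]`` is the bulk density of target group j used in
    window w; ``counts`` are raw pair counts so coordination numbers can be
    derived without re-reading the trajectory.
    """

    g: np.ndarray  # (R, T, W, B)
    counts: np.ndarray  # (R, T, W, B) int64
    grid: RadialGrid
    windows: list[Window]
    ref_names: list[str]
    target_names: list[str]
    ref_sizes: np.ndarray
    target_sizes: np.ndarray
    densities: np.ndarray  # (T, W)
    window_start_ps: np.ndarray
    density_source: str

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def to_dataframe(self):
        """Long-format table: one row per (ref, target, window, bin)."""
        import pandas as pd

        R, T, W, B = self.g.shape
        ref = np.repeat(self.ref_names, T * W * B)
        tgt = np.tile(np.repeat(self.target_names, W * B), R)
        win = np.tile(np.repeat(np.arange(W), B), R * T)
        centers = np.tile(self.grid.centers, R * T * W)
        return pd.DataFrame(
            {
                "ref_group": ref,
                "target_group": tgt,
                "window": win,
                "window_start_ps": np.tile(
                    np.repeat(self.window_start_ps, B), R * T
                ),
                "bin_center_nm": centers,
                "g": self.g.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class CoordinationProfile:
    """Running coordination numbers n(r, W) on the TRRDF layout.

    ``n[i, j, w, k]`` is the mean number of target-j particles within the
    outer edge of bin k of a reference-i particle during window w;
    non-decreasing in k, fractional values read as occupancy likelihood.
    """

    n: np.ndarray  # (R, T, W, B)
    grid: RadialGrid
    windows: list[Window]
    ref_names: list[str]
    target_names: list[str]

    def at_cutoff(self, cutoff: float) -> np.ndarray:
        """n(cutoff, W) for all groups/windows: value at the last bin whose
        outer edge is <= cutoff."""
        return self.n[..., self.grid.cutoff_bin(cutoff)]


def compute_trrdf(
    trajectory: Trajectory,
    groups: ParticleGroups,
    grid: RadialGrid | None = None,
    scheme: WindowScheme | None = None,
    density: BulkDensity | str = "auto",
    pbc: bool = True,
) -> TRRDFResult:
    """Windowed RDF over all (reference x target x window) combinations."""
    grid = grid or RadialGrid()
    scheme = scheme or WindowScheme(frames_per_window=trajectory.n_frames)
    groups.validate_against(trajectory)
    windows = partition_windows(trajectory.n_frames, scheme)
    all_frames = (
        np.concatenate([w.frames for w in windows]) if windows else np.array([], dtype=np.intp)
    )
    if pbc and len(all_frames):
        check_pbc_range(trajectory, all_frames, grid)

    R = len(groups.reference_groups)
    T = len(groups.target_groups)
    W = len(windows)
    B = grid.n_bins
    g = np.zeros((R, T, W, B))
    counts = np.zeros((R, T, W, B), dtype=np.int64)
    densities = np.zeros((T, W))

    ref_items = list(groups.reference_groups.items())
    tgt_items = list(groups.target_groups.items())
    for w, window in enumerate(windows):
        for j, (tgt_name, tgt_idx) in enumerate(tgt_items):
            if isinstance(density, BulkDensity):
                rho = density
            else:
                rho = estimate_bulk_density(trajectory, window.frames, len(tgt_idx))
            densities[j, w] = rho.value
            for i, (ref_name, ref_idx) in enumerate(ref_items):
                c, _ = _accumulate_counts(
                    trajectory, window.frames, ref_idx, tgt_idx, grid, pbc
                )
                counts[i, j, w] = c
                norm = grid.shell_volumes * rho.value * len(ref_idx) * window.n_frames
                g[i, j, w] = c / norm

    return TRRDFResult(
        g=g,
        counts=counts,
        grid=grid,
        windows=windows,
        ref_names=[n for n, _ in ref_items],
        target_names=[n for n, _ in tgt_items],
        ref_sizes=np.array([len(ix) for _, ix in ref_items]),
        target_sizes=np.array([len(ix) for _, ix in tgt_items]),
        densities=densities,
        window_start_ps=np.array(
            [trajectory.time[w_.frames[0]] for w_ in windows]
        ),
        density_source=(
            density.source if isinstance(density, BulkDensity) else "estimated-from-box"
        ),
    )


def running_coordination(
    result: TRRDFResult | RDFProfile, mode: str = "from-counts"
) -> CoordinationProfile:
    """Running coordination numbers from a TRRDF result (or a plain RDF).

    mode "from-counts" (default): n = cumulative pair count / (N_a * N_W),
    no bulk density involved.  mode "from-g": n = rho * cumsum(g * V_shell),
    the density-based route; the two agree to rounding and the second is
    retained for cross-checking.
    """
    if isinstance(result, RDFProfile):
        pseudo = _profile_as_result(result)
        return running_coordination(pseudo, mode=mode)
    if mode == "from-counts":
        if result.counts is None:
            raise ValueError("raw counts absent from result; cannot form n(r)")
        nw = np.array([w.n_frames for w in result.windows], dtype=np.float64)
        denom = (
            result.ref_sizes[:, None, None, None] * nw[None, None, :, None]
        )
        n = np.cumsum(result.counts, axis=-1) / denom
    elif mode == "from-g":
        integrand = result.g * result.grid.shell_volumes
        n = np.cumsum(integrand, axis=-1) * result.densities[None, :, :, None]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoordinationProfile(
        n=n,
        grid=result.grid,
        windows=result.windows,
        ref_names=result.ref_names,
        target_names=result.target_names,
    )


def _profile_as_result(profile: RDFProfile) -> TRRDFResult:
    """View a whole-trajectory RDF as a single-window TRRDF result."""
    window = Window(index=0, frames=np.arange(profile.n_frames, dtype=np.intp))
    return TRRDFResult(
        g=profile.g[None, None, None, :],
        counts=profile.counts[None, None, None, :],
        grid=profile.grid,
        windows=[window],
        ref_names=[profile.ref_group],
        target_names=[profile.target_group],
        ref_sizes=np.array([profile.n_ref]),
        target_sizes=np.array([profile.n_target]),
        densities=np.array([[profile.density.value]]),
        window_start_ps=np.array([0.0]),
        density_source=profile.density.source,
    )


def window_average_rdf(result: TRRDFResult) -> dict[tuple[str, str], RDFProfile]:
    """Unweighted mean of g over windows, per (reference, target) pair.

    With a constant cell and equal-size windows tiling all frames this is
    bin-for-bin identical to the whole-trajectory RDF.
    """
    if result.n_windows < 1:
        raise ValueError("result has no windows")
    out: dict[tuple[str, str], RDFProfile] = {}
    total_frames = int(sum(w.n_frames for w in result.windows))
    for i, ref in enumerate(result.ref_names):
        for j, tgt in enumerate(result.target_names):
            g_mean = result.g[i, j].mean(axis=0)
            out[(ref, tgt)] = RDFProfile(
                g=g_mean,
                counts=result.counts[i, j].sum(axis=0),
                grid=result.grid,
                ref_group=ref,
                target_group=tgt,
                n_ref=int(result.ref_sizes[i]),
                n_target=int(result.target_sizes[j]),
                n_frames=total_frames,
                density=BulkDensity(
                    value=float(result.densities[j].mean()),
                    source=result.density_source,
                ),
            )
    return out
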