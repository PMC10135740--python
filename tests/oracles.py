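"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's optimized code paths: distances by
exhaustive enumeration over a large block of periodic images, histograms
by per-pair loop classification.  They are slow and only ever run on tiny
fixtures.
"""

import itertools

import numpy as np


def brute_min_image(x1, x2, cell_matrix, n_images: int = 2) -> float:
    """Minimum distance over the (2n+1)^3 block of periodic images."""
    shifts = np.array(
        list(itertools.product(range(-n_images, n_images + 1), repeat=3)), dtype=float
    )
    images = np.asarray(x2) + shifts @ np.asarray(cell_matrix)
    return float(np.min(np.linalg.norm(np.asarray(x1) - images, axis=1)))


def brute_distance_matrix(ref_xyz, tgt_xyz, cell_matrix, n_images: int = 2) -> np.ndarray:
    out = np.empty((len(ref_xyz), len(tgt_xyz)))
    for i, a in enumerate(ref_xyz):
        for j, b in enumerate(tgt_xyz):
            out[i, j] = brute_min_image(a, b, cell_matrix, n_images)
    return out


def brute_histogram(distances, edges) -> np.ndarray:
    """Loop classification with half-open bins [lo, hi)."""
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for d in np.ravel(distances):
        for k in range(len(edges) - 1):
            if edges[k] <= d < edges[k + 1]:
                counts[k] += 1
                break
    return counts


def brute_window_counts(traj, ref_idx, tgt_idx, frames, edges, n_images: int = 2):
    """Per-window histogram of minimum-image distances, self pairs excluded."""
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for f in frames:
        d = brute_distance_matrix(
            traj.xyz[f][ref_idx], traj.xyz[f][tgt_idx], traj.cells[f], n_images
        )
        keep = np.asarray(ref_idx)[:, None] != np.asarray(tgt_idx)[None, :]
        counts += brute_histogram(d[keep], edges)
    return counts


def brute_shell_occupancy(traj, site_idx, ion_idx, frames, cutoff, n_images: int = 2):
    """Number of (site, ion) pairs within the cutoff, summed over frames."""
    total = 0
    for f in frames:
        d = brute_distance_matrix(
            traj.xyz[f][site_idx], traj.xyz[f][ion_idx], traj.cells[f], n_images
        )
        total += int(np.sum(d < cutoff))
    return total
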