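"""Result writers: tidy CSV and an HDF5 array container.

HDF5 layout for windowed results::

    /g                (ref, target, window, bin)
    /counts           (ref, target, window, bin)
    /n                (ref, target, window, bin)   when coordination given
    /bin_centers      (bin,)                        nm
    /window_start_ps  (window,)
    /meta             attrs: group names, grid parameters, density mode

Van Hove results use the same layout with /lags_ps and /lags_frames in
place of the window metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .rdf import RDFProfile
from .trrdf_engine import CoordinationProfile, TRRDFResult
from .vhf import VHFResult

__all__ = ["write_rdf_csv", "write_trrdf_h5", "write_trrdf_csv", "write_vhf_h5"]


def write_rdf_csv(profiles: dict[tuple[str, str], RDFProfile], path) -> Path:
    """Tidy CSV: ref_group, target_group, bin_center_nm, g, count."""
    frames = [p.to_dataframe() for p in profiles.values()]
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _write_meta(h5: h5py.File, result, extra: dict) -> None:
    meta = h5.create_group("meta")
    meta.attrs["ref_groups"] = json.dumps(result.ref_names)
    meta.attrs["target_groups"] = json.dumps(result.target_names)
    meta.attrs["r_min_nm"] = result.grid.r_min
    meta.attrs["r_max_nm"] = result.grid.r_max
    meta.attrs["n_bins"] = result.grid.n_bins
    for key, val in extra.items():
        meta.attrs[key] = val


def write_trrdf_h5(
    result: TRRDFResult, path, coordination: CoordinationProfile | None = None
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("g", data=result.g)
        h5.create_dataset("counts", data=result.counts)
        if coordination is not None:
            h5.create_dataset("n", data=coordination.n)
        h5.create_dataset("bin_centers", data=result.grid.centers)
        h5.create_dataset("window_start_ps", data=result.window_start_ps)
        h5.create_dataset(
            "window_n_frames", data=np.array([w.n_frames for w in result.windows])
        )
        h5.create_dataset("densities", data=result.densities)
        _write_meta(h5, result, {"density_source": result.density_source})
    return path


def write_trrdf_csv(result: TRRDFResult, path) -> Path:
    path = Path(path)
    result.to_dataframe().to_csv(path, index=False)
    return path


def write_vhf_h5(result: VHFResult, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("g", data=result.G)
        h5.create_dataset("counts", data=result.counts)
        h5.create_dataset("bin_centers", data=result.grid.centers)
        h5.create_dataset("lags_ps", data=result.lags_ps)
        h5.create_dataset("lags_frames", data=result.lags_frames)
        h5.create_dataset("origins_per_lag", data=result.origins_per_lag)
        _write_meta(h5, result, {})
    return path
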