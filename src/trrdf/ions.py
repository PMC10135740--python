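"""Protein-facing conventions for ion–residue interaction analysis.

This module turns the generic windowed pair-correlation machinery into
per-residue ion statistics:

* the Bjerrum length — the distance at which two unit charges interact
  with thermal energy k_B T, about 0.70 nm in water at 300 K — as the
  default cutoff for comparing local ion distributions;
* one carbon "site" atom per residue (two heavy-atom bonds from the
  residue's donor/acceptor), each becoming a TRRDF reference group;
* mean ion counts per residue, read from the running coordination number
  at the cutoff and averaged over time windows, optionally grouped by
  externally supplied conformational-cluster labels;
* residue–residue mean-distance maps with a 0.5 nm contact criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import constants

from .errors import MappingError
from .pbc import min_image_distance_matrix
from .trajectory import Trajectory, Window
from .trrdf_engine import CoordinationProfile

__all__ = [
    "bjerrum_length",
    "IonSiteTable",
    "load_ion_site_table",
    "default_ion_sites",
    "residue_site_groups",
    "per_residue_ion_counts",
    "ClusterAssignment",
    "assign_windows_to_clusters",
    "residue_distance_map",
]

log = logging.getLogger(__name__)

DEFAULT_ION_CUTOFF_NM = 0.70
DEFAULT_CONTACT_CUTOFF_NM = 0.5


def bjerrum_length(temperature: float = 300.0, relative_permittivity: float = 80.0) -> float:
    """Bjerrum length lambda_B = e^2 / (4 pi eps0 eps_r k_B T), in nm.

    At 300 K in water (eps_r ~ 80) this is ~0.70 nm, a physically
    meaningful radius at which to compare ion distributions: closer than
    lambda_B, the ion–site electrostatic interaction exceeds thermal
    energy.  Scales as 1/T and 1/eps_r.
    """
    if temperature <= 0 or relative_permittivity <= 0:
        raise ValueError("temperature and relative permittivity must be positive")
    lam_m = constants.elementary_charge**2 / (
        4.0
        * np.pi
        * constants.epsilon_0
        * relative_permittivity
        * constants.Boltzmann
        * temperature
    )
    return lam_m * 1e9


@dataclass(frozen=True)
class IonSiteTable:
    """Residue-name -> designated carbon site atom names."""

    sites: dict[str, tuple[str, ...]]
    provenance: str = "default"  # or "user"


def load_ion_site_table(path=None) -> IonSiteTable:
    """Load the packaged default site table, or a user file of the same layout.

    Layout: tab-separated, ``resname<TAB>site_atoms<TAB>anchor`` with
    space-separated atom names in the second column; '#' starts a comment.
    """
    if path is None:
        text = (resources.files("trrdf") / "data" / "ion_sites.tsv").read_text()
        provenance = "default"
    else:
        text = Path(path).read_text()
        provenance = "user"
    sites: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        sites[parts[0]] = tuple(parts[1].split())
    return IonSiteTable(sites=sites, provenance=provenance)


def default_ion_sites(
    topology: pd.DataFrame, table: IonSiteTable | None = None
) -> tuple[dict[int, np.ndarray], IonSiteTable]:
    """Resolve one carbon-site index set per residue.

    Residues missing from the table fall back to the alpha-carbon (logged);
    residues containing no carbon at all are skipped with a warning.
    Returns (resid -> atom indices, table used).
    """
    table = table or load_ion_site_table()
    out: dict[int, np.ndarray] = {}
    for resid, res in topology.groupby("resid"):
        resname = res["resname"].iloc[0]
        wanted = table.sites.get(resname)
        if wanted is None:
            wanted = ("CA",)
            log.warning(
                "residue %s%d not in ion-site table; falling back to alpha-carbon",
                resname,
                resid,
            )
        sel = res[res["name"].isin(wanted)]
        # keep only genuine carbons; a mis-typed table entry must not
        # silently shift the analysis onto a heteroatom
        sel = sel[sel["element"].str.upper().isin(["C", ""])]
        if sel.empty:
            carbons = res[res["element"].str.upper() == "C"]
            if carbons.empty:
                log.warning("residue %s%d has no carbon atoms; skipped", resname, resid)
                continue
            ca = carbons[carbons["name"] == "CA"]
            sel = ca if not ca.empty else carbons.iloc[:1]
            log.warning(
                "residue %s%d lacks site atoms %s; using %s",
                resname,
                resid,
                wanted,
                list(sel["name"]),
            )
        out[int(resid)] = sel.index.to_numpy(dtype=np.intp)
    return out, table


def residue_site_groups(
    topology: pd.DataFrame, table: IonSiteTable | None = None
) -> dict[str, np.ndarray]:
    """Ion sites as named reference groups ("res<resid>") for the TRRDF engine."""
    sites, _ = default_ion_sites(topology, table)
    return {f"res{resid}": idx for resid, idx in sites.items()}


def per_residue_ion_counts(
    coord: CoordinationProfile,
    sites: dict[int, str] | None = None,
    cutoff: float = DEFAULT_ION_CUTOFF_NM,
    clusters: "ClusterAssignment | None" = None,
) -> pd.DataFrame:
    """Mean ion count within ``cutoff`` of each residue site.

    Reads n(cutoff, W) from the coordination profile (last bin whose outer
    edge is <= cutoff) and averages over windows — per cluster when an
    assignment is given, with unassigned windows reported under cluster -1.

    Parameters
    ----------
    sites : optional resid -> reference-group-name mapping; by default
        group names of the form "res<resid>" are parsed back to residues.

    Returns a tidy DataFrame: resid, species, cluster, mean_count, n_windows.
    """
    if sites is None:
        sites = {}
        for name in coord.ref_names:
            if name.startswith("res") and name[3:].lstrip("-").isdigit():
                sites[int(name[3:])] = name
            else:
                raise ValueError(
                    f"cannot infer residue id from group name {name!r}; "
                    "pass an explicit sites mapping"
                )
    name_to_row = {name: i for i, name in enumerate(coord.ref_names)}
    values = coord.at_cutoff(cutoff)  # (R, T, W)
    n_windows = values.shape[2]

    if clusters is None:
        labels = np.zeros(n_windows, dtype=np.int64)
        label_set = [None]
    else:
        labels = np.array(
            [-1 if l is None else int(l) for l in clusters.labels], dtype=np.int64
        )
        if len(labels) != n_windows:
            raise MappingError(
                f"{len(labels)} cluster labels for {n_windows} windows"
            )
        label_set = sorted(set(labels.tolist()))

    rows = []
    for resid, gname in sorted(sites.items()):
        i = name_to_row[gname]
        for j, species in enumerate(coord.target_names):
            for lab in label_set:
                if lab is None:
                    mask = np.ones(n_windows, dtype=bool)
                    out_label = "all"
                else:
                    mask = labels == lab
                    out_label = lab
                if not mask.any():
                    continue
                rows.append(
                    {
                        "resid": resid,
                        "species": species,
                        "cluster": out_label,
                        "mean_count": float(values[i, j, mask].mean()),
                        "n_windows": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-window conformational-cluster labels; None = unassigned."""

    labels: tuple

    @property
    def n_assigned(self) -> int:
        return sum(1 for l in self.labels if l is not None)


def assign_windows_to_clusters(
    windows: list[Window],
    frame_labels,
    label_frames=None,
) -> ClusterAssignment:
    """Assign each time window the majority cluster label of its frames.

    ``frame_labels`` are per-frame integer labels.  By default label k
    belongs to trajectory frame k; when the labels come from a different
    (e.g. coarser-sampled) trajectory, ``label_frames`` gives the
    trajectory frame index of each label.  Ties resolve to unassigned.
    """
    frame_labels = np.asarray(frame_labels, dtype=np.int64)
    if label_frames is None:
        label_frames = np.arange(len(frame_labels), dtype=np.intp)
    else:
        label_frames = np.asarray(label_frames, dtype=np.intp)
        if len(label_frames) != len(frame_labels):
            raise MappingError("label_frames and frame_labels lengths differ")
    lookup = dict(zip(label_frames.tolist(), frame_labels.tolist()))

    out = []
    any_overlap = False
    for window in windows:
        labs = [lookup[f] for f in window.frames.tolist() if f in lookup]
        if not labs:
            out.append(None)
            continue
        any_overlap = True
        vals, cnts = np.unique(labs, return_counts=True)
        top = cnts.max()
        winners = vals[cnts == top]
        out.append(int(winners[0]) if len(winners) == 1 else None)
    if windows and not any_overlap:
        raise MappingError("cluster labels have no temporal overlap with the windows")
    return ClusterAssignment(labels=tuple(out))


def residue_distance_map(
    trajectory: Trajectory,
    frames=None,
    residue_reps: dict[int, int] | None = None,
    mode: str = "representative",
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    pbc: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean inter-residue distance matrix and contact mask.

    mode "representative" (default) measures between one representative
    atom per residue — the alpha-carbon unless ``residue_reps`` overrides
    it; mode "min" takes the per-frame minimum over all atom pairs of the
    two residues.  A contact is a mean distance <= ``contact_cutoff``
    (default 0.5 nm).

    Returns (mean_distances, contact_mask, resids), matrices symmetric
    with zero diagonal, ordered by residue index.
    """
    topo = trajectory.topology
    if frames is None:
        frames = np.arange(trajectory.n_frames, dtype=np.intp)
    else:
        frames = np.asarray(frames, dtype=np.intp)
    if frames.size == 0:
        raise ValueError("need at least one frame")

    resids = np.array(sorted(topo["resid"].unique()), dtype=np.int64)
    if mode == "representative":
        reps = dict(residue_reps) if residue_reps else {}
        for resid in resids:
            if int(resid) in reps:
                continue
            res = topo[topo["resid"] == resid]
            ca = res[res["name"] == "CA"]
            reps[int(resid)] = int(ca.index[0] if not ca.empty else res.index[0])
        rep_idx = np.array([reps[int(r)] for r in resids], dtype=np.intp)
        acc = np.zeros((len(resids), len(resids)))
        for f in frames:
            cell = trajectory.cell(int(f)) if pbc else None
            xyz = trajectory.xyz[f, rep_idx]
            acc += min_image_distance_matrix(xyz, xyz, cell)
        mean = acc / len(frames)
    elif mode == "min":
        atom_groups = [
            topo.index[topo["resid"] == resid].to_numpy(dtype=np.intp) for resid in resids
        ]
        acc = np.zeros((len(resids), len(resids)))
        for f in frames:
            cell = trajectory.cell(int(f)) if pbc else None
            all_idx = np.concatenate(atom_groups)
            d = min_image_distance_matrix(
                trajectory.xyz[f, all_idx], trajectory.xyz[f, all_idx], cell
            )
            offs = np.cumsum([0] + [len(g) for g in atom_groups])
            for a in range(len(resids)):
                for b in range(len(resids)):
                    blockd = d[offs[a] : offs[a + 1], offs[b] : offs[b + 1]]
                    acc[a, b] += blockd.min()
        mean = acc / len(frames)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    np.fill_diagonal(mean, 0.0)
    mean = 0.5 * (mean + mean.T)
    contact = mean <= contact_cutoff
    np.fill_diagonal(contact, False)
    return mean, contact, resids
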