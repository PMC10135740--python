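# trrdf

Time-resolved radial distribution functions, running coordination numbers
and van Hove functions for molecular-dynamics trajectories, with the
analysis conventions needed to profile ion distributions around
biomolecules — in particular intrinsically disordered proteins, whose
transient conformational states are invisible in whole-trajectory
averages.

## The problem

The radial distribution function

```
g_ab(r) = 1 / (V(r) ρ_b N_a N_frames) · Σ_t Σ_{i∈a} Σ_{j∈b} δ_bin(r − r_ij(t))
```

measures the density of target particles *b* at distance *r* from
reference particles *a*, relative to the bulk density ρ_b, with
V(r) = (4π/3)(r_out³ − r_in³) the radial shell volume.  Averaged over a
whole trajectory it erases temporal structure: an ion that stabilises a
transient loop for 50 ps leaves no trace.  The **time-resolved RDF
(TRRDF)** computes the same estimator separately over consecutive,
user-defined windows of N_W frames,

```
g_ab(r, W) = 1 / (V(r) ρ_b N_a N_W) · Σ_{t∈W} Σ_{i∈a} Σ_{j∈b} δ_bin(r − r_ij(t))
```

and its cumulative integral, the **running coordination number**

```
n_ab(r, W) = Σ_{bins ≤ r} counts_W / (N_a N_W)
```

needs no bulk density at all, so it remains well defined for dilute
species in fluctuating (NPT) boxes.  For ions, fractional values of
n(r, W) read as the likelihood of finding an ion within *r* of a site
during the window.  The package compares local ion distributions at the
Bjerrum length (≈0.70 nm at 300 K in water, where the ion–site
electrostatic energy crosses k_B T), designates one carbon atom per
residue (two heavy-atom bonds from the residue's donor/acceptor) as its
ion-interaction site, aggregates windows by externally supplied
conformational-cluster labels, and builds residue contact maps
(mean distance ≤ 0.5 nm).

All distances use the minimum-image convention under arbitrary triclinic
cells (rhombic-dodecahedral boxes in their triclinic representation
included); histograms are refused beyond half the minimal cell width,
where minimum images become ambiguous.  A distinct-part van Hove function
G_d(r, τ) — the time-lagged generalisation of g(r) — is included.

## Worked example

Everything below is synthetic: a frozen "protein" site with chloride-like
random-walk ions around it, generated by the built-in fixtures module.

```python
import numpy as np
from trrdf import (ParticleGroups, RadialGrid, WindowScheme, compute_trrdf,
                   running_coordination, resolve_selection, residue_site_groups,
                   per_residue_ion_counts, bjerrum_length)
from trrdf.fixtures import generate_random_walk_ions

print("Bjerrum length at 300 K, eps_r=80: %.2f nm" % bjerrum_length(300.0, 80.0))

traj = generate_random_walk_ions(n_ions=8, n_frames=200, cell=3.0,
                                 step_nm=0.08, seed=11)
groups = ParticleGroups(
    reference_groups=residue_site_groups(traj.topology),
    target_groups={"CL": resolve_selection(traj, "name CL")},
)
grid = RadialGrid(r_min=0.0, r_max=1.4, n_bins=280)
result = compute_trrdf(traj, groups, grid, WindowScheme(frames_per_window=50))
coord = running_coordination(result)
profile = per_residue_ion_counts(coord, cutoff=0.70)
print(profile)
print()
print("n(0.70 nm, W) per window:", np.round(coord.at_cutoff(0.70)[0, 0], 3))
```

prints

```
Bjerrum length at 300 K, eps_r=80: 0.70 nm
   resid species cluster  mean_count  n_windows
0      0      CL     all       0.245      4

n(0.70 nm, W) per window: [0.26 0.   0.56 0.16]
```

Read: over the four 50-frame windows the site had on average 0.245
chloride ions inside its 0.70 nm shell, but the per-window values swing
from 0 to 0.56 — exactly the transient occupancy structure that a single
whole-trajectory g(r) would flatten into one number.

The same analyses are available from the shell:

```bash
trrdf fixtures random-walk --seed 11 --out sys        # writes sys.gro + sys.xtc
trrdf trrdf --traj sys.xtc --top sys.gro \
      --ref "name CA" --target "name CL" \
      --window-frames 50 --r-max 1.4 --n-bins 280 --out result
trrdf sites --traj sys.xtc --top sys.gro --ions "name CL" \
      --window-frames 50 --r-max 1.4 --n-bins 280 --out ions
```

`result.h5` holds `/g[ref,target,window,bin]`, `/n[...]`, `/counts`,
`/bin_centers` and window metadata; `result.csv` the same in long form.

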