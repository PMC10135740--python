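# Methods

## Estimators

**RDF.** For reference group *a* (N_a atoms), target group *b* (N_b
atoms) and a uniform radial grid with half-open bins [r_k, r_{k+1}),
the whole-trajectory estimator is

    g_ab(k) = C(k) / ( V(k) · ρ_b · N_a · N_frames ),

where C(k) is the number of ordered (i, j) pairs whose minimum-image
distance falls in bin k, accumulated over frames, and
V(k) = (4π/3)(r_{k+1}³ − r_k³).  When the same atom index appears in
both groups, only the identical-index pair is excluded per frame; other
pairs within the same residue are physical and retained — removing more
would bias ion–site profiles.  A distance exactly equal to r_max is not
counted: a literal "within dr of the bin centre" reading would
double-count bin edges, so the standard half-open histogram convention
is used throughout.

**TRRDF.** The identical estimator restricted to one time window W of
N_W frames, normalised by N_W in place of N_frames.  Windows are
contiguous, non-overlapping blocks of the (optionally strided) frame
range.  A trailing block shorter than N_W is dropped by default: a
partial window changes the normalisation's frame count and silently
carries a different noise level (keep-partial mode retains it, flagged).
The unweighted mean of g(·, W) over equal-size windows tiling all frames
reproduces the whole-trajectory RDF bin-for-bin (asserted to 1e-10 in
the tests).

**Bulk density.** ρ_b is not operationally defined by the estimator
itself; the default is N_b over the mean cell volume of the frames in
scope, recomputed per window so that constant-pressure volume
fluctuations do not couple windows.  A user-supplied density overrides
this for cross-simulation comparability.  Numerical detail: when all
frame volumes in scope are bit-identical the volume is taken directly
rather than via the accumulating mean, so windows or lags of different
lengths over a constant cell receive bit-identical normalisations.

**Running coordination number.** The primary form is density-free:

    n_ab(r, W) = Σ_{k: r_{k+1} ≤ r} C_W(k) / ( N_a · N_W ),

i.e. the mean number of b-particles within r of an a-particle during the
window; for dilute targets it is fractional and reads as an occupancy
likelihood.  The equivalent density-based route
n = ρ_b · Σ g(k) V(k) is retained purely as a cross-check; the two agree
to rounding (tested at 1e-9).

**Van Hove function (distinct part).** For lag τ, the histogram of
minimum-image distances between reference positions at origin t₀ and
target positions at t₀ + τ, averaged over origins (every
origin_stride-th frame) and normalised per origin like the RDF, so
G_d(r, 0) is exactly the RDF over the origin frames and an uncorrelated
system gives G_d = 1 at every lag.  Two conventions had to be fixed
because no printed formula constrains them: (1) the standard
distinct-part normalisation (Hansen–McDonald) is adopted; (2) a
cross-time distance is measured under the **origin** frame's cell — in
NVT the choice is immaterial, and a strict mode refuses lags across
which any cell entry changes by more than 1%.  The self part (same
particle tracked over time) is out of scope; identical-index pairs are
excluded at every lag.

## Periodic geometry

Cells are stored row-wise in the reduced triclinic (GROMACS) form —
first vector along x, second in the xy-plane, off-diagonals at most half
the corresponding diagonal.  Arbitrary cell matrices are brought into
this form by a rigid rotation (QR) plus lattice-preserving row shifts;
both leave all pair distances unchanged.  Rhombic-dodecahedral boxes are
handled in their triclinic representation; there is no native
dodecahedron code path.

Minimum-image distances convert the separation to fractional
coordinates, round, and then search the 3×3×3 block of neighbouring
images of the rounded shift: rounding alone is not exhaustive for
strongly skewed (e.g. dodecahedral) cells, while 27 images are
sufficient for reduced cells at distances below half the minimal cell
width.  The engines refuse any r_max beyond that radius (half the
smallest face-to-face distance over all frames in scope), where
minimum-image histograms become ambiguous.  An exhaustive 125-image
search exists only as a test oracle.  Orthorhombic cells take a direct
component-wise wrap; the two paths agree to 1e-12 on orthorhombic input
(tested).  Distance matrices are computed frame by frame and pair by
pair with chunked separation buffers: the full frames × pairs tensor is
never resident.

## Ion–residue conventions

* **Cutoff.** λ_B = e²/(4π ε₀ ε_r k_B T) with CODATA constants
  (scipy.constants); 0.6963 nm ≈ 0.70 nm at 300 K, ε_r = 80.  The
  per-residue profile value is n(cutoff, W) read at the last bin whose
  outer edge is ≤ cutoff, averaged over windows (optionally per
  cluster); cluster-wise profiles, weighted by window counts, recover
  the unconditional profile exactly.
* **Sites.** One carbon per residue, two heavy-atom bonds from the
  residue's principal donor/acceptor (e.g. Lys→CD from NZ, Asp→CB from
  the carboxylate, Tyr→CZ from OH); residues without a side-chain
  donor/acceptor use the α-carbon.  The packaged table
  (`src/trrdf/data/ion_sites.tsv`) documents each anchor; it is a
  reconstruction from standard amino-acid connectivity — counting bonds
  through heavy atoms only, hydrogens are ignored — and is fully
  overridable by a user file of the same layout.  Entries failing the
  carbon-by-element check fall back (logged) rather than silently
  shifting the analysis onto a heteroatom.
* **Cluster assignment.** Each window takes the majority label of its
  frames (an explicit frame map supports labels sampled on a coarser
  trajectory); ties are left unassigned rather than guessed.
* **Contact maps.** Mean over frames of the minimum-image distance
  between residue representatives (α-carbon by default; a min-over-atom-
  pairs mode exists), contact = mean ≤ 0.5 nm.  Both cutoffs are
  configuration, not constants.

## Synthetic fixtures and what they do (not) show

All tests run on generated trajectories with analytically known pair
statistics: ideal gases (exact g = 1), frozen sc/fcc lattices (exact
coordination shells 6/18/26 and 12), two-particle systems with scripted
separations (closed-form single-bin g, exact fractional occupancies),
and wrapped random-walk ions around frozen sites (brute-force countable
shell occupancy).  These pin the estimator algebra, the periodic
geometry, the windowing and the normalisation exactly — but they contain
no force-field physics, no solvent structure, no correlated ion motion
and no conformational dynamics, so passing them validates the
*computation*, not any biological conclusion drawn from real
trajectories.  Stochastic checks use an ideal gas of 500 particles and
50 frames in an 8000 nm³ box with 0.05 nm bins, sized so every tested
bin holds enough pairs for a meaningful 4σ Poisson band (with the 2μ
variance correction for ordered-pair double counting when reference and
target groups coincide); smaller configurations in the unit tests keep
brute-force oracles affordable.

## Numerical choices and limitations

* Units nm/ps throughout; readers convert on load.  Frame indices and
  residue indices are 0-based.
* Default grid r_max = 2.0 nm, 400 bins (dr = 0.005 nm): resolves first
  and second hydration shells and contains the 0.70 nm cutoff with a bin
  edge exactly at 0.70.
* The selection grammar is a deliberately small, stable subset (name /
  element / resname / resid with ranges / chainid, and/or/not,
  parentheses, raw index lists) evaluated against the topology table;
  zero matches raise rather than produce silent empty groups.
* Scripted fixture distances placed exactly on bin edges are knife-edge
  under floating point (the half-open convention assigns them by the
  rounded value); tests script mid-bin separations.
* XTC coordinates are single-precision and quantised (~1e-3 nm);
  bit-exact round-trips use the JSON trajectory format instead.
* No neighbour lists: each frame's group-pair distance matrix is dense.
  Correct and memory-bounded, but O(N_a · N_b) per frame — adequate for
  per-residue site groups and ion counts, not tuned for full-solvent
  RDFs of very large systems.
* Overlapping/sliding windows and intermediate scattering functions are
  out of scope.
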