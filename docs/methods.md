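# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `membind`, in the order the pipeline applies them.

## System model

All analyses operate on a labelled particle system: an ordered `Topology`
assigning each bead a 1-based residue index (carried verbatim from input,
so conventional protein numbering such as 296–304 survives round trips), a
particle name, a role (`protein`, `lipid_head`, `lipid_tail`, `other`),
and — for lipids — a lipid class and leaflet; plus per-frame coordinates
and an orthorhombic box.  Lengths are nanometres everywhere inside the
package; ångström appear only at I/O boundaries with a fixed factor of
10 Å/nm.  Triclinic boxes are rejected: the minimum-image convention is
implemented for orthorhombic cells only, which covers the membrane systems
this package targets.  When leaflet labels are absent from input they are
assigned from frame 0 by comparing each lipid's head-bead z to the membrane
midplane (mean z of all lipid beads).

"Membrane" in every distance computation defaults to *all* lipid beads,
head and tail.  Whether solvent-facing beads should be excluded is a
modelling choice with no practical effect for a protein approaching from
solvent (head beads are always nearest); the selection is exposed for
callers who want otherwise.

## Minimum-distance engine

`min_distance_frame` computes min over pairs of the minimum-image distance
with the periodic axes chosen by `pbc_mode` (`xyz` default, matching
standard practice for periodic boxes; `xy` for analyses that must not wrap
across the membrane normal; `none` for plain Euclidean).  Two code paths
exist deliberately:

- a brute-force broadcast over all pairs, used when |A|·|B| ≤ 250 000;
- a k-d tree (scipy `cKDTree`) with per-axis periodic topology above that
  threshold, after shifting coordinates non-negative and wrapping the
  periodic axes.

The brute-force path doubles as the in-package reference for the
accelerated path; the test suite additionally checks both against an
independent double-loop oracle and against MDAnalysis' periodic
`distance_array` (the latter only to single precision, which is what that
library uses).  Distances are computed in double precision and reported to
1e-6 nm in output files.  Per-residue distances reduce the per-bead matrix
with `minimum.reduceat` over contiguous residue blocks, so the row-wise
minimum over residues reproduces the global trace identically.  Whole-frame
computations are chunked (~96 MB of displacement workspace) so memory stays
bounded for arbitrarily long trajectories; a streaming variant
(`min_distance_over_frames`) consumes a frame iterator without
materializing the trajectory at all.

## Bound-state classification

A frame is bound when the protein–membrane minimum distance is ≤ 0.7 nm
(inclusive comparison).  The 0.7 nm default is the operative cutoff for
coarse-grained bead systems: roughly the first minimum of the bead–bead
radial distribution, i.e. direct contact.  The KDE-derivative detector is
provided as an alternative: a Gaussian KDE of the pooled distances
(direct kernel-sum evaluation on a fixed grid, default [0, 5] nm with
1001 points; Scott's rule h = σ·n^(−1/5) by default, with a 0.01 nm floor
for degenerate zero-variance samples; mass outside the grid truncated and
the curve renormalized to unit trapezoidal integral) is scanned via the
central-difference first derivative.  Candidate modes are +→− sign changes,
valleys are −→+ changes; because sampling noise puts tiny wiggles in the
density tails, only modes reaching ≥ 5% of the peak density count, and a
valley is accepted only with a genuine mode on each side.  Unimodal
densities fall back to the fixed cutoff, tagged as such.  The fixed cutoff
is the default and the detector opt-in: the fixed number is exactly
reproducible, while valley location inherits bandwidth sensitivity.

The binding percentage of a condition is replica-averaged, never pooled:
each replica yields its own bound fraction (frame count at the shared
threshold, or — the `kde_area` method — the KDE mass below it, "the area
below the curve" on the bound side), and the condition reports
100·mean ± 100·sd(n−1)/√R.  Replica averaging is required for the standard
error to be meaningful; a single replica reports SE = 0.  The two
bound-fraction methods converge as bandwidth → 0 (verified at 0.01 nm to
within 0.01); the KDE-mass reading is used because binding is reported as a
percentage, which a time-integral of distance could not produce.

## Per-residue interface profile

Residue contact uses its own, stricter cutoff — strictly < 0.5 nm — kept
independent of the 0.7 nm bound threshold (two rules, two config values, no
attempt to unify).  Frequencies are contact frames pooled over all replicas
divided by pooled frames (`per_frame_fraction`), making the profile
invariant to replica order and bounded above by the global bound fraction
at 0.5 nm.  A `max_scaled` mode (divide by the maximum frequency) is
offered because published heat maps are often max-scaled; the mode is
recorded in the output metadata.  Ranking breaks ties by ascending residue
index; contiguous regions are maximal runs of consecutive residues with
frequency ≥ level·max (level 0.5 by default).

## Insertion depth

The membrane surface is the per-frame mean z of "PO4" head beads of the
proximal leaflet — a flat reference plane, matching how such depth profiles
are drawn, and unbiased for planar membranes; no smooth surface is fitted.
The proximal leaflet is chosen once per window (at its first frame, protein
centroid versus leaflet planes) to avoid mid-window flapping.  Depth of a
residue is surface minus mean bead z (sign flipped for a lower-leaflet
binder so positive always means inserted); a `deepest` mode uses the most
inserted bead instead of the mean.  No z-wrapping is applied — the membrane
is assumed whole within the box, and a guard rejects trajectories where
lipids cross the z boundary.  `compare_windows` evaluates the first and
last window (default 20 ns each) and reports per-residue |Δdepth| plus its
maximum as a binding-mode drift scalar: ≈ noise level for a stationary
binder, > 1 nm when the interface is lost.

## Flotation quantification

Bound fraction = top-fraction intensity / total over the four gradient
fractions (fraction 1 = first collected = top).  The estimator is
scale-invariant, so uncalibrated densitometry units are fine.  Summaries
report per-sample mean and sample SD (n−1) in percent, with n = 1 lanes
flagged rather than silently given SD 0 semantics.  Densitometry itself
(image → intensity) is upstream and out of scope.

## Synthetic data generator

The generator produces the geometry the analyses consume, with exact
ground truth, and deliberately nothing more:

- **Bilayer** — two leaflets of one head ("PO4") plus two tail beads per
  lipid on a jittered square lattice, head planes ±2.0 nm from the box
  z-midplane (a DOPC-like phosphate–phosphate spacing), default area per
  lipid 0.64 nm²; lipid classes assigned by largest-remainder rounding of
  the composition (exact within ±1 lipid per class per leaflet).  Default
  composition 60% DOPC / 40% DOPA — the PA-rich condition where binding of
  a PA sensor is strongest; the default box is 17 × 17 × 25 nm.
- **Protein** — `n_residues` (default 125, numbered 284–408 like a
  DysF-domain construct) of ≥ 1 bead each in a compact layered cloud; the
  designated interface residues (default 296–304 ∪ 378–395, two contiguous
  membrane-binding regions) form the membrane-facing bottom layer.  Initial placement puts the lowest
  bead exactly 2.5 nm above the upper head plane.
- **Binding process** — a discrete-time two-state Markov chain per frame
  (p_bind, p_unbind; stationary occupancy p_bind/(p_bind+p_unbind)) rather
  than Langevin dynamics: the analyses consume only geometry, and a chain
  gives provable ground-truth occupancy with closed-form uncertainty,
  var(occupancy) ≈ π₀π₁(1+ρ)/(1−ρ)/n with ρ = 1 − p_bind − p_unbind.
  Defaults p_bind = 0.12, p_unbind = 0.08 give occupancy 0.6 with
  realistic frame-to-frame persistence (ρ = 0.8).  Bound frames place each
  interface residue at its configured depth (default 0.2 nm) below the head
  plane, laterally snapped to a head-bead lattice site; unbound frames ride
  a mean-reverting altitude excursion (rest 2.5 nm, reversion 0.1/frame,
  noise 0.1 nm) clamped above a floor.  Frames are 40 ps apart and runs
  default to 1250 frames (≈ 50 ns), so two disjoint 20 ns windows fit.
- **Hard margins** — all positional noise (default sd 0.05 nm) is clipped
  at ±3σ, turning the classification margins into guarantees rather than
  probabilities: every interface residue registers < 0.5 nm contact in
  every bound frame, non-interface residues never do, and the unbound
  floor (threshold + 4σ) keeps unbound frames strictly above 0.7 nm.
  Parameters that would break a guarantee (too-shallow rest altitude,
  too-deep insertion for the contact cutoff) are rejected at construction
  with the violated margin.  Setting `clean_margins=False` narrows the
  unbound floor to threshold + 1.5σ for robustness experiments.
  Binding kinetics are free parameters of the generator: there is no
  canonical rate constant to emulate, so occupancies and persistence are
  chosen per experiment.
- **Determinism** — one seed drives everything through spawned
  sub-generators; replica r uses seed base + r; identical parameters give
  bit-identical trajectories.

What passing recovery tests therefore shows: the estimators are unbiased
and correctly implemented on geometry satisfying their assumptions.  What
they do not show: behaviour under real-data complications — membrane
undulations and curvature, lipid diffusion and flip-flop, protein
conformational change, partial or ambiguous binding poses, force-field
physics.  The generator makes no attempt at physical realism beyond
geometry and composition bookkeeping.

## Numerical choices and degenerate inputs

- Comparisons: bound is ≤ threshold, residue contact is strictly < cutoff.
- KDE grid resolution (5 nm / 1000) bounds threshold-detection precision to
  0.005 nm; the valley index refines to the lower-density neighbour of the
  sign change.
- Empty selections are valid results of `select_particles`; empty *groups*
  are errors for distance operations, as are overlapping groups.
- Validation (`validate_trajectory`) reports violations and never raises on
  content, so malformed frames can be triaged before construction.
- Zero-variance KDE samples get a 0.01 nm bandwidth floor; all-zero
  frequency profiles segment to an empty region list; flotation lanes with
  zero total intensity are unquantifiable errors, not zeros.
- Ranking ties (equal frequencies) resolve to the lower residue index, so
  top-k lists are deterministic.
- Problem sizes in the validation suite are chosen to exercise the stated
  statistics at desk scale: 20 000-frame chains for occupancy recovery
  (3σ band ≈ 0.03 at occupancy 0.5), 500-frame windows for depth recovery
  (noise-limited SE ≈ 0.002 nm), 100-system ensembles for the distance
  oracle.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- No lipid-species-resolved contacts (PA versus PC partner identity),
  contact lifetimes, or dwell-time kinetics; error bars are plain replica
  SE without autocorrelation correction.
- The insertion-depth surface is a flat plane; curved or undulating
  membranes would bias depths.
- GRO/PDB coordinate precision (0.001 nm / 0.001 Å fields) bounds
  round-trip fidelity; compressed binary trajectory formats are not read.
- The flotation module starts from band intensities; gel image processing
  and background subtraction are out of scope.
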