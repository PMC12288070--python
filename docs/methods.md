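# Methods

This note documents the models behind `dynenv`, the parameters that
matter, the numerical choices, and what the synthetic generators do and
do not emulate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The problem setting

A particle system (molecules in a simulation box, colloids in a 2D
cell) is observed as N particles over T frames separated by a sampling
interval `dt_sample`. Each particle carries a per-frame signal — a
high-dimensional structural descriptor, a scalar order parameter, or a
projection thereof — and the goal is to partition *signal stretches*
(not instantaneous points) into statistically distinct dynamical
environments, plus an explicit "don't know" remainder. Internally all
times are integer frames; `dt_sample` is applied only at I/O boundaries
and when Δt values are reported in physical time, which keeps units
consistent under resampling.

## SOAP power spectra

The neighborhood of a center is represented by the density
ρ(r) = Σ_j f_cut(r_j) exp(−|r − r_j|²/(2σ_atom²)) over the neighbors
within `r_cut` (the center itself is excluded by default;
`include_center` adds it, contributing only to the l = 0 channel).
The density is expanded as c_nlm = ⟨g_n Y_lm | ρ⟩ with real spherical
harmonics and an orthonormal radial basis, and summarized by

    p_nn'l = π √(8/(2l+1)) Σ_m c_nlm c_n'lm .

Choices and rationale:

- **Component ordering.** l varies slowest; within an l-block the
  ordered (n, n′) pairs are n-major; indices 0-based. This is the only
  layout consistent with a vector length n_max²(l_max+1) in which
  (n = n′ = n_max, l = 0) occupies index n_max² − 1 (#63 at n_max = 8).
  All published component numbers quoted by users of such descriptors
  depend on this convention, so it is fixed and tested.
- **Radial basis.** Gaussians of width r_cut/n_max centered at
  k·r_cut/n_max (k = 1..n_max), Löwdin-orthonormalized under r² dr on
  [0, r_cut]. Any smooth complete basis works for downstream analysis;
  bit-compatibility with other SOAP implementations is not a goal, and
  the test suite pins correctness to an independent dense-quadrature
  oracle instead (agreement ≤ 1e-6 relative for small bases).
- **Evaluation.** The angular integral for a displaced Gaussian has the
  closed form 4π e^{−α(r²+r_j²)} i_l(2αr r_j) Y_lm(r̂_j); the radial
  integral is 128-node Gauss–Legendre. The modified spherical Bessel
  factor is evaluated in exponentially scaled form
  (√(π/2x)·ive(l+½, x)), which is stable up to the largest arguments a
  10 Å cutoff produces.
- **Cutoff smoothing.** A cosine taper over the outer 10% of r_cut
  keeps the descriptor continuous as neighbors cross the cutoff.
- **Defaults.** r_cut = 10 (water-like oxygen networks), σ_atom = 0.5,
  n_max = l_max = 8 (576 components); per-vector normalization is off
  (an optional flag) because populations and variances downstream are
  easier to interpret on raw spectra.

Invariances (rotation ≤ 1e-8 relative, translation ≤ 1e-12,
permutation, coefficient additivity) are asserted in the tests.

## Active-matter descriptors

d_min is the distance to the nearest other particle (periodic-aware).
φ is the mean cosine between a particle's velocity and its neighbors'
within r_c (default 15, pixel units for tracked data). The particle
itself is excluded from the neighbor sum — self-inclusion would bias φ
toward +1. Particles with no neighbor or zero speed have no defined φ
and are marked NaN; NaN samples break classification runs and end up in
ENV0, which avoids inventing values for undefined geometry. Velocities
may be supplied by the tracker or derived as forward differences
(`finite_difference_velocities`, stride flag).

## Spatial denoising

Each particle's value (scalar or vector, componentwise) is replaced by
the unweighted mean over {itself} ∪ {neighbors within cutoff} at the
same frame. No kernel weighting and no temporal smoothing: the intent
is to average out single-particle noise against the local environment,
which is a purely spatial notion here. Averaging happens on descriptor
vectors *before* any projection, so denoised PCs are PCs of denoised
data.

## Variance views

PCA is covariance PCA (correlation PCA behind a `standardize` flag) on
rows pooled over particles and frames — the ergodic pooling that makes
"the PC1 time-series of particle i" well defined after reshaping the
scores back to (N, T). Signs are fixed by making each loading's
largest-magnitude entry positive, since eigenvector signs are otherwise
arbitrary and would break run-to-run reproducibility. Per-component
variance ranking carries an l = 0 / l > 0 family split so that
low-variance angular components can be found and extracted: leading
variance measures how much a component moves, not whether its motion
distinguishes environments.

## Onion clustering

At a fixed time resolution Δt (frames, ≥ 2), the algorithm repeats:

1. estimate the density of currently unassigned points — Gaussian KDE
   (Silverman bandwidth) on a ≤ 20 000-point deterministic stride
   subsample in 1D; a histogram with Freedman–Diaconis bins (8–64 per
   axis) in ≥ 2D;
2. fit a Gaussian to the highest peak: in 1D a least-squares Gaussian
   on the density between the flanking local minima, in ≥ 2D moments of
   the points inside the box bounded by the flanking minima along each
   axis through the peak; both initial fits are then **polished by a
   self-consistent truncated-moment iteration** (select points within
   Mahalanobis k_sigma, re-estimate moments with the χ² truncation
   correction F_{d+2}(k²)/F_d(k²), iterate to a fixed point). The
   polish is essential: Silverman bandwidths oversmooth each peak of a
   multimodal density, and axis-aligned histogram boxes truncate
   correlated clusters;
3. assign every maximal run of ≥ Δt frames whose points all lie within
   k_sigma spreads (Mahalanobis distance in ≥ 2D) of the state;
4. remove assigned points. A candidate whose mean falls inside an
   existing state's window extends that state rather than founding a
   duplicate; a candidate that gains less than `min_population` of all
   points has its window masked out of subsequent *density estimates*
   (never out of assignment) and the search continues, so discovery
   does not depend on the order in which peaks happen to be probed.
   Peeling stops when no classifiable density remains or `max_states`
   is reached.

Afterwards the states are re-fitted on their assigned points
(truncation-corrected moments) and all points re-assigned from scratch,
iterated to a label fixed point (≤ 10 rounds); states below
`min_population` (default 1%) are dissolved into ENV0, and survivors
are ordered by ascending mean (lexicographic for vectors). Ties between
equal-height peaks resolve toward the lower mean through this ordering.

**k_sigma default 3.0.** The assignment rule demands *every* point of a
run stay inside the window, so the per-point inside-probability
p = 2Φ(k) − 1 compounds over Δt frames. For a single pure Gaussian
state at Δt = 10, k = 2 (p ≈ 0.954) strands ≈ 12% of points in
sub-threshold runs — an unclassified fraction that contradicts the
intent that a clean single state be almost fully classified — while
k = 3 (p ≈ 0.9973) leaves ≈ 0.5%. The default is therefore 3.0,
derived from this closed-form dwell analysis and exposed in the
parameters. A σ floor of 1e-9 guards zero-variance degeneracies, so
ensembles of identical values still form one state.

**Δt scan.** Default grid: 30 log-spaced integers from 2 to T,
de-duplicated, endpoints forced. Per grid point the fit reports the
number of surviving states and the ENV0 fraction. A state with mean
dwell D is detectable only for Δt ≲ D (runs longer than the dwell are
exponentially rare), which is what detection windows measure. Note the
converse limit: at k = 3 the outlier rate alone (0.0027/frame) caps
run survival near Δt ≈ 10³ frames even for a permanent state, so at
Δt → T most series end in ENV0 unless T is small.

## Frustration diagnostics

info_loss(Δt) = max(max(n₁, n₂) − n₁₂, 0) on a shared Δt grid; the raw
(signed) gap is reported alongside. The bivariate analysis is
intrinsically stricter per point — P(χ²₂ ≤ k²) < P(χ²₁ ≤ k²) — so a
dimension that adds no discriminating structure still shortens run
survival and can push minor states below the population filter: that
is the frustration mechanism in this framework. Combining a dimension
with an exact copy of itself is the built-in control
(`self_combination_control`): the covariance degenerates to rank one,
the Mahalanobis rule reduces to the univariate rule (the truncation
correction uses the *effective* dimension, counted from non-floored
eigenvalues), and no information is lost.

Detection windows are reported on the discrete grid without
interpolation, in frames and in absolute time; the sampling scan
resamples the ensemble at integer strides (dt_sample scales
accordingly) and compares windows in absolute time. Windows are deemed
consistent when edges differ by at most one local grid step — grids at
different strides cannot share points, so sub-step agreement is the
strongest statement the discretization supports.

## Synthetic generators: what they emulate, and what not

All generators draw from substreams spawned off one master seed (state
path vs emission noise separately), so outputs are bit-reproducible
and changing one noise source does not perturb the other.

- **Markov ensembles** (`gen_state_ensemble`): independent per-particle
  chains over Gaussian emission states; mean dwell of state k is
  1/(1 − T_kk) frames. The canonical three-state chain (means −2/0/2,
  σ 0.25, middle dwell 50 frames, outer dwells 1000) emulates two bulk
  phases exchanging through a short-lived interfacial environment
  (~5% occupancy). Emission σ of exactly 0 is floored to 1e-9.
- **Two-phase toy** (`gen_two_phase_toy`): a cubic lattice slab (anchor
  + i.i.d. jitter) against a reflected-random-walk liquid at about half
  the solid density, with behaviour swaps (probability `exchange_prob`
  per frame) restricted to within one lattice constant of the slab
  face — localizing the short-dwell environment at the interface.
- **Wave toy** (`gen_wave_toy`): quasi-static uniform positions; a band
  of width `band_width` translating at `wave_speed` assigns coherent
  +x velocity plus jitter to its members, isotropic jitter elsewhere.
  Residence per sweep is band_width/wave_speed frames by construction.
- **Frustration fixture** (`gen_frustrated_pair`): dimension 1 is the
  three-state chain; dimension 2 shares the state path but merges the
  minor state into its nearest dominant neighbour and adds emission
  noise of σ = 2 × (the minor state's separation), i.e. a dimension
  carrying only coarse information drowned in noise.

They deliberately do **not** emulate: spatial correlation of switching
between neighboring particles, non-Gaussian or drifting emissions,
hydrodynamic or elastic interactions, tracking errors, or any real
force field. Passing tests therefore demonstrate the *statistical*
machinery — detection, dwell-time windows, population filtering,
frustration — under the assumptions the method itself makes, not
agreement with any particular physical system.

## Problem sizes and numerical tolerances

Test fixtures are sized for desk-scale runs as the package's own
choice: state-recovery rates use 200 series × 5000 frames over 20
seeds; the frustration rate uses 80 × 1500 with a 12-point Δt grid
(20 seeds) plus a 3-seed exact-copy control; the sampling scan uses
100 × 3000 (σ 0.1, middle dwell 60 frames) at strides {1, 2, 5}. The
dwell of 60 frames places the fixture in the regime where the
detection edge is governed by residence time rather than by the
k_sigma outlier rate (1/60 ≫ 0.0027), which is the regime the
consistency statement is about. Oracle tolerances: quadrature 1e-6
relative, rotation invariance 1e-8, explained-variance and trace
identities 1e-9, population accounting 1e-12.

## Known limitations

- Single-species SOAP only; no gradients; multivariate onion uses full
  covariance but has been exercised mainly in 2D.
- The peel-stage density estimators assume states are unimodal Gaussian
  blobs separated by ≥ ~k_sigma spreads; heavily overlapping states
  merge (inherent to the windowed-assignment model).
- Histogram binning in ≥ 3 signal dimensions becomes data-hungry;
  practical use should reduce to 1–2 informative dimensions first —
  which is, in fact, the package's central message.
- The extended-XYZ dialect is minimal: orthorhombic `Lattice`,
  `species/pos/vel` properties, fixed particle count across frames.
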