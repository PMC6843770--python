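# Methods

## The fluctuation model

`EnsembleDynamics.fit()` estimates a Gaussian fluctuation model of a
conformational ensemble: a mean structure and a positional covariance
matrix of the analysis beads, from which every reported statistic
derives. The analysis beads are one per residue — the Cα atom for
standard amino acids, the phosphorus atom for nucleotides — because a
per-residue description is what makes the cross-correlation and
correlation-score matrices comparable across models of a large
protein/RNA assembly. Residues lacking their bead atom (a 5′-terminal
nucleotide has no phosphate) are skipped with a warning; one bead per
residue is an invariant.

Frames are first superposed on a reference frame (by default the first
frame of the ensemble, i.e. the starting configuration of the analysis
window) with the optimal least-squares rotation/translation. The fit
is computed over the bead selection (uniform weights by default, mass
weights optional) and applied to all atoms, so that bead-level
covariance analysis and all-atom hydrogen-bond geometry share one
frame. The rotation is the Kabsch solution, computed for all frames at
once by a batched SVD; it agrees with `scipy`'s `align_vectors` to
machine precision (tested) and removes a planted rigid motion exactly.
`fit="none"` declares an ensemble as already expressed in a common
frame. This is exact for the synthetic generators here, which plant no
rigid-body motion, and it matters: a least-squares fit removes the
six rigid-body degrees of freedom *of the observed displacement
field*, which perturbs planted per-bead statistics at order 1/N. Where
a test checks a planted value exactly, it uses the common frame; where
it checks pipeline behaviour on data with arbitrary pose, it uses the
Kabsch path.

The covariance is taken about the window mean with population (1/n)
normalisation, so small hand-computed examples are exact. Mass
weighting multiplies the (i,j) 3×3 block by √(mᵢmⱼ) (units amu·Å²).
Masses come from standard atomic weights of the element, never from
coordinate files.

RMSF is computed about the window mean structure (not the reference
frame): RMSF_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩. It is unweighted; with the
unweighted covariance, RMSF_i² equals the trace of bead i's diagonal
covariance block identically, which is used as a cross-module
consistency test. RMSD is measured to the reference frame over the
beads; the radius of gyration is mass-weighted.

### Analysis windows

All estimators accept a window: `"all"`, `"last P%"`, or an explicit
half-open frame range. Comparative studies typically discard an
initial stretch of the production run this way. `"last P%"` keeps the
final ⌊n·P/100⌋ frames ("last 50%" of 101 frames keeps frames
[51, 101)). Frame indices are 0-based half-open everywhere in code;
residue ranges in component maps are 1-based inclusive, matching how
domain boundaries are cited in the literature (HEAT repeats H1–H20).

## Cross-correlation and correlation scores

The dynamical cross-correlation matrix uses the vector dot-product
convention: CC_ij is the trace of the (i,j) covariance block divided by
the bead standard deviations, so CC_ii = 1 exactly and mass factors
cancel — the DCCM is identical for weighted and unweighted covariance
(tested). A bead with zero variance makes CC undefined and raises an
error naming the bead; this arises only for ensembles analysed in a
frame where some bead never moves.

The correlation score CS(A,B) is the mean of CC over the A×B bead
block — the "correlation density" obtained by dividing the block sum
by the product of the component sizes. No cutoff is applied to the CC
values entering the sum. Two conventions are fixed here and exposed:

- Diagonal blocks include the i=j self terms, so CS(A,A) is inflated
  by |A|·1/|A|² = 1/|A| relative to the off-diagonal mean of the
  block. With components of tens of residues this is a few percent.
- Stored CS values are never clipped. Display clipping (e.g. to ±0.6,
  common in published CS heatmaps) is available as a rendering option
  (`CorrelationScoreMatrix.clipped`) and never touches the data.

Beads not covered by the component map are labelled "unassigned"; they
participate in all per-bead analyses and are excluded from CS
aggregation, which is defined only over named components.

## Switch-region detection

Inter-domain "spring-pulling" motions of a solenoid produce a
characteristic signature: the correlation of beads against a probe
component flips sign across the pivot, and the pivot itself carries
almost no displacement in the dominant principal mode. The detector
makes this qualitative criterion operational:

1. per bead, s_i = mean CC against the probe component's beads;
2. candidate boundaries: adjacent bead pairs where s changes sign and
   the flanking 5-bead means differ by at least `min_flip` (default
   0.2) with opposite signs;
3. per-bead amplitude a_i = ‖3-vector of bead i in the first
   eigenvector‖, thresholded at `amplitude_percentile` (default 20);
4. a switch region is the maximal contiguous run of low-amplitude
   beads around a candidate boundary; candidates landing in the same
   run are merged and regions are ranked by flip magnitude.

All three thresholds are package-defined defaults (the underlying
criterion in the literature is qualitative) and are exposed in the API
and config. The percentile should be matched to the expected pivot
width: in an ensemble whose amplitude profile is flat away from the
pivot, a generous percentile sweeps in tied beads and widens the
region (this is exercised in the tests). An ensemble with no sign
change yields an empty list, not an error.

## Essential dynamics

Eigendecomposition uses the dense symmetric solver up to 3N = 6000 and
a partial Lanczos decomposition above (threshold configurable);
cumulative variance is always reported against the full trace.
Eigenvector sign is fixed by making the largest-magnitude component
positive, so repeated runs are bitwise identical. Projections carry
the same mass weighting as the covariance (q_t = Σᵢ √mᵢ Δrᵢ(t)·vᵢ), so
the population variance of the mode-k projections equals eigenvalue k;
this identity is asserted to 1e-6 relative for every mode whose
eigenvalue exceeds 1e-9 of the leading one — below that the motion is
rank-deficient and a relative comparison is numerical noise. Modes are
exported in the NMD format readable by the Normal Mode Wizard; the
`scale` factor multiplies mode vector components only, never
coordinates.

## Hydrogen bonds

A donor–acceptor pair is bonded in a frame when the heavy-atom
distance is at most 3.3 Å and the best donor–H···acceptor angle over
the donor's hydrogens is at least 145°. The angle convention is
deliberately a *linearity minimum* (DHA ≥ threshold): this is how the
standard trajectory-analysis tools apply a "145° angle cutoff", and
the chemically sensible reading — a literal maximum on D–H···A would
reject near-linear (strong) bonds and accept bent ones. Both
thresholds are configurable; `angle_threshold=None` selects
distance-only mode, which also serves structures without hydrogens
and salt-bridge-style contacts.

Donors are N/O atoms with at least one hydrogen within 1.2 Å in the
reference frame (coordinate files carry no bond table, so covalent
hydrogens are inferred by name prefix plus distance); acceptors are
all N/O atoms. Pair identity is keyed by the heavy atoms, not the
hydrogen. Occupancy is count/window-size, so occupancy × n_frames is
an integer by construction. Loosening either threshold can only add
detections (monotonicity, property-tested), and occupancies are
invariant under rigid motion since both criteria are internal
coordinates.

## Synthetic generators: what they emulate, and what they do not

The generators provide planted ground truth for the analysis surface;
they are not physical samplers. All draw from a single explicitly
seeded RNG per call and record their seed and planted parameters in
the ensemble metadata. Defaults below are the study conditions used
by the test suite and the acceptance script.

**Block-correlated Gaussian ensembles.** Frames are i.i.d.; bead
displacements are scalar Gaussians with a prescribed block correlation
matrix (validated positive semidefinite; an infeasible spec is
rejected with the offending eigenvalue), applied along a fixed random
unit direction. By default the direction is *shared* by all beads: the
dot-product CC_ij of the ensemble then equals the planted scalar
correlation exactly in expectation, which makes recovery tolerances
purely statistical (SE ≈ (1−ρ²)/√n). A per-bead-direction mode exists;
there the observable CC is attenuated by the direction cosines
u_i·u_j, which is why it is not the default for planted-value tests.
Not emulated: temporal autocorrelation (frames are exchangeable, so
autocorrelation-dependent analyses are out of scope) and anisotropic
per-bead fluctuation.

**Hinge ensembles.** Two straight rigid arms of beads (3.8 Å spacing)
joined at a pivot bead open and close in a plane: the inter-arm angle
is rest_angle + amplitude·sin(φ) with φ uniform per frame, both arms
rotating symmetrically about the pivot. Defaults: 30+30 beads,
rest angle 30°, amplitude 20° — a closed-horseshoe geometry like a
HEAT-repeat solenoid, keeping the inter-arm angle positive through the
cycle. Intra-arm distances are constant to machine precision and the
pivot bead never moves in the generated coordinates, so in the common
frame the pivot's RMSF is exactly zero and it is exactly the argmin.
A subtlety worth knowing: after a Kabsch fit, the node of the residual
motion sits at the inertia balance point of the two arms, which for
this necessarily asymmetric layout (one arm carries the immobile
pivot) is about one bead away from the pivot — a property of
rigid-body removal itself, not of the detector. Switch-region
detection, which runs on the superposed ensemble, localises the pivot
via the flanking low-amplitude run and contains it robustly.

**H-bond geometry series.** Three atoms (donor N, hydrogen at 1.0 Å,
acceptor O). Each frame is independently in the bound geometry
(2.9 Å / 165°, validated to satisfy the default criterion) with the
target probability, else in the unbound geometry (4.5 Å / 120°,
validated to fail it). The realized bound-frame count is recorded, so
occupancy recovery can be asserted exactly, not statistically.

Passing tests on these ensembles demonstrate that the estimators
recover planted statistical structure at the stated tolerances; they
do not demonstrate force-field realism, convergence behaviour of real
trajectories, or robustness to the correlated noise of physical
dynamics.

## Problem sizes and numerical choices

The test suite and acceptance script use 20,000 frames for
planted-correlation recovery (tolerance 3 standard errors of a single
Pearson estimate; the block-mean CS is additionally checked against a
brute-force double loop to 1e-12), 5,000 frames × 20 seeds for hinge
recovery, and 300–2,000-frame ensembles elsewhere — sizes at which
every sampling tolerance in the suite is comfortably analytic.
Degenerate inputs are errors, not silent results: fewer than 3
non-collinear fit beads, single-frame RMSF windows, zero-variance
beads in the DCCM, empty bead selections, overlapping component
ranges, inconsistent model atom counts. CSV outputs use a fixed float
format and no timestamps, so a manifest run is byte-reproducible given
identical inputs and seed; provenance (config hash, input checksums,
package version, seed) is written alongside.

## Known limitations

- No temporal statistics: everything here is frame-order invariant.
- CS diagonal self-term inflation (above) makes CS(A,A) of small
  components approach 1 regardless of internal coherence.
- Donor-hydrogen inference is geometric; exotic protonation states or
  misnamed hydrogens will be missed.
- The NMD reader/writer covers the subset of the format needed for
  mode visualisation (names/resids/chainids/coordinates/mode lines).
- No XTC/TRR/NetCDF or mmCIF support; DCD and multi-model PDB only.
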