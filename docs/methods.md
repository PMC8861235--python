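# Methods

## Attenuation model and material library

Linear attenuation is expressed in the standard two-function basis
μ(E) = a_pe·f_pe(E) + a_c·f_KN(E), with f_pe(E) = (60/E)³ and f_KN the
Klein–Nishina total cross-section evaluated at α = E/510.975 keV, both
normalized to 1 at the 60 keV reference energy.  K-edge materials are
out of scope, so two basis functions suffice over the 30–120 keV
support.  Material coefficients are obtained at import by non-negative
least squares against a small bundled reference attenuation table
(representative linear-attenuation values for water, soft tissue,
cartilage, synovial/cyst fluid, cortical bone, a homogeneous
trabecular-bone+marrow mixture, and a hydroxyapatite-like
calcification).  The tissue surrogates are generic, not
specimen-matched: soft tissue and cartilage are modelled as water plus a
small share of the bone curve (0.5% and 1.5% respectively), which makes
them slightly photoelectric-enriched relative to water — the physical
reason their HU fingerprints fall with VMI energy and why cartilage sits
above, and never crosses, soft tissue.  Joint and cyst fluid are
water-like (1.005 × water).  The water model reproduces its reference
table to < 0.2%.

## Phantoms

The knee phantom is a stylized axial femoro-patellar section on a square
grid (default 256² at 0.25 mm isotropic voxels; the scanner-scale 640²
grid is a configuration option, the default is sized for desk-scale
runtimes).  Two elliptical bone bodies (cortical rim of 1 mm, trabecular
interior) face each other across a fluid-filled joint space; articular
cartilage (default 2.5 mm, thick enough to contain the radius-4-pixel
noise disc) lines both articular surfaces; soft tissue surrounds the
joint.  3D phantoms stack identical anatomical slices; cysts and
calcifications are then true spheres.  Cyst centres are drawn uniformly
from trabecular voxels inside the 10 mm subchondral band with a margin
that keeps each sphere clear of cortical bone, cartilage, other cysts
and the stack boundaries; an unplaceable cyst raises a configuration
error rather than being silently dropped.  All randomness flows from one
explicit integer seed through `numpy.random.default_rng`; generation is
bit-reproducible.  The phantom also carries the measurement geometry as
ROIs: the noise disc (radius 4 pixels inside femoral cartilage), a
cartilage measurement line and a parallel joint-space line, per-tissue
fingerprint ROIs (eroded to avoid partial-volume rims), the
medial/lateral split at the mid-sagittal column, the articular-surface
interface layer and the bone mask.  A uniform water cylinder (radius one
third of the field of view by default) calibrates and verifies the HU
scale.

## Acquisition model

The source is a Kramers bremsstrahlung shape (kVp − E) hardened by an
aluminium-equivalent filtration (default 2.5 mm Al) and truncated to
30–120 keV, tabulated at 1 keV steps; the quadrature error of the 1 keV
grid is far below Poisson noise at the default fluence of 10⁵ expected
photons per ray (split over bins).  A user-supplied tabulated spectrum
can be substituted.  Geometry is parallel-beam over 360° (the clinical
fan beam adds nothing to the downstream computations); projections are
Radon transforms of the two basis-coefficient maps, so the polychromatic
forward model needs exactly two projections per slice regardless of the
spectral grid.  The detector is ideal: each photon is counted in the bin
containing its energy, bins partition the spectrum (bin b spans
[T_b, T_{b+1}), the last bin extends to 120 keV), and counts are
independent Poisson draws per (bin, angle, detector).  Scatter, pulse
pile-up, charge sharing and detector blur are not modelled.  Noiseless
expectations are retained on the sinogram object for validation.

## Decomposition

Each ray is decomposed independently by maximizing the Poisson
log-likelihood over (A_pe, A_c) ≥ 0 — conventional maximum likelihood,
pixel-by-pixel in sinogram space, no regularisation.  The solver is a
damped projected Newton iteration using the analytic gradient and
Hessian of the two-parameter negative log-likelihood (exact derivatives
are cheap here and remove finite-difference step-size choices), run
vectorized across all rays simultaneously.  Initialization comes from a
two-bin log-ratio linearization using fluence-weighted mean basis values
of the outermost bins, clamped non-negative.  Convergence requires a
relative log-likelihood change below 1e-8 (at most 100 iterations) or a
projected-gradient norm below 1e-7 relative to the likelihood scale;
backtracking accepts steps up to a scale-aware rounding tolerance, since
the log-likelihood magnitude (~10⁴) makes absolute comparisons
meaningless at float precision.  Indefinite Hessians receive Levenberg
damping.  Rays that still fail fall back to a coarse grid search refined
by Nelder–Mead and are flagged and counted, never fatal; rays with zero
counts in every bin are assigned a saturation value (A = 50) and flagged.
Zero-count bins need no special handling — the n_b = 0 likelihood term
is simply −λ_b.  Decomposition may deliberately be run with a spectrum
different from the acquisition's to study model mismatch; by default the
simulator's own spectrum is used (an acknowledged inverse crime).

## Reconstruction and VMI synthesis

Both basis sinograms are reconstructed by standard parallel-beam FBP
(frequency-domain Ram-Lak filter by default, apodized variants by
option, linear-interpolation back-projection), scaled so a uniform disc
reconstructs its attenuation value.  A VMI at energy E is the linear
combination of the reconstructed maps converted to Hounsfield units with
μ_water(E) from the water material; the default ladder is 40–110 keV in
10 keV steps (the stated 40-to-110 range at 10 keV steps yields eight
energies; the list is configurable).  Internally HU is standard (water
0, air −1000); reported tissue values around +100 HU for cartilage are
on this scale, and an optional +1000 offset output mode exists only for
comparability with offset conventions.  The conventional image sums
counts over bins, forms −ln(n_total/blank_total) with a 0.5-count floor
on zero-count rays, reconstructs by the same FBP, and converts to HU
using the mean reconstructed value inside a noiseless water-cylinder
scan at identical settings (the effective water attenuation of the
merged-bin channel, ≈ 0.216 /cm, slightly above μ_water(60) because the
merged channel weights the softer part of the spectrum).

## Image quality and energy selection

Noise is the sample SD (ddof 1) inside the cartilage disc; CNR is the
absolute difference of mean HU along the cartilage and joint-space lines
divided by that SD; line means are unweighted over the stored pixel
paths (no sub-pixel interpolation).  Energy selection returns the
argmax-CNR and argmin-noise energies among the monoenergetic rows, ties
broken toward the lower energy and flagged.  On the default synthetic
study the noise curve is U-shaped with its minimum at 60–70 keV and CNR
peaks at 60 keV.  A caveat documented deliberately: with an ideal
counting detector and the merged-bin conventional image defined as the
sum of counts, the conventional channel is statistically near-efficient,
and the best VMI's cartilage-ROI noise lands a few percent above it at
the desk-scale 360-projection dose (a Cramér–Rao computation on the
per-ray model confirms this is fundamental, not a solver artifact).  At
the scanner-scale 2400-projection dose the comparison tightens and the
CNR ordering flips in the VMI's favour, because the merged-bin image
retains beam-hardening bias that the model-based decomposition removes.
Real-detector effects (energy weighting, spectral distortions), absent
here, further penalize physical conventional images.

## Cyst quantification

The subchondral band is the set of bone voxels within 10 mm Euclidean
distance of the articular surface, where the surface mask is the
interface layer just outside the bone (so depth 0 yields an empty band);
distances use the physical voxel sampling.  Region growing selects the
connected component (8-connectivity in 2D, 26 in 3D, for both growth and
labeling) of voxels within an absolute HU half-width of the seed value,
restricted to the band; the default tolerance is half the HU gap between
cyst fluid and trabecular bone, overridable, and seeds mirror the
operator's clicks (the driver takes them from ground-truth centroids).
Objects under 20 voxels (strict inequality; 0.31 mm³ at 250 µm voxels)
are removed as noise.  Cysts are assigned to the medial or lateral
compartment by centroid (nearest compartment, flagged, if the centroid
falls in neither); per-site totals sum counts and volumes over
compartments and take the maximum of the per-compartment maxima, with
volumes reported at one decimal.  Both the raw count and the density
(count per mm³ of band) are reported, since the two conventions coexist.
Growth is clipped at the band boundary by construction, so a cyst
straddling the 10 mm depth is quantified only over its in-band part.

## What the synthetic data do and do not show

The generator reproduces the acquisition's structure (spectrum support,
five thresholds, Poisson counting, axial geometry, 250 µm grid) and a
knee-like tissue inventory with ground truth, so it validates the
estimators, the HU scale, the energy-selection logic and the
segmentation pipeline end-to-end.  It does not reproduce specimen
anatomy, detector physics, scanner calibration or the published
specimen-specific magnitudes (noise/CNR percentages, absolute fingerprint
levels, per-specimen cyst counts); passing tests demonstrate
correctness of the methods, not agreement with any particular specimen.

## Problem sizes and numerical defaults

Default study: 256² grid, 0.25 mm voxels, 360 projections, 10⁵
photons/ray, thresholds 30/51/62/72/81 keV — chosen as a desk-scale
configuration that preserves every computation of the full-scale
pipeline.  Spectral quadrature 1 keV; solver tolerances as above;
FBP filter Ram-Lak; cyst analyses use 24-slice stacks.  Degenerate
inputs (empty bins, empty ROIs, single-pixel noise masks, zero-count
rays, unplaceable cysts, sub-two-angle sinograms) raise explicit errors
or are flagged, as described per module.
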