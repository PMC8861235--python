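# kneespec

Photon-counting spectral CT (PCSCT) simulation and analysis of knee
joints, aimed at quantitative, contrast-agent-free imaging of cartilage
and subchondral bone in osteoarthritis research.

A photon-counting detector sorts each photon into one of five energy
bins (thresholds 30/51/62/72/81 keV under a 120 kVp spectrum truncated
to 30–120 keV).  The energy-dependent linear attenuation of every tissue
is modelled in a two-function basis,

    μ(x; E) = a_pe(x) · f_pe(E) + a_c(x) · f_KN(E),

with a photoelectric term `f_pe(E) = (60/E)³` and a Compton term
`f_KN(E)` following the Klein–Nishina total cross-section, both
normalized to 1 at 60 keV.  For each detector ray the package maximizes
the Poisson log-likelihood

    ℓ(A) = Σ_b [ n_b ln λ_b(A) − λ_b(A) ],
    λ_b(A) = Σ_{E∈bin b} S(E) · exp(−A_pe f_pe(E) − A_c f_KN(E)),

over the non-negative basis line integrals `A = (A_pe, A_c)` —
pixel-by-pixel, without regularisation — then reconstructs both basis
sinograms by filtered back-projection.  Virtual monoenergetic images
(VMIs) at any energy are linear combinations of the two maps, expressed
in Hounsfield units; the conventional image merges all bins into one
transmission measurement.  Downstream analyses reproduce the standard
image-quality and lesion workflow: cartilage-ROI noise (SD in a
radius-4-pixel disc), CNR between a cartilage line and a joint-space
line, per-tissue attenuation-vs-energy fingerprints, optimal-energy
selection, and subchondral bone-cyst quantification by seeded region
growing in a 10 mm subchondral band with a 20-voxel (0.31 mm³) minimum
object size.

Because no public specimen data exist, the package ships a labeled
digital knee phantom (cortical/trabecular bone, cartilage, joint fluid,
soft tissue, cysts, calcifications, with ground-truth masks and all
measurement ROIs) and a water cylinder for HU calibration.

## Worked example

```python
import kneespec as ks
res = ks.run_knee_study(seed=0)
print(res.quality)
print(res.optimal)
```

prints (ground-truth knee phantom, 256² grid at 0.25 mm, 360
projections, 10⁵ photons/ray):

```
       image  noise_sd_hu      cnr
       40.00       137.85     0.91
       50.00        74.22     1.46
       60.00        52.56     1.87
       70.00        52.22     1.78
       ...
conventional        49.39     2.03

optimal energy by CNR:   60 keV
optimal energy by noise: 70 keV
```

Noise falls steeply from 40 keV, dips around 60–70 keV and rises again
toward 110 keV; CNR peaks at 60 keV — the energies at which the
photoelectric and Compton noise contributions cancel best.  The
fingerprint table (`res.fingerprints`) shows every tissue's HU falling
with energy at its own rate, cartilage staying cleanly above soft
tissue.  See `examples/` for one narrative script per capability
(phantom construction, acquisition, decomposition + reconstruction,
energy selection, cyst quantification), each printing the numbers it
computes and what they mean.

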