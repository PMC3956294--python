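# Methods

## Geometry

Cells are modelled as spherocylinders: a cylinder of radius R capped by
two hemispheres, total length L. The caps exactly replace the cylinder's
end disks in the surface integral, so the membrane area is strictly
proportional to length, `A_cor = 2πRL`, and the volume is
`V = πR²(L − 2R) + (4/3)πR³`. The medial nodal band of axial width
`w_nod` occupies `A_nod = 2πR·w_nod` and must lie on the cylindrical
part (`w_nod ≤ L − 2R`). Wild-type-like defaults: R = 1.5 µm, L growing
from 7 to 14 µm over interphase, `w_nod` = 3 µm (the standard medial
measurement window).

Sizes can also be measured from traced outlines. A closed 2-D perimeter
is split at its two extreme-x points, the halves averaged into an axial
radius profile r(x), and area/volume computed as a surface/solid of
revolution with midpoint-radius frustum quadrature (second-order
accurate; converges to the closed forms as the sampling step shrinks —
0.5% at 0.1 µm, 5·10⁻⁵ relative at 0.01 µm). Contours are assumed
pre-clipped to exclude the septum.

## Steady-state models

Three pools — cytoplasmic, cortical, nodal — exchange on timescales of
seconds to minutes, far faster than growth (hours), so every size is a
quasi-steady state of the exchange kinetics.

Model I parameters (defaults in parentheses): β, cytoplasm→membrane
association, µm s⁻¹ (1, arbitrary units — it enters every density only
as a prefactor, so absolute densities are relative unless calibrated);
ν, cortical dissociation, s⁻¹ (5·10⁻³); α, band-restricted
cortical→nodal uptake, s⁻¹ (1.0, large so nodes are strongly enriched:
ρ_nod/ρ_cor = α/η = 200); η, nodal dissociation, s⁻¹ (5·10⁻³, the
inverse of the ~3-min nodal occupancy time measured by FRAP). The
cytoplasmic concentration optionally declines linearly with length at a
relative slope of −0.01 µm⁻¹ about a reference length L_ref = 10.5 µm
(the midpoint of the growth range; the measurement that motivates the
trend normalizes to an average cytoplasmic intensity without stating a
reference length). The closed-form solution and a damped-Newton solve of
the raw balance equations (on log copy numbers, analytic Jacobian,
residual tolerance 10⁻¹² of the influx) agree to better than 10⁻¹⁰ and
cross-validate each other.

Model II (modification route) defaults: ν = 0.5 s⁻¹ (keeps the cortical
pool low), α = 0.5 µm s⁻¹ (binding constant of the modified form to the
band), η = 5·10⁻³ s⁻¹, µ = 0.03 s⁻¹ (slow spontaneous reversion). With
µ = 0 the nodal density is exactly (β/η)(A_cor/A_nod)ρ_cyt; reversion
damps the 14-vs-7-µm density ratio from 2.0 to 1.82 at the defaults.

The direct-to-node null model binds cytoplasmic protein straight onto
the nodes: ρ_nod = (β/η)ρ_cyt, flat in L. It formalizes why membrane
localization alone cannot sense size: sensing requires one process
(association) that scales with total area and a second (uptake) confined
to a region that does not.

Scaling-curve fitting exploits that every variant is linear in its
prefactor: the least-squares prefactor is `Σg·d / Σg²` for the
unit-prefactor curve g(L). When the fitted observable is a transformed
readout (a band-integrated intensity rather than a density), the fit
accepts the noise-free forward model of the measurement as its curve, so
a zero-noise dataset yields r² = 1 by construction.

## Spatial model

On the membrane, densities depend only on the long-axis coordinate x
(origin at mid-cell, domain [−L/2, +L/2]):

    0 = D_cor ρ_cor″ − ν ρ_cor − α(x) ρ_cor + β ρ_cyt
    0 = D_nod ρ_nod″ + α(x) ρ_cor − η ρ_nod

with α(x) = α₀ exp(−x²/2ω²), ω = a(1 − e^(−L/s)), and hard walls at the
tips read as zero-flux (reflecting) boundaries — molecules leave the
membrane only by dissociation, so the stationary balance
β ρ_cyt L = ν ∫ρ_cor + η ∫ρ_nod holds exactly. Defaults: D_cor = 0.2
µm² s⁻¹, D_nod = 0 (immobile nodes, in which case
ρ_nod = α(x)ρ_cor/η pointwise), α₀ = 0.5 s⁻¹, a = 2.2 µm, s = 7 µm,
ν = η = 5·10⁻³ s⁻¹. The cortical lifetime τ = 1/ν ≈ 180 s gives a
diffusional reach √(2D_cor τ) ≈ 8.5 µm, comfortably above the ~5 µm
needed for tip-born protein to reach the medial band before dissociating.

Discretization: second-order central differences with ghost-point
Neumann closure and a direct banded solve (the system is linear), plus
Richardson extrapolation over solves at h and h/2, leaving O(h⁴) error —
about 10⁻⁹ relative at the default 0.02 µm step, verified against an
independent collocation (solve_bvp) solution. The circumferential
dimension is collapsed; 2πR enters only when integrating densities to
copy numbers.

**Behavior at the defaults, and a known discrepancy.** Total nodal
content rises ≈1.9-fold from L = 7 to 14 µm: the collection area scales
with the cell while the uptake region does not, so the model senses area
robustly. The *mean density in the central 3-µm window*, however, is
flat (−2% over the range) rather than rising. The cause is that at these
parameters the band is a diffusion-limited absorber (absorption length
√(D_cor/α₀) ≈ 0.63 µm ≪ ω): incoming cortical protein deposits near the
*edge* of the uptake region, at |x| ≈ ω and beyond, and as ω(L) widens
the deposition zone migrates out of the fixed ±1.5 µm window, offsetting
the growing influx. The central-window density does rise monotonically
whenever the absorber is weak — faster cortical diffusion (D_cor ≳ 1
µm² s⁻¹), a smaller α₀, or a roughly twofold narrower uptake Gaussian —
while flux conservation and symmetry hold in every regime. One
acceptance check asserts the monotone central-window rise at the strict
defaults and is left failing rather than met by adjusting parameters;
the accompanying tests pin down the behaviors that do hold (monotone
total content, conservation, symmetry, the well-mixed limit equivalence
with the uniform model to 1%).

## Profile quantification

All fitters are nonlinear least squares (`scipy.optimize.curve_fit`) and
scale-invariant in the shape parameters.

- **Tip-gradient decay length.** The profile is shifted so its level
  5 µm from the tip is zero (anchored on a ±0.15 µm neighborhood rather
  than one noisy pixel), scaled to ~1 at the tip, and fit to exp(−x/λ)
  over [0, 5 µm]. The model curve receives the *identical*
  normalization, and a free amplitude absorbs the noise of the tip
  anchor — without these two choices the shift biases λ downward by
  ~10%. Non-decaying profiles are flagged, not fit.
- **Node-band width.** Four-parameter Gaussian-plus-offset fit;
  accepted only when r² ≥ 0.8 (the "good quality of fit" threshold is a
  package choice, configurable) and σ > 0.5 µm (narrower apparent widths
  typically reflect one very bright node distorting the fit). Rejections
  carry their reason.
- **Medial band intensity.** Background-subtracted sum and mean over a
  3-µm window about the profile center.
- **Node detection.** Local maxima above twice the background that
  stand out by at least the threshold (prominence) and are separated by
  more than a ~0.3 µm resolution element; plateaus count once at their
  leftmost point. Merged nodes register once, so counts are lower
  bounds.
- **FRAP.** Single-exponential recovery A(1 − e^(−kt)) + c with a
  floating plateau; t½ = ln2/k. Non-recovering traces are flagged.
- **Molecule counting.** Sample-to-standard intensity ratio times the
  standard's copy number (22-molecule dots by default).
- **Cortical loops.** Angular profiles are binned into 100 sectors and
  angles converted to tip distances by approximating the mid-plane
  outline as two semicircles joined by straight lines; empty sectors are
  flagged missing, never interpolated.

## Statistics

Jensen–Shannon distance uses base-2 logarithms so its range is exactly
[0, 1] (0 for identical, 1 for disjoint distributions); inputs must be
normalized — no silent renormalization — and continuous samples are
binned on shared Freedman–Diaconis edges over the pooled data. The
correlation-robustness test redraws *both* members of every
growth/accumulation pair from Gaussians with the measured per-cell
errors, refits the OLS slope, and reports the fraction of replicates
(default 10⁶, chunk-vectorized, one seed) with slope ≤ 0. Matched-subset
selection scans the inclusion fraction f ∈ [0.10, 0.20] per strain and
picks, for each strain, the f whose subset mean lands closest to the
cross-strain target, succeeding when all subset means agree within 1%;
failure returns the best achievable selection with a warning flag.
Length binning uses half-open 1-µm bins.

## Synthetic data

The generators define the study conditions; every observable carries the
ground-truth parameters that produced it, and recovery tests compare
against that recorded truth.

- **Populations.** Radii per strain (wt/fat/thin = 1.5/1.75/1.3 ±
  0.05 µm), linear growth at 2 ± 0.4 µm h⁻¹, division when the rule's
  quantity (area 150 µm² by default) crosses a lognormal-jittered
  threshold (CV 5%); a 5-generation lineage with symmetric halving makes
  birth sizes self-consistent, which matters only for the timer rule.
- **Cdr2p profiles.** A Gaussian nodal band of width ω(L) atop a
  cortical baseline and cytoplasmic haze, plus additive background and
  5% multiplicative Gaussian noise; a discrete-node variant places
  Poisson-distributed ~90-molecule dots along the band. Loop profiles
  paint the same signal on angular coordinates.
- **Tip gradients** exp(−x/λ)(1 + noise) + background; **FRAP traces**
  at t½ = 3 min, 30 points over 12 min, 5% noise, n = 14; **growth
  tracks** with sizer coupling (accumulation ∝ growth) or timer coupling
  (constant accumulation), n = 21, per-pair measurement errors attached;
  **cytoplasmic intensities** with the −0.01 µm⁻¹ relative trend,
  n = 267.

What the generators do *not* emulate: 2-D/3-D image formation, the
photobleaching process itself, optical blur between neighboring nodes
beyond a fixed resolution element, correlated cell-to-cell measurement
error, and birth-size correlation structure beyond symmetric halving.
Passing tests therefore demonstrate that the procedures recover known
truth under the assumed noise structure, not that they are robust to
every artifact of real microscopy.

## Reproducibility and problem sizes

Every stochastic path takes one explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical
outputs, and pipeline reports embed a config hash and the package
version. Default problem sizes (100–200 cells per population, 14 FRAP
traces, 10⁶ robustness replicates in the analysis driver and 10⁵ in
routine runs, 0.02 µm spatial grids) keep any single analysis under a
minute on one core; the Monte-Carlo replicate count is the only knob
with material cost and converges at the binomial rate.

## Limitations

Node formation/growth dynamics are deliberately absent (uptake is a
smooth rate, not aggregation); the spatial model is strictly 1-D; the
molecule-counting calibration ignores spectral and maturation
differences between fluorophores; the 385→237 node-band filter yield is
reproduced by construction (a generator mixing wide and narrow bands at
the observed acceptance fraction), since the real width distribution is
unpublished; and absolute densities are in arbitrary units unless a
calibration standard is supplied.
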