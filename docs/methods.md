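# Methods

## Model

The tumor is idealized as a homogeneous poroelastic sphere of radius `a`
perfectly bonded to normal tissue and small relative to the sample (remote-load
assumption). Under creep compression the interstitial fluid pressure takes the
form `p(R) = Ψ (1 − sinh(αR/a)/((R/a) sinh α))` with the dimensionless
spatial-distribution parameter `α = a √((Lp/k)·S/V)`; `α` controls how sharply
pressure and solid stress concentrate toward the center (`α ≲ 1`: nearly
parabolic, shallow; `α ≳ 30`: a plateau near the peak with a thin boundary
layer). The compression-induced solid stress is the boundary stress minus
`p(R)`; the growth-induced solid stress shares the same sinh-profile shape with
its own boundary (`Ω_b`) and peak (`Ω_p`) amplitudes. Both normalize to the
single dimensionless field `SSn(R)`, with peak `SSn,p = 1 − α cosech α`; the
method therefore images the *normalized* stress distribution and its peak, not
absolute stress magnitudes.

The model is static: creep acquisition happens at a fixed time point and the
amplitude Ψ absorbs the time scale. Non-spherical tumors, spatially
heterogeneous `α` and transient consolidation dynamics are out of scope.

## Units, conventions, numerics

Stresses are in kPa, lengths in mm (transport properties in SI, converted at
`alpha_from_transport`), radii normalized to [0, 1] at type construction.
Compression is negative: an applied pressure of `P` kPa enters as
`σ_applied = −P`.

The sinh ratio is evaluated as
`exp(α(r−1))·(1−exp(−2αr)) / (r·(1−exp(−2α)))`, which is overflow-free to at
least `α = 10⁴`; the `r → 0` limit uses the series
`α(1 + (αr)²/6)` below `r = 10⁻⁸`, and `peak_ssn` switches to its Taylor
expansion `α²/6 − 7α⁴/360` below `α = 10⁻⁴` where the direct expression
cancels. In double precision `1 − α cosech α` rounds to exactly 1 for
`α ≳ 37`, so monotonicity in `α` is strict only where the value is resolvable
from that plateau — the documented behavior of the implementation and its
tests.

## Boundary stress (Eshelby stage)

The boundary scalars `σᵃ_RR, σᵃ_θθ` come from the uniform interior stress of a
spherical elastic inhomogeneity in an infinite matrix under remote uniaxial
load, solved by the equivalent-inclusion method on the normal-component block
(the shear block decouples for axisymmetric loading; the interior `s_rz` is
identically zero). Drained elastic constants are used — the poroelastic
problem reduces to the elastic one at the instant of load transfer. The
θ-dependent spherical components on the tumor surface are reduced to the two
scalars the 1-D model needs by a surface-area-weighted average over the polar
angle by default (`⟨cos²θ⟩ = 1/3`); evaluation on the compression axis or the
equator is available via `reduction=` for sensitivity checks, since no single
reduction is canonical for a spherically symmetric approximation of an
axisymmetric field.

## Synthetic phantoms

`generate_ssc_map` renders the 2-D slice through the center of the spherical
inclusion: in-mask pixels carry `σᵃ_RR − p(ρ/a)`, the exterior is a constant
background (the reconstruction consumes only in-mask pixels, so exterior
realism is deliberately not modeled). Additive zero-mean Gaussian noise is
calibrated so that `10·log₁₀(var(signal in mask)/σ²_noise) = snr_db`; the
variance (contrast-power) convention is used because the informative signal is
the spatial stress variation, not the DC offset of the map. The default
fixture is a 32-pixel-radius inclusion at 0.125 mm spacing (binary-exact
spacing keeps the discrete geometry exactly symmetric under rotation), Ψ = 1
kPa, boundary −1 kPa, 20 dB SNR. What the phantom does **not** emulate:
ultrasound speckle, strain-estimation artifacts, segmentation error, off-center
imaging planes, heterogeneous tissue — so passing recovery tests bound
estimator error under idealized imaging, not in vivo performance.

Longitudinal cohorts for the statistics stage use per-arm geometric weekly
trajectories of `α` (defaults: start 2.0, untreated ×1.5/week, treated
×0.7/week, 6 subjects per arm, 3 weeks) with multiplicative lognormal
observation noise (sd 0.1). The starting value reflects a low-stress early
tumor (peak SSn ≈ 0.3); the multipliers produce clearly separated arms by week
3, the regime the group-comparison stage is meant to resolve.

## Reconstruction

The map is reduced to a radial profile by equal-width annular binning of
normalized radius over [0, 1] (default 15 bins), each bin carrying its pixel
mean and count; empty bins are dropped from the fit, not interpolated. The
profile retains its pixel radii so the fit's per-bin model prediction is the
model averaged over the bin's actual pixels — evaluating at bin centers
instead leaves an O(1%) discretization bias in `α̂`, which would dominate the
noiseless error budget.

`fit_alpha` minimizes weighted least squares over `log α ∈ [log 10⁻³, log 10³]`
from a fixed grid of 9 log-spaced initializations (best residual wins, ties to
the smallest `α`, followed by a local polish), so the fit is deterministic.
In `known_scale` mode the boundary stress and Ψ are supplied (e.g. from the
Eshelby stage and the applied pressure) and only `α` is fitted on the
normalized profile; in `free_scale` mode (σᵃ, Ψ, α) are fitted jointly — for
fixed `α` the model is linear in (σᵃ, Ψ), so the joint fit is a 1-D search
with an inner weighted linear solve. `known_scale` mirrors the in vivo
procedure and is markedly better conditioned at low contrast (at `α = 2`,
20 dB, the 3-parameter free fit has a median relative error above 10%, the
known-scale fit below 1%); the Monte-Carlo validation therefore runs in
known-scale mode, with a separate looser regression test for the free mode.

Degenerate inputs: a flat profile has no resolvable amplitude and returns
`converged=False` with a `non_identifiable` flag rather than raising. For
plateaued profiles `α` is only lower-bound identifiable; the result carries a
`saturated` flag when `SSn(α̂, 0.5) > 0.99·SSn,p(α̂)`, i.e. when the plateau
covers half the radius (this trips from `α̂ ≈ 13` upward).

`ssn_map` applies `(value − σ̂ᵃ)/(−Ψ̂)` in-mask, NaN outside; values are not
clipped, and the fraction outside [−0.2, 1.2] is reported in the metadata.

## Statistics

The Kruskal-Wallis H uses midranks and the standard tie-correction divisor;
p-values come from the chi-square upper tail, or from exact enumeration of all
rank assignments for pooled N ≤ 10. At these sample sizes the permutation
distribution of H is discrete, with CDF steps near H = 0 of ~0.09 for 5+5, so
chi-square and exact p agree tightly only in the rejection region — the
regression tests assert 0.05 agreement there and 0.1 overall. Weekly
summaries compare arms within each week (pairwise), matching the longitudinal
study design; no multiplicity correction is applied by default, with a Holm
step-down switch available.

## Validation scale

The Monte-Carlo recovery experiments use 100 seeded replicates per condition
on 73×73 phantoms, and the null calibration of the chi-square approximation
uses 10,000 simulations of two groups of six — sizes at which the full
validation suite completes in well under a minute on a single core while the
medians and rates being asserted are stable to the tolerances tested.
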