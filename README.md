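# ssn-poro

Modeling and imaging of **normalized solid stress (SSn)** in spherical tumors
from ultrasound poroelastography stress maps.

Solid stress accumulates inside a growing tumor (growth-induced solid stress,
SSg) and is a marker of progression: it compresses vessels, raises interstitial
fluid pressure and hinders drug delivery. It cannot be imaged directly, but
during a creep-compression (poroelastography) experiment the tumor develops a
compression-induced solid stress (SSc) with the *same spatial distribution*.
This package implements that model and the imaging pipeline built on it, for
researchers working on tumor biomechanics and quantitative elastography.

## The model

For a spherical poroelastic tumor of radius `a` under a constant applied
pressure, the compression-induced interstitial fluid pressure is

```
p(R) = Ψ · (1 − sinh(α R/a) / ((R/a) sinh α)),    α = a √((Lp/k) · S/V)
```

where `Lp` is vascular permeability, `k` interstitial permeability and `S/V`
the capillary surface-to-volume ratio. The solid stresses follow as

```
σᶜ_RR(R) = σᵃ_RR − p(R)                        (compression-induced, radial)
σᵍ_RR(R) = −Ω_bR − Ω_pR (1 − sinh(αR/a)/((R/a) sinh α))   (growth-induced)
```

and analogously for the circumferential components. Normalizing either by its
boundary value and amplitude yields one dimensionless field,

```
SSn(R) = 1 − sinh(α R/a) / ((R/a) sinh α),     SSn,p = 1 − α cosech α,
```

zero at the boundary and peaking at the center. The boundary scalars
`σᵃ_RR, σᵃ_θθ` come from Eshelby's equivalent-inclusion solution for a
spherical inhomogeneity under remote uniaxial load, rotated from cylindrical
to spherical components. The imaging problem is the inverse: from a measured
SSc map, estimate `α`, normalize, and report the SSn image and its peak.

## Modules

- `ssn_poro.model_core` — closed-form profiles: fluid pressure, SSc, SSg, SSn, peak SSn
- `ssn_poro.boundary_stress` — Eshelby interior stress, tensor rotation, boundary scalars
- `ssn_poro.phantom` — seeded synthetic stress-map phantoms and longitudinal cohorts
- `ssn_poro.reconstruct` — annular profile extraction, α fitting, SSn map
- `ssn_poro.stats` — Kruskal-Wallis (chi-square and exact permutation), weekly summaries
- `ssn_poro.io` / `ssn_poro.cli` — TIFF/CSV/JSON formats and the `ssn-poro` command

## Worked example

```python
import numpy as np
from ssn_poro import peak_ssn
from ssn_poro.experiments import make_phantom
from ssn_poro.reconstruct import extract_radial_profile, fit_alpha

smap, center, radius = make_phantom(alpha=5.0, snr_db=20.0, seed=1)
profile = extract_radial_profile(smap, center, radius, n_bins=15)
fit = fit_alpha(profile, mode="known_scale", known=(-1.0, 1.0))
print(f"alpha_hat = {fit.alpha_hat:.3f}")
print(f"peak SSn  = {fit.ssn_peak_hat:.3f}  (true {peak_ssn(5.0):.3f})")
```

prints

```
alpha_hat = 5.004
peak SSn  = 0.933  (true 0.933)
```

The phantom is a 73×73-pixel map of a 32-pixel-radius spherical inclusion with
boundary stress −1 kPa and amplitude Ψ = 1 kPa at 20 dB SNR; the fit recovers
the spatial-distribution parameter `α = 5` to within ~0.1% here, and
`peak SSn = 1 − α̂ cosech α̂` is the reconstructed peak normalized solid
stress.

The same pipeline is available from the shell:

```
ssn-poro simulate --out run/ --seed 0
ssn-poro reconstruct --map run/ssc_map.tif --out run/rec/
ssn-poro stats --cohort run/cohort.csv --out run/stats/
ssn-poro curves --out run/curves/
```

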