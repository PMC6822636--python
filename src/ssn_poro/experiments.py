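"""Reproducible end-to-end study harnesses built from the package's own pieces.

These functions regenerate the quantities the package is validated on — the
printed boundary-stress worked example, Monte-Carlo alpha-recovery error on
phantoms, and the null rejection rate of the Kruskal-Wallis test — from
scratch at run time, seeded.
"""

from __future__ import annotations

import numpy as np

from .boundary_stress import BoundaryStress
from .model_core import GrowthStressParams, PressureProfileParams, growth_stress_profiles
from .phantom import PhantomConfig, generate_ssc_map
from .reconstruct import extract_radial_profile, fit_alpha
from .stats import GroupedSamples, kruskal_wallis

__all__ = [
    "boundary_growth_stress_example",
    "make_phantom",
    "noiseless_roundtrip_error",
    "alpha_recovery_errors",
    "kw_type_i_error",
]

# Radial/circumferential SSg amplitude set used for the model curves (kPa)
CURVE_AMPLITUDES = dict(omega_bR=0.4, omega_pR=0.2, omega_bT=0.0, omega_pT=0.6)


def boundary_growth_stress_example(alpha: float = 33.0, n_points: int = 201):
    """Radial and circumferential SSg at the tumor boundary for the standard amplitude set.

    Returns ``(sigma_RR_g_at_a, sigma_thth_g_at_a, n_points)`` in kPa, taken
    from profiles evaluated on an ``n_points`` grid ending at R/a = 1.
    """
    g = GrowthStressParams(alpha=alpha, **CURVE_AMPLITUDES)
    r = np.linspace(0.0, 1.0, n_points)
    radial, circ = growth_stress_profiles(g, r)
    return float(radial.values[-1]), float(circ.values[-1]), n_points


def make_phantom(
    alpha: float,
    snr_db: float = np.inf,
    seed: int = 0,
    radius_px: int = 32,
    pad_px: int = 4,
    pixel_mm: float = 0.125,
    psi_kpa: float = 1.0,
    s_rr_a: float = -1.0,
):
    """Centered spherical-inclusion SSc phantom; returns (map, center_mm, radius_mm)."""
    a_mm = radius_px * pixel_mm
    center = (a_mm + pad_px * pixel_mm, a_mm + pad_px * pixel_mm)
    n = 2 * radius_px + 2 * pad_px + 1
    cfg = PhantomConfig(
        grid_shape=(n, n),
        pixel_mm=pixel_mm,
        center_mm=center,
        radius_mm=a_mm,
        pressure=PressureProfileParams(alpha=alpha, psi_kpa=psi_kpa, a_mm=a_mm),
        boundary=BoundaryStress(s_RR_a=s_rr_a, s_thth_a=s_rr_a),
        snr_db=snr_db,
        seed=seed,
    )
    smap, _ = generate_ssc_map(cfg)
    return smap, center, a_mm


def noiseless_roundtrip_error(alpha: float, mode: str = "free_scale", n_bins: int = 15) -> float:
    """Relative alpha error of the noiseless generate -> bin -> fit round trip."""
    smap, center, a_mm = make_phantom(alpha)
    prof = extract_radial_profile(smap, center, a_mm, n_bins)
    known = (-1.0, 1.0) if mode == "known_scale" else None
    fit = fit_alpha(prof, mode=mode, known=known)
    return abs(fit.alpha_hat - alpha) / alpha


def alpha_recovery_errors(
    alpha: float,
    snr_db: float,
    n_seeds: int,
    seed0: int = 0,
    mode: str = "known_scale",
    n_bins: int = 15,
    radius_px: int = 32,
) -> np.ndarray:
    """Relative alpha-recovery errors over ``n_seeds`` noisy phantom realizations."""
    errs = np.empty(n_seeds)
    for i in range(n_seeds):
        smap, center, a_mm = make_phantom(alpha, snr_db, seed=seed0 + i, radius_px=radius_px)
        prof = extract_radial_profile(smap, center, a_mm, n_bins)
        known = (-1.0, 1.0) if mode == "known_scale" else None
        fit = fit_alpha(prof, mode=mode, known=known)
        errs[i] = abs(fit.alpha_hat - alpha) / alpha
    return errs


def kw_type_i_error(
    n_sims: int = 10_000, group_size: int = 6, level: float = 0.05, seed: int = 0
) -> float:
    """Null rejection rate of the chi-square Kruskal-Wallis test for two equal groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        g = GroupedSamples.from_arrays([rng.normal(size=group_size), rng.normal(size=group_size)])
        if kruskal_wallis(g, method="chi2").p < level:
            rejections += 1
    return rejections / n_sims
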