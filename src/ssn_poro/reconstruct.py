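"""Reconstruction of the normalized solid stress from a 2-D stress map.

Pipeline mirroring the in vivo imaging procedure: a compression-induced
radial-stress map with an inclusion mask is reduced to a radial profile by
annular binning; the spatial-distribution parameter alpha is estimated by
bounded multi-start nonlinear least squares against the sinh-profile shape;
the fitted scale then normalizes the full map into a dimensionless SSn image
whose peak is ``1 - alpha_hat * cosech(alpha_hat)``.

Two fitting modes are exposed.  In ``known_scale`` the boundary stress
``sigma_RR^a`` and amplitude ``Psi`` are given (e.g. from Eshelby theory and
the applied pressure) and only alpha is fitted on the normalized profile.  In
``free_scale`` all three are estimated jointly; for a fixed alpha the model
``sigma_a - Psi * SSn(alpha, r)`` is linear in (sigma_a, Psi), so the joint fit
reduces to a 1-D search over log alpha with an inner weighted linear solve
(variable projection), which keeps the fit deterministic and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import RadialProfile, peak_ssn, sinh_ratio
from .phantom import ScalarMap

__all__ = [
    "RecoveryResult",
    "extract_radial_profile",
    "fit_alpha",
    "ssn_map",
    "mask_from_threshold",
]

_ALPHA_BOUNDS = (1e-3, 1e3)
_N_STARTS = 9


@dataclass
class RecoveryResult:
    """Result of an alpha fit on a radial stress profile.

    ``ssn_peak_hat`` is always ``1 - alpha_hat*cosech(alpha_hat)`` evaluated at
    the fitted alpha.  ``flags`` may contain ``non_identifiable`` (flat profile,
    no scale) and ``saturated`` (profile plateau: alpha is only a lower bound).
    """

    alpha_hat: float
    amplitude_hat: float
    boundary_hat: float
    ssn_peak_hat: float
    rss: float
    n_bins: int
    converged: bool
    mode: str
    flags: dict = field(default_factory=dict)


def extract_radial_profile(
    smap: ScalarMap,
    center_mm: Tuple[float, float],
    radius_mm: float,
    n_bins: int = 15,
) -> RadialProfile:
    """Average an axisymmetric map into equal-width annular bins of R/a.

    Pixels inside the mask (or, lacking one, inside the circle of
    ``radius_mm``) are binned by their normalized distance from the center into
    ``n_bins`` annuli over [0, 1]; per-bin means and pixel counts are returned
    at the bin centers.  Empty bins carry NaN values and zero counts.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be at least 4")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    rows, cols = smap.values.shape
    rr, cc = np.meshgrid(
        np.arange(rows) * smap.pixel_mm, np.arange(cols) * smap.pixel_mm, indexing="ij"
    )
    rho = np.hypot(rr - center_mm[0], cc - center_mm[1])
    inside = smap.mask if smap.mask is not None else rho <= radius_mm
    if not np.any(inside):
        raise ValueError("no pixels inside the inclusion mask")
    r_norm = np.clip(rho[inside] / radius_mm, 0.0, 1.0)
    vals = np.asarray(smap.values, dtype=float)[inside]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(r_norm, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    if counts.sum() == 0:
        raise ValueError("all annular bins are empty")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(
        r=centers, values=means, units=smap.units, counts=counts, pixel_r=r_norm, pixel_bin=idx
    )


def _fit_data(profile: RadialProfile):
    """Kept bins, weights, and the per-bin SSn model evaluator.

    Weights are pixel counts (1 for analytic profiles).  When the profile
    retains its pixel-level radii, the model prediction for a bin is the mean
    of SSn over that bin's actual pixel radii — the same averaging the data
    went through — so a noiseless map round-trips exactly; otherwise SSn is
    evaluated at the bin centers.
    """
    ok = np.isfinite(profile.values)
    if profile.counts is not None:
        w = profile.counts.astype(float)
        ok &= w > 0
    else:
        w = np.ones_like(profile.values)
    r, y, w = profile.r[ok], profile.values[ok], w[ok]
    if r.size < 4:
        raise ValueError("need at least 4 non-empty bins to fit")

    if profile.pixel_r is not None:
        kept = np.flatnonzero(ok)
        pos = -np.ones(int(profile.pixel_bin.max()) + 1, dtype=int)
        pos[kept] = np.arange(kept.size)
        sel = pos[profile.pixel_bin] >= 0
        u_r, inv = np.unique(profile.pixel_r[sel], return_inverse=True)
        # sparse averaging matrix: bin value = mean of model over the bin's pixels
        flat = pos[profile.pixel_bin[sel]] * u_r.size + inv
        weights = np.bincount(flat, minlength=kept.size * u_r.size).reshape(kept.size, u_r.size)
        avg = weights / weights.sum(axis=1, keepdims=True)

        def model_ssn(alpha: float) -> np.ndarray:
            return avg @ (1.0 - sinh_ratio(alpha, u_r))

    else:

        def model_ssn(alpha: float) -> np.ndarray:
            return 1.0 - sinh_ratio(alpha, r)

    return r, y, w, model_ssn


def _rss_known_scale(log_alpha: float, model_ssn, ssn_obs, w) -> float:
    return float(np.sum(w * (model_ssn(np.exp(log_alpha)) - ssn_obs) ** 2))


def _solve_scale(log_alpha: float, model_ssn, y, w):
    """Weighted linear solve for (sigma_a, Psi) at fixed alpha; returns (rss, sigma_a, psi)."""
    ssn = model_ssn(np.exp(log_alpha))
    A = np.column_stack([np.ones_like(y), -ssn])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    resid = y - A @ coef
    return float(np.sum(w * resid**2)), float(coef[0]), float(coef[1])


def fit_alpha(
    profile: RadialProfile,
    mode: str = "free_scale",
    known: Optional[Tuple[float, float]] = None,
) -> RecoveryResult:
    """Estimate alpha (and, in free_scale mode, the stress scale) from a profile.

    Parameters
    ----------
    profile : RadialProfile
        Binned radial SSc profile (kPa), e.g. from :func:`extract_radial_profile`.
    mode : {"free_scale", "known_scale"}
        ``known_scale`` requires ``known = (sigma_RR^a, Psi)`` in kPa and fits
        alpha on the normalized profile; ``free_scale`` estimates all three.
    known : tuple, optional
        Boundary stress and amplitude for ``known_scale``.

    The 1-D objective over log alpha is minimized from a fixed grid of 9
    log-spaced starts in [1e-3, 1e3]; the best residual sum of squares wins,
    ties resolved toward the smallest alpha, so the fit is deterministic.
    A flat profile (no resolvable amplitude) is returned with
    ``converged=False`` and the ``non_identifiable`` flag instead of raising.
    """
    if mode not in ("free_scale", "known_scale"):
        raise ValueError(f"mode must be 'free_scale' or 'known_scale', got {mode!r}")
    r, y, w, model_ssn = _fit_data(profile)
    lo, hi = np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1])
    starts = np.linspace(lo, hi, _N_STARTS)
    edges = np.concatenate([[lo], 0.5 * (starts[:-1] + starts[1:]), [hi]])

    if mode == "known_scale":
        if known is None:
            raise ValueError("known_scale mode requires known=(sigma_a, psi)")
        sigma_a, psi = known
        if abs(psi) < 1e-300:
            raise ValueError("degenerate normalization: known Psi is zero")
        ssn_obs = (y - sigma_a) / (-psi)
        objective = lambda la: _rss_known_scale(la, model_ssn, ssn_obs, w)
    else:
        objective = lambda la: _solve_scale(la, model_ssn, y, w)[0]

    candidates = []
    for i in range(_N_STARTS):
        res = minimize_scalar(
            objective, bounds=(edges[i], edges[i + 1]), method="bounded",
            options={"xatol": 1e-12},
        )
        candidates.append((float(res.fun), float(res.x), bool(res.success)))
    for x in (lo, hi):  # include the bounds themselves
        candidates.append((objective(x), x, True))
    best_rss = min(c[0] for c in candidates)
    # ties toward smallest alpha
    tol = 1e-12 * max(1.0, abs(best_rss))
    rss, log_alpha_hat, success = min(
        (c for c in candidates if c[0] <= best_rss + tol), key=lambda c: c[1]
    )
    # local polish around the winner for full floating-point accuracy
    res = minimize_scalar(
        objective,
        bounds=(max(lo, log_alpha_hat - 1e-2), min(hi, log_alpha_hat + 1e-2)),
        method="bounded",
        options={"xatol": 1e-14},
    )
    if res.fun <= rss:
        rss, log_alpha_hat = float(res.fun), float(res.x)
    alpha_hat = float(np.exp(log_alpha_hat))

    if mode == "known_scale":
        boundary_hat, amplitude_hat = float(sigma_a), float(psi)
    else:
        rss, boundary_hat, amplitude_hat = _solve_scale(log_alpha_hat, model_ssn, y, w)

    flags = {}
    converged = success
    contrast = float(np.max(y) - np.min(y))
    scale = max(abs(boundary_hat), abs(amplitude_hat), np.max(np.abs(y)), 1e-30)
    if abs(amplitude_hat) <= 1e-10 * scale or contrast == 0.0:
        flags["non_identifiable"] = True
        converged = False
    if (1.0 - sinh_ratio(alpha_hat, 0.5)) > 0.99 * peak_ssn(alpha_hat):
        # plateau covers half the radius: alpha is only lower-bound identifiable
        flags["saturated"] = True

    return RecoveryResult(
        alpha_hat=alpha_hat,
        amplitude_hat=amplitude_hat,
        boundary_hat=boundary_hat,
        ssn_peak_hat=peak_ssn(alpha_hat),
        rss=float(rss),
        n_bins=int(r.size),
        converged=converged,
        mode=mode,
        flags=flags,
    )


def ssn_map(smap: ScalarMap, fit: RecoveryResult) -> ScalarMap:
    """Normalize a stress map into the dimensionless SSn image.

    In-mask pixels become ``(value - sigma_a_hat) / (-Psi_hat)``; out-of-mask
    pixels are NaN and flagged in the metadata.  Values are not clipped; the
    fraction outside [-0.2, 1.2] is recorded in ``meta['fraction_outside']``.
    """
    if smap.mask is None:
        raise ValueError("ssn_map requires a map with an inclusion mask")
    if not fit.converged:
        raise ValueError("cannot normalize with a non-converged fit")
    if abs(fit.amplitude_hat) < 1e-300:
        raise ValueError("degenerate normalization: fitted amplitude is zero")
    out = np.full(smap.values.shape, np.nan, dtype=float)
    out[smap.mask] = (np.asarray(smap.values, dtype=float)[smap.mask] - fit.boundary_hat) / (
        -fit.amplitude_hat
    )
    inside = out[smap.mask]
    frac_outside = float(np.mean((inside < -0.2) | (inside > 1.2)))
    meta = dict(smap.meta)
    meta.update({"out_of_mask": "NaN", "fraction_outside": frac_outside})
    return ScalarMap(values=out, pixel_mm=smap.pixel_mm, units="dimensionless", mask=smap.mask, meta=meta)


def mask_from_threshold(smap: ScalarMap, quantile: float = 0.5) -> np.ndarray:
    """Crude intensity-threshold mask (pixels below the given quantile).

    Convenience for maps lacking a mask; phantom masks and manually segmented
    masks are the supported inputs for the pipeline proper.
    """
    thresh = np.quantile(np.asarray(smap.values, dtype=float), quantile)
    return np.asarray(smap.values) < thresh
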