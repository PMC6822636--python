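"""Closed-form model of solid stress in a spherical tumor under creep compression.

A poroelastic tumor of radius ``a`` embedded in normal tissue and loaded by a
constant (creep) pressure develops a compression-induced interstitial fluid
pressure with the radial profile

    p(R) = Psi * (1 - sinh(alpha*R/a) / ((R/a) * sinh(alpha)))

where ``alpha = a * sqrt((Lp/k) * S/V)`` is a dimensionless spatial-distribution
parameter combining vascular permeability ``Lp``, interstitial permeability
``k`` and the capillary surface-to-volume ratio ``S/V``.  The compression-induced
solid stress (SSc) is the boundary stress minus this fluid pressure, and the
growth-induced solid stress (SSg) that accumulates as the tumor grows shares the
same spatial shape.  Normalizing either stress by its boundary value and peak
amplitude therefore yields a single dimensionless field, the normalized solid
stress SSn(R) = 1 - sinh(alpha*R/a)/((R/a)*sinh(alpha)), which is zero at the
tumor boundary and maximal (SS_n,p = 1 - alpha*cosech(alpha)) at the center.

All stresses are in kPa, lengths in mm; radii are normalized to [0, 1] before
evaluation.  The model is static: the creep acquisition time is absorbed into
the amplitude Psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TransportProperties",
    "PressureProfileParams",
    "GrowthStressParams",
    "RadialProfile",
    "alpha_from_transport",
    "sinh_ratio",
    "fluid_pressure_profile",
    "compression_stress_profiles",
    "growth_stress_profiles",
    "ssn_profile",
    "peak_ssn",
    "normalize_growth_profile",
]


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class TransportProperties:
    """Fluid-transport constants of the tumor interstitium, in SI units.

    Parameters
    ----------
    lp : float
        Vascular permeability of the capillary walls (m Pa^-1 s^-1).
    k : float
        Interstitial (Darcy) permeability (m^2 Pa^-1 s^-1).
    sv : float
        Capillary surface-area-to-volume ratio (m^-1).
    """

    lp: float
    k: float
    sv: float

    def __post_init__(self) -> None:
        _require_positive("lp", self.lp)
        _require_positive("k", self.k)
        _require_positive("sv", self.sv)


def alpha_from_transport(a_mm: float, tp: TransportProperties) -> float:
    """Spatial-distribution parameter ``alpha = a * sqrt((Lp/k) * S/V)``.

    ``a_mm`` is the tumor radius in mm and is converted to meters before being
    combined with the SI transport properties.  ``alpha`` is dimensionless and
    strictly increasing in the radius.
    """
    _require_positive("a_mm", a_mm)
    a_m = a_mm * 1e-3
    return a_m * np.sqrt((tp.lp / tp.k) * tp.sv)


@dataclass(frozen=True)
class PressureProfileParams:
    """Parameters of the compression-induced fluid-pressure profile.

    ``psi_kpa`` is the amplitude Psi (kPa); it may alternatively be given
    through the source constant ``w_kpa`` with Psi = W / alpha**2.  The center
    peak pressure is ``P0 = Psi * (1 - alpha*cosech(alpha))``.
    """

    alpha: float
    psi_kpa: float
    a_mm: float
    w_kpa: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha)
        _require_positive("a_mm", self.a_mm)
        if not np.isfinite(self.psi_kpa):
            raise ValueError("psi_kpa must be finite")
        if self.w_kpa is not None:
            implied = self.w_kpa / self.alpha**2
            if abs(implied - self.psi_kpa) > 1e-12 * max(1.0, abs(self.psi_kpa)):
                raise ValueError(
                    f"inconsistent amplitude: w/alpha^2 = {implied!r} but psi_kpa = {self.psi_kpa!r}"
                )

    @property
    def p0_kpa(self) -> float:
        """Peak (center) fluid pressure ``Psi * (1 - alpha*cosech(alpha))``."""
        return self.psi_kpa * peak_ssn(self.alpha)


@dataclass(frozen=True)
class GrowthStressParams:
    """Amplitudes of the growth-induced solid-stress profiles.

    ``omega_bR`` / ``omega_bT`` are (minus) the radial / circumferential SSg at
    the tumor boundary; ``omega_pR`` / ``omega_pT`` set the additional stress
    accumulated toward the center.  The center peaks are
    ``S_R = -omega_bR - omega_pR*(1 - alpha*cosech(alpha))`` and analogously
    ``S_T`` for the circumferential component.
    """

    omega_bR: float
    omega_pR: float
    omega_bT: float
    omega_pT: float
    alpha: float
    a_mm: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha)
        _require_positive("a_mm", self.a_mm)
        for name in ("omega_bR", "omega_pR", "omega_bT", "omega_pT"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def peak_radial_kpa(self) -> float:
        return -self.omega_bR - self.omega_pR * peak_ssn(self.alpha)

    @property
    def peak_circumferential_kpa(self) -> float:
        return -self.omega_bT - self.omega_pT * peak_ssn(self.alpha)


@dataclass
class RadialProfile:
    """Samples of a radially symmetric field on the normalized radius R/a.

    ``r`` must be sorted strictly ascending within [0, 1].  ``counts`` holds the
    number of pixels averaged into each sample when the profile was extracted
    from an image (None for analytic profiles).  ``pixel_r`` / ``pixel_bin``
    optionally retain the normalized radius and bin index of every contributing
    pixel, so a fit can average the model over each annulus exactly as the
    data were averaged instead of evaluating it at the bin center.
    """

    r: np.ndarray
    values: np.ndarray
    units: str = "kPa"
    counts: Optional[np.ndarray] = field(default=None)
    pixel_r: Optional[np.ndarray] = field(default=None, repr=False)
    pixel_bin: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.values.shape:
            raise ValueError("r and values must be 1-D arrays of equal length")
        if self.r.size and (self.r.min() < 0 or self.r.max() > 1 + 1e-12):
            raise ValueError("normalized radii must lie in [0, 1]")
        if self.r.size > 1 and not np.all(np.diff(self.r) > 0):
            raise ValueError("r must be strictly ascending")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.r.shape:
                raise ValueError("counts must match r in shape")
        if (self.pixel_r is None) != (self.pixel_bin is None):
            raise ValueError("pixel_r and pixel_bin must be given together")
        if self.pixel_r is not None:
            self.pixel_r = np.asarray(self.pixel_r, dtype=float)
            self.pixel_bin = np.asarray(self.pixel_bin, dtype=int)
            if self.pixel_r.shape != self.pixel_bin.shape:
                raise ValueError("pixel_r and pixel_bin must have equal shape")


def _check_radii(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("normalized radii must lie in [0, 1]")
    return r


def sinh_ratio(alpha: float, r) -> np.ndarray:
    """Evaluate ``sinh(alpha*r) / (r*sinh(alpha))`` stably for r in [0, 1].

    Written as ``exp(alpha*(r-1)) * (1 - exp(-2*alpha*r)) / (r*(1 - exp(-2*alpha)))``
    so that no intermediate overflows even for alpha ~ 1e4.  At r = 0 the
    analytic limit ``alpha / sinh(alpha)`` is used (series for r < 1e-8).
    """
    _require_positive("alpha", alpha)
    r = _check_radii(r)
    scalar = np.ndim(r) == 0
    r = np.atleast_1d(r)
    out = np.empty_like(r)
    small = r < 1e-8
    rs = r[~small]
    denom = -np.expm1(-2.0 * alpha)
    out[~small] = np.exp(alpha * (rs - 1.0)) * (-np.expm1(-2.0 * alpha * rs)) / (rs * denom)
    if np.any(small):
        # sinh(alpha*r)/r -> alpha * (1 + (alpha*r)^2/6) as r -> 0
        limit = 2.0 * alpha * np.exp(-alpha) / denom  # alpha / sinh(alpha), overflow-free
        out[small] = limit * (1.0 + (alpha * r[small]) ** 2 / 6.0)
    return out[0] if scalar else out


def ssn_profile(alpha: float, r) -> RadialProfile:
    """Normalized solid stress ``SSn(r) = 1 - sinh(alpha*r)/(r*sinh(alpha))``.

    Dimensionless, zero at the boundary r = 1, maximal at the center where it
    equals ``peak_ssn(alpha)``; monotone nonincreasing in r.
    """
    r = np.atleast_1d(_check_radii(r))
    return RadialProfile(r=r, values=1.0 - sinh_ratio(alpha, r), units="dimensionless")


def peak_ssn(alpha: float) -> float:
    """Peak normalized solid stress ``SS_n,p = 1 - alpha*cosech(alpha)``.

    Strictly increasing in alpha, tending to 0 as alpha -> 0 and to 1 as
    alpha -> inf.  Evaluated overflow-free; a series is used for tiny alpha
    where the direct expression loses precision to cancellation.
    """
    _require_positive("alpha", alpha)
    if alpha < 1e-4:
        return alpha**2 / 6.0 - 7.0 * alpha**4 / 360.0
    return 1.0 - 2.0 * alpha * np.exp(-alpha) / (-np.expm1(-2.0 * alpha))


def fluid_pressure_profile(p: PressureProfileParams, r) -> RadialProfile:
    """Compression-induced fluid pressure ``p(r) = Psi*(1 - sinh(alpha r)/(r sinh alpha))``.

    Zero at the tumor boundary, ``P0`` at the center.
    """
    ssn = ssn_profile(p.alpha, r)
    return RadialProfile(r=ssn.r, values=p.psi_kpa * ssn.values, units="kPa")


def compression_stress_profiles(b, p: PressureProfileParams, r):
    """Radial and circumferential compression-induced solid stress (SSc).

    ``sigma_RR^c(r) = sigma_RR^a - p(r)`` and
    ``sigma_thth^c(r) = sigma_thth^a - p(r)`` where the boundary scalars come
    from ``b`` (a :class:`~ssn_poro.boundary_stress.BoundaryStress`).  Both
    profiles equal their boundary value at r = 1.
    """
    fp = fluid_pressure_profile(p, r)
    radial = RadialProfile(r=fp.r, values=b.s_RR_a - fp.values, units="kPa")
    circ = RadialProfile(r=fp.r, values=b.s_thth_a - fp.values, units="kPa")
    return radial, circ


def growth_stress_profiles(g: GrowthStressParams, r):
    """Radial and circumferential growth-induced solid stress (SSg).

    ``sigma_RR^g(r) = -omega_bR - omega_pR*SSn(r)`` and analogously for the
    circumferential component with (omega_bT, omega_pT).  At the boundary the
    profiles equal ``-omega_bR`` / ``-omega_bT``; at the center they reach the
    peaks ``S_R`` / ``S_T``.
    """
    ssn = ssn_profile(g.alpha, r)
    radial = RadialProfile(r=ssn.r, values=-g.omega_bR - g.omega_pR * ssn.values, units="kPa")
    circ = RadialProfile(r=ssn.r, values=-g.omega_bT - g.omega_pT * ssn.values, units="kPa")
    return radial, circ


def normalize_growth_profile(g: GrowthStressParams, r, component: str = "radial") -> RadialProfile:
    """Normalize an SSg profile to the dimensionless SSn shape.

    Computes ``(sigma^g + omega_b) / (-omega_p)`` from the growth-stress
    profiles; by construction this equals ``ssn_profile(alpha, r)`` for either
    component, which is the testable statement that growth- and
    compression-induced stress share one spatial distribution.
    """
    radial, circ = growth_stress_profiles(g, r)
    if component == "radial":
        omega_b, omega_p, prof = g.omega_bR, g.omega_pR, radial
    elif component == "circumferential":
        omega_b, omega_p, prof = g.omega_bT, g.omega_pT, circ
    else:
        raise ValueError(f"component must be 'radial' or 'circumferential', got {component!r}")
    if omega_p == 0:
        raise ValueError(f"degenerate normalization: peak amplitude for {component} component is zero")
    return RadialProfile(r=prof.r, values=(prof.values + omega_b) / (-omega_p), units="dimensionless")
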