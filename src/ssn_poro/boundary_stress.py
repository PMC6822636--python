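"""Boundary stress of a spherical tumor under remote uniaxial compression.

The 1-D stress model needs the two scalars ``sigma_RR^a`` and
``sigma_thetatheta^a`` — the radial and polar solid stress at the tumor
boundary.  For a stiff (or soft) spherical inclusion embedded in an infinite
matrix under a remote uniaxial load these follow from Eshelby's
equivalent-inclusion solution: the interior stress is uniform and is obtained
by solving the equivalent-eigenstrain system with the closed-form spherical
Eshelby tensor, whose components depend only on the matrix Poisson ratio
(e.g. S1111 = (7 - 5 nu)/(15 (1 - nu))).

The interior tensor is naturally expressed in the cylindrical coordinates of
the elastography experiment (compression along z); the spherical components on
the tumor surface follow from the standard second-order tensor rotation and are
reduced to scalars either on the compression axis, on the equator, or by a
surface-area-weighted average over the polar angle (the default, since the
spherically symmetric radial model needs theta-independent scalars).

Sign convention: compression negative; an applied creep pressure of P kPa
enters as ``sigma_applied = -P``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElasticProperties",
    "CylStressTensor",
    "BoundaryStress",
    "eshelby_interior_stress",
    "cyl_to_sph_stress",
    "boundary_stress_scalars",
]


@dataclass(frozen=True)
class ElasticProperties:
    """Drained isotropic elastic constants: Young's modulus (kPa), Poisson ratio."""

    E_kpa: float
    nu: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.E_kpa) or self.E_kpa <= 0:
            raise ValueError(f"E_kpa must be strictly positive, got {self.E_kpa!r}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"nu must lie in [0, 0.5), got {self.nu!r}")

    @property
    def shear_kpa(self) -> float:
        return self.E_kpa / (2.0 * (1.0 + self.nu))

    @property
    def bulk_kpa(self) -> float:
        return self.E_kpa / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def lame_lambda_kpa(self) -> float:
        return self.E_kpa * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class CylStressTensor:
    """Axisymmetric stress tensor in cylindrical components (kPa).

    For the uniform interior field of a spherical inclusion under an
    axisymmetric remote load the shear component ``s_rz`` vanishes.
    """

    s_rr: float
    s_phiphi: float
    s_zz: float
    s_rz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s_rr", "s_phiphi", "s_zz", "s_rz"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class BoundaryStress:
    """Spherical radial / polar stress scalars at the tumor boundary (kPa)."""

    s_RR_a: float
    s_thth_a: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s_RR_a) and np.isfinite(self.s_thth_a)):
            raise ValueError("boundary stress components must be finite")


def _stiffness_normal_block(props: ElasticProperties) -> np.ndarray:
    """3x3 stiffness acting on the normal strain components (rr, phiphi, zz)."""
    lam = props.lame_lambda_kpa
    mu = props.shear_kpa
    return lam * np.ones((3, 3)) + 2.0 * mu * np.eye(3)


def _eshelby_normal_block(nu: float) -> np.ndarray:
    """Normal-component block S_iijj of the spherical Eshelby tensor."""
    diag = (7.0 - 5.0 * nu) / (15.0 * (1.0 - nu))
    off = (5.0 * nu - 1.0) / (15.0 * (1.0 - nu))
    return off * np.ones((3, 3)) + (diag - off) * np.eye(3)


def eshelby_interior_stress(
    sigma_applied_kpa: float, incl: ElasticProperties, bg: ElasticProperties
) -> CylStressTensor:
    """Uniform interior stress of a spherical inhomogeneity under remote uniaxial load.

    Equivalent-inclusion method: the remote strain is ``eps_inf = C_m^-1 sigma_inf``
    and the equivalent eigenstrain solves
    ``[(C_i - C_m) S + C_m] eps* = (C_m - C_i) eps_inf``; the interior stress is
    then ``C_i (eps_inf + S eps*)``.  Only the normal components are involved for
    a uniaxial load along z, so the system is solved on the (rr, phiphi, zz)
    block.  Compression is negative (``sigma_applied_kpa < 0`` for compression).
    """
    if not np.isfinite(sigma_applied_kpa):
        raise ValueError("sigma_applied_kpa must be finite")
    C_m = _stiffness_normal_block(bg)
    C_i = _stiffness_normal_block(incl)
    S = _eshelby_normal_block(bg.nu)
    sigma_inf = np.array([0.0, 0.0, sigma_applied_kpa])
    eps_inf = np.linalg.solve(C_m, sigma_inf)
    eig = np.linalg.solve((C_i - C_m) @ S + C_m, (C_m - C_i) @ eps_inf)
    s_rr, s_phiphi, s_zz = C_i @ (eps_inf + S @ eig)
    return CylStressTensor(s_rr=s_rr, s_phiphi=s_phiphi, s_zz=s_zz, s_rz=0.0)


def cyl_to_sph_stress(t: CylStressTensor, theta: float):
    """Spherical stress components on a sphere from axisymmetric cylindrical ones.

    ``theta`` is the polar angle from the compression (z) axis, in radians.
    Returns ``(s_RR, s_thth, s_phph, s_Rth)``.  This is the in-plane rotation of
    a second-order tensor; the azimuthal component is unchanged and the trace is
    invariant.
    """
    if not (0.0 <= theta <= np.pi):
        raise ValueError(f"theta must lie in [0, pi], got {theta!r}")
    c, s = np.cos(theta), np.sin(theta)
    s_RR = t.s_zz * c * c + t.s_rr * s * s + 2.0 * t.s_rz * s * c
    s_thth = t.s_zz * s * s + t.s_rr * c * c - 2.0 * t.s_rz * s * c
    s_phph = t.s_phiphi
    s_Rth = (t.s_rr - t.s_zz) * s * c + t.s_rz * (c * c - s * s)
    return s_RR, s_thth, s_phph, s_Rth


_REDUCTIONS = ("angle_average", "axis", "equator")


def boundary_stress_scalars(
    sigma_applied_kpa: float,
    incl: ElasticProperties,
    bg: ElasticProperties,
    reduction: str = "angle_average",
) -> BoundaryStress:
    """Reduce the theta-dependent boundary stress to the two model scalars.

    ``angle_average`` (default) takes the surface-area-weighted mean over the
    polar angle (weight ``sin(theta)/2`` on [0, pi]; the mean of ``cos^2 theta``
    is 1/3), which is the least-committal reduction for the spherically
    symmetric 1-D model.  ``axis`` evaluates at theta = 0, ``equator`` at
    theta = pi/2.
    """
    t = eshelby_interior_stress(sigma_applied_kpa, incl, bg)
    if reduction == "axis":
        s_RR, s_thth, _, _ = cyl_to_sph_stress(t, 0.0)
    elif reduction == "equator":
        s_RR, s_thth, _, _ = cyl_to_sph_stress(t, np.pi / 2.0)
    elif reduction == "angle_average":
        # <cos^2> = 1/3, <sin^2> = 2/3, <sin*cos> = 0 under the sin(theta)/2 weight
        s_RR = t.s_zz / 3.0 + 2.0 * t.s_rr / 3.0
        s_thth = 2.0 * t.s_zz / 3.0 + t.s_rr / 3.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}; expected one of {_REDUCTIONS}")
    return BoundaryStress(s_RR_a=float(s_RR), s_thth_a=float(s_thth))
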