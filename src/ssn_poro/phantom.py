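"""Seeded synthetic phantoms for the stress-imaging pipeline.

Two generators:

* :func:`generate_ssc_map` builds a 2-D axisymmetric compression-induced
  radial-stress map of a spherical inclusion under creep compression.  Inside
  the inclusion the pixel value is the boundary stress minus the
  sinh-profile fluid pressure evaluated at the pixel's normalized radius;
  outside it is a constant background.  Additive zero-mean Gaussian noise is
  calibrated to a requested in-mask SNR in dB.  The imaging plane is assumed to
  pass through the sphere's center, and the exterior field is a constant (the
  reconstruction only consumes in-mask pixels).

* :func:`generate_cohort` emulates a longitudinal treated/untreated small-animal
  study: per-arm geometric weekly trajectories of the spatial-distribution
  parameter alpha with multiplicative lognormal observation noise, for the
  group-comparison statistics stage.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .boundary_stress import BoundaryStress
from .model_core import PressureProfileParams, sinh_ratio

__all__ = [
    "PhantomConfig",
    "ScalarMap",
    "CohortSpec",
    "generate_ssc_map",
    "generate_cohort",
]


@dataclass
class ScalarMap:
    """2-D scalar field with pixel spacing, units and an optional inclusion mask."""

    values: np.ndarray
    pixel_mm: float
    units: str
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, physics and noise settings of a synthetic stress map.

    ``center_mm`` is the inclusion center in (row, col) millimeters measured
    from the grid origin (pixel centers at ``index * pixel_mm``).  ``snr_db``
    is the ratio of in-mask signal power to noise power in dB;
    ``snr_db = inf`` disables noise.
    """

    grid_shape: Tuple[int, int]
    pixel_mm: float
    center_mm: Tuple[float, float]
    radius_mm: float
    pressure: PressureProfileParams
    boundary: BoundaryStress
    background_value_kpa: float = 0.0
    snr_db: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError("grid_shape must be at least 2x2")
        if self.pixel_mm <= 0 or self.radius_mm <= 0:
            raise ValueError("pixel_mm and radius_mm must be positive")
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")
        cr, cc = self.center_mm
        extent_r = (rows - 1) * self.pixel_mm
        extent_c = (cols - 1) * self.pixel_mm
        if (
            cr - self.radius_mm < 0
            or cc - self.radius_mm < 0
            or cr + self.radius_mm > extent_r
            or cc + self.radius_mm > extent_c
        ):
            raise ValueError("inclusion must lie fully inside the grid")


def generate_ssc_map(cfg: PhantomConfig):
    """Generate a radial-SSc map and return it with the ground-truth parameters.

    Inside the inclusion the noiseless value is ``sigma_RR^a - p(rho/a)``;
    outside it is ``background_value_kpa``.  Gaussian noise is added everywhere
    with variance ``var(signal_in_mask) / 10^(snr_db/10)``.

    Returns
    -------
    (ScalarMap, dict)
        The map (with inclusion mask) and a truth dict holding the
        :class:`PressureProfileParams` and :class:`BoundaryStress` used.
    """
    rows, cols = cfg.grid_shape
    rr, cc = np.meshgrid(
        np.arange(rows) * cfg.pixel_mm, np.arange(cols) * cfg.pixel_mm, indexing="ij"
    )
    rho = np.hypot(rr - cfg.center_mm[0], cc - cfg.center_mm[1])
    mask = rho <= cfg.radius_mm

    values = np.full((rows, cols), cfg.background_value_kpa, dtype=float)
    r_norm = np.clip(rho[mask] / cfg.radius_mm, 0.0, 1.0)
    pressures = cfg.pressure.psi_kpa * (1.0 - sinh_ratio(cfg.pressure.alpha, r_norm))
    values[mask] = cfg.boundary.s_RR_a - pressures

    if np.isfinite(cfg.snr_db):
        # signal power = in-mask variance: the spatial stress contrast carries
        # the information; a constant offset does not make a map less noisy
        signal_power = float(np.var(values[mask]))
        noise_var = signal_power / 10.0 ** (cfg.snr_db / 10.0)
        rng = np.random.default_rng(cfg.seed)
        values = values + rng.normal(0.0, np.sqrt(noise_var), size=values.shape)

    smap = ScalarMap(
        values=values,
        pixel_mm=cfg.pixel_mm,
        units="kPa",
        mask=mask,
        meta={
            "center_mm": list(cfg.center_mm),
            "radius_mm": cfg.radius_mm,
            "snr_db": cfg.snr_db,
            "seed": cfg.seed,
        },
    )
    truth = {"pressure": cfg.pressure, "boundary": cfg.boundary}
    return smap, truth


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal two-arm cohort of alpha estimates.

    Per subject, ``alpha_true(week) = alpha_start * multiplier**(week-1)`` with
    the arm's weekly multiplier (> 1 untreated: stress concentrates as the tumor
    grows; < 1 treated); the observed value carries multiplicative lognormal
    noise with log-scale standard deviation ``subject_lognormal_sd``.
    """

    n_per_arm: int = 6
    weeks: int = 3
    alpha_start: float = 2.0
    weekly_multiplier_untreated: float = 1.5
    weekly_multiplier_treated: float = 0.7
    subject_lognormal_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1 or self.weeks < 1:
            raise ValueError("n_per_arm and weeks must be positive")
        if self.alpha_start <= 0:
            raise ValueError("alpha_start must be positive")
        if self.weekly_multiplier_untreated <= 0 or self.weekly_multiplier_treated <= 0:
            raise ValueError("weekly multipliers must be positive")
        if self.subject_lognormal_sd < 0:
            raise ValueError("subject_lognormal_sd must be nonnegative")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the cohort table: columns arm, subject, week, alpha_true, alpha_observed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for arm, mult in (
        ("untreated", spec.weekly_multiplier_untreated),
        ("treated", spec.weekly_multiplier_treated),
    ):
        for subject in range(1, spec.n_per_arm + 1):
            for week in range(1, spec.weeks + 1):
                alpha_true = spec.alpha_start * mult ** (week - 1)
                noise = np.exp(rng.normal(0.0, spec.subject_lognormal_sd)) if spec.subject_lognormal_sd > 0 else 1.0
                rows.append(
                    {
                        "arm": arm,
                        "subject": f"{arm[0]}{subject:02d}",
                        "week": week,
                        "alpha_true": alpha_true,
                        "alpha_observed": alpha_true * noise,
                    }
                )
    return pd.DataFrame(rows, columns=["arm", "subject", "week", "alpha_true", "alpha_observed"])
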