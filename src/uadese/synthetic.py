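"""Truth-known synthetic data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and each
inverts an estimator in the package, so generator/estimator round trips
close exactly at zero noise: a quadratic surface plus homoscedastic
Gaussian replicate noise for design-table responses, absorbance pairs
that evaluate to a prescribed yield under the pH-differential formula,
and peak-area tables with prescribed purities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assays import PhDiffMeasurement, PuritySet
from .design import DesignTable
from .rsm import QuadraticModel, model_matrix

__all__ = [
    "DEFAULT_NOISE_SD",
    "SurfaceSpec",
    "reference_surface",
    "simulate_bbd_responses",
    "simulate_ph_diff",
    "simulate_peak_areas",
]

# Replicate SD matching a pure-error mean square of ~1.212e-3 (mg/g)^2,
# the scatter level of quintuplicate center runs in this assay.
DEFAULT_NOISE_SD = float(np.sqrt(1.212e-3))  # ~0.0348 mg/g


@dataclass
class SurfaceSpec:
    """True quadratic surface plus replicate noise level.

    ``coefficients`` follows the same canonical term order as
    :class:`~uadese.rsm.QuadraticModel` (intercept, linear, quadratic,
    pairwise interactions).
    """

    coefficients: np.ndarray
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_model(
        cls, model: QuadraticModel, noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0
    ) -> "SurfaceSpec":
        return cls(model.coefficients.copy(), noise_sd=noise_sd, seed=seed)


def reference_surface(noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0) -> SurfaceSpec:
    """Default 4-factor truth with realistic effect sizes.

    The coefficient vector is the reduced significance-filtered model of the
    raspberry-extraction study (intercept 1.32, dominant negative quadratic
    curvature, two active interactions), so recovery tests exercise effects
    of the magnitude real extraction data shows.
    """
    coefs = np.zeros(15)
    # order: Intercept, X1..X4, X1^2..X4^2, X1X2, X1X3, X1X4, X2X3, X2X4, X3X4
    coefs[0] = 1.32
    coefs[1] = -0.028
    coefs[3] = 0.036
    coefs[4] = 0.02
    coefs[5] = -0.12
    coefs[6] = -0.038
    coefs[7] = -0.10
    coefs[8] = -0.045
    coefs[11] = 0.056  # X1*X4
    coefs[12] = 0.037  # X2*X3
    return SurfaceSpec(coefs, noise_sd=noise_sd, seed=seed)


def simulate_bbd_responses(spec: SurfaceSpec, design: DesignTable) -> DesignTable:
    """Evaluate the true surface on a design and add Gaussian replicate noise."""
    k = design.n_factors
    n_terms = 1 + 2 * k + k * (k - 1) // 2
    if spec.coefficients.shape != (n_terms,):
        raise ValueError(
            f"spec has {spec.coefficients.shape[0]} coefficients but a "
            f"{k}-factor design needs {n_terms}"
        )
    truth = model_matrix(design.coded_matrix) @ spec.coefficients
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(truth)) if spec.noise_sd > 0 else 0.0
    return design.with_responses(truth + noise)


def simulate_ph_diff(
    true_yield: float,
    *,
    dilution_factor: float = 1.0,
    volume: float = 0.02,
    mass: float = 1.0,
    path_length: float = 1.0,
    baseline_a700: float = 0.02,
    ph45_a510: float = 0.05,
    absorbance_noise_sd: float = 0.0,
    seed: int = 0,
) -> PhDiffMeasurement:
    """Construct absorbance readings whose pH-differential evaluation is ``true_yield``.

    Inverts the yield formula for the pH 1.0 A510 reading given plausible
    values for the other three absorbances; optional Gaussian noise is added
    to all four readings independently.
    """
    if true_yield < 0:
        raise ValueError("true_yield must be >= 0")
    from .assays import C3G_MOLAR_ABSORPTIVITY, C3G_MOLAR_MASS

    dd = (
        true_yield
        * mass
        * C3G_MOLAR_ABSORPTIVITY
        * path_length
        / (C3G_MOLAR_MASS * dilution_factor * 1000.0 * volume)
    )
    a510_ph1 = dd + ph45_a510 + baseline_a700  # makes the double difference equal dd
    readings = np.array([a510_ph1, baseline_a700, ph45_a510, 0.0])
    if absorbance_noise_sd > 0:
        rng = np.random.default_rng(seed)
        readings = readings + rng.normal(0.0, absorbance_noise_sd, size=4)
    return PhDiffMeasurement(
        a510_ph1=float(readings[0]),
        a700_ph1=float(readings[1]),
        a510_ph45=float(readings[2]),
        a700_ph45=float(readings[3]),
        dilution_factor=dilution_factor,
        volume=volume,
        mass=mass,
        path_length=path_length,
    )


def simulate_peak_areas(
    true_purities: Sequence[float],
    total_area: float = 1000.0,
    factors: Optional[Sequence[float]] = None,
    seed: int = 0,
    area_noise_sd: float = 0.0,
) -> PuritySet:
    """Peak areas whose corrected area fractions equal ``true_purities`` (percent)."""
    w = np.asarray(true_purities, dtype=float)
    if not np.isclose(w.sum(), 100.0):
        raise ValueError(f"purities must sum to 100, got {w.sum()}")
    if total_area <= 0:
        raise ValueError("total_area must be > 0")
    f = (
        np.ones_like(w)
        if factors is None
        else np.asarray(factors, dtype=float)
    )
    if f.shape != w.shape:
        raise ValueError("factors must match purities in length")
    areas = (w / 100.0) * total_area / f
    if area_noise_sd > 0:
        rng = np.random.default_rng(seed)
        areas = np.clip(areas + rng.normal(0.0, area_noise_sd, size=areas.shape), 0, None)
    return PuritySet(areas=tuple(float(a) for a in areas), factors=tuple(float(x) for x in f))
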