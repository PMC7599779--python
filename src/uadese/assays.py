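"""Assay arithmetic for the extraction and purification workflow.

Covers the pH-differential anthocyanin yield, HPLC area-normalized purity,
the counter-current-chromatography partition coefficient K with its
solvent-system screening window, stationary-phase retention, and a minimal
UV-Vis classification rule separating anthocyanins (absorption near 280 and
520 nm) from other flavonoids (240-280 and 300-400 nm only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "C3G_MOLAR_MASS",
    "C3G_MOLAR_ABSORPTIVITY",
    "PhDiffMeasurement",
    "PartitionMeasurement",
    "PuritySet",
    "anthocyanin_yield",
    "purity",
    "partition_coefficient",
    "screen_solvent_systems",
    "stationary_retention",
    "classify_uv_spectrum",
]

# cyanidin-3-glucoside, the quantification reference of the pH-differential method
C3G_MOLAR_MASS = 449.2  # g/mol
C3G_MOLAR_ABSORPTIVITY = 26_900.0  # L/(mol*cm)


@dataclass(frozen=True)
class PhDiffMeasurement:
    """One pH-differential measurement pair.

    Absorbances at 510 and 700 nm in pH 1.0 and pH 4.5 buffers; 700 nm
    corrects for haze.  ``volume`` is the total extraction-solvent volume in
    liters by default (see :func:`anthocyanin_yield` for the alternative
    literal-mL convention), ``mass`` the powder weight in grams,
    ``path_length`` the cuvette path in cm.
    """

    a510_ph1: float
    a700_ph1: float
    a510_ph45: float
    a700_ph45: float
    dilution_factor: float = 1.0
    volume: float = 0.02
    mass: float = 1.0
    path_length: float = 1.0
    mol_weight: float = C3G_MOLAR_MASS
    epsilon: float = C3G_MOLAR_ABSORPTIVITY

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def double_difference(self) -> float:
        """(A510 - A700) at pH 1.0 minus (A510 - A700) at pH 4.5."""
        return (self.a510_ph1 - self.a700_ph1) - (self.a510_ph45 - self.a700_ph45)


@dataclass(frozen=True)
class PartitionMeasurement:
    """Peak areas of one component in the two phases of a solvent system."""

    component: str
    area_upper: float
    area_lower: float

    def __post_init__(self) -> None:
        if self.area_upper < 0 or self.area_lower < 0:
            raise ValueError("peak areas must be >= 0")


@dataclass(frozen=True)
class PuritySet:
    """Per-component HPLC peak areas with response correction factors."""

    areas: tuple[float, ...]
    factors: tuple[float, ...] = ()
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.areas:
            raise ValueError("at least one peak area is required")
        if any(a < 0 for a in self.areas):
            raise ValueError("peak areas must be >= 0")
        if not self.factors:
            object.__setattr__(self, "factors", (1.0,) * len(self.areas))
        if len(self.factors) != len(self.areas):
            raise ValueError("factors must match areas in length")
        if any(f <= 0 for f in self.factors):
            raise ValueError("correction factors must be > 0")
        if not any(a > 0 for a in self.areas):
            raise ValueError("all peak areas are zero; purity undefined")


def anthocyanin_yield(meas: PhDiffMeasurement, *, volume_in_ml: bool = False) -> float:
    """Total monomeric anthocyanin yield (mg/g) by the pH-differential method.

    c = ddA * M * DF * 1000 / (eps * L)   [mg/L, as cyanidin-3-glucoside]
    yield = c * V / m                     [mg/g]

    with ddA the double absorbance difference, M the reference molar mass,
    DF the dilution factor, eps the molar absorptivity and L the path
    length.  ``volume_in_ml`` switches to the literal convention where V is
    in mL and still multiplied by 1000 (some method write-ups carry both;
    the default liter reading is the dimensionally consistent one).

    A negative double difference signals a measurement problem and triggers
    a warning, but the value is returned unclamped.
    """
    dd = meas.double_difference
    if dd < 0:
        warnings.warn(
            f"negative double absorbance difference ({dd:.4f}); "
            "check buffer preparation or baseline",
            UserWarning,
            stacklevel=2,
        )
    conc_mg_per_l = dd * meas.mol_weight * meas.dilution_factor * 1000.0 / (
        meas.epsilon * meas.path_length
    )
    # volume_in_ml keeps the x1000 factor while reading meas.volume as mL,
    # reproducing the literal (dimensionally inconsistent) write-up exactly
    return conc_mg_per_l * meas.volume / meas.mass


def purity(pset: PuritySet) -> np.ndarray:
    """Area-normalized purity per component, in percent (sums to 100)."""
    a = np.asarray(pset.areas, dtype=float)
    f = np.asarray(pset.factors, dtype=float)
    w = f * a
    return 100.0 * w / w.sum()


def partition_coefficient(meas: PartitionMeasurement) -> float:
    """Partition coefficient K = A_upper / A_lower."""
    if meas.area_lower == 0:
        raise ValueError(
            f"component {meas.component!r}: lower-phase area is zero, K undefined"
        )
    return meas.area_upper / meas.area_lower


@dataclass(frozen=True)
class ScreeningResult:
    system: str
    accepted: bool
    out_of_range: tuple[str, ...] = ()

    @property
    def reason(self) -> str:
        if self.accepted:
            return "all components partition within the window"
        return "out-of-window components: " + ", ".join(self.out_of_range)


def screen_solvent_systems(
    k_table: Mapping[str, Mapping[str, float]],
    k_min: float = 0.5,
    k_max: float = 2.0,
) -> list[ScreeningResult]:
    """Screen candidate solvent systems by the K suitability window.

    A system is accepted only when every target component's partition
    coefficient lies in [k_min, k_max]: below the window the compound
    elutes with the solvent front (washed out too quickly), above it the
    run time grows and peaks broaden.

    Parameters
    ----------
    k_table
        ``{system: {component: K}}``.
    """
    if not 0 <= k_min < k_max:
        raise ValueError("require 0 <= k_min < k_max")
    if not k_table:
        raise ValueError("empty K table")
    results = []
    for system, comps in k_table.items():
        if not comps:
            raise ValueError(f"system {system!r} has no components")
        bad = tuple(
            f"{c} (K={k:.3g}, {'washed out quickly' if k < k_min else 'retained too long'})"
            for c, k in comps.items()
            if not k_min <= k <= k_max
        )
        results.append(ScreeningResult(system=system, accepted=not bad, out_of_range=bad))
    return results


def stationary_retention(v_stationary: float, v_column: float) -> float:
    """Stationary-phase retention S_r = (V_s / V_c) x 100%."""
    if v_column <= 0:
        raise ValueError("column capacity must be > 0")
    if v_stationary < 0:
        raise ValueError("stationary-phase volume must be >= 0")
    if v_stationary > v_column:
        raise ValueError(
            f"stationary-phase volume {v_stationary} exceeds column capacity {v_column}"
        )
    return 100.0 * v_stationary / v_column


def classify_uv_spectrum(
    peaks: Sequence[float],
    tol: float = 15.0,
) -> str:
    """Classify a UV-Vis absorption spectrum by its peak wavelengths.

    'anthocyanin' requires peaks near both 280 nm and 520 nm (within
    ``tol``); 'non-anthocyanin flavonoid' requires peaks in the 240-280 and
    300-400 nm bands with nothing near 520 nm; anything else is
    'unclassified'.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    pk = np.asarray(peaks, dtype=float)
    near_280 = np.any(np.abs(pk - 280) <= tol)
    near_520 = np.any(np.abs(pk - 520) <= tol)
    if near_280 and near_520:
        return "anthocyanin"
    band_uv = np.any((pk >= 240) & (pk <= 280))
    band_mid = np.any((pk >= 300) & (pk <= 400))
    if band_uv and band_mid and not near_520:
        return "non-anthocyanin flavonoid"
    return "unclassified"
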