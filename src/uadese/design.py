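"""Box-Behnken designs and coded/natural factor-level mapping.

A Box-Behnken design (BBD) for k three-level factors places runs at the
midpoints of the edges of the factor cube: every unordered factor pair
contributes the four sign combinations (-1,-1), (-1,+1), (+1,-1), (+1,+1)
with all other factors at 0, giving 2k(k-1) edge runs, plus n_c replicated
center runs used to estimate pure error.

Factors are handled on two scales.  The *coded* scale puts the low, center
and high levels at -1, 0 and +1; fitting happens there because the linear
and interaction columns of a BBD are mutually orthogonal.  The *natural*
scale is the physical one (%, W, degC, min) related affinely to the coded
scale by ``natural = center + step * coded``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorDef",
    "DesignRun",
    "DesignTable",
    "BoundaryMaximumWarning",
    "build_bbd",
    "select_bbd_levels",
    "read_design_csv",
    "write_design_csv",
]

RESPONSE_COLUMN = "yield_mg_per_g"


class BoundaryMaximumWarning(UserWarning):
    """Screening maximum sits at the edge of the screened range."""


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor with its coded-to-natural mapping.

    ``center`` is the natural value at coded 0 and ``step`` the half-range,
    so coded -1/0/+1 map to center-step / center / center+step.
    """

    name: str
    units: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")

    def to_natural(self, coded: float) -> float:
        return self.center + self.step * coded

    def to_coded(self, natural: float) -> float:
        return (natural - self.center) / self.step


@dataclass
class DesignRun:
    """A single design run: coded levels plus the measured response, if any."""

    run_id: int
    coded_levels: tuple[float, ...]
    response: Optional[float] = None

    def __post_init__(self) -> None:
        if self.run_id < 1:
            raise ValueError("run_id must be a positive integer")


@dataclass
class DesignTable:
    """An ordered set of design runs over a fixed factor list.

    The unit of model fitting: ``coded_matrix`` and ``responses`` feed the
    least-squares fit, and center-point replicates supply the pure-error
    degrees of freedom for the lack-of-fit test.
    """

    factors: list[FactorDef]
    runs: list[DesignRun] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.factors)
        for run in self.runs:
            if len(run.coded_levels) != k:
                raise ValueError(
                    f"run {run.run_id} has {len(run.coded_levels)} coded levels, "
                    f"expected {k}"
                )

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([run.coded_levels for run in self.runs], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        """Response vector; NaN where a run has not been measured."""
        return np.array(
            [np.nan if run.response is None else run.response for run in self.runs]
        )

    def center_responses(self) -> np.ndarray:
        """Measured responses of the all-zero (center) runs."""
        out = [
            run.response
            for run in self.runs
            if all(level == 0 for level in run.coded_levels)
            and run.response is not None
        ]
        return np.array(out, dtype=float)

    def missing_response_ids(self) -> list[int]:
        return [run.run_id for run in self.runs if run.response is None]

    def with_responses(self, values: Sequence[float]) -> "DesignTable":
        if len(values) != self.n_runs:
            raise ValueError(f"expected {self.n_runs} responses, got {len(values)}")
        runs = [
            DesignRun(run.run_id, run.coded_levels, float(v))
            for run, v in zip(self.runs, values)
        ]
        return DesignTable(self.factors, runs)

    def encode(self, natural_point: Sequence[float]) -> np.ndarray:
        """Map a natural-scale point to coded units."""
        if len(natural_point) != self.n_factors:
            raise ValueError(
                f"point has {len(natural_point)} entries, expected {self.n_factors}"
            )
        return np.array(
            [f.to_coded(x) for f, x in zip(self.factors, natural_point)]
        )

    def decode(self, coded_point: Sequence[float]) -> np.ndarray:
        """Map a coded point back to natural units (affine: center + step*coded)."""
        if len(coded_point) != self.n_factors:
            raise ValueError(
                f"point has {len(coded_point)} entries, expected {self.n_factors}"
            )
        return np.array(
            [f.to_natural(x) for f, x in zip(self.factors, coded_point)]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coded_matrix, columns=[f.name for f in self.factors])
        df.insert(0, "run_id", [run.run_id for run in self.runs])
        for f in self.factors:
            df[f"{f.name}_nat"] = f.center + f.step * df[f.name]
        df[RESPONSE_COLUMN] = self.responses
        return df


def encode(natural_point: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Natural -> coded, one value per factor."""
    if len(natural_point) != len(factors):
        raise ValueError(f"point has {len(natural_point)} entries, expected {len(factors)}")
    return np.array([f.to_coded(x) for f, x in zip(factors, natural_point)])


def decode(coded_point: Sequence[float], factors: Sequence[FactorDef]) -> np.ndarray:
    """Coded -> natural, the exact affine inverse of :func:`encode`."""
    if len(coded_point) != len(factors):
        raise ValueError(f"point has {len(coded_point)} entries, expected {len(factors)}")
    return np.array([f.to_natural(x) for f, x in zip(factors, coded_point)])


def build_bbd(
    factors: Sequence[FactorDef],
    n_center: int,
    *,
    shuffle_seed: Optional[int] = None,
) -> DesignTable:
    """Construct a Box-Behnken design.

    Parameters
    ----------
    factors
        Between 3 and 7 factor definitions.
    n_center
        Number of replicated center runs (>= 1); replication at the center
        is what makes the pure-error estimate possible.
    shuffle_seed
        If given, the run order is randomized with this seed.  Off by
        default: the fit is order-invariant and deterministic fixtures are
        easier to audit.

    Returns
    -------
    DesignTable
        2k(k-1) edge runs (factor pairs in lexicographic order, each pair
        contributing (-1,-1), (-1,+1), (+1,-1), (+1,+1)) followed by the
        center runs.
    """
    k = len(factors)
    if k < 3:
        raise ValueError(
            f"a Box-Behnken design needs at least 3 factors (got {k}); "
            "with 2 factors the edge-midpoint construction is undefined"
        )
    if k > 7:
        raise ValueError(f"at most 7 factors supported, got {k}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")

    rows: list[tuple[float, ...]] = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
            level = [0.0] * k
            level[i], level[j] = float(si), float(sj)
            rows.append(tuple(level))
    rows.extend([(0.0,) * k] * n_center)

    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        rows = [rows[i] for i in rng.permutation(len(rows))]

    runs = [DesignRun(run_id=i + 1, coded_levels=row) for i, row in enumerate(rows)]
    return DesignTable(list(factors), runs)


def select_bbd_levels(
    screening: Sequence[tuple[float, float]],
) -> tuple[float, float, tuple[float, float, float]]:
    """Pick BBD center and step from single-factor screening results.

    The center is the screened level with the highest mean yield; the step
    is the screening spacing, so the three BBD levels are the argmax and its
    two neighbours.  If the best level sits on the boundary of the screened
    range the BBD would extrapolate beyond tested conditions, so a
    :class:`BoundaryMaximumWarning` is issued.

    Parameters
    ----------
    screening
        (level, mean yield) pairs for one factor, at >= 3 equally spaced
        levels.

    Returns
    -------
    (center, step, levels)
        ``levels`` is the (low, center, high) triple.
    """
    if len(screening) < 3:
        raise ValueError("need at least 3 screening levels")
    levels = np.array([lv for lv, _ in screening], dtype=float)
    yields = np.array([y for _, y in screening], dtype=float)
    order = np.argsort(levels)
    levels, yields = levels[order], yields[order]
    spacings = np.diff(levels)
    if not np.allclose(spacings, spacings[0]):
        raise ValueError("screening levels must be equally spaced")
    step = float(spacings[0])
    best = int(np.argmax(yields))
    center = float(levels[best])
    if best in (0, len(levels) - 1):
        warnings.warn(
            f"screening maximum at the boundary level {center}; the design "
            "will extrapolate beyond the screened range",
            BoundaryMaximumWarning,
            stacklevel=2,
        )
    return center, step, (center - step, center, center + step)


def write_design_csv(table: DesignTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_design_csv(path, factors: Sequence[FactorDef]) -> DesignTable:
    """Read a design table written by :func:`write_design_csv`.

    Coded-level columns (named after the factors) are authoritative; the
    ``*_nat`` columns are informational and ignored on input.
    """
    df = pd.read_csv(path)
    missing = [f.name for f in factors if f.name not in df.columns]
    if missing:
        raise ValueError(f"design file {path} lacks coded columns: {missing}")
    runs = []
    has_response = RESPONSE_COLUMN in df.columns
    for i, row in df.iterrows():
        resp = None
        if has_response and not pd.isna(row[RESPONSE_COLUMN]):
            resp = float(row[RESPONSE_COLUMN])
        run_id = int(row["run_id"]) if "run_id" in df.columns else i + 1
        runs.append(
            DesignRun(
                run_id=run_id,
                coded_levels=tuple(float(row[f.name]) for f in factors),
                response=resp,
            )
        )
    return DesignTable(list(factors), runs)
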