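"""Second-order response-surface fitting, ANOVA and model reduction.

The full second-order polynomial for k coded factors,

    Y = b0 + sum_j b_j X_j + sum_j b_jj X_j^2 + sum_{i<j} b_ij X_i X_j + e,

is fitted by ordinary least squares in coded space.  The ANOVA reports the
partial (drop-one-term) extra sum of squares for every term, splits the
residual into lack-of-fit and pure error using the center-point replicates,
and carries the usual fit statistics (R^2, adjusted R^2, CV%).  Model
reduction removes linear and interaction terms that fail a significance
threshold; quadratic terms are kept when significant.  Reduction does not
enforce hierarchy — a quadratic may survive while its linear parent is
dropped — matching common response-surface practice.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, FactorDef

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "fit_quadratic",
    "anova",
    "reduce_model",
    "surface_grid",
    "diagnostics",
    "term_names",
]


def term_names(factor_names: Sequence[str]) -> list[str]:
    """Canonical term order: intercept, linear, quadratic, pairwise interactions."""
    k = len(factor_names)
    names = ["Intercept"]
    names += list(factor_names)
    names += [f"{n}^2" for n in factor_names]
    names += [
        f"{factor_names[i]}*{factor_names[j]}"
        for i, j in itertools.combinations(range(k), 2)
    ]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix (1 + k + k + k(k-1)/2 columns) in coded units."""
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, j] for j in range(k)]
    cols += [coded[:, j] ** 2 for j in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """A fitted (or constructed) second-order polynomial in coded space.

    ``coefficients`` holds one value per term in canonical order; excluded
    terms (``included`` False) carry coefficient exactly 0.  ``factors``
    enables decoding predictions and optima back to natural units.
    """

    factors: list[FactorDef]
    coefficients: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.factors)
        n_terms = 1 + 2 * k + k * (k - 1) // 2
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.coefficients.shape != (n_terms,):
            raise ValueError(f"expected {n_terms} coefficients, got {self.coefficients.shape}")
        if self.included.shape != (n_terms,):
            raise ValueError(f"expected {n_terms} inclusion flags")
        if np.any(self.coefficients[~self.included] != 0):
            raise ValueError("excluded terms must carry coefficient exactly 0")

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def term_names(self) -> list[str]:
        return term_names([f.name for f in self.factors])

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def linear(self) -> np.ndarray:
        k = self.n_factors
        return self.coefficients[1 : 1 + k]

    @property
    def quadratic(self) -> np.ndarray:
        k = self.n_factors
        return self.coefficients[1 + k : 1 + 2 * k]

    @property
    def interaction(self) -> dict[tuple[int, int], float]:
        k = self.n_factors
        pairs = list(itertools.combinations(range(k), 2))
        vals = self.coefficients[1 + 2 * k :]
        return {pair: float(v) for pair, v in zip(pairs, vals)}

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.term_names.index(name)])

    def predict(self, coded_point: Sequence[float]) -> float:
        """Evaluate the polynomial (included terms only) at one coded point."""
        pt = np.asarray(coded_point, dtype=float)
        if pt.shape != (self.n_factors,):
            raise ValueError(f"point must have {self.n_factors} entries, got {pt.shape}")
        row = model_matrix(pt[None, :])[0]
        return float(row @ self.coefficients)

    def predict_many(self, coded_points: np.ndarray) -> np.ndarray:
        pts = np.asarray(coded_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.n_factors:
            raise ValueError(f"points must be (n, {self.n_factors})")
        return model_matrix(pts) @ self.coefficients

    def quadratic_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (c, b, A) with Y(x) = c + b.x + x' A x; A symmetric."""
        k = self.n_factors
        b = self.linear.copy()
        A = np.diag(self.quadratic.astype(float))
        for (i, j), v in self.interaction.items():
            A[i, j] += v / 2
            A[j, i] += v / 2
        return self.intercept, b, A

    def natural_coefficients(self) -> dict[str, float]:
        """Re-express the polynomial in natural units.

        Provided for reporting only; inference always happens in coded
        space, where the design columns are orthogonal.
        """
        c, b, A = self.quadratic_form()
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        # x_coded = (x_nat - center)/step; substitute and collect.
        Anat = A / np.outer(steps, steps)
        bnat = b / steps - 2 * Anat @ centers
        cnat = c - b @ (centers / steps) + centers @ Anat @ centers
        out = {"Intercept": float(cnat)}
        names = [f.name for f in self.factors]
        for j, n in enumerate(names):
            out[n] = float(bnat[j])
        for j, n in enumerate(names):
            out[f"{n}^2"] = float(Anat[j, j])
        for i, j in itertools.combinations(range(self.n_factors), 2):
            out[f"{names[i]}*{names[j]}"] = float(2 * Anat[i, j])
        return out

    def to_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "units": f.units, "center": f.center, "step": f.step}
                for f in self.factors
            ],
            "terms": [
                {"name": n, "coefficient": float(c), "included": bool(m)}
                for n, c, m in zip(self.term_names, self.coefficients, self.included)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        factors = [FactorDef(**f) for f in d["factors"]]
        coefs = np.array([t["coefficient"] for t in d["terms"]])
        included = np.array([t["included"] for t in d["terms"]])
        return cls(factors, coefs, included)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AnovaTable:
    """Per-term and pooled variance decomposition of a quadratic fit.

    ``rows`` has one entry per model term plus Model, Residual, Lack of fit,
    Pure error and Corrected total, each with sum of squares, degrees of
    freedom, mean square, F and p where defined.  Additivity holds by
    construction: SS_model + SS_residual = SS_total and
    SS_residual = SS_lack_of_fit + SS_pure_error.
    """

    rows: pd.DataFrame
    r2: float
    r2_adj: float
    cv_percent: float

    def row(self, source: str) -> pd.Series:
        return self.rows.set_index("source").loc[source]

    def term_pvalues(self) -> dict[str, float]:
        pooled = {"Model", "Residual", "Lack of fit", "Pure error", "Corrected total"}
        out = {}
        for _, r in self.rows.iterrows():
            if r["source"] not in pooled and np.isfinite(r["p"]):
                out[r["source"]] = float(r["p"])
        return out

    def to_dict(self) -> dict:
        return {
            "rows": [
                {k: (None if (isinstance(v, float) and not np.isfinite(v)) else v)
                 for k, v in r.items()}
                for r in self.rows.to_dict(orient="records")
            ],
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "cv_percent": self.cv_percent,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _design_response(table: DesignTable) -> tuple[np.ndarray, np.ndarray]:
    missing = table.missing_response_ids()
    if missing:
        raise ValueError(f"runs without responses: {missing}")
    return table.coded_matrix, table.responses


def fit_quadratic(table: DesignTable) -> QuadraticModel:
    """Fit the full second-order polynomial to a design table by OLS.

    Requires at least as many measured runs as model terms and a
    full-column-rank coded model matrix.
    """
    coded, y = _design_response(table)
    M = model_matrix(coded)
    n, p = M.shape
    if n < p:
        raise ValueError(f"need >= {p} runs to fit {p} terms, have {n}")
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        names = term_names([f.name for f in table.factors])
        # identify columns whose removal restores full rank relative to the rest
        collinear = []
        for j in range(p):
            others = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear}")
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return QuadraticModel(
        factors=list(table.factors),
        coefficients=beta,
        included=np.ones(p, dtype=bool),
    )


def anova(model: QuadraticModel, table: DesignTable) -> AnovaTable:
    """ANOVA of a fitted quadratic with lack-of-fit / pure-error split.

    Per-term sums of squares are partial (drop-one-term extra SS from the
    full model): for the orthogonal coded columns of a BBD these equal the
    sequential SS, and they stay well defined for the quadratic columns,
    which are not orthogonal to the intercept or to each other.  Pure error
    is the within-replicate SS of the center runs; lack of fit is the
    remainder of the residual.
    """
    coded, y = _design_response(table)
    M_full = model_matrix(coded)
    M = M_full[:, model.included]
    names = [n for n, m in zip(model.term_names, model.included) if m]
    n, p_with_icpt = M.shape
    p = p_with_icpt - 1  # predictors excluding intercept

    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_mod = ss_tot - ss_res
    df_res = n - p_with_icpt
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    rows = []
    f_mod = (ss_mod / p) / ms_res if df_res > 0 else np.nan
    p_mod = float(stats.f.sf(f_mod, p, df_res)) if np.isfinite(f_mod) else np.nan
    rows.append(("Model", ss_mod, p, ss_mod / p, f_mod, p_mod))

    # drop-one partial SS per non-intercept term
    for j in range(1, p_with_icpt):
        keep = [c for c in range(p_with_icpt) if c != j]
        b2, *_ = np.linalg.lstsq(M[:, keep], y, rcond=None)
        r2_ = y - M[:, keep] @ b2
        ss_term = float(r2_ @ r2_) - ss_res
        f_term = ss_term / ms_res if df_res > 0 else np.nan
        p_term = float(stats.f.sf(f_term, 1, df_res)) if np.isfinite(f_term) else np.nan
        rows.append((names[j], ss_term, 1, ss_term, f_term, p_term))

    rows.append(("Residual", ss_res, df_res, ms_res, np.nan, np.nan))

    center = table.center_responses()
    if len(center) >= 2:
        ss_pe = float(((center - center.mean()) ** 2).sum())
        df_pe = len(center) - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
        f_lof = ms_lof / ms_pe if ms_pe > 0 and df_lof > 0 else np.nan
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe)) if np.isfinite(f_lof) else np.nan
        rows.append(("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
        rows.append(("Pure error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
    else:
        warnings.warn(
            "fewer than 2 center replicates: lack-of-fit / pure-error split omitted",
            UserWarning,
            stacklevel=2,
        )

    rows.append(("Corrected total", ss_tot, n - 1, np.nan, np.nan, np.nan))

    df = pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"])
    r2 = ss_mod / ss_tot
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    cv = 100 * np.sqrt(ms_res) / y.mean() if df_res > 0 else np.nan
    return AnovaTable(rows=df, r2=float(r2), r2_adj=float(r2_adj), cv_percent=float(cv))


def reduce_model(
    model: QuadraticModel,
    anova_table: AnovaTable,
    table: DesignTable,
    alpha: float = 0.05,
) -> QuadraticModel:
    """Drop non-significant linear and interaction terms and refit.

    Linear and interaction terms with p >= alpha are excluded; quadratic
    terms are kept when p < alpha.  Hierarchy is not enforced.  Because the
    coded linear and interaction columns of a BBD are mutually orthogonal,
    the surviving linear/interaction coefficients are unchanged by the
    refit; this is asserted to 1e-10.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    k = model.n_factors
    pvals = anova_table.term_pvalues()
    included = model.included.copy()
    names = model.term_names
    for idx, name in enumerate(names):
        if idx == 0 or not included[idx]:
            continue  # intercept always kept
        p = pvals.get(name)
        if p is not None and p >= alpha:
            included[idx] = False

    coded, y = _design_response(table)
    M_full = model_matrix(coded)
    beta_red, *_ = np.linalg.lstsq(M_full[:, included], y, rcond=None)
    coefs = np.zeros(len(names))
    coefs[included] = beta_red

    # orthogonality check: surviving linear/interaction coefficients unchanged
    lin_int = np.zeros(len(names), dtype=bool)
    lin_int[1 : 1 + k] = True
    lin_int[1 + 2 * k :] = True
    surviving = lin_int & included & model.included
    if not np.allclose(coefs[surviving], model.coefficients[surviving], atol=1e-10):
        raise AssertionError(
            "linear/interaction coefficients changed under reduction; "
            "coded design columns are not orthogonal"
        )
    return QuadraticModel(model.factors, coefs, included)


def surface_grid(
    model: QuadraticModel,
    factor_pair: tuple[int, int],
    fixed_levels: Optional[Sequence[float]] = None,
    resolution: int = 41,
) -> pd.DataFrame:
    """Tabulate predicted yield over a coded [-1, 1]^2 grid for one factor pair.

    The remaining factors are held at ``fixed_levels`` (coded 0 by default).
    Output columns carry both coded and natural coordinates for external
    contour/surface plotting.
    """
    i, j = factor_pair
    if i == j:
        raise ValueError("factor pair must name two distinct factors")
    k = model.n_factors
    if not (0 <= i < k and 0 <= j < k):
        raise ValueError(f"factor indices must be in [0, {k})")
    fixed = np.zeros(k) if fixed_levels is None else np.asarray(fixed_levels, float)
    if fixed.shape != (k,):
        raise ValueError(f"fixed_levels must have {k} entries")
    axis = np.linspace(-1, 1, resolution)
    gi, gj = np.meshgrid(axis, axis, indexing="ij")
    pts = np.tile(fixed, (resolution * resolution, 1))
    pts[:, i] = gi.ravel()
    pts[:, j] = gj.ravel()
    pred = model.predict_many(pts)
    fi, fj = model.factors[i], model.factors[j]
    return pd.DataFrame(
        {
            f"{fi.name}_coded": pts[:, i],
            f"{fj.name}_coded": pts[:, j],
            f"{fi.name}_nat": fi.center + fi.step * pts[:, i],
            f"{fj.name}_nat": fj.center + fj.step * pts[:, j],
            "predicted_yield": pred,
        }
    )


def diagnostics(model: QuadraticModel, table: DesignTable) -> pd.DataFrame:
    """Residual report: predicted vs actual and internally studentized residuals.

    A run is flagged when its |studentized residual| exceeds 3 — the usual
    screen for observations the quadratic cannot accommodate.
    """
    coded, y = _design_response(table)
    M = model_matrix(coded)[:, model.included]
    n, p = M.shape
    pred = M @ np.linalg.lstsq(M, y, rcond=None)[0]
    resid = y - pred
    H = M @ np.linalg.pinv(M.T @ M) @ M.T
    lev = np.clip(np.diag(H), 0, 1 - 1e-12)
    df_res = n - p
    ms_res = float(resid @ resid) / df_res if df_res > 0 else np.nan
    denom = np.sqrt(ms_res * (1 - lev)) if df_res > 0 else np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        student = np.where(denom > 0, resid / denom, 0.0)
    return pd.DataFrame(
        {
            "run_id": [r.run_id for r in table.runs],
            "actual": y,
            "predicted": pred,
            "residual": resid,
            "leverage": np.diag(H),
            "studentized": student,
            "flagged": np.abs(student) > 3,
        }
    )
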