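"""Multivariate regression of ilr movement-behaviour outcomes on exposures.

The 4-part daily composition is expressed as three ilr coordinates and
regressed, as a multivariate outcome, on a standardised exposure plus
confounders (sex, ethnicity, maternal education, maternal age category,
child BMI).  Reported quantities:

* per-behaviour one-vs-rest "pivot" coefficients with t-based 95% CIs —
  the exposure coefficient on the first coordinate of each of the four
  pivot bases (equivalently sqrt(4/3) times the exposure effect on the clr
  scale);
* an overall Type II MANOVA Pillai-trace test for the exposure term
  (invariant to the choice of pivot basis);
* compositional estimated marginal means: predicted compositions in
  minutes/day over an exposure grid z in {-2..+2}, with continuous
  covariates at their sample means and categorical covariates at sample
  proportions, back-transformed from the ilr scale.

Because the ilr bases are orthonormal rotations of one another, the
multivariate fit is identical to stacking three univariate least-squares
fits, and the overall test does not depend on which basis carries the
outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import (
    KAPPA,
    Composition4,
    IlrBasis,
    MVPA_FIRST,
    PARTS,
    close,
    ilr_back_transform,
    ilr_transform,
    pivot_sets,
)

__all__ = [
    "ModelSpec",
    "CodaFit",
    "EmmGrid",
    "DEFAULT_COVARIATES",
    "CATEGORICAL_REFERENCES",
    "COMPOSITION_COLUMNS",
    "build_design",
    "fit_coda",
    "pivot_coefficients",
    "manova_pillai",
    "estimated_means",
    "fit_movement_model",
]

PIVOT_SCALE = math.sqrt(4.0 / 3.0)  # first pivot coordinate = sqrt(4/3) * clr

DEFAULT_COVARIATES = (
    "sex",
    "ethnicity",
    "maternal_education",
    "maternal_age_cat",
    "bmi",
)

#: Reference level for each dummy-coded categorical covariate.
CATEGORICAL_REFERENCES = {
    "sex": "boy",
    "ethnicity": "Chinese",
    "maternal_education": "secondary_or_below",
    "maternal_age_cat": "27-33",
}

COMPOSITION_COLUMNS = ("mvpa_min", "lpa_min", "inactivity_min", "sleep_min")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what: one exposure, optional confounders."""

    exposure: str
    adjusted: bool = True
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    timepoint: str = "5.5y"


@dataclass
class CodaFit:
    """A fitted compositional regression."""

    spec: ModelSpec
    predictor_names: list[str]
    basis: IlrBasis
    B: np.ndarray  # predictors x 3, primary-basis ilr scale
    E: np.ndarray  # 3 x 3 residual SSCP
    n: int
    dfe: int
    xtx_inv: np.ndarray
    x_mean: np.ndarray  # design column means (EMM covariate reference)
    pivot_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    pillai: dict = field(default_factory=dict)

    @property
    def exposure_index(self) -> int:
        return self.predictor_names.index(self.spec.exposure)


@dataclass
class EmmGrid:
    """Estimated marginal compositions over an exposure z grid."""

    exposure: str
    z_values: np.ndarray
    compositions: pd.DataFrame  # one row per z, columns COMPOSITION_COLUMNS
    deltas: pd.Series  # minutes at z=+2 minus minutes at z=-2, per behaviour


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, exposure, then confounders if adjusted.

    Categorical covariates are dummy-coded against the declared reference
    level; unknown reference levels raise.
    """
    if spec.exposure not in data.columns:
        raise ValueError(f"exposure column {spec.exposure!r} not in data")
    cols: list[pd.Series] = [
        pd.Series(1.0, index=data.index, name="intercept"),
        data[spec.exposure].astype(float),
    ]
    if spec.adjusted:
        for cov in spec.covariates:
            if cov not in data.columns:
                raise ValueError(f"covariate column {cov!r} not in data")
            if cov in CATEGORICAL_REFERENCES:
                ref = CATEGORICAL_REFERENCES[cov]
                levels = pd.Index(sorted(data[cov].astype(str).unique()))
                if ref not in levels:
                    raise ValueError(
                        f"reference level {ref!r} absent from {cov!r} ({list(levels)})"
                    )
                for lev in levels:
                    if lev == ref:
                        continue
                    cols.append(
                        (data[cov].astype(str) == lev)
                        .astype(float)
                        .rename(f"{cov}[{lev}]")
                    )
            else:
                cols.append(data[cov].astype(float))
    X = pd.concat(cols, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )


def fit_coda(
    Y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    spec: ModelSpec | None = None,
    basis: IlrBasis = MVPA_FIRST,
) -> CodaFit:
    """Least-squares multivariate fit of (n x 3) ilr outcomes on (n x p) X.

    The coefficient matrix equals the stack of three per-coordinate
    univariate fits; E is the residual cross-product matrix.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("Y must be n x 3 ilr coordinates")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n <= p + 3:
        raise ValueError(f"n={n} too small for p={p} predictors and 3 outcomes")
    _check_rank(X, names)
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    E = resid.T @ resid
    return CodaFit(
        spec=spec or ModelSpec(exposure=names[1] if p > 1 else names[0]),
        predictor_names=list(names),
        basis=basis,
        B=B,
        E=E,
        n=n,
        dfe=n - p,
        xtx_inv=xtx_inv,
        x_mean=X.mean(axis=0),
    )


def _coef_ci(
    fit: CodaFit, row: int, col: int, conf_level: float = 0.95
) -> tuple[float, float, float, float]:
    sigma2 = fit.E[col, col] / fit.dfe
    se = math.sqrt(sigma2 * fit.xtx_inv[row, row])
    tcrit = stats.t.ppf(0.5 + conf_level / 2, fit.dfe)
    est = fit.B[row, col]
    return est, se, est - tcrit * se, est + tcrit * se


def pivot_coefficients(
    parts: np.ndarray,
    X: np.ndarray,
    names: list[str],
    exposure: str,
    conf_level: float = 0.95,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """One-vs-rest exposure coefficients for all four behaviours.

    Fits the same design to the outcome expressed in each of the four pivot
    bases and reports each basis's first-coordinate exposure coefficient
    with a t-based CI.  The estimates, divided by sqrt(4/3), sum to zero:
    the four balances are linear images of one clr vector.
    """
    parts = np.asarray(parts, dtype=float)
    if parts.ndim != 2 or parts.shape[1] != 4:
        raise ValueError("parts must be n x 4 minutes")
    row_idx = names.index(exposure)
    records = []
    for basis in pivot_sets():
        Y = ilr_transform(parts, basis)
        fit = fit_coda(Y, X, names, spec=spec, basis=basis)
        est, se, lo, hi = _coef_ci(fit, row_idx, 0, conf_level)
        records.append(
            {
                "behaviour": basis.lead,
                "estimate": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(records)


def clr_exposure_effect(fit: CodaFit, exposure: str | None = None) -> np.ndarray:
    """Exposure effect on the clr scale from a single-basis fit.

    The first pivot coordficient of behaviour j equals sqrt(4/3) times this
    vector's j-th entry, so one fit determines all four one-vs-rest
    estimates (the 'clr bridge').
    """
    row = (
        fit.exposure_index
        if exposure is None
        else fit.predictor_names.index(exposure)
    )
    return fit.basis.contrast_matrix @ fit.B[row]


def manova_pillai(
    Y: np.ndarray, X: np.ndarray, term_columns: list[int] | np.ndarray
) -> dict:
    """Type II MANOVA Pillai-trace test for one design term.

    H is the extra residual SSCP from dropping the term's columns (term
    entered last among non-interacting terms, so Type II = Type III here);
    V = tr(H (H + E)^-1) with the standard F approximation
    s = min(3, q), m = (|3-q|-1)/2, n* = (N - rank(X) - 3 - 1)/2.
    For a single-column term the F test is exact (equals Hotelling's T^2).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    term_columns = list(np.atleast_1d(term_columns))
    n, p = X.shape
    q = len(term_columns)
    if q == 0:
        raise ValueError("term has no columns")
    keep = [j for j in range(p) if j not in term_columns]
    B_full, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y.T @ Y - B_full.T @ (X.T @ X) @ B_full
    X_red = X[:, keep]
    B_red, *_ = np.linalg.lstsq(X_red, Y, rcond=None)
    E_red = Y.T @ Y - B_red.T @ (X_red.T @ X_red) @ B_red
    H = E_red - E
    p_dim = 3
    ve = n - np.linalg.matrix_rank(X)
    if ve <= p_dim:
        raise np.linalg.LinAlgError("residual SSCP singular: n too small")
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p_dim, q)
    m = (abs(p_dim - q) - 1) / 2.0
    nstar = (ve - p_dim - 1) / 2.0
    df1 = float(s * (2 * m + s + 1))
    df2 = float(s * (2 * nstar + s + 1))
    F = (df2 / df1) * V / (s - V)
    pval = float(stats.f.sf(F, df1, df2))
    return {"V": V, "F": float(F), "df1": df1, "df2": df2, "p": pval}


def estimated_means(
    fit: CodaFit,
    z_values=(-2.0, -1.0, 0.0, 1.0, 2.0),
    kappa: float = KAPPA,
    reference: np.ndarray | None = None,
) -> EmmGrid:
    """Compositional estimated marginal means over the exposure grid.

    Predicts the ilr outcome at each z with every other design column held
    at its sample mean (dummy columns: sample proportions), then
    back-transforms to minutes/day.  ``deltas`` is minutes at the highest z
    minus minutes at the lowest.
    """
    z_values = np.asarray(z_values, dtype=float)
    x_ref = np.array(fit.x_mean if reference is None else reference, dtype=float)
    rows = np.tile(x_ref, (z_values.size, 1))
    rows[:, fit.exposure_index] = z_values
    coords = rows @ fit.B
    parts = ilr_back_transform(coords, fit.basis, kappa)
    comp = pd.DataFrame(parts, columns=list(COMPOSITION_COLUMNS))
    comp.insert(0, "z", z_values)
    deltas = pd.Series(
        parts[np.argmax(z_values)] - parts[np.argmin(z_values)],
        index=list(COMPOSITION_COLUMNS),
        name="delta_min",
    )
    return EmmGrid(
        exposure=fit.spec.exposure,
        z_values=z_values,
        compositions=comp,
        deltas=deltas,
    )


def fit_movement_model(
    data: pd.DataFrame,
    exposure: str,
    adjusted: bool = True,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    conf_level: float = 0.95,
    kappa: float = KAPPA,
) -> CodaFit:
    """End-to-end fit from a per-child table.

    ``data`` carries the composition in minutes (mvpa_min, lpa_min,
    inactivity_min, sleep_min), the standardised exposure, and covariate
    columns.  Returns the MVPA-first fit with the four-behaviour pivot
    table and the overall Pillai test attached.
    """
    missing = [c for c in COMPOSITION_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"missing composition columns: {missing}")
    spec = ModelSpec(exposure=exposure, adjusted=adjusted, covariates=covariates)
    X, names = build_design(data, spec)
    raw = data.loc[:, list(COMPOSITION_COLUMNS)].to_numpy(dtype=float)
    parts = np.stack([close(row, kappa).as_array() for row in raw])
    Y = ilr_transform(parts, MVPA_FIRST)
    fit = fit_coda(Y, X, names, spec=spec, basis=MVPA_FIRST)
    fit.pivot_table = pivot_coefficients(
        parts, X, names, exposure, conf_level, spec=spec
    )
    fit.pillai = manova_pillai(Y, X, [names.index(exposure)])
    return fit
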