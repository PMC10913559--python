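"""Scoring of parental-practice and neighbourhood-environment questionnaires.

Six constructs are measured by multi-item scales: parental involvement in
PA, parental support for PA, parental control of the screen-viewing
context, neighbourhood facilities for active play, facilitators for active
mobility, and barriers to active mobility.  Each construct is scored by a
one-factor maximum-likelihood model on the item correlation matrix
(regression-method factor scores, standardised in-sample), and internal
consistency is reported as Cronbach's alpha.

Two overall composites are formed from the standardised construct scores:

* overall parental practices = involvement + support + screen_control
* overall environment = facilities + facilitators - barriers

and re-standardised, since exposures are analysed per z-score unit.

Ordinal item responses are treated as numeric.  Full multi-factor CFA with
fit indices is out of scope; the one-factor model is the scoring engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "PARENTAL_CONSTRUCTS",
    "ENVIRONMENT_CONSTRUCTS",
    "CONSTRUCTS",
    "OneFactorModel",
    "cronbach_alpha",
    "fit_one_factor",
    "factor_scores",
    "overall_composites",
    "score_items",
]

PARENTAL_CONSTRUCTS = ("involvement", "support", "screen_control")
ENVIRONMENT_CONSTRUCTS = ("facilities", "mobility_facilitators", "mobility_barriers")
CONSTRUCTS = PARENTAL_CONSTRUCTS + ENVIRONMENT_CONSTRUCTS

_UNIQUENESS_FLOOR = 5e-3
_RELIABLE_LOADING = 0.3


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of
    the item sum).  Invariant to adding constants to items."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D array with at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


@dataclass
class OneFactorModel:
    """A fitted single-factor measurement model for one construct."""

    item_names: tuple[str, ...]
    loadings: np.ndarray  # standardised (correlation-metric) loadings
    uniquenesses: np.ndarray
    item_means: np.ndarray
    item_sds: np.ndarray
    method: str = "ml"  # "ml" or "mean" (2-item fallback)
    flags: list[str] = field(default_factory=list)

    @property
    def reliable(self) -> bool:
        return "unreliable" not in self.flags and "degenerate" not in self.flags


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("an item has zero variance")
    return (x - mu) / sd, mu, sd


def fit_one_factor(items: pd.DataFrame) -> OneFactorModel:
    """Fit a one-factor ML model to a (respondents x items) table.

    Loadings are sign-fixed so their sum is positive.  Heywood cases
    (uniqueness <= 0) are truncated at a small floor with a warning.
    Constructs with only two items fall back to a standardised item mean.
    """
    x = np.asarray(items, dtype=float)
    names = tuple(items.columns) if isinstance(items, pd.DataFrame) else tuple(
        f"item{i+1}" for i in range(x.shape[1])
    )
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items")
    complete = x[~np.isnan(x).any(axis=1)]
    if complete.shape[0] < x.shape[1] + 1:
        raise ValueError("too few complete responses to fit")
    z, mu, sd = _standardise(complete)
    mu_all = np.nanmean(x, axis=0)
    sd_all = np.nanstd(x, axis=0, ddof=1)
    flags: list[str] = []

    if x.shape[1] == 2:
        flags.append("two-item-fallback")
        k = 2
        r = np.corrcoef(z, rowvar=False)[0, 1]
        # equal loadings consistent with the observed correlation
        lam = np.full(k, np.sqrt(max(r, 0.0)))
        if r <= 0:
            flags.append("unreliable")
        return OneFactorModel(
            names, lam, 1 - lam**2, mu_all, sd_all, method="mean", flags=flags
        )

    corr = np.corrcoef(z, rowvar=False)
    if np.linalg.eigvalsh(corr).min() < 1e-10:
        flags.append("degenerate")
        warnings.warn(
            "item correlation matrix is singular (duplicated items?)",
            stacklevel=2,
        )
    fa = FactorAnalysis(n_components=1, svd_method="lapack")
    fa.fit(z)
    lam = fa.components_.ravel().copy()
    if lam.sum() < 0:
        lam = -lam
    psi = fa.noise_variance_.copy()
    if np.any(psi <= 0):
        flags.append("heywood")
        warnings.warn("Heywood case: uniqueness truncated at floor", stacklevel=2)
        psi = np.maximum(psi, _UNIQUENESS_FLOOR)
    if np.abs(lam).max() < _RELIABLE_LOADING:
        flags.append("unreliable")
        warnings.warn("all loadings < 0.3; construct unreliable", stacklevel=2)
    return OneFactorModel(names, lam, psi, mu_all, sd_all, method="ml", flags=flags)


def factor_scores(model: OneFactorModel, items: pd.DataFrame) -> np.ndarray:
    """Regression-method factor scores, standardised to mean 0 / sd 1.

    f_i = lambda' Sigma^-1 z_i with Sigma = lambda lambda' + Psi.  Children
    with missing items are scored from the available items with the
    corresponding sub-blocks of lambda and Sigma; all-missing rows get NaN.
    """
    x = np.asarray(items, dtype=float)
    if x.shape[1] != len(model.item_names):
        raise ValueError("item table does not match the fitted model")
    z = (x - model.item_means) / model.item_sds
    lam, psi = model.loadings, model.uniquenesses
    sigma = np.outer(lam, lam) + np.diag(psi)
    raw = np.full(x.shape[0], np.nan)
    obs_patterns: dict[tuple, np.ndarray] = {}
    observed = ~np.isnan(z)
    for i in range(x.shape[0]):
        idx = tuple(np.flatnonzero(observed[i]))
        if not idx:
            continue
        if idx not in obs_patterns:
            sub = np.ix_(idx, idx)
            obs_patterns[idx] = np.linalg.solve(sigma[sub], lam[list(idx)])
        raw[i] = z[i, list(idx)] @ obs_patterns[idx]
    ok = ~np.isnan(raw)
    if ok.sum() < 2 or np.nanstd(raw[ok], ddof=1) == 0:
        raise ValueError("factor scores degenerate; cannot standardise")
    out = raw.copy()
    out[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std(ddof=1)
    return out


def overall_composites(scores: pd.DataFrame) -> pd.DataFrame:
    """Add standardised overall composites to a construct-score table.

    Barriers to active mobility enter the environment composite negatively.
    Rows missing any contributing construct get a missing composite.
    """
    missing = [c for c in CONSTRUCTS if c not in scores.columns]
    if missing:
        raise ValueError(f"missing construct columns: {missing}")
    out = scores.copy()
    parental = (
        out["involvement"] + out["support"] + out["screen_control"]
    )
    environment = (
        out["facilities"] + out["mobility_facilitators"] - out["mobility_barriers"]
    )
    for name, comp in (
        ("overall_parental", parental),
        ("overall_environment", environment),
    ):
        z = (comp - comp.mean()) / comp.std(ddof=1)
        out[name] = z
    return out


def score_items(item_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Score a long item table into the eight exposure columns.

    Input columns: child_id, construct, item_name, response.  Returns
    (scores frame indexed by child_id with six construct columns + two
    overall composites, diagnostics dict with per-construct alpha, loadings
    and flags).
    """
    required = {"child_id", "construct", "item_name", "response"}
    if not required.issubset(item_table.columns):
        raise ValueError(f"item table needs columns {sorted(required)}")
    children = pd.Index(sorted(item_table["child_id"].unique()), name="child_id")
    scores = pd.DataFrame(index=children)
    diagnostics: dict[str, dict] = {}
    for construct in CONSTRUCTS:
        sub = item_table[item_table["construct"] == construct]
        if sub.empty:
            raise ValueError(f"no items for construct {construct!r}")
        wide = sub.pivot_table(
            index="child_id", columns="item_name", values="response"
        ).reindex(children)
        model = fit_one_factor(wide)
        scores[construct] = factor_scores(model, wide)
        complete = wide.dropna()
        diagnostics[construct] = {
            "alpha": cronbach_alpha(complete) if len(complete) >= 3 else np.nan,
            "loadings": dict(zip(model.item_names, model.loadings.round(4))),
            "flags": model.flags,
        }
    return overall_composites(scores), diagnostics
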