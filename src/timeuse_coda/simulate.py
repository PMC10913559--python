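"""Synthetic cohorts with the statistical structure the analysis assumes.

The study data (a Singaporean mother-offspring cohort, n = 425 children
with valid accelerometry at ages 5.5 and 8 y) are restricted, so every
pipeline stage is exercised on simulated data built to match the published
marginals: covariate distributions (48% girls; ethnicity 59/25/16%
Chinese/Malay/Indian; maternal education 31/34/35%; maternal age category
22/41/37%; BMI 15.44 +/- 1.95 kg/m^2), the baseline daily composition
(71/344/488/537 min MVPA/LPA/inactivity/sleep at age 5.5 y; 70/333/512/526
at 8 y, closed to 1440), and exposure effects planted on the clr scale from
published one-vs-rest pivot coefficients.

The outcome model is the one the regression assumes: ilr(composition) =
ilr(baseline) + sum of planted effects x predictors + Gaussian noise.  The
default residual sd (0.30 per ilr coordinate, diagonal) gives simulated CI
widths of the same order as the published tables; no residual covariance is
published, so recovery targets concern means, not variances.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviours import EpochSeries, MINUTES_PER_DAY
from .coda import KAPPA, MVPA_FIRST, close, ilr_transform
from .questionnaires import CONSTRUCTS, ENVIRONMENT_CONSTRUCTS, PARENTAL_CONSTRUCTS
from .regression import COMPOSITION_COLUMNS, PIVOT_SCALE

__all__ = [
    "GeneratorConfig",
    "BASELINE_5_5Y",
    "BASELINE_8Y",
    "plant_from_pivots",
    "loadings_for_alpha",
    "gen_item_block",
    "gen_cohort",
    "gen_compositions",
    "gen_enmo_day",
    "gen_epoch_week",
]

#: Published mean daily compositions (minutes), ages 5.5 and 8 years.
BASELINE_5_5Y = (71.0, 344.0, 488.0, 537.0)
BASELINE_8Y = (70.0, 333.0, 512.0, 526.0)  # printed means sum to 1441; closed later

_DEF_ETHNICITY = {"Chinese": 0.59, "Malay": 0.25, "Indian": 0.16}
_DEF_EDUCATION = {
    "secondary_or_below": 0.31,
    "post_secondary": 0.34,
    "university": 0.35,
}
_DEF_MATERNAL_AGE = {"<27": 0.22, "27-33": 0.41, ">33": 0.37}

# Internal-consistency targets: the parental item set and the environment
# item set were reported at alpha 0.82 and 0.91 respectively.
_DEF_ALPHAS = {c: 0.82 for c in PARENTAL_CONSTRUCTS} | {
    c: 0.91 for c in ENVIRONMENT_CONSTRUCTS
}


def _validate_probs(name: str, probs: dict[str, float]) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must be nonnegative and sum to 1")


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator, defaulting to the study conditions."""

    n: int = 425
    girl_proportion: float = 0.48
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_ETHNICITY)
    )
    education_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_EDUCATION)
    )
    maternal_age_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_MATERNAL_AGE)
    )
    bmi_mean: float = 15.44
    bmi_sd: float = 1.95
    baseline: tuple[float, float, float, float] = BASELINE_5_5Y
    #: predictor column -> clr effect vector (4, summing to 0)
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    #: residual covariance of the 3 ilr coordinates
    resid_cov: np.ndarray = field(
        default_factory=lambda: np.diag([0.30**2] * 3)
    )
    items_per_construct: int = 4
    construct_alphas: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_ALPHAS)
    )

    def __post_init__(self) -> None:
        _validate_probs("ethnicity", self.ethnicity_probs)
        _validate_probs("education", self.education_probs)
        _validate_probs("maternal_age", self.maternal_age_probs)
        if not (0 <= self.girl_proportion <= 1):
            raise ValueError("girl_proportion must be in [0, 1]")
        self.resid_cov = np.asarray(self.resid_cov, dtype=float)
        if self.resid_cov.shape != (3, 3) or np.any(
            np.linalg.eigvalsh(self.resid_cov) <= 0
        ):
            raise ValueError("resid_cov must be a 3x3 positive-definite matrix")
        for name, eff in self.effects.items():
            eff = np.asarray(eff, dtype=float)
            if eff.shape != (4,) or not np.all(np.isfinite(eff)):
                raise ValueError(f"effect {name!r} must be 4 finite clr values")
            self.effects[name] = eff - eff.mean()


def plant_from_pivots(pivots) -> np.ndarray:
    """Convert four one-vs-rest pivot estimates to a centred clr effect.

    clr = pivots / sqrt(4/3), re-centred to sum exactly to zero (absorbing
    print rounding in published coefficient quadruples).
    """
    p = np.asarray(pivots, dtype=float)
    if p.shape != (4,) or not np.all(np.isfinite(p)):
        raise ValueError("need four finite pivot values")
    c = p / PIVOT_SCALE
    return c - c.mean()


def loadings_for_alpha(alpha: float, k: int) -> float:
    """Equal standardised loading implying Cronbach's alpha for k items.

    With equal loadings lambda, inter-item correlation r = lambda^2 and
    alpha = k r / (1 + (k-1) r); inverting gives r = alpha / (k - alpha(k-1)).
    """
    if not (0 < alpha < 1) or k < 2:
        raise ValueError("need 0 < alpha < 1 and k >= 2")
    r = alpha / (k - alpha * (k - 1))
    return math.sqrt(r)


def gen_item_block(
    rng: np.random.Generator, factor: np.ndarray, k: int, alpha: float
) -> np.ndarray:
    """Item responses from a one-factor model hitting a target alpha."""
    lam = loadings_for_alpha(alpha, k)
    n = factor.shape[0]
    eps = rng.normal(size=(n, k))
    return lam * factor[:, None] + math.sqrt(1 - lam**2) * eps


def gen_cohort(
    config: GeneratorConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate covariates, true construct factors and questionnaire items.

    Returns ``(cohort, items)``: a per-child frame with covariates and the
    six true standard-normal factor columns (independent of covariates, as
    no joint distribution is published), and a long item table in the
    schema the questionnaire scorer reads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n
    child_id = [f"C{i:05d}" for i in range(n)]

    def draw_cat(probs: dict[str, float]) -> np.ndarray:
        return rng.choice(list(probs), size=n, p=list(probs.values()))

    cohort = pd.DataFrame(
        {
            "child_id": child_id,
            "sex": np.where(
                rng.random(n) < config.girl_proportion, "girl", "boy"
            ),
            "ethnicity": draw_cat(config.ethnicity_probs),
            "maternal_education": draw_cat(config.education_probs),
            "maternal_age_cat": draw_cat(config.maternal_age_probs),
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, size=n),
        }
    )
    item_rows = []
    for construct in CONSTRUCTS:
        factor = rng.normal(size=n)
        cohort[construct] = factor
        alpha = config.construct_alphas.get(construct, 0.82)
        block = gen_item_block(rng, factor, config.items_per_construct, alpha)
        for j in range(config.items_per_construct):
            item_rows.append(
                pd.DataFrame(
                    {
                        "child_id": child_id,
                        "construct": construct,
                        "item_name": f"{construct}_q{j+1}",
                        "response": block[:, j],
                    }
                )
            )
    cohort["overall_parental"] = _standardise(
        sum(cohort[c] for c in PARENTAL_CONSTRUCTS)
    )
    cohort["overall_environment"] = _standardise(
        cohort["facilities"]
        + cohort["mobility_facilitators"]
        - cohort["mobility_barriers"]
    )
    return cohort, pd.concat(item_rows, ignore_index=True)


def _standardise(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def gen_compositions(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
    kappa: float = KAPPA,
) -> pd.DataFrame:
    """Weekly compositions from the planted ilr-scale outcome model.

    ilr(composition) = ilr(baseline) + sum over planted effects of
    (clr effect expressed in ilr coordinates) x predictor value + noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)
    base = ilr_transform(close(config.baseline, kappa).as_array(), MVPA_FIRST)
    mean_coords = np.tile(base, (n, 1))
    V = MVPA_FIRST.contrast_matrix
    for col, clr_eff in config.effects.items():
        if col not in cohort.columns:
            raise ValueError(f"effect predictor {col!r} not in cohort")
        z = cohort[col].to_numpy(dtype=float)
        mean_coords += np.outer(z, V.T @ clr_eff)
    chol = np.linalg.cholesky(config.resid_cov)
    coords = mean_coords + rng.normal(size=(n, 3)) @ chol.T
    raw = np.exp(coords @ V.T)
    parts = raw * (kappa / raw.sum(axis=1, keepdims=True))
    out = cohort.copy()
    for j, col in enumerate(COMPOSITION_COLUMNS):
        out[col] = parts[:, j]
    return out


# ---------------------------------------------------------------------------
# epoch-level fixture days

# ENMO levels placed safely inside each cut-point band (mg).
_ENMO_SLEEP = 10.0
_ENMO_INACT = 20.0
_ENMO_LPA = 100.0
_ENMO_MVPA = 300.0

_MAX_INACT_BOUT_MIN = 14  # keep waking stillness below the nap threshold


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(targets).astype(int)
    short = total - floors.sum()
    if short < 0:
        order = np.argsort(targets - floors)
        for i in order[: -short]:
            floors[i] -= 1
    elif short > 0:
        order = np.argsort(-(targets - floors))
        for i in order[:short]:
            floors[i] += 1
    return floors


def gen_enmo_day(
    target,
    epoch_length: int = 5,
    night_window: tuple[float, float] = (1320.0, 360.0),
    child_id: str = "SIM",
    date: _dt.date = _dt.date(2019, 6, 3),
    nap_min_bout: float = 15.0,
) -> EpochSeries:
    """A fully recorded epoch day whose classification recovers ``target``.

    The night window carries the declared night sleep; any sleep beyond it
    is emitted as still bouts of at least ``nap_min_bout`` minutes (naps).
    Waking inactivity is laid down in runs of at most 14 minutes separated
    by LPA (or MVPA) epochs so it is never mistaken for napping.  Each class
    is recovered within one epoch.
    """
    comp = close(np.asarray(target, dtype=float))
    epm = 60 // epoch_length
    start, end = night_window
    window_min = (end - start) % MINUTES_PER_DAY or (
        MINUTES_PER_DAY if start != end else 0
    )
    nap_min = comp.sleep - window_min
    if nap_min < -1e-9:
        raise ValueError(
            f"target sleep ({comp.sleep:.1f} min) is below the night window "
            f"({window_min:.1f} min)"
        )
    nap_min = max(nap_min, 0.0)
    if 0 < nap_min < nap_min_bout - 1e-9:
        raise ValueError(
            f"sleep excess {nap_min:.1f} min cannot form a >={nap_min_bout}-min nap"
        )
    waking_epochs = (MINUTES_PER_DAY - round(window_min)) * epm
    targets_e = np.array(
        [nap_min, comp.inactivity, comp.lpa, comp.mvpa], dtype=float
    ) * epm
    nap_e, inact_e, lpa_e, mvpa_e = _largest_remainder(targets_e, waking_epochs)

    blocks: list[tuple[float, int]] = []  # (enmo, n_epochs)
    if nap_e:
        blocks.append((_ENMO_SLEEP, int(nap_e)))
    max_run = _MAX_INACT_BOUT_MIN * epm
    sep_pool = [[_ENMO_LPA, int(lpa_e)], [_ENMO_MVPA, int(mvpa_e)]]

    def take_separator() -> tuple[float, int]:
        for pool in sep_pool:
            if pool[1] > 0:
                pool[1] -= 1
                return (pool[0], 1)
        raise ValueError("infeasible target: no LPA/MVPA epochs to break bouts")

    remaining = int(inact_e)
    first = True
    while remaining > 0:
        if blocks and not first:
            blocks.append(take_separator())
        elif blocks and first and blocks[-1][0] == _ENMO_SLEEP:
            blocks.append(take_separator())  # keep naps and stillness apart
        run = min(remaining, max_run)
        blocks.append((_ENMO_INACT, run))
        remaining -= run
        first = False
    for enmo, left in sep_pool:
        if left > 0:
            blocks.append((enmo, left))

    n_total = MINUTES_PER_DAY * epm
    enmo = np.full(n_total, _ENMO_SLEEP)
    start_min = np.arange(n_total) / epm
    if start <= end:
        night = (start_min >= start) & (start_min < end)
    else:
        night = (start_min >= start) | (start_min < end)
    waking_idx = np.flatnonzero(~night)
    # place waking blocks chronologically from the end of the night window
    order = np.argsort((waking_idx - round(end) * epm) % n_total)
    waking_idx = waking_idx[order]
    pos = 0
    for value, count in blocks:
        enmo[waking_idx[pos : pos + count]] = value
        pos += count
    if pos != waking_idx.size:
        raise AssertionError("waking epochs not fully assigned")
    return EpochSeries(
        child_id=child_id,
        date=date,
        epoch_length=epoch_length,
        enmo=enmo,
        night_windows=[night_window],
    )


def gen_epoch_week(
    target,
    child_id: str = "SIM",
    monday: _dt.date = _dt.date(2019, 6, 3),
    epoch_length: int = 5,
    night_window: tuple[float, float] = (1320.0, 360.0),
) -> list[EpochSeries]:
    """Seven consecutive fixture days (Mon-Sun) at one target composition."""
    if monday.weekday() != 0:
        raise ValueError("monday must be a Monday")
    return [
        gen_enmo_day(
            target,
            epoch_length=epoch_length,
            night_window=night_window,
            child_id=child_id,
            date=monday + _dt.timedelta(days=d),
        )
        for d in range(7)
    ]
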