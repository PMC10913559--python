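"""Compositional algebra for 4-part 24-hour movement-behaviour compositions.

A day is decomposed into MVPA, LPA, inactivity and sleep minutes summing to
1440 (the closure constant kappa).  Analyses operate on isometric log-ratio
(ilr) coordinates built from a sequential binary partition that isolates one
behaviour first ("pivot" coordinates): the first coordinate contrasts the
lead part against the geometric mean of the remaining three, the second the
next part against the remaining two, and the third the final pair.

Only D = 4 with this partition family is supported; this is not a general
CoDA library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PARTS",
    "KAPPA",
    "Composition4",
    "IlrBasis",
    "IlrVector",
    "DegenerateCompositionError",
    "close",
    "zero_replace",
    "ilr_forward",
    "ilr_inverse",
    "ilr_transform",
    "ilr_back_transform",
    "pivot_sets",
    "clr",
    "compositional_mean",
]

#: Canonical part order used throughout the package.
PARTS: tuple[str, ...] = ("mvpa", "lpa", "inactivity", "sleep")

#: Minutes in a civil day — the closure constant for daily compositions.
KAPPA: float = 1440.0

_ROUND_TRIP_TOL = 1e-9


class DegenerateCompositionError(ValueError):
    """Raised when a composition has no usable positive mass."""


@dataclass(frozen=True)
class Composition4:
    """Minutes/day spent in each of the four movement behaviours.

    Parts are strictly positive and sum to the closure constant (1440 min
    for a full day) — construct via :func:`close` rather than directly when
    the inputs are raw, possibly zero-containing minutes.
    """

    mvpa: float
    lpa: float
    inactivity: float
    sleep: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mvpa, self.lpa, self.inactivity, self.sleep])

    @property
    def total(self) -> float:
        return self.mvpa + self.lpa + self.inactivity + self.sleep

    @classmethod
    def from_array(cls, parts: Sequence[float]) -> "Composition4":
        a = np.asarray(parts, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 parts, got shape {a.shape}")
        return cls(*a.tolist())


def zero_replace(parts: Sequence[float], delta: float = 1.0) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros become ``delta`` and the nonzero parts are scaled down
    proportionally so the total is preserved.  ``delta`` must stay below the
    smallest nonzero part, otherwise the replacement would reorder parts.
    """
    a = np.asarray(parts, dtype=float)
    if np.any(a < 0):
        raise ValueError("parts must be nonnegative")
    zeros = a == 0
    if not zeros.any():
        return a.copy()
    if not (~zeros).any():
        raise DegenerateCompositionError("all parts are zero")
    if delta <= 0:
        raise ValueError("delta must be positive")
    smallest_nonzero = a[~zeros].min()
    if delta >= smallest_nonzero:
        raise ValueError(
            f"delta={delta} must be smaller than the smallest nonzero part "
            f"({smallest_nonzero})"
        )
    total = a.sum()
    replaced = a * (total - delta * zeros.sum()) / total
    replaced[zeros] = delta
    return replaced


def close(
    parts: Sequence[float], kappa: float = KAPPA, delta: float = 1.0
) -> Composition4:
    """Close raw minutes to a :class:`Composition4` summing to ``kappa``.

    Zero parts are first handled by :func:`zero_replace` (the replacement
    delta is expressed on the output kappa scale).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    a = np.asarray(parts, dtype=float)
    if a.shape != (4,):
        raise ValueError("a 4-part composition is required")
    if np.any(a < 0):
        raise ValueError("parts must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise DegenerateCompositionError("all parts are zero")
    scaled = a * (kappa / total)
    if (scaled == 0).any():
        scaled = zero_replace(scaled, delta=delta)
    return Composition4.from_array(scaled)


@lru_cache(maxsize=None)
def _contrast_matrix(perm: tuple[int, ...]) -> np.ndarray:
    # Sequential binary partition in pivot form: columns are the orthonormal
    # balances for (lead vs rest), (second vs last two), (third vs fourth),
    # expressed in the canonical part order.
    v = np.zeros((4, 3))
    raw = [
        (math.sqrt(3.0 / 4.0), [1.0, -1 / 3, -1 / 3, -1 / 3]),
        (math.sqrt(2.0 / 3.0), [0.0, 1.0, -1 / 2, -1 / 2]),
        (math.sqrt(1.0 / 2.0), [0.0, 0.0, 1.0, -1.0]),
    ]
    for j, (scale, col) in enumerate(raw):
        for pos, part_idx in enumerate(perm):
            v[part_idx, j] = scale * col[pos]
    v.flags.writeable = False
    return v


@dataclass(frozen=True)
class IlrBasis:
    """A pivot ilr basis: a permutation of the four behaviours.

    ``part_order[0]`` is the isolated lead behaviour; its first coordinate
    is the one-vs-rest balance reported in the analysis tables.
    """

    part_order: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if sorted(self.part_order) != sorted(PARTS):
            raise ValueError(f"part_order must permute {PARTS}")

    @property
    def lead(self) -> str:
        return self.part_order[0]

    @property
    def permutation(self) -> tuple[int, ...]:
        return tuple(PARTS.index(p) for p in self.part_order)

    @property
    def contrast_matrix(self) -> np.ndarray:
        """4x3 orthonormal contrast matrix in canonical part order."""
        return _contrast_matrix(self.permutation)

    @property
    def tag(self) -> str:
        return "|".join(
            {"mvpa": "MVPA", "lpa": "LPA", "inactivity": "INACT", "sleep": "SLEEP"}[p]
            for p in self.part_order
        )

    @classmethod
    def from_lead(cls, lead: str) -> "IlrBasis":
        """Basis isolating ``lead`` first, remaining parts in cyclic order."""
        if lead not in PARTS:
            raise ValueError(f"unknown behaviour {lead!r}")
        i = PARTS.index(lead)
        order = tuple(PARTS[(i + k) % 4] for k in range(4))
        return cls(order)  # type: ignore[arg-type]


#: Default basis: MVPA isolated first, as in the worked ilr equations.
MVPA_FIRST = IlrBasis.from_lead("mvpa")


@dataclass(frozen=True)
class IlrVector:
    ilr1: float
    ilr2: float
    ilr3: float
    basis: IlrBasis = MVPA_FIRST

    def as_array(self) -> np.ndarray:
        return np.array([self.ilr1, self.ilr2, self.ilr3])


def _as_positive_array(comp) -> np.ndarray:
    a = comp.as_array() if isinstance(comp, Composition4) else np.asarray(comp, float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("composition parts must be strictly positive and finite")
    return a


def ilr_transform(parts: np.ndarray, basis: IlrBasis = MVPA_FIRST) -> np.ndarray:
    """Vectorised ilr: maps (..., 4) strictly positive parts to (..., 3)."""
    a = np.asarray(parts, dtype=float)
    if np.any(a <= 0):
        raise ValueError("composition parts must be strictly positive")
    return np.log(a) @ basis.contrast_matrix


def ilr_back_transform(
    coords: np.ndarray, basis: IlrBasis = MVPA_FIRST, kappa: float = KAPPA
) -> np.ndarray:
    """Vectorised inverse ilr: (..., 3) coordinates to closed (..., 4) parts."""
    z = np.asarray(coords, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    with np.errstate(over="raise"):
        try:
            raw = np.exp(z @ basis.contrast_matrix.T)
        except FloatingPointError as exc:  # pragma: no cover - extreme inputs
            raise ValueError("ilr coordinates overflow the exponential") from exc
    return raw * (kappa / raw.sum(axis=-1, keepdims=True))


def ilr_forward(comp, basis: IlrBasis = MVPA_FIRST) -> IlrVector:
    """ilr pivot coordinates of one composition.

    With parts (p1..p4) in basis order:
    ilr1 = sqrt(3/4) ln(p1 / (p2 p3 p4)^(1/3)),
    ilr2 = sqrt(2/3) ln(p2 / (p3 p4)^(1/2)),
    ilr3 = sqrt(1/2) ln(p3 / p4).
    Scale-invariant: the closure constant drops out of every log-ratio.
    """
    a = _as_positive_array(comp)
    z = ilr_transform(a, basis)
    return IlrVector(float(z[0]), float(z[1]), float(z[2]), basis)


def ilr_inverse(v, kappa: float = KAPPA, basis: IlrBasis | None = None) -> Composition4:
    """Back-transform ilr coordinates to a composition closed to ``kappa``."""
    if isinstance(v, IlrVector):
        basis = v.basis if basis is None else basis
        z = v.as_array()
    else:
        basis = MVPA_FIRST if basis is None else basis
        z = np.asarray(v, dtype=float)
    parts = ilr_back_transform(z, basis, kappa)
    return Composition4.from_array(parts)


def pivot_sets() -> tuple[IlrBasis, IlrBasis, IlrBasis, IlrBasis]:
    """The four pivot bases, one per behaviour placed first.

    The non-lead parts follow the canonical cyclic order; only the first
    coordinate of each basis is interpreted, and downstream results do not
    depend on that residual ordering.
    """
    return tuple(IlrBasis.from_lead(p) for p in PARTS)  # type: ignore[return-value]


def clr(comp) -> np.ndarray:
    """Centred log-ratio: log parts minus their mean log; sums to 0 exactly."""
    a = _as_positive_array(comp)
    logs = np.log(a)
    out = logs - logs.mean()
    return out - out.mean()  # re-centre to kill the last ulp of drift


def compositional_mean(comps: Iterable, kappa: float = KAPPA) -> Composition4:
    """Mean in ilr space, back-transformed: the closed geometric mean."""
    arrays = [
        c.as_array() if isinstance(c, Composition4) else np.asarray(c, float)
        for c in comps
    ]
    if not arrays:
        raise ValueError("need at least one composition")
    stack = np.stack(arrays)
    if np.any(stack <= 0):
        raise ValueError("composition parts must be strictly positive")
    mean_coords = ilr_transform(stack, MVPA_FIRST).mean(axis=0)
    return ilr_inverse(mean_coords, kappa=kappa, basis=MVPA_FIRST)
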