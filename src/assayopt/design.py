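"""Rotatable central composite designs and factor coding.

A central composite design (CCD) for k factors combines a full 2^k
factorial, 2k axial ("star") points at coded distance ``alpha`` from the
centre, and replicated centre points.  With ``alpha = 2**(k/4)`` the design
is rotatable: the prediction variance of the fitted quadratic depends only
on the distance from the design centre.

Factors are handled on two scales.  The *actual* scale carries physical
units (°C, min, µL); the *coded* scale maps the factorial low/high levels
to -1/+1 and the centre to 0.  All model fitting happens on the coded
scale; coding and decoding are exact affine inverses of each other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Invalid factor definition or design request."""


@dataclass(frozen=True)
class Factor:
    """One experimental factor with its factorial (±1) levels on the actual scale.

    ``low`` and ``high`` are the actual values assigned to coded -1 and +1.
    Axial points lie beyond them, at coded ±alpha.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise DesignError(f"factor {self.name!r}: levels must be finite")
        if self.high <= self.low:
            raise DesignError(
                f"factor {self.name!r}: high level ({self.high}) must exceed "
                f"low level ({self.low})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual: float) -> float:
        """Map an actual value to the coded scale."""
        return (actual - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        """Map a coded value back to the actual scale."""
        return self.center + coded * self.half_range


def make_factor(name: str, units: str, low: float, high: float) -> Factor:
    """Construct a :class:`Factor`; raises :class:`DesignError` on a degenerate range."""
    return Factor(name, units, float(low), float(high))


def rotatable_alpha(k: int) -> float:
    """Axial distance ``2**(k/4)`` giving a rotatable CCD for ``k`` factors."""
    if k < 2:
        raise DesignError("a CCD needs at least 2 factors")
    return 2.0 ** (k / 4.0)


def code_point(factors: Sequence[Factor], actual: Sequence[float]) -> np.ndarray:
    """Code an actual-scale point componentwise."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape != (len(factors),):
        raise DesignError(
            f"point has {actual.size} coordinates, design has {len(factors)} factors"
        )
    return np.array([f.code(x) for f, x in zip(factors, actual)])


def decode_point(factors: Sequence[Factor], coded: Sequence[float]) -> np.ndarray:
    """Decode a coded point to the actual scale componentwise."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape != (len(factors),):
        raise DesignError(
            f"point has {coded.size} coordinates, design has {len(factors)} factors"
        )
    return np.array([f.decode(c) for f, c in zip(factors, coded)])


@dataclass(frozen=True)
class DesignPoint:
    """A single run: coded and actual coordinates plus its role in the design."""

    run_id: int
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    point_class: str  # "factorial" | "axial" | "center"


@dataclass
class CentralCompositeDesign:
    """A CCD: factors, the ordered list of runs and the axial distance."""

    factors: list[Factor]
    runs: list[DesignPoint]
    alpha: float

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded for p in self.runs])

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([p.actual for p in self.runs])

    @property
    def run_ids(self) -> list[int]:
        return [p.run_id for p in self.runs]

    def replicate_groups(self, decimals: int = 6) -> list[list[int]]:
        """Indices of runs sharing identical coded coordinates (rounded).

        Only groups of size >= 2 are returned; they supply pure error in the
        lack-of-fit partition.
        """
        groups: dict[tuple, list[int]] = {}
        for i, p in enumerate(self.runs):
            key = tuple(np.round(p.coded, decimals))
            groups.setdefault(key, []).append(i)
        return [g for g in groups.values() if len(g) >= 2]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run_id, point_class, then actual and coded columns."""
        data: dict[str, list] = {
            "run_id": self.run_ids,
            "point_class": [p.point_class for p in self.runs],
        }
        for j, f in enumerate(self.factors):
            data[f"{f.name}_actual"] = [p.actual[j] for p in self.runs]
        for j, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = [p.coded[j] for p in self.runs]
        return pd.DataFrame(data)


def classify_point(coded: Sequence[float], alpha: float, atol: float = 1e-6) -> str:
    """Classify a coded point as factorial, axial or center.

    Factorial: every |coordinate| = 1.  Axial: exactly one coordinate at
    ±alpha, the rest 0.  Center: all 0.  Anything else raises.
    """
    c = np.asarray(coded, dtype=float)
    if np.allclose(c, 0.0, atol=atol):
        return "center"
    if np.allclose(np.abs(c), 1.0, atol=atol):
        return "factorial"
    nonzero = np.abs(c) > atol
    if nonzero.sum() == 1 and np.isclose(np.abs(c[nonzero][0]), alpha, atol=1e-3):
        return "axial"
    raise DesignError(f"coded point {c.tolist()} is not a CCD point for alpha={alpha}")


def build_ccd(
    factors: Sequence[Factor],
    n_center: int = 4,
    alpha: float | str = "rotatable",
) -> CentralCompositeDesign:
    """Build a CCD: 2^k factorial runs, 2k axial runs, ``n_center`` centre runs.

    Run ordering is deterministic: factorial points in lexicographic sign
    order (low first), then axial pairs by factor index (-alpha before
    +alpha), then centre replicates.  Actual values are computed by exact
    decoding and never rounded internally.
    """
    factors = list(factors)
    k = len(factors)
    if k < 2:
        raise DesignError("a CCD needs at least 2 factors")
    if n_center < 1:
        raise DesignError("at least one centre point is required")
    if isinstance(alpha, str):
        if alpha != "rotatable":
            raise DesignError(f"unknown alpha keyword {alpha!r}")
        alpha = rotatable_alpha(k)
    alpha = float(alpha)
    if not np.isfinite(alpha) or alpha <= 0:
        raise DesignError("alpha must be a positive finite number")

    coded_rows: list[tuple[np.ndarray, str]] = []
    for signs in itertools.product((-1.0, 1.0), repeat=k):
        coded_rows.append((np.array(signs), "factorial"))
    for j in range(k):
        for s in (-1.0, 1.0):
            row = np.zeros(k)
            row[j] = s * alpha
            coded_rows.append((row, "axial"))
    for _ in range(n_center):
        coded_rows.append((np.zeros(k), "center"))

    runs = [
        DesignPoint(
            run_id=i + 1,
            coded=tuple(row),
            actual=tuple(decode_point(factors, row)),
            point_class=cls,
        )
        for i, (row, cls) in enumerate(coded_rows)
    ]
    return CentralCompositeDesign(factors=factors, runs=runs, alpha=alpha)


def design_from_coded(
    factors: Sequence[Factor],
    coded_rows: Iterable[Sequence[float]],
    alpha: float | None = None,
    run_ids: Sequence[int] | None = None,
) -> CentralCompositeDesign:
    """Assemble a design from explicit coded rows (e.g. a published run table)."""
    factors = list(factors)
    rows = [np.asarray(r, dtype=float) for r in coded_rows]
    if alpha is None:
        mags = {round(abs(v), 6) for r in rows for v in r if abs(v) > 1 + 1e-6}
        alpha = max(mags) if mags else rotatable_alpha(len(factors))
    ids = list(run_ids) if run_ids is not None else list(range(1, len(rows) + 1))
    runs = [
        DesignPoint(
            run_id=i,
            coded=tuple(r),
            actual=tuple(decode_point(factors, r)),
            point_class=classify_point(r, alpha),
        )
        for i, r in zip(ids, rows)
    ]
    return CentralCompositeDesign(factors=factors, runs=runs, alpha=float(alpha))
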