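"""Derringer desirability scoring and optimization over the design region.

Each response is mapped to a desirability d in [0, 1] by a piecewise power
ramp; multiple responses combine into an overall score D as an
importance-weighted geometric mean.  A single maximize goal makes D a
monotone function of the predicted response, so the optimum *location* does
not depend on the ramp limits or weights — only the D value does.

Optimization is deterministic: a dense grid search on the coded scale
followed by a bounded Nelder–Mead polish from the best grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_optimize


class SpecError(ValueError):
    """Invalid desirability specification."""


@dataclass(frozen=True)
class DesirabilitySpec:
    """Derringer ramp for one response.

    For ``goal="maximize"``: d = 0 below ``low``, 1 above ``target`` and
    ((y - low)/(target - low))**weight in between.  ``goal="minimize"``
    mirrors it; ``goal="target"`` ramps up to ``target`` then down to
    ``high``.  ``importance`` is the exponent weight in the composite
    geometric mean.
    """

    goal: str = "maximize"
    low: float = 0.0
    target: float = 1.0
    high: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise SpecError(f"unknown goal {self.goal!r}")
        if self.weight <= 0 or self.importance <= 0:
            raise SpecError("weight and importance must be positive")
        if self.goal in ("maximize", "minimize") and self.target <= self.low:
            raise SpecError("target/upper limit must exceed the lower limit")
        if self.goal == "target":
            hi = self.high if self.high is not None else self.target
            if not (self.low < self.target <= hi):
                raise SpecError("target goal needs low < target <= high")


def desirability(y, spec: DesirabilitySpec):
    """Desirability d(y) in [0, 1] for scalar or array ``y``."""
    y = np.asarray(y, dtype=float)
    L, T, w = spec.low, spec.target, spec.weight
    if spec.goal == "maximize":
        d = np.clip((y - L) / (T - L), 0.0, 1.0) ** w
    elif spec.goal == "minimize":
        d = np.clip((T - y) / (T - L), 0.0, 1.0) ** w
    else:
        H = spec.high if spec.high is not None else spec.target
        up = np.clip((y - L) / (T - L), 0.0, 1.0) ** w
        down = np.ones_like(y) if H == T else np.clip((H - y) / (H - T), 0.0, 1.0) ** w
        d = np.where(y <= T, up, down)
    return d if d.ndim else float(d)


def composite_desirability(d_values, importances=None) -> float:
    """Importance-weighted geometric mean D = (prod d_i^r_i)^(1/sum r_i)."""
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise SpecError("at least one desirability value is required")
    if np.any((d < 0) | (d > 1)):
        raise SpecError("desirabilities must lie in [0, 1]")
    r = np.ones_like(d) if importances is None else np.asarray(importances, float)
    if np.any(r <= 0):
        raise SpecError("importances must be positive")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(r * np.log(d)) / np.sum(r)))


@dataclass
class OptimizationResult:
    """Argmax of the overall desirability over the search box."""

    settings_actual: np.ndarray
    settings_coded: np.ndarray
    predicted_response: float
    D: float
    spec: DesirabilitySpec
    near_optimal: list = field(default_factory=list)


def default_maximize_spec(results) -> DesirabilitySpec:
    """Maximize ramp spanning the observed response range (w = r = 1).

    For a prediction-only surface (no attached observations) the ramp spans
    the predictions at the corners and centre of the factorial box instead.
    """
    if hasattr(results, "model"):
        y = results.model.y_raw
    else:
        k = len(results.factors)
        corners = np.array(list(np.ndindex(*(2,) * k))) * 2.0 - 1.0
        pts = np.vstack([corners, np.zeros(k)])
        y = np.asarray(results.predict(coded=pts, back_transform=True))
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        hi = lo + max(1.0, abs(lo))  # flat surface: any ramp works
    return DesirabilitySpec(goal="maximize", low=lo, target=hi)


def _coded_bounds(results, bounds_actual):
    """Per-factor coded intervals from actual-scale bounds (default: ±1 box)."""
    factors = results.factors
    if bounds_actual is None:
        return [(-1.0, 1.0)] * len(factors)
    if len(bounds_actual) != len(factors):
        raise SpecError("one (low, high) bound pair per factor is required")
    out = []
    for f, (lo, hi) in zip(factors, bounds_actual):
        if hi <= lo:
            raise SpecError(f"empty bounds for factor {f.name!r}")
        out.append((f.code(lo), f.code(hi)))
    return out


def _grid(coded_bounds, grid_density):
    axes = [np.linspace(lo, hi, grid_density) for lo, hi in coded_bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def optimize(results, spec: DesirabilitySpec | None = None,
             bounds_actual=None, grid_density: int = 101,
             refine: bool = True) -> OptimizationResult:
    """Maximize D(predicted response) over a box in factor space.

    ``results`` is a fitted surface (anything with ``factors`` and
    ``predict``).  ``bounds_actual`` gives per-factor (low, high) actual
    intervals; the default is the factorial box (coded [-1, 1]^k).  Ties on
    the grid break toward smaller coded values in factor order; the polish
    step never moves outside the bounds nor below the best grid value.
    """
    if spec is None:
        spec = default_maximize_spec(results)
    cb = _coded_bounds(results, bounds_actual)
    pts = _grid(cb, grid_density)
    yhat = np.asarray(results.predict(coded=pts, back_transform=True), dtype=float)
    d = np.asarray(desirability(yhat, spec), dtype=float)
    # lexicographic tie-break toward smaller coded coordinates
    order = np.lexsort(pts.T[::-1])
    d_sorted = d[order]
    best_idx = order[int(np.argmax(d_sorted))]
    best = pts[best_idx]
    best_d = float(d[best_idx])

    if refine:
        def neg_d(x):
            return -desirability(float(results.predict(coded=x)), spec)

        # desirability plateaus once yhat >= target; polish the response
        # itself for a monotone single-response goal so the argmax is sharp
        if spec.goal == "maximize":
            def neg_d(x):  # noqa: F811
                return -float(results.predict(coded=x, back_transform=True))

        res = sp_optimize.minimize(
            neg_d, best, method="Nelder-Mead",
            bounds=cb, options={"xatol": 1e-8, "fatol": 1e-12},
        )
        cand = np.clip(res.x, [b[0] for b in cb], [b[1] for b in cb])
        cand_y = float(results.predict(coded=cand, back_transform=True))
        if desirability(cand_y, spec) >= best_d - 1e-12:
            best = cand

    y_best = float(results.predict(coded=best, back_transform=True))
    actual = np.array([f.decode(c) for f, c in zip(results.factors, best)])
    return OptimizationResult(
        settings_actual=actual,
        settings_coded=np.asarray(best, dtype=float),
        predicted_response=y_best,
        D=float(desirability(y_best, spec)),
        spec=spec,
    )


def solution_set(results, spec: DesirabilitySpec | None = None,
                 bounds_actual=None, grid_density: int = 51,
                 d_threshold: float = 0.998):
    """Near-optimal region: grid points with D >= threshold and per-factor ranges.

    Returns ``(points, ranges)`` where ``points`` is a structured array of
    (coded, actual, D) rows and ``ranges`` maps factor name to the
    (min, max) actual values attained within the set.  The set may be empty.
    """
    if not (0 < d_threshold <= 1):
        raise SpecError("threshold must lie in (0, 1]")
    if spec is None:
        spec = default_maximize_spec(results)
    cb = _coded_bounds(results, bounds_actual)
    pts = _grid(cb, grid_density)
    yhat = np.asarray(results.predict(coded=pts, back_transform=True), dtype=float)
    d = np.asarray(desirability(yhat, spec), dtype=float)
    keep = d >= d_threshold
    kept = pts[keep]
    factors = results.factors
    actual = np.array([[f.decode(c) for f, c in zip(factors, row)] for row in kept]) \
        if len(kept) else np.empty((0, len(factors)))
    ranges = {
        f.name: (float(actual[:, j].min()), float(actual[:, j].max()))
        for j, f in enumerate(factors)
    } if len(kept) else {}
    return {"coded": kept, "actual": actual, "D": d[keep]}, ranges
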