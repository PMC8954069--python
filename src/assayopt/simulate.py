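"""Seeded generators emulating the assay's data-generating assumptions.

The plate-reader yield surface is modelled as a quadratic in coded factors
on the natural-log scale with multiplicative (log-normal) measurement
noise — the model under which the log transform is variance-stabilizing.
Calibration standards follow a straight line with additive Gaussian noise,
recovery replicates scatter normally around a true recovery, and signal
time series drift linearly.  Every generator is driven by a
``numpy.random.default_rng`` seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import CentralCompositeDesign, Factor
from .datasets import REFERENCE_FACTORS
from .rsm import build_model_matrix, quadratic_terms
from .validation import RecoverySet, StabilitySeries


class SimulationError(ValueError):
    """Invalid simulation configuration."""


#: ln-scale quadratic coefficients of the reference yield surface
#: (terms on coded factors; anchored to the study's fitted effect sizes).
REFERENCE_SURFACE_COEFFS = {
    "1": 10.22,
    "temperature": 0.35,
    "time": 0.46,
    "volume": 0.32,
    "temperature:time": -0.13,
    "temperature:volume": -0.13,
    "time:volume": -0.15,
    "temperature^2": 0.014,
    "time^2": -0.25,
    "volume^2": 0.071,
}

#: ln-scale replicate noise, calibrated to the spread of the four
#: centre-point replicates of the reference design.
DEFAULT_NOISE_SD_LN = 0.13


@dataclass
class TrueSurface:
    """Known ln-scale quadratic truth used to generate synthetic responses."""

    factors: list[Factor] = field(default_factory=lambda: list(REFERENCE_FACTORS))
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_SURFACE_COEFFS))
    noise_sd_ln: float = DEFAULT_NOISE_SD_LN

    def __post_init__(self) -> None:
        if self.noise_sd_ln < 0:
            raise SimulationError("noise SD must be nonnegative")
        expected = quadratic_terms([f.name for f in self.factors])
        missing = set(expected) - set(self.coefficients)
        if missing:
            raise SimulationError(f"missing surface terms: {sorted(missing)}")

    def linear_predictor(self, design: CentralCompositeDesign) -> np.ndarray:
        X = build_model_matrix(design)
        beta = np.array([self.coefficients[t] for t in X.columns])
        return X.to_numpy() @ beta


def simulate_surface(truth: TrueSurface, design: CentralCompositeDesign,
                     seed: int, noise: str = "multiplicative") -> np.ndarray:
    """Simulate raw responses ``exp(x'beta + eps)`` for each design run.

    ``noise="multiplicative"`` draws eps ~ N(0, noise_sd_ln²) on the ln
    scale (log-normal responses); ``noise="additive"`` instead adds
    Gaussian noise of the same relative magnitude on the raw scale, for
    sensitivity checks.
    """
    if len(design.factors) != len(truth.factors):
        raise SimulationError("design and truth disagree on factor count")
    rng = np.random.default_rng(seed)
    eta = truth.linear_predictor(design)
    if noise == "multiplicative":
        eps = rng.normal(0.0, truth.noise_sd_ln, size=len(eta))
        return np.exp(eta + eps)
    if noise == "additive":
        mu = np.exp(eta)
        return mu + rng.normal(0.0, truth.noise_sd_ln * mu, size=len(eta))
    raise SimulationError(f"unknown noise model {noise!r}")


def simulate_calibration(slope: float, intercept: float, noise_sd: float,
                         levels, replicates: int, seed: int):
    """Simulate calibration standards: signal = slope*c + intercept + noise.

    Returns ``(concs, signals)`` with ``replicates`` signals per level.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise SimulationError("at least one concentration level is required")
    if slope <= 0:
        raise SimulationError("calibration slope must be positive")
    rng = np.random.default_rng(seed)
    concs = np.repeat(levels, replicates)
    signals = slope * concs + intercept + rng.normal(0.0, noise_sd, size=concs.size)
    return concs, signals


def simulate_recovery_batch(true_recovery_pct: float, rsd_pct: float,
                            n: int, seed: int, label: str = "sim") -> RecoverySet:
    """Simulate percent-recovery replicates around a true recovery."""
    if n < 2:
        raise SimulationError("a recovery batch needs n >= 2")
    if rsd_pct < 0:
        raise SimulationError("RSD must be nonnegative")
    rng = np.random.default_rng(seed)
    sd = true_recovery_pct * rsd_pct / 100.0
    vals = rng.normal(true_recovery_pct, sd, size=n)
    return RecoverySet(label, vals)


def simulate_signal_timeseries(level: float, drift_pct_per_30min: float,
                               noise_sd: float, timepoints,
                               seed: int) -> StabilitySeries:
    """Simulate a signal-kinetics series: linear drift plus Gaussian noise."""
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SimulationError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    drift = level * (drift_pct_per_30min / 100.0) * (t - t[0]) / 30.0
    s = level + drift + rng.normal(0.0, noise_sd, size=t.size)
    return StabilitySeries(timepoints=t, signals=s)
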