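"""ICH Q2-style validation statistics for a quantitative assay.

Covers linearity (calibration line), blank-based LOD/LOQ, accuracy
(recovery by level), precision (repeatability and intermediate precision),
robustness (recovery under deliberate small condition changes) and signal /
solution stability, each with pass/fail evaluation against configurable
limits.  Sample statistics use the n-1 (Bessel) denominator throughout;
values exactly at a limit pass (limits are inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    """Invalid validation input."""


def rsd_pct(values) -> float:
    """Relative standard deviation, 100 * SD / mean (sample SD, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("at least two values are needed for an RSD")
    return float(100.0 * v.std(ddof=1) / v.mean())


# -- linearity -------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Unweighted OLS calibration line signal = slope * conc + intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    conc_range: tuple[float, float]

    def signal_at(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def back_calc(self, signal):
        """Concentration corresponding to a signal (inverse prediction)."""
        out = (np.asarray(signal, dtype=float) - self.intercept) / self.slope
        return out if out.ndim else float(out)


def fit_calibration(concs, signals) -> CalibrationCurve:
    """Fit the calibration line by unweighted ordinary least squares."""
    c = np.asarray(concs, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.shape != s.shape:
        raise ValidationError("concentration and signal arrays differ in length")
    if np.unique(c).size < 3:
        raise ValidationError("at least 3 distinct concentrations are required")
    res = stats.linregress(c, s)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r2=float(res.rvalue ** 2),
        conc_range=(float(c.min()), float(c.max())),
    )


# -- LOD / LOQ -------------------------------------------------------------

def lod_loq(blank_signals, curve: CalibrationCurve) -> tuple[float, float]:
    """Detection and quantification limits from blank ("zero sample") signals.

    LOD is the back-calculated concentration at (mean blank + 3 SD), LOQ at
    (mean blank + 10 SD); SD is the sample standard deviation of the blank
    signals.  Requires a positive calibration slope.
    """
    b = np.asarray(blank_signals, dtype=float)
    if b.size < 2:
        raise ValidationError("at least two blank signals are required")
    if curve.slope <= 0:
        raise ValidationError("LOD/LOQ need a positive calibration slope")
    mean, sd = b.mean(), b.std(ddof=1)
    return (float(curve.back_calc(mean + 3.0 * sd)),
            float(curve.back_calc(mean + 10.0 * sd)))


# -- recovery containers ---------------------------------------------------

@dataclass
class RecoverySet:
    """Replicate percent recoveries for one level / day / condition."""

    label: str
    recoveries: np.ndarray
    nominal_conc: float | None = None

    def __post_init__(self) -> None:
        self.recoveries = np.asarray(self.recoveries, dtype=float)
        if self.recoveries.size == 0:
            raise ValidationError(f"recovery set {self.label!r} is empty")
        if np.any(self.recoveries <= 0):
            raise ValidationError(f"recovery set {self.label!r} has nonpositive %R")

    @property
    def mean(self) -> float:
        return float(self.recoveries.mean())

    @property
    def sd(self) -> float:
        if self.recoveries.size < 2:
            raise ValidationError("SD needs >= 2 replicates")
        return float(self.recoveries.std(ddof=1))

    @property
    def rsd(self) -> float:
        return rsd_pct(self.recoveries)


# -- accuracy --------------------------------------------------------------

def accuracy_assess(levels: list[RecoverySet],
                    mean_limits: tuple[float, float] = (98.0, 102.0),
                    rsd_max: float = 1.0) -> pd.DataFrame:
    """Per-level mean/SD/%RSD with pass flags.

    A level passes when its mean recovery lies inside ``mean_limits``
    (inclusive) and its %RSD does not exceed ``rsd_max``.  The frame's
    ``attrs["pass"]`` is True only if every level passes both.
    """
    if not levels:
        raise ValidationError("no accuracy levels supplied")
    rows = []
    for lv in levels:
        if lv.recoveries.size < 2:
            raise ValidationError(f"level {lv.label!r} needs >= 2 replicates")
        ok_mean = mean_limits[0] <= lv.mean <= mean_limits[1]
        ok_rsd = lv.rsd <= rsd_max
        rows.append({"level": lv.label, "n": lv.recoveries.size,
                     "mean": lv.mean, "sd": lv.sd, "rsd_pct": lv.rsd,
                     "pass_mean": ok_mean, "pass_rsd": ok_rsd,
                     "pass": ok_mean and ok_rsd})
    out = pd.DataFrame(rows)
    out.attrs["pass"] = bool(out["pass"].all())
    out.attrs["limits"] = {"mean": list(mean_limits), "rsd_max": rsd_max}
    return out


# -- precision -------------------------------------------------------------

def precision_assess(days: list[RecoverySet], rsd_max: float = 2.0,
                     intermediate_method: str = "mean_of_day_rsds") -> dict:
    """Repeatability per day (%RSD_r) and intermediate precision (%RSD_R).

    ``intermediate_method`` selects how the between-day figure is formed:

    - ``"mean_of_day_rsds"`` (default): arithmetic mean of the per-day RSDs;
    - ``"pooled"``: RSD over all measurements pooled across days;
    - ``"anova"``: one-way random-effects reproducibility,
      100*sqrt(s_within^2 + s_between^2)/grand mean, with the between-day
      variance component from the one-way ANOVA mean squares (clipped at 0).
    """
    if len(days) < 2:
        raise ValidationError("intermediate precision needs >= 2 days")
    for d in days:
        if d.recoveries.size < 2:
            raise ValidationError(f"day {d.label!r} needs >= 2 replicates")
    day_rsds = {d.label: d.rsd for d in days}
    allvals = np.concatenate([d.recoveries for d in days])

    if intermediate_method == "mean_of_day_rsds":
        rsd_R = float(np.mean(list(day_rsds.values())))
    elif intermediate_method == "pooled":
        rsd_R = rsd_pct(allvals)
    elif intermediate_method == "anova":
        groups = [d.recoveries for d in days]
        grand = allvals.mean()
        n_per = np.array([len(g) for g in groups])
        ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / \
            (allvals.size - len(groups))
        ms_between = sum(n * (g.mean() - grand) ** 2
                         for n, g in zip(n_per, groups)) / (len(groups) - 1)
        n0 = (allvals.size - (n_per ** 2).sum() / allvals.size) / (len(groups) - 1)
        var_between = max(0.0, (ms_between - ms_within) / n0)
        rsd_R = float(100.0 * np.sqrt(ms_within + var_between) / grand)
    else:
        raise ValidationError(f"unknown intermediate method {intermediate_method!r}")

    flags = {label: r <= rsd_max for label, r in day_rsds.items()}
    return {
        "day_rsd_r": day_rsds,
        "rsd_R": rsd_R,
        "method": intermediate_method,
        "pass_days": flags,
        "pass": bool(all(flags.values()) and rsd_R <= rsd_max),
        "limit_rsd_max": rsd_max,
    }


# -- robustness ------------------------------------------------------------

def robustness_assess(parameter_groups: dict[str, list[RecoverySet]],
                      rsd_max: float = 2.0) -> pd.DataFrame:
    """%RSD across all replicate recoveries per varied parameter.

    Each parameter carries recovery sets for its deliberately perturbed
    condition levels; the statistic pools every individual measurement for
    that parameter.
    """
    if not parameter_groups:
        raise ValidationError("no robustness parameters supplied")
    rows = []
    for param, sets in parameter_groups.items():
        if len(sets) < 2:
            raise ValidationError(f"parameter {param!r} needs >= 2 condition levels")
        pooled = np.concatenate([s.recoveries for s in sets])
        r = rsd_pct(pooled)
        rows.append({"parameter": param,
                     "n_conditions": len(sets),
                     "n_values": pooled.size,
                     "mean": float(pooled.mean()),
                     "rsd_pct": r,
                     "pass": r <= rsd_max})
    out = pd.DataFrame(rows)
    out.attrs["pass"] = bool(out["pass"].all())
    out.attrs["limit_rsd_max"] = rsd_max
    return out


# -- stability -------------------------------------------------------------

@dataclass
class StabilitySeries:
    """Replicate-averaged signal versus time (minutes)."""

    timepoints: np.ndarray
    signals: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.timepoints.shape != self.signals.shape:
            raise ValidationError("timepoints and signals differ in length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError("timepoints must be strictly increasing")


def stability_assess(series: StabilitySeries, window_min: float | None = None,
                     rsd_max: float = 2.0) -> dict:
    """Signal stability over a time window: drift, deviation and %RSD.

    Reports the maximum percent deviation from the t0 signal, the %RSD over
    the window and the least-squares drift slope (signal units per minute).
    """
    t, s = series.timepoints, series.signals
    if window_min is not None:
        if window_min < t[0]:
            raise ValidationError("window ends before the data start")
        keep = t <= t[0] + window_min
        t, s = t[keep], s[keep]
    if t.size < 3:
        raise ValidationError("at least 3 timepoints are needed in the window")
    slope = float(stats.linregress(t, s).slope)
    max_dev = float(np.max(np.abs(s - s[0]) / s[0]) * 100.0)
    r = rsd_pct(s)
    return {
        "max_deviation_pct": max_dev,
        "rsd_pct": r,
        "drift_slope_per_min": slope,
        "pass": r <= rsd_max,
        "limit_rsd_max": rsd_max,
    }


# -- report ----------------------------------------------------------------

@dataclass
class ValidationReport:
    """Aggregated validation outcome across the individual assessments."""

    calibration: CalibrationCurve | None = None
    lod: float | None = None
    loq: float | None = None
    accuracy: pd.DataFrame | None = None
    precision: dict | None = None
    robustness: pd.DataFrame | None = None
    stability: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"schema_version": 1}
        if self.calibration is not None:
            c = self.calibration
            out["calibration"] = {
                "slope": c.slope, "intercept": c.intercept,
                "slope_se": c.slope_se, "intercept_se": c.intercept_se,
                "r2": c.r2, "range": list(c.conc_range),
            }
        if self.lod is not None:
            out["lod"] = self.lod
        if self.loq is not None:
            out["loq"] = self.loq
        if self.accuracy is not None:
            out["accuracy"] = {
                "levels": self.accuracy.to_dict(orient="records"),
                "pass": self.accuracy.attrs.get("pass"),
                "limits": self.accuracy.attrs.get("limits"),
            }
        if self.precision is not None:
            out["precision"] = self.precision
        if self.robustness is not None:
            out["robustness"] = {
                "parameters": self.robustness.to_dict(orient="records"),
                "pass": self.robustness.attrs.get("pass"),
            }
        if self.stability is not None:
            out["stability"] = self.stability
        out.update(self.extras)
        return out
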