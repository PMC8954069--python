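"""Full quadratic response-surface fitting on the (natural-log) response scale.

The model is the standard second-order response surface in coded factors

    g(y) = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fitted by ordinary least squares, where g is the identity or the natural
log.  Fluorescence yields from derivatization reactions typically show
multiplicative error, so the log transform both stabilizes variance and
makes the quadratic a sensible local approximation; predictions are
back-transformed with ``exp``.

Adequacy diagnostics follow standard response-surface practice: ANOVA with
the residual split into lack of fit and pure error (from replicated runs),
the R²/adjusted-R²/predicted-R² family, and per-coefficient t tests with a
significance star notation ("**" for p < 0.01, "***" for p < 0.001).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import CentralCompositeDesign, DesignError, code_point


class FitError(ValueError):
    """Response/transform/rank problems during model fitting."""


def quadratic_terms(factor_names: list[str]) -> list[str]:
    """Term labels in canonical order: 1, linear, two-way interactions, squares."""
    names = list(factor_names)
    terms = ["1"] + names
    terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def build_model_matrix(design: CentralCompositeDesign) -> pd.DataFrame:
    """Model matrix for the full quadratic on the coded scale.

    Columns are ordered intercept, linear, two-way interactions, pure
    quadratics; rows follow the design's run order.
    """
    X = design.coded_matrix
    n, k = X.shape
    n_terms = 1 + k + k * (k - 1) // 2 + k
    if n < n_terms:
        raise FitError(
            f"{n} runs cannot identify the {n_terms}-term quadratic for k={k}"
        )
    cols = [np.ones(n)]
    cols += [X[:, j] for j in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [X[:, j] ** 2 for j in range(k)]
    names = quadratic_terms([f.name for f in design.factors])
    return pd.DataFrame(np.column_stack(cols), columns=names, index=design.run_ids)


@dataclass
class AnovaTable:
    """Sum-of-squares partition with the lack-of-fit vs pure-error split."""

    ss_model: float
    ss_residual: float
    ss_lack_of_fit: float | None
    ss_pure_error: float | None
    ss_total: float
    df_model: int
    df_residual: int
    df_lack_of_fit: int | None
    df_pure_error: int | None
    df_total: int
    f_model: float
    p_model: float
    f_lof: float | None
    p_lof: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("model", self.ss_model, self.df_model, self.f_model, self.p_model),
            ("residual", self.ss_residual, self.df_residual, np.nan, np.nan),
        ]
        if self.ss_lack_of_fit is not None:
            rows += [
                ("lack of fit", self.ss_lack_of_fit, self.df_lack_of_fit,
                 self.f_lof, self.p_lof),
                ("pure error", self.ss_pure_error, self.df_pure_error,
                 np.nan, np.nan),
            ]
        rows.append(("total", self.ss_total, self.df_total, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["source", "SS", "df", "F", "p"])


@dataclass
class FitDiagnostics:
    """R² family and the PRESS statistic."""

    r2: float
    adj_r2: float
    pred_r2: float
    press: float


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


class ResponseSurfaceModel:
    """OLS quadratic response-surface model for a designed experiment.

    Parameters
    ----------
    design : CentralCompositeDesign
        The design whose coded coordinates form the model matrix.
    response : array-like
        Measured responses aligned with ``design.runs`` (raw scale, e.g. RFU).
    transform : {"ln", "none"}
        Response transform applied before fitting.  ``"ln"`` requires
        strictly positive responses.
    """

    def __init__(self, design: CentralCompositeDesign, response, transform: str = "ln"):
        y_raw = np.asarray(response, dtype=float)
        if y_raw.shape != (design.n_runs,):
            raise FitError(
                f"{y_raw.size} responses for {design.n_runs} runs"
            )
        if transform not in ("ln", "none"):
            raise FitError(f"unknown transform {transform!r}")
        if transform == "ln" and np.any(y_raw <= 0):
            raise FitError("ln transform requires strictly positive responses")
        self.design = design
        self.transform = transform
        self.y_raw = y_raw
        self.y_work = np.log(y_raw) if transform == "ln" else y_raw.copy()
        self.exog = build_model_matrix(design)

    @classmethod
    def from_dataframe(cls, design: CentralCompositeDesign, frame: pd.DataFrame,
                       response_col: str = "response", transform: str = "ln"):
        """Build from a run table indexed/keyed by ``run_id``."""
        frame = frame.set_index("run_id") if "run_id" in frame.columns else frame
        y = frame.loc[design.run_ids, response_col].to_numpy(dtype=float)
        return cls(design, y, transform=transform)

    def fit(self) -> "ResponseSurfaceResults":
        X = self.exog.to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FitError("model matrix is rank deficient")
        res = sm.OLS(self.y_work, self.exog).fit()
        return ResponseSurfaceResults(self, res)


class ResponseSurfaceResults:
    """Fitted quadratic surface: coefficients, uncertainties and diagnostics."""

    def __init__(self, model: ResponseSurfaceModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = sm_results.params  # pd.Series indexed by term
        self.bse = sm_results.bse
        self.resid = np.asarray(sm_results.resid, dtype=float)
        self.hat = sm_results.get_influence().hat_matrix_diag
        self.df_resid = int(sm_results.df_resid)
        self.nobs = int(sm_results.nobs)

    # -- inference ---------------------------------------------------------

    @property
    def tvalues(self) -> pd.Series:
        return self._sm.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    def coefficient_tests(self) -> pd.DataFrame:
        """Per-term estimate, SE, t, two-sided p and significance stars."""
        if self.df_resid < 1:
            raise FitError("no residual degrees of freedom for t tests")
        sigma2 = self.resid @ self.resid / self.df_resid
        # a numerically-exact fit leaves no residual variance to test against
        if sigma2 <= 1e-20 * float(np.mean(self.model.y_work ** 2)):
            raise FitError("zero residual variance: t tests undefined")
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "stars": [significance_stars(p) for p in self.pvalues],
            }
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha=alpha)
        ci.columns = ["lower", "upper"]
        return ci

    # -- ANOVA / lack of fit ----------------------------------------------

    def anova_lof(self, require_replicates: bool = True) -> AnovaTable:
        """ANOVA with the residual partitioned into lack of fit and pure error.

        Pure error is the within-group sum of squares over replicate groups
        (runs with identical coded coordinates); lack of fit is the
        remainder of the residual.  With no replicates the partition is
        unavailable; pass ``require_replicates=False`` for the plain table.
        """
        y = self.model.y_work
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(self.resid @ self.resid)
        ss_model = ss_total - ss_res
        n = self.nobs
        p = len(self.params)
        df_model, df_res, df_total = p - 1, n - p, n - 1
        f_model = (ss_model / df_model) / (ss_res / df_res)
        p_model = float(stats.f.sf(f_model, df_model, df_res))

        groups = self.model.design.replicate_groups()
        if not groups:
            if require_replicates:
                raise FitError(
                    "no replicate groups: pure error unavailable "
                    "(pass require_replicates=False for the plain ANOVA)"
                )
            return AnovaTable(ss_model, ss_res, None, None, ss_total,
                              df_model, df_res, None, None, df_total,
                              f_model, p_model, None, None)

        ss_pe = 0.0
        df_pe = 0
        for g in groups:
            vals = y[g]
            ss_pe += float(np.sum((vals - vals.mean()) ** 2))
            df_pe += len(g) - 1
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = np.nan, np.nan
        return AnovaTable(ss_model, ss_res, ss_lof, ss_pe, ss_total,
                          df_model, df_res, df_lof, df_pe, df_total,
                          f_model, p_model, f_lof, p_lof)

    # -- goodness of fit ---------------------------------------------------

    def diagnostics(self) -> FitDiagnostics:
        """R², adjusted R², PRESS and predicted R².

        PRESS uses the exact leave-one-out identity e_(i) = e_i/(1 - h_ii)
        for linear least squares; predicted R² = 1 - PRESS/SS_total.
        """
        y = self.model.y_work
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(self.resid @ self.resid)
        n, p = self.nobs, len(self.params)
        if np.any(self.hat >= 1 - 1e-12):
            raise FitError("a leverage of 1 makes PRESS undefined")
        press = float(np.sum((self.resid / (1.0 - self.hat)) ** 2))
        r2 = 1.0 - ss_res / ss_total
        adj = 1.0 - (ss_res / (n - p)) / (ss_total / (n - 1))
        pred = 1.0 - press / ss_total
        return FitDiagnostics(r2=r2, adj_r2=adj, pred_r2=pred, press=press)

    # -- prediction --------------------------------------------------------

    @property
    def factors(self):
        return self.model.design.factors

    @property
    def transform(self) -> str:
        return self.model.transform

    def _row(self, coded: np.ndarray) -> np.ndarray:
        k = len(self.model.design.factors)
        c = np.atleast_2d(np.asarray(coded, dtype=float))
        if c.shape[1] != k:
            raise DesignError(f"expected {k} coordinates, got {c.shape[1]}")
        cols = [np.ones(len(c))]
        cols += [c[:, j] for j in range(k)]
        cols += [c[:, i] * c[:, j] for i, j in itertools.combinations(range(k), 2)]
        cols += [c[:, j] ** 2 for j in range(k)]
        return np.column_stack(cols)

    def predict(self, actual=None, coded=None, back_transform: bool = True):
        """Predict the response at one or more points.

        Provide the point on the actual scale (physical units) or directly
        on the coded scale.  Under the ln transform and
        ``back_transform=True`` the prediction is ``exp(x'beta)`` on the
        original response scale.  Points beyond the axial distance alpha
        are extrapolations; a warning field is not raised but callers can
        check ``np.linalg.norm(coded)``.
        """
        if (actual is None) == (coded is None):
            raise DesignError("provide exactly one of actual= or coded=")
        if actual is not None:
            actual = np.atleast_2d(np.asarray(actual, dtype=float))
            coded = np.array(
                [code_point(self.model.design.factors, row) for row in actual]
            )
        rows = self._row(coded)
        eta = rows @ self.params.to_numpy()
        if back_transform and self.model.transform == "ln":
            eta = np.exp(eta)
        return eta if eta.size > 1 else float(eta[0])

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report: coefficients with stars, ANOVA, R² family."""
        ct = self.coefficient_tests()
        an = self.anova_lof(require_replicates=False) \
            if not self.model.design.replicate_groups() else self.anova_lof()
        dg = self.diagnostics()
        lines = ["Quadratic response-surface fit"
                 f" (transform={self.model.transform}, n={self.nobs})", ""]
        lines.append(f"{'term':>12} {'coef':>10} {'se':>8} {'t':>8} {'p':>9} stars")
        for term, row in ct.iterrows():
            lines.append(
                f"{term:>12} {row['coef']:>10.4f} {row['se']:>8.4f} "
                f"{row['t']:>8.2f} {row['p']:>9.4f} {row['stars']}"
            )
        lines.append("")
        p_model = "<= 0.0001" if an.p_model < 1e-4 else f"{an.p_model:.4f}"
        lines.append(f"ANOVA: F = {an.f_model:.2f} (p = {p_model})")
        if an.p_lof is not None and np.isfinite(an.p_lof):
            lines.append(
                f"Lack of fit: F = {an.f_lof:.2f} (p = {an.p_lof:.2f}; "
                f"df {an.df_lack_of_fit}/{an.df_pure_error})"
            )
        lines.append(
            f"R2 = {dg.r2:.2f}, adj R2 = {dg.adj_r2:.2f}, pred R2 = {dg.pred_r2:.2f}"
        )
        return "\n".join(lines)

    def to_json(self) -> str:
        """Serialize the fitted model (round-trippable via ``results_from_json``)."""
        an = self.anova_lof(require_replicates=False) \
            if not self.model.design.replicate_groups() else self.anova_lof()
        dg = self.diagnostics()
        payload = {
            "schema_version": 1,
            "transform": self.model.transform,
            "factors": [
                {"name": f.name, "units": f.units, "low": f.low, "high": f.high}
                for f in self.model.design.factors
            ],
            "alpha": self.model.design.alpha,
            "coefficients": {t: float(v) for t, v in self.params.items()},
            "coefficient_se": {t: float(v) for t, v in self.bse.items()},
            "diagnostics": {"r2": dg.r2, "adj_r2": dg.adj_r2,
                            "pred_r2": dg.pred_r2, "press": dg.press},
            "anova": {
                "ss_model": an.ss_model, "ss_residual": an.ss_residual,
                "ss_lack_of_fit": an.ss_lack_of_fit,
                "ss_pure_error": an.ss_pure_error, "ss_total": an.ss_total,
                "df_model": an.df_model, "df_residual": an.df_residual,
                "df_lack_of_fit": an.df_lack_of_fit,
                "df_pure_error": an.df_pure_error,
                "f_model": an.f_model, "p_model": an.p_model,
                "f_lof": an.f_lof, "p_lof": an.p_lof,
            },
        }
        return json.dumps(payload, indent=2)
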