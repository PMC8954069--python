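"""End-to-end replay of the reference optimization and validation analysis.

Fits the ln-scale quadratic surface to the bundled 18-run CCD, runs the
adequacy diagnostics, maximizes the predicted fluorescence over the
factorial box, and recomputes the accuracy and precision statistics from
the bundled validation tables.  The whole report is deterministic.
"""

from __future__ import annotations

from . import datasets
from .desirability import optimize, solution_set, DesirabilitySpec
from .rsm import ResponseSurfaceModel
from .validation import accuracy_assess, precision_assess


def run_reference_pipeline() -> dict:
    """Recompute the full reference analysis from the bundled datasets.

    Returns a nested dict: fitted coefficients with significance stars,
    the ANOVA/lack-of-fit partition, the R² family, the optimum over the
    factorial region with its back-transformed prediction, and the
    accuracy/precision validation statistics with pass flags.
    """
    design, y = datasets.load_design()
    results = ResponseSurfaceModel(design, y, transform="ln").fit()
    ct = results.coefficient_tests()
    an = results.anova_lof()
    dg = results.diagnostics()
    opt = optimize(results)
    # near-optimal region under a ramp reaching the fitted maximum
    spec = DesirabilitySpec(goal="maximize", low=float(y.min()),
                            target=opt.predicted_response)
    _, ranges = solution_set(results, spec=spec, grid_density=61,
                             d_threshold=0.998)

    accuracy = accuracy_assess(datasets.load_accuracy_levels())
    precision = precision_assess(datasets.load_precision_days())

    return {
        "schema_version": 1,
        "model": {
            "transform": "ln",
            "coefficients": {t: float(v) for t, v in results.params.items()},
            "se": {t: float(v) for t, v in results.bse.items()},
            "stars": dict(zip(ct.index, ct["stars"])),
            "intercept": float(results.params["1"]),
        },
        "anova": {
            "f_model": an.f_model, "p_model": an.p_model,
            "f_lof": an.f_lof, "p_lof": an.p_lof,
            "df": {"model": an.df_model, "lack_of_fit": an.df_lack_of_fit,
                   "pure_error": an.df_pure_error},
        },
        "diagnostics": {"r2": dg.r2, "adj_r2": dg.adj_r2,
                        "pred_r2": dg.pred_r2, "press": dg.press},
        "optimum": {
            "settings_actual": [float(v) for v in opt.settings_actual],
            "settings_coded": [float(v) for v in opt.settings_coded],
            "predicted_rfu": opt.predicted_response,
            "near_optimal_ranges": {k: list(v) for k, v in ranges.items()},
        },
        "validation": {
            "accuracy": {
                "levels": accuracy.to_dict(orient="records"),
                "pass": accuracy.attrs["pass"],
            },
            "precision": precision,
        },
    }
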