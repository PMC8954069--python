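"""Bundled reference datasets from a published plate-reader assay
optimization and validation study of fluorogenic pregabalin derivatization.

The study varied three derivatization-reaction factors — temperature (°C),
reaction time (min) and the added volume of 10% triethylamine solution (µL)
— in an 18-run rotatable central composite design read out as fluorescence
(RFU), then validated the optimized assay (recovery accuracy, three-day
precision, robustness).  These tables are exact transcriptions and are kept
byte-stable: thousands separators are stripped and the typeset day columns
of the precision table are resolved positionally into per-day sextets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Factor, design_from_coded
from .validation import RecoverySet

#: Factorial (coded ±1) levels of the three reaction factors.
REFERENCE_FACTORS = [
    Factor("temperature", "degC", 50.0, 72.0),
    Factor("time", "min", 35.0, 85.0),
    Factor("volume", "uL", 50.0, 110.0),
]

_A = 2.0 ** 0.75  # rotatable axial distance for k=3, printed as 1.68

# run_id, coded (A, B, C), fluorescence response (RFU)
_TABLE1 = [
    (1,  (0, 0, 0),    26080),
    (2,  (0, 0, 0),    26490),
    (3,  (_A, 0, 0),   46600),
    (4,  (-_A, 0, 0),  13920),
    (5,  (0, _A, 0),   27960),
    (6,  (0, 0, -_A),  20910),
    (7,  (-1, -1, 1),  20350),
    (8,  (1, 1, -1),   42810),
    (9,  (1, -1, -1),  17280),
    (10, (0, 0, _A),   42690),
    (11, (-1, 1, -1),  21280),
    (12, (0, 0, 0),    25280),
    (13, (1, -1, 1),   39720),
    (14, (-1, -1, -1), 5150),
    (15, (1, 1, 1),    54370),
    (16, (-1, 1, 1),   45850),
    (17, (0, -_A, 0),  5240),
    (18, (0, 0, 0),    33570),
]

_TABLE2 = {  # accuracy: recovery triplicates by spike level
    "80%": {"nominal": 4.00, "values": (100.5, 100.1, 98.92)},
    "100%": {"nominal": 5.00, "values": (99.77, 100.9, 100.2)},
    "120%": {"nominal": 6.00, "values": (98.25, 99.05, 99.16)},
}

_TABLE3 = {  # precision: six recoveries per day at the 100% level
    "day1": (100.32, 101.27, 100.44, 101.28, 100.39, 99.12),
    "day2": (99.08, 101.25, 100.60, 101.28, 100.25, 100.78),
    "day3": (101.33, 100.62, 101.39, 101.32, 102.14, 99.88),
}

_TABLE4 = {  # robustness: mean recovery (n=3) per perturbed condition
    "temperature": {"units": "degC",
                    "conditions": ((71, 101.80), (72, 100.25), (73, 100.27)),
                    "reported_rsd": 0.75},
    "time": {"units": "min",
             "conditions": ((67.8, 100.45), (68.8, 99.95), (69.8, 101.77)),
             "reported_rsd": 0.82},
    "volume": {"units": "uL",
               "conditions": ((108, 100.58), (110, 101.23), (112, 99.57)),
               "reported_rsd": 0.87},
}

DATASET_NAMES = ("table1_design", "table2_accuracy",
                 "table3_precision", "table4_robustness")


def load_design(with_response: bool = True):
    """The 18-run CCD and, optionally, its fluorescence responses.

    Returns ``(design, responses)`` where ``responses`` is a numpy array of
    RFU values aligned with the design's run order, or just the design.
    """
    design = design_from_coded(
        REFERENCE_FACTORS,
        [row for _, row, _ in _TABLE1],
        alpha=_A,
        run_ids=[rid for rid, _, _ in _TABLE1],
    )
    if not with_response:
        return design
    return design, np.array([resp for _, _, resp in _TABLE1], dtype=float)


def load_accuracy_levels() -> list[RecoverySet]:
    return [RecoverySet(label, np.array(d["values"]), nominal_conc=d["nominal"])
            for label, d in _TABLE2.items()]


def load_precision_days() -> list[RecoverySet]:
    return [RecoverySet(day, np.array(vals), nominal_conc=5.00)
            for day, vals in _TABLE3.items()]


def load_robustness_conditions() -> dict[str, list[RecoverySet]]:
    """Per-parameter condition-level mean recoveries (replicates not published)."""
    return {
        param: [RecoverySet(f"{param}={lvl}", np.array([rec]))
                for lvl, rec in d["conditions"]]
        for param, d in _TABLE4.items()
    }


def load_dataset(name: str):
    """Load a bundled dataset by name as a :class:`pandas.DataFrame`.

    Valid names: ``table1_design`` (runs with coded/actual settings and RFU
    response), ``table2_accuracy`` (recovery replicates by level),
    ``table3_precision`` (recovery replicates by day), ``table4_robustness``
    (condition-level mean recoveries by parameter).
    """
    if name == "table1_design":
        design, y = load_design()
        frame = design.to_frame()
        frame["response"] = y
        return frame
    if name == "table2_accuracy":
        rows = [
            {"level": label, "replicate": i + 1, "nominal_conc": d["nominal"],
             "recovery_pct": v}
            for label, d in _TABLE2.items()
            for i, v in enumerate(d["values"])
        ]
        return pd.DataFrame(rows)
    if name == "table3_precision":
        rows = [
            {"day": day, "replicate": i + 1, "recovery_pct": v}
            for day, vals in _TABLE3.items()
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows)
    if name == "table4_robustness":
        rows = [
            {"parameter": param, "units": d["units"], "condition": lvl,
             "mean_recovery_pct": rec, "reported_rsd": d["reported_rsd"]}
            for param, d in _TABLE4.items()
            for lvl, rec in d["conditions"]
        ]
        return pd.DataFrame(rows)
    raise KeyError(
        f"unknown dataset {name!r}; valid names: {', '.join(DATASET_NAMES)}"
    )
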