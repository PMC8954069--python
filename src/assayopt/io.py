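"""CSV/JSON serialization for designs, responses and fitted models.

CSV dialect: comma-delimited UTF-8 with a header row and "." decimal mark.
All writes are atomic (write to a temp file in the destination directory,
then rename), so a crashed write never leaves a half-written file.
Schemas carry a ``schema_version`` field where they are JSON.
"""

from __future__ import annotations

import itertools
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (CentralCompositeDesign, Factor, design_from_coded,
                     make_factor)


class SchemaError(ValueError):
    """A file does not match the expected schema."""


def atomic_write_text(path, text: str) -> None:
    """Write text atomically: temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- factors JSON config ---------------------------------------------------

def read_factors_json(path) -> tuple[list[Factor], int, float | str]:
    """Read a factors config: list of {name, units, low, high} plus options.

    Returns ``(factors, n_center, alpha)`` where alpha may be the keyword
    ``"rotatable"``.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if isinstance(cfg, list):
        cfg = {"factors": cfg}
    try:
        factors = [make_factor(f["name"], f.get("units", ""),
                               f["low"], f["high"]) for f in cfg["factors"]]
    except KeyError as exc:
        raise SchemaError(f"factors config missing key {exc}") from exc
    return factors, int(cfg.get("n_center", 4)), cfg.get("alpha", "rotatable")


# -- design CSV ------------------------------------------------------------

def write_design_csv(path, design: CentralCompositeDesign,
                     response=None) -> None:
    """Write a design (and optional responses) to the design CSV schema.

    Columns: run_id, point_class, one ``<name>_actual`` and one
    ``<name>_coded`` column per factor, and ``response`` when given.
    Actual values are rounded to 2 decimals at serialization only.
    """
    frame = design.to_frame()
    for f in design.factors:
        frame[f"{f.name}_actual"] = frame[f"{f.name}_actual"].round(2)
    if response is not None:
        frame["response"] = np.asarray(response, dtype=float)
    atomic_write_text(path, frame.to_csv(index=False))


def read_design_csv(path, factors: list[Factor] | None = None):
    """Read a design CSV back into typed objects.

    Returns ``(design, response)`` where ``response`` is None when the file
    has no response column.  Factor low/high levels are recovered from the
    coded/actual columns when ``factors`` is not supplied.  Schema
    violations raise :class:`SchemaError` naming the offending column/row.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"cannot parse design CSV {path}: {exc}") from exc
    if "run_id" not in frame.columns:
        raise SchemaError("design CSV is missing the run_id column")
    if frame["run_id"].duplicated().any():
        dup = frame.loc[frame["run_id"].duplicated(), "run_id"].iloc[0]
        raise SchemaError(f"duplicate run_id {dup}")
    names = [c[:-len("_coded")] for c in frame.columns if c.endswith("_coded")]
    if not names:
        raise SchemaError("design CSV has no *_coded columns")
    for col in [f"{n}_actual" for n in names] + [f"{n}_coded" for n in names]:
        if col not in frame.columns:
            raise SchemaError(f"design CSV is missing column {col!r}")
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index[0]
            raise SchemaError(f"non-numeric value in column {col!r}, row {bad}")

    if factors is None:
        factors = []
        for n in names:
            coded = frame[f"{n}_coded"].to_numpy(float)
            actual = frame[f"{n}_actual"].to_numpy(float)
            # recover the affine coding map from two distinct coded levels
            order = np.argsort(coded)
            c_lo, c_hi = coded[order[0]], coded[order[-1]]
            if c_hi - c_lo < 1e-9:
                raise SchemaError(f"factor {n!r} has a single coded level")
            a_lo, a_hi = actual[order[0]], actual[order[-1]]
            half = (a_hi - a_lo) / (c_hi - c_lo)
            center = a_lo - c_lo * half
            factors.append(make_factor(n, "", center - half, center + half))

    coded_rows = frame[[f"{n}_coded" for n in names]].to_numpy(float)
    design = design_from_coded(factors, coded_rows,
                               run_ids=frame["run_id"].astype(int).tolist())
    response = frame["response"].to_numpy(float) if "response" in frame.columns \
        else None
    return design, response


def read_response_csv(path, design: CentralCompositeDesign) -> np.ndarray:
    """Read a (run_id, response) CSV aligned to a design's run order."""
    frame = pd.read_csv(path)
    for col in ("run_id", "response"):
        if col not in frame.columns:
            raise SchemaError(f"response CSV is missing column {col!r}")
    lookup = dict(zip(frame["run_id"].astype(int), frame["response"].astype(float)))
    missing = [r for r in design.run_ids if r not in lookup]
    if missing:
        raise SchemaError(f"response CSV is missing run_ids {missing}")
    return np.array([lookup[r] for r in design.run_ids])


# -- fitted-model JSON -----------------------------------------------------

class SurfacePredictor:
    """Prediction-only view of a fitted quadratic surface loaded from JSON.

    Exposes the same ``factors`` / ``predict`` interface the optimizer
    consumes, so a serialized model can be optimized without refitting.
    """

    def __init__(self, factors: list[Factor], coefficients: dict[str, float],
                 transform: str):
        self.factors = factors
        self.coefficients = coefficients
        self.transform = transform
        from .rsm import quadratic_terms
        self._terms = quadratic_terms([f.name for f in factors])
        self._beta = np.array([coefficients[t] for t in self._terms])

    def predict(self, actual=None, coded=None, back_transform: bool = True):
        from .design import code_point
        if (actual is None) == (coded is None):
            raise SchemaError("provide exactly one of actual= or coded=")
        if actual is not None:
            actual = np.atleast_2d(np.asarray(actual, dtype=float))
            coded = np.array([code_point(self.factors, r) for r in actual])
        c = np.atleast_2d(np.asarray(coded, dtype=float))
        k = len(self.factors)
        cols = [np.ones(len(c))]
        cols += [c[:, j] for j in range(k)]
        cols += [c[:, i] * c[:, j] for i, j in itertools.combinations(range(k), 2)]
        cols += [c[:, j] ** 2 for j in range(k)]
        eta = np.column_stack(cols) @ self._beta
        if back_transform and self.transform == "ln":
            eta = np.exp(eta)
        return eta if eta.size > 1 else float(eta[0])


def write_model_json(path, results) -> None:
    atomic_write_text(path, results.to_json())


def read_model_json(path) -> SurfacePredictor:
    """Load a serialized fit back as a :class:`SurfacePredictor`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        factors = [make_factor(f["name"], f.get("units", ""), f["low"], f["high"])
                   for f in payload["factors"]]
        return SurfacePredictor(factors, payload["coefficients"],
                                payload["transform"])
    except KeyError as exc:
        raise SchemaError(f"model JSON missing key {exc}") from exc
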