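"""Applying fitted or published models to held-out compounds.

External validation in QSPR compares the property value a model
*calculates* from a new compound's descriptor against the
experimentally tabulated value.  Models can be :class:`~.qspr.FitResult`
objects produced in-package or plain printed-coefficient models taken
from the literature — the latter are first-class so that a published
validation table can be reproduced without regenerating any training
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qspr import FAMILIES, FitResult, RegressionDataset

__all__ = ["PredictionRecord", "predict", "validation_table", "residual_table"]


@dataclass(frozen=True)
class PredictionRecord:
    """One model evaluation on one compound."""

    compound: str
    property: str
    model: str
    x: float
    calculated: float
    experimental: float | None = None

    @property
    def residual(self) -> float | None:
        if self.experimental is None:
            return None
        return self.experimental - self.calculated


def _coeffs(model) -> tuple[str, float, tuple[float | None, ...]]:
    if isinstance(model, FitResult):
        return model.family, model.a, model.b
    if isinstance(model, Mapping):
        return model["family"], float(model["a"]), tuple(model.get("b", ()))
    raise TypeError(f"cannot interpret model of type {type(model).__name__}")


def predict(model, x: float) -> float:
    """Evaluate a family equation at descriptor value ``x``.

    Excluded or unused slope slots count as zero.  The logarithmic
    family requires x > 0.
    """
    family, a, b = _coeffs(model)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    b1, b2, b3 = (list(b) + [None, None, None])[:3]
    b1 = b1 or 0.0
    b2 = b2 or 0.0
    b3 = b3 or 0.0
    if family in ("linear", "quadratic", "cubic"):
        return a + b1 * x + b2 * x ** 2 + b3 * x ** 3
    if family == "logarithmic":
        if x <= 0:
            raise ValueError("logarithmic model requires x > 0")
        return a + b1 * math.log(x)
    return a * math.exp(b1 * x)


def validation_table(
    models: Sequence[Mapping | FitResult],
    new_descriptors: pd.DataFrame,
    new_properties: pd.DataFrame | None = None,
    model_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Experimental-vs-calculated comparison for held-out compounds.

    Each model must carry the ``descriptor`` column it consumes and the
    ``property`` it predicts (FitResults may be passed as dicts from
    :func:`~.qspr.fit_to_dict` to attach these).  Returns one row per
    (model, compound) with columns compound, property, model, x,
    calculated, experimental, residual.  Calculated values keep full
    precision; round at serialization.
    """
    rows = []
    for pos, model in enumerate(models):
        if isinstance(model, Mapping):
            descriptor = model.get("descriptor")
            prop = model.get("property")
        else:
            raise TypeError("pass models as mappings with 'descriptor' and 'property' keys")
        if descriptor is None or prop is None:
            raise ValueError(f"model #{pos} lacks a descriptor or property name")
        if descriptor not in new_descriptors.columns:
            raise KeyError(f"missing descriptor column {descriptor!r} for model #{pos}")
        label = (
            model_names[pos]
            if model_names is not None
            else f"{prop}~{model['family']}({descriptor})"
        )
        for compound in new_descriptors.index:
            x = float(new_descriptors.at[compound, descriptor])
            calc = predict(model, x)
            exp_val = None
            if new_properties is not None and prop in new_properties.columns:
                v = new_properties.at[compound, prop] if compound in new_properties.index else None
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    exp_val = float(v)
            rows.append(
                {
                    "compound": compound,
                    "property": prop,
                    "model": label,
                    "x": x,
                    "calculated": calc,
                    "experimental": exp_val,
                    "residual": None if exp_val is None else exp_val - calc,
                }
            )
    return pd.DataFrame(
        rows, columns=["compound", "property", "model", "x", "calculated", "experimental", "residual"]
    )


def residual_table(fit, data: RegressionDataset) -> pd.DataFrame:
    """Per-compound predicted values and residuals on the training data.

    The returned frame carries ``mean_residual`` and ``rmse`` in its
    ``attrs``; for any intercept OLS fit the mean residual is 0 and
    RMSE = SE * sqrt((n - k - 1)/n).
    """
    preds = np.array([predict(fit, xi) for xi in data.x])
    observed = data.y
    if isinstance(fit, FitResult) and fit.family == "exponential":
        # residual diagnostics on the fitting (log) scale
        preds_scale = np.log(preds)
        observed_scale = np.log(observed)
    else:
        preds_scale, observed_scale = preds, observed
    resid = observed_scale - preds_scale
    labels = data.labels if data.labels is not None else [str(i) for i in range(data.n)]
    out = pd.DataFrame(
        {"x": data.x, "observed": observed, "predicted": preds, "residual": resid},
        index=pd.Index(labels, name="compound"),
    )
    out.attrs["mean_residual"] = float(resid.mean())
    out.attrs["rmse"] = float(np.sqrt((resid ** 2).mean()))
    return out
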