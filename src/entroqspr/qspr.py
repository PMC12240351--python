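"""Curvilinear single-descriptor regression with a full statistics block.

Five model families link a physicochemical property Y to a single
molecular descriptor X:

    linear        Y = a + b1 X
    quadratic     Y = a + b1 X + b2 X^2
    cubic         Y = a + b1 X + b2 X^2 + b3 X^3
    logarithmic   Y = a + b1 ln X
    exponential   Y = a exp(b1 X), fitted as ln Y = ln a + b1 X

All families are solved by ordinary least squares; the transformed
families report every goodness-of-fit statistic on the transformed
scale, following the curve-estimation convention of classic statistics
packages.  With k slope coefficients and n observations:

    r^2    = 1 - SSE/SST          (SST about the mean)
    r      = sign(b1) sqrt(r^2) for single-predictor families,
             +sqrt(r^2) for polynomial families
    adj R2 = 1 - (1 - r^2)(n - 1)/(n - k - 1)
    SE     = sqrt(SSE / (n - k - 1))
    F      = (r^2/k) / ((1 - r^2)/(n - k - 1)),  p = upper F tail (k, n-k-1)
    CI     = estimate +/- t(0.975, n-k-1) * coefficient standard error

Collinearity guard
------------------
Polynomial designs on a narrow, strictly positive descriptor range are
nearly singular (x, x^2, x^3 are almost collinear).  Classic
curve-estimation software resolves this by refusing to enter a term
whose entry would push any in-model term's *tolerance* (the fraction of
its variance unexplained by the other terms) below a minimum, and that
convention is what published QSPR tables reflect.  ``fit_model``
reproduces it when ``collinearity_tol`` is set: terms are offered in
descending degree and a candidate is skipped if the resulting minimum
tolerance would fall below the threshold.  The default is ``None``
(plain full-design OLS); report generation enables the guard at the
conventional 1e-4 so that rendered tables match the published ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "FAMILIES",
    "RegressionDataset",
    "FitResult",
    "fit_model",
    "fit_report",
    "best_model",
    "fit_to_dict",
    "fit_from_dict",
]

FAMILIES: tuple[str, ...] = ("linear", "quadratic", "cubic", "logarithmic", "exponential")

_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}
#: number of slope coefficients per family (full design)
_K = {"linear": 1, "quadratic": 2, "cubic": 3, "logarithmic": 1, "exponential": 1}


@dataclass(frozen=True)
class RegressionDataset:
    """Paired descriptor/property observations for one regression."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-d sequences of equal length")
        if self.labels is not None and len(self.labels) != len(x):
            raise ValueError("labels length mismatch")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in regression data")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class FitResult:
    """One fitted curvilinear model with its statistics block.

    ``b`` always has three slots (b1, b2, b3); slots the family does not
    use — or that the collinearity guard excluded — are ``None``.  For
    the exponential family ``a`` is the multiplicative constant
    a = exp(fitted intercept) while the statistics refer to the fit of
    ln Y on X.
    """

    family: str
    a: float
    b: tuple[float | None, float | None, float | None]
    r: float
    r2: float
    adj_r2: float
    se: float
    F: float
    p: float
    coef_ci: Mapping[str, tuple[float, float]]
    df: int
    n: int
    k: int
    std_beta: float | None = None
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"r2 out of range: {self.r2}")
        if abs(self.r * self.r - self.r2) > 1e-9:
            raise ValueError("r^2 != r2")


def _design(family: str, x: np.ndarray, powers: Sequence[int] | None = None) -> tuple[np.ndarray, list[str]]:
    if family in _POLY_DEGREE:
        powers = powers if powers is not None else range(1, _POLY_DEGREE[family] + 1)
        cols = [x ** p for p in powers]
        names = [f"b{p}" for p in powers]
    elif family == "logarithmic":
        cols, names = [np.log(x)], ["b1"]
    elif family == "exponential":
        cols, names = [x], ["b1"]
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return np.column_stack(cols), names


def _tolerances(X: np.ndarray) -> np.ndarray:
    """Per-column tolerance: 1 - R^2 of the column on the remaining columns."""
    n, p = X.shape
    if p == 1:
        return np.ones(1)
    out = np.empty(p)
    for idx in range(p):
        target = X[:, idx]
        others = np.column_stack([np.ones(n), np.delete(X, idx, axis=1)])
        beta, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        sst = ((target - target.mean()) ** 2).sum()
        out[idx] = (resid ** 2).sum() / sst if sst > 0 else 0.0
    return out


def _guarded_powers(x: np.ndarray, degree: int, tol: float) -> tuple[list[int], list[int]]:
    """Enter polynomial terms highest degree first under a tolerance floor.

    Returns (entered powers ascending, excluded powers).
    """
    entered: list[int] = []
    excluded: list[int] = []
    for p in range(degree, 0, -1):
        trial = sorted(entered + [p])
        X = np.column_stack([x ** q for q in trial])
        if len(trial) > 1 and _tolerances(X).min() < tol:
            excluded.append(p)
        else:
            entered = trial
    return entered, sorted(excluded)


def fit_model(
    data: RegressionDataset,
    family: str,
    collinearity_tol: float | None = None,
) -> FitResult:
    """Fit one curvilinear family by ordinary least squares.

    Parameters
    ----------
    data
        The descriptor/property pairs.
    family
        One of ``linear, quadratic, cubic, logarithmic, exponential``.
    collinearity_tol
        If set, apply the curve-estimation tolerance guard to polynomial
        designs (see module docstring); ``None`` fits the full design.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x, y = data.x, data.y
    n = data.n
    k_full = _K[family]
    if n < k_full + 2:
        raise ValueError(f"{family} family needs at least {k_full + 2} points, got {n}")
    if family == "logarithmic" and (x <= 0).any():
        raise ValueError("logarithmic family requires strictly positive x")
    if family == "exponential" and (y <= 0).any():
        raise ValueError("exponential family requires strictly positive y")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x values identical")

    powers: Sequence[int] | None = None
    excluded: tuple[str, ...] = ()
    if collinearity_tol is not None and family in _POLY_DEGREE:
        entered, dropped = _guarded_powers(x, _POLY_DEGREE[family], collinearity_tol)
        powers = entered
        excluded = tuple(f"b{p}" for p in dropped)

    X, names = _design(family, x, powers)
    response = np.log(y) if family == "exponential" else y
    model = sm.OLS(response, sm.add_constant(X, prepend=True))
    res = model.fit()

    k = X.shape[1]
    dof = n - k - 1
    if dof <= 0:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, k={k})")

    sse = float(res.ssr)
    sst = float(((response - response.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    se = math.sqrt(sse / dof)
    if r2 >= 1.0:
        fstat, p = math.inf, 0.0
    else:
        fstat = (r2 / k) / ((1.0 - r2) / dof)
        p = float(scipy.stats.f.sf(fstat, k, dof))

    params = res.params
    intercept = float(params[0])
    slope_map = dict(zip(names, (float(v) for v in params[1:])))
    b: list[float | None] = [None, None, None]
    for label, value in slope_map.items():
        b[int(label[1]) - 1] = value

    if family in ("linear", "logarithmic", "exponential"):
        r = math.copysign(math.sqrt(r2), slope_map["b1"])
    else:
        r = math.sqrt(r2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof

    tcrit = scipy.stats.t.ppf(0.975, dof)
    bse = res.bse
    ci: dict[str, tuple[float, float]] = {
        "a": (intercept - tcrit * float(bse[0]), intercept + tcrit * float(bse[0]))
    }
    for idx, label in enumerate(names, start=1):
        est = float(params[idx])
        half = tcrit * float(bse[idx])
        ci[label] = (est - half, est + half)

    std_beta = None
    if family in ("linear", "logarithmic", "exponential"):
        pred = X[:, 0]
        sx, sy = pred.std(ddof=1), response.std(ddof=1)
        if sy > 0:
            std_beta = slope_map["b1"] * sx / sy

    a = math.exp(intercept) if family == "exponential" else intercept
    if family == "exponential":
        # the intercept CI transforms monotonically to the multiplicative scale
        ci["a"] = (math.exp(ci["a"][0]), math.exp(ci["a"][1]))

    return FitResult(
        family=family,
        a=a,
        b=tuple(b),
        r=r,
        r2=r2,
        adj_r2=adj_r2,
        se=se,
        F=fstat,
        p=p,
        coef_ci=ci,
        df=dof,
        n=n,
        k=k,
        std_beta=std_beta,
        excluded=excluded,
    )


def fit_report(
    descriptors: pd.DataFrame,
    properties: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    index_columns: Sequence[str] | None = None,
    property_columns: Sequence[str] | None = None,
    collinearity_tol: float | None = 1e-4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per (descriptor column, property, family) with the full block.

    Compound labels must align between the two tables.  The guard is on
    by default so the rendered tables follow the published convention.
    """
    mismatch = descriptors.index.symmetric_difference(properties.index)
    if len(mismatch):
        raise ValueError(f"compound labels do not align: {sorted(mismatch)}")
    properties = properties.loc[descriptors.index]

    index_columns = list(index_columns) if index_columns is not None else list(descriptors.columns)
    property_columns = (
        list(property_columns) if property_columns is not None else list(properties.columns)
    )
    bad = [f for f in families if f not in FAMILIES]
    if bad:
        raise ValueError(f"unknown families: {bad}")

    rows = []
    for prop in property_columns:
        y = properties[prop].to_numpy(dtype=float)
        for ix in index_columns:
            xv = descriptors[ix].to_numpy(dtype=float)
            data = RegressionDataset(xv, y, labels=tuple(descriptors.index))
            for fam in families:
                fit = fit_model(data, fam, collinearity_tol=collinearity_tol)
                rows.append(
                    {
                        "index": ix,
                        "property": prop,
                        "family": fam,
                        "a": fit.a,
                        "b1": fit.b[0],
                        "b2": fit.b[1],
                        "b3": fit.b[2],
                        "r": fit.r,
                        "r2": fit.r2,
                        "adj_r2": fit.adj_r2,
                        "se": fit.se,
                        "F": fit.F,
                        "p": fit.p,
                        "significant": "Significant" if fit.p <= alpha else "Not significant",
                    }
                )
    return pd.DataFrame(rows)


def best_model(report: pd.DataFrame) -> pd.DataFrame:
    """Select, per (index, property), the family with the highest r2.

    Ties are broken toward the family with fewer slope coefficients.
    """
    if report.empty:
        raise ValueError("empty report")
    df = report.copy()
    df["_k"] = df["family"].map(_K)
    df = df.sort_values(["r2", "_k"], ascending=[False, True], kind="stable")
    out = df.groupby(["index", "property"], sort=True).head(1).drop(columns="_k")
    return out.reset_index(drop=True)


def round_report(report: pd.DataFrame, coef_dp: int = 1, r_dp: int = 2, r2_dp: int = 3) -> pd.DataFrame:
    """Apply the rounding profile used in published tables (serialization only)."""
    out = report.copy()
    for c in ("a", "b1", "b2", "b3", "se", "F"):
        if c in out:
            out[c] = out[c].round(coef_dp)
    if "r" in out:
        out["r"] = out["r"].round(r_dp)
    for c in ("r2", "adj_r2", "p"):
        if c in out:
            out[c] = out[c].round(r2_dp)
    return out


def fit_to_dict(fit: FitResult, descriptor: str | None = None, property_name: str | None = None) -> dict:
    """JSON-serializable form of a fitted model (consumed by prediction)."""
    return {
        "family": fit.family,
        "a": fit.a,
        "b": [v for v in fit.b],
        "descriptor": descriptor,
        "property": property_name,
        "stats": {
            "r": fit.r,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "se": fit.se,
            "F": None if math.isinf(fit.F) else fit.F,
            "p": fit.p,
            "n": fit.n,
            "k": fit.k,
        },
    }


def fit_from_dict(d: Mapping) -> dict:
    """Validate a model JSON object into the plain-coefficient form."""
    fam = d.get("family")
    if fam not in FAMILIES:
        raise ValueError(f"unknown family {fam!r} in model JSON")
    b = list(d.get("b", []))
    if len(b) > 3:
        raise ValueError("too many slope coefficients")
    b = (b + [None, None, None])[:3]
    return {
        "family": fam,
        "a": float(d["a"]),
        "b": tuple(None if v is None else float(v) for v in b),
        "descriptor": d.get("descriptor"),
        "property": d.get("property"),
    }


def dump_models(models: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(list(models), fh, indent=2, sort_keys=True)


def load_models(path) -> list[dict]:
    with open(path) as fh:
        raw = json.load(fh)
    return [fit_from_dict(d) for d in raw]
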