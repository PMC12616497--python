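"""Severity scoring: harmonization, standardization, and component weights.

The deployable global-severity score is a weighted average of the nine
harmonized clinical-outcome scores.  Weights come from an ordinary
least-squares regression of the (standardized) SEM factor score on the nine
harmonized indicators over complete cases, with the slope coefficients
rescaled to sum to one so the composite lives on the same 0-100 metric as
its components.  A published default weight set is shipped for use when no
cohort is available to re-derive weights.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import HIGHER_IS_BETTER, OBSERVED_VARS, SCALE_RANGES

log = logging.getLogger(__name__)


def harmonize(cohort: pd.DataFrame, *, orientation: dict[str, bool] | None = None,
              ranges: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Map every observed score to a common 0-100 severity direction.

    x' = 100 * (x - min) / (max - min), then x' <- 100 - x' for variables
    whose raw direction is higher-is-better.  Values outside the declared
    range raise, naming the row and column.
    """
    orientation = dict(HIGHER_IS_BETTER if orientation is None else orientation)
    ranges = {v: SCALE_RANGES[v] for v in OBSERVED_VARS} if ranges is None else dict(ranges)
    out = cohort.copy()
    for var in OBSERVED_VARS:
        lo, hi = ranges[var]
        x = out[var].to_numpy(dtype=float)
        bad = ~np.isnan(x) & ((x < lo - 1e-9) | (x > hi + 1e-9))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"value {x[bad][0]!r} in column {var!r} (row {row}) outside "
                f"declared range [{lo}, {hi}]")
        h = 100.0 * (x - lo) / (hi - lo)
        if orientation.get(var, False):
            h = 100.0 - h
        out[var] = h
    return out


def standardize(scores) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator).

    NaNs are ignored in the moments and propagated in the output.  Fewer
    than two distinct finite values is an error (zero variance would
    otherwise silently propagate NaN).
    """
    x = np.asarray(scores, dtype=float)
    finite = x[~np.isnan(x)]
    if np.unique(finite).size < 2:
        raise ValueError("standardize needs at least two distinct values")
    sd = finite.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: cannot standardize")
    return (x - finite.mean()) / sd


@dataclass
class WeightSet:
    """Nine component weights over the observed variables, unit sum."""

    weights: dict[str, float]
    provenance: str = "derived"

    def __post_init__(self) -> None:
        missing = set(OBSERVED_VARS) - set(self.weights)
        if missing:
            raise ValueError(f"weight set is missing variables: {sorted(missing)}")
        s = sum(self.weights.values())
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1 (got {s!r})")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.weights[v] for v in OBSERVED_VARS])

    @classmethod
    def from_raw(cls, raw: dict[str, float], provenance: str = "derived") -> "WeightSet":
        """Rescale raw coefficients by their sum to satisfy unit sum."""
        s = sum(raw.values())
        if abs(s) < 1e-10:
            raise ValueError("coefficient sum is (numerically) zero; "
                             "unit-sum rescaling is undefined")
        return cls({k: float(v / s) for k, v in raw.items()},
                   provenance=provenance)

    def to_json(self, path: str | Path, *, meta: dict | None = None) -> None:
        payload = {"weights": self.weights, "provenance": self.provenance}
        if meta:
            payload["_provenance"] = meta
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightSet":
        payload = json.loads(Path(path).read_text())
        return cls.from_raw(payload["weights"],
                            provenance=payload.get("provenance", "file"))


def default_weights() -> WeightSet:
    """The published default component weights.

    The printed constants sum to 0.999 after rounding; they are renormalized
    by their sum at load so the unit-sum invariant holds while preserving
    the printed ratios.
    """
    text = importlib.resources.files("cddsev.data").joinpath(
        "default_weights.json").read_text()
    payload = json.loads(text)
    return WeightSet.from_raw(payload["weights"], provenance="published-default")


def derive_weights(harmonized: pd.DataFrame, scores, *,
                   provenance: str = "derived") -> WeightSet:
    """Regress the standardized global score on the nine harmonized
    indicators over complete cases only; rescale slopes to unit sum.

    ``scores`` is a per-row vector aligned with ``harmonized`` (the
    standardized global factor score).  The intercept is discarded.
    Negative slopes are kept, with a warning, since a negative weight
    breaks the weighted-average reading of the composite.
    """
    y = np.asarray(scores, dtype=float)
    X = harmonized[list(OBSERVED_VARS)].to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    n_cc = int(ok.sum())
    if n_cc <= len(OBSERVED_VARS):
        raise ValueError(
            f"only {n_cc} complete cases; need more than {len(OBSERVED_VARS)}")
    design = sm.add_constant(X[ok])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix in weight regression")
    res = sm.OLS(y[ok], design).fit()
    raw = dict(zip(OBSERVED_VARS, res.params[1:]))
    if any(v < 0 for v in raw.values()):
        neg = [k for k, v in raw.items() if v < 0]
        warnings.warn(f"negative regression slopes for {neg}; the weighted "
                      "average is no longer a convex combination", stacklevel=2)
    log.info("weight regression on %d complete cases, R^2=%.6f", n_cc, res.rsquared)
    return WeightSet.from_raw(raw, provenance=provenance)


def apply_weights(subject_scores, weights: WeightSet, *,
                  missing: str = "error") -> float | np.ndarray:
    """Weighted-average global severity on the component 0-100 metric.

    ``subject_scores`` is a mapping or DataFrame of harmonized scores.
    Missing components: ``missing='error'`` (default) refuses and names the
    absent components; ``missing='renormalize'`` reweights the present ones
    (an extrapolation beyond the published procedure).
    """
    w = weights.as_array
    if isinstance(subject_scores, pd.DataFrame):
        X = subject_scores[list(OBSERVED_VARS)].to_numpy(dtype=float)
    else:
        X = np.array([[float(subject_scores.get(v, np.nan)) for v in OBSERVED_VARS]])
    nan = np.isnan(X)
    if missing == "error":
        if nan.any():
            row = int(np.flatnonzero(nan.any(axis=1))[0])
            absent = [v for v, m in zip(OBSERVED_VARS, nan[row]) if m]
            raise ValueError(f"missing components {absent} (row {row}); "
                             "select an imputation policy to score anyway")
        out = X @ w
    elif missing == "renormalize":
        wm = np.where(nan, 0.0, w)
        denom = wm.sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError("no positively-weighted components present")
        out = np.nansum(X * wm, axis=1) / denom
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    return float(out[0]) if out.size == 1 and not isinstance(
        subject_scores, pd.DataFrame) else out
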