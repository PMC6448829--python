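"""Linear models of WGBS differential methylation from MREBS/RRBS signals.

Per CpG dimer, four signals are assembled (all differential, sample A minus
sample B):

- ``y``  — WGBS conversion-based differential methylation (the response),
- ``r``  — RRBS conversion-based differential methylation,
- ``x1`` — MREBS conversion-based differential methylation,
- ``x2`` — MREBS read-count difference in the 1 kb window around the dimer.

The four OLS models are

1. ``y = b0 + b*r``          (RRBS benchmark)
2. ``y = b0 + b1*x1 + b2*x2`` (both MREBS signals)
3. ``y = b0 + b1*x1``         (conversion signal only)
4. ``y = b0 + b2*x2``         (count signal only)

Model 4 applies wherever the window-count filter passes (~most of the
genome); model 2 only where the 5X conversion filter also passes. The
*combined* estimator takes the model-2 prediction where available and the
model-4 prediction elsewhere — accuracy where the data support it, coverage
everywhere else. Because MRE cutting is blocked by methylation, the model-4
slope is expected to be negative.

Fit quality is summarised by R², the observed-vs-fitted Pearson
correlation, RMSE and MAE in percentage points, and concordance metrics
``methylN``: the percentage of dimers where |observed - fitted| <= N
percentage points (N = 15, 25 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

MODEL_PREDICTORS: Dict[int, Tuple[str, ...]] = {
    1: ("r",),
    2: ("x1", "x2"),
    3: ("x1",),
    4: ("x2",),
}


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit of one of the four differential-methylation models."""

    model_id: int
    predictors: Tuple[str, ...]
    intercept: float
    coefficients: Dict[str, float]
    n: int
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class MetricsReport:
    """Observed-vs-fitted evaluation metrics (percent scale).

    ``concordance`` maps each threshold N (percentage points) to the
    percentage of dimers with |observed - fitted| <= N.
    """

    n: int
    correlation: Optional[float]
    rmse: float
    mae: float
    concordance: Dict[int, float]

    @property
    def methyl15(self) -> Optional[float]:
        return self.concordance.get(15)

    @property
    def methyl25(self) -> Optional[float]:
        return self.concordance.get(25)

    def to_dict(self) -> Dict[str, float]:
        out = {"n": self.n, "correlation": self.correlation, "rmse": self.rmse,
               "mae": self.mae}
        for t, v in self.concordance.items():
            out[f"methyl{t}"] = v
        return out


def fit_ols(
    y: np.ndarray, design_columns: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Ordinary least squares with an intercept.

    Parameters
    ----------
    y : (n,) response vector.
    design_columns : (n, k) predictor matrix, k in {1, 2}, without the
        intercept column (it is added here).

    Returns ``(params, fitted, r_squared)`` with ``params[0]`` the
    intercept. Raises on rank-deficient designs, constant predictors,
    zero response variance, or too few observations (n must exceed the
    coefficient count by at least 2).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design_columns, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(y) != n:
        raise ValueError("response and design lengths differ")
    if n < k + 1 + 2:
        raise ValueError(f"need at least {k + 3} observations, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("zero response variance: R-squared undefined")
    if any(np.ptp(X[:, j]) == 0 for j in range(k)):
        raise ValueError("constant predictor column")
    design = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    return res.params, res.fittedvalues, float(res.rsquared)


def fit_model(records: pd.DataFrame, model_id: int) -> ModelFit:
    """Fit one of models 1–4 on the records where y and the model's
    predictors are all present (non-NaN)."""
    if model_id not in MODEL_PREDICTORS:
        raise ValueError(f"unknown model id {model_id}")
    predictors = MODEL_PREDICTORS[model_id]
    cols = ["y", *predictors]
    sub = records[cols].dropna()
    params, _, r2 = fit_ols(sub["y"].to_numpy(), sub[list(predictors)].to_numpy())
    return ModelFit(
        model_id=model_id,
        predictors=predictors,
        intercept=float(params[0]),
        coefficients={p: float(b) for p, b in zip(predictors, params[1:])},
        n=len(sub),
        r_squared=r2,
    )


def predict(fit: ModelFit, records: pd.DataFrame) -> pd.Series:
    """Fitted differential methylation for every record with the model's
    predictors present; records missing a predictor yield no prediction."""
    sub = records[list(fit.predictors)].dropna()
    values = np.full(len(sub), fit.intercept)
    for p in fit.predictors:
        values = values + fit.coefficients[p] * sub[p].to_numpy()
    return pd.Series(values, index=sub.index, name=f"model{fit.model_id}")


def combine_estimates(
    model4_predictions: pd.Series, model2_predictions: pd.Series
) -> pd.Series:
    """Model-4 estimates updated with model-2 values where available.

    The support is the union of the two inputs; on the overlap the model-2
    value wins.
    """
    combined = model2_predictions.combine_first(model4_predictions)
    combined.name = "combined"
    return combined


def evaluate_fit(
    observed: pd.Series,
    fitted: pd.Series,
    thresholds: Sequence[int] = (15, 25),
) -> MetricsReport:
    """Compare a fitted track to the observed one on their common dimers.

    RMSE/MAE are in percentage points; the correlation is Pearson's r (None
    when either track is constant); ``methylN`` counts |d| <= N inclusively.
    """
    joined = pd.DataFrame({"obs": observed, "fit": fitted}).dropna()
    if joined.empty:
        raise ValueError("observed and fitted share no dimers")
    d = joined["obs"].to_numpy() - joined["fit"].to_numpy()
    rmse = float(np.sqrt(np.mean(d**2)))
    mae = float(np.mean(np.abs(d)))
    if joined["obs"].std(ddof=0) == 0 or joined["fit"].std(ddof=0) == 0:
        corr: Optional[float] = None
    else:
        corr = float(np.corrcoef(joined["obs"], joined["fit"])[0, 1])
    concordance = {
        int(t): float(100.0 * np.mean(np.abs(d) <= t)) for t in thresholds
    }
    return MetricsReport(
        n=len(joined), correlation=corr, rmse=rmse, mae=mae, concordance=concordance
    )


def correlation_matrix(
    tracks: Mapping[str, pd.Series], min_n: int = 3
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between per-dimer tracks.

    Each pair is compared on the intersection of its defined dimers; pairs
    sharing fewer than ``min_n`` dimers get NaN. Returns ``(r, n)`` — the
    symmetric correlation matrix (diagonal 1) and the matching matrix of
    intersection sizes.
    """
    names = list(tracks)
    r = pd.DataFrame(np.nan, index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names, dtype=np.int64)
    for i, a in enumerate(names):
        for b in names[i:]:
            joined = pd.DataFrame({"a": tracks[a], "b": tracks[b]}).dropna()
            n.loc[a, b] = n.loc[b, a] = len(joined)
            if a == b:
                r.loc[a, b] = 1.0
            elif len(joined) >= min_n and joined["a"].std() > 0 and joined["b"].std() > 0:
                val = float(np.corrcoef(joined["a"], joined["b"])[0, 1])
                r.loc[a, b] = r.loc[b, a] = val
    return r, n


def assemble_records(
    y: Optional[pd.Series] = None,
    r: Optional[pd.Series] = None,
    x1: Optional[pd.Series] = None,
    x2: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Outer-join the per-dimer signals into the model input table.

    Missing signals become NaN columns; the index is the union of the
    inputs' ``(chrom, pos)`` indices.
    """
    named = {"y": y, "r": r, "x1": x1, "x2": x2}
    present = {k: v for k, v in named.items() if v is not None}
    if not present:
        raise ValueError("at least one signal required")
    table = pd.DataFrame(present)
    for k in named:
        if k not in table:
            table[k] = np.nan
    return table[["y", "r", "x1", "x2"]].sort_index()
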