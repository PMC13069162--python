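"""Feature-versus-PC-score regression.

Each geometric feature is regressed on each retained PC score by simple
ordinary least squares (feature = intercept + slope·score); results report
R², the two-sided p value of the slope (t statistic, n−2 df) and its 95%
confidence interval.  Scores are passed in raw (unnormalized) units and the
direction of the regression is recorded in the table metadata.

A constant feature cannot be regressed; by convention it yields slope 0,
R² 0, p 1 and is flagged rather than aborting the whole table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .canal_features import FEATURE_NAMES

__all__ = ["RegressionResult", "ols_feature_on_score", "regression_table"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_two_sided: float
    ci95_slope: tuple[float, float]
    n: int
    flagged: bool = False  # constant response handled by convention


def ols_feature_on_score(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of a feature (y) on a PC score (x) with R², p, and 95% CI of slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: scores have zero variance")
    if np.ptp(y) == 0:
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_two_sided=1.0,
            ci95_slope=(0.0, 0.0),
            n=n,
            flagged=True,
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_two_sided=float(res.pvalues[1]),
        ci95_slope=(float(lo), float(hi)),
        n=n,
    )


def regression_table(
    scores: pd.DataFrame, features: pd.DataFrame, n_pcs: int = 3
) -> pd.DataFrame:
    """All feature × PC regressions, one row each.

    ``scores`` has one column per PC (pc1, pc2, ...) and ``features`` one
    column per feature; both are indexed by specimen id, and the indices must
    agree (same ids, any consistent order).
    """
    if set(scores.index) != set(features.index):
        raise ValueError("scores and features must cover the same specimen ids")
    features = features.loc[scores.index]
    feature_cols = [c for c in FEATURE_NAMES if c in features.columns]
    rows = []
    for feat in feature_cols:
        for j in range(n_pcs):
            pc = f"pc{j + 1}"
            r = ols_feature_on_score(
                scores[pc].to_numpy(), features[feat].to_numpy()
            )
            rows.append(
                {
                    "feature": feat,
                    "pc": pc,
                    "slope": r.slope,
                    "ci_lo": r.ci95_slope[0],
                    "ci_hi": r.ci95_slope[1],
                    "r2": r.r_squared,
                    "p": r.p_two_sided,
                    "n": r.n,
                    "flagged": r.flagged,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["direction"] = "feature = f(score); scores in raw units"
    return table


def scores_to_frame(ids: list[str], scores: np.ndarray, n_pcs: int = 3) -> pd.DataFrame:
    """First ``n_pcs`` training scores as a DataFrame indexed by specimen id."""
    return pd.DataFrame(
        scores[:, :n_pcs],
        index=pd.Index(ids, name="specimen_id"),
        columns=[f"pc{j + 1}" for j in range(n_pcs)],
    )
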