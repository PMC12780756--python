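"""Nuisance fits and local centering.

Before any effect estimation, outcome and treatment are orthogonalized
against the covariates: honest regression forests estimate the outcome
surface m(x) = E[Y|X=x] and the propensity e(x) = E[W|X=x], and every
person's prediction is out-of-bag (only trees whose subsample excluded the
person contribute).  The centered residuals

    y~_i = Y_i - m^(-i)(X_i),    w~_i = W_i - e^(-i)(X_i)

feed the causal forest's residual-on-residual regressions.  Propensity
predictions are clipped to [eps, 1 - eps] (default eps = 0.01, below the
~3.7% design propensity of the 1:26 matched design, so clipping never
distorts the bulk of the data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ForestParams
from .forest import RegressionForest

__all__ = ["NuisanceFit", "CenteredData", "fit_regression_forest", "local_center"]


@dataclass
class NuisanceFit:
    """Per-person out-of-bag nuisance predictions."""

    m_hat: np.ndarray
    e_hat: np.ndarray
    params: ForestParams
    clip_epsilon: float

    def to_frame(self, row_ids: np.ndarray | None = None) -> pd.DataFrame:
        ids = row_ids if row_ids is not None else np.arange(len(self.m_hat))
        return pd.DataFrame({"person_id": ids, "m_hat": self.m_hat, "e_hat": self.e_hat})


@dataclass
class CenteredData:
    """Orthogonalized residuals aligned with the input rows."""

    y_tilde: np.ndarray
    w_tilde: np.ndarray
    X: np.ndarray
    row_ids: np.ndarray


def fit_regression_forest(X: np.ndarray, target: np.ndarray,
                          params: ForestParams | None = None,
                          seed: int = 0) -> np.ndarray:
    """Out-of-bag predictions of an honest regression forest.

    A constant target short-circuits to that constant for every row.
    """
    forest = RegressionForest(params).fit(np.asarray(X, float), target, seed=seed)
    return forest.predict_oob()


def local_center(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 params: ForestParams | None = None, seed: int = 0,
                 row_ids: np.ndarray | None = None) -> tuple[CenteredData, NuisanceFit]:
    """Orthogonalize (y, w) against X with out-of-bag forest fits."""
    params = params or ForestParams()
    X = np.ascontiguousarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not np.isfinite(y).all():
        raise ValueError("outcome contains missing values; drop censored/dead rows first")
    uniq = np.unique(w)
    if uniq.size < 2:
        raise ValueError("propensity degenerate: all rows share treatment status")
    ss = np.random.SeedSequence([int(seed)]).generate_state(2)
    m_hat = fit_regression_forest(X, y, params, seed=int(ss[0]) % 2**31)
    e_hat = fit_regression_forest(X, w, params, seed=int(ss[1]) % 2**31)
    eps = params.clip_epsilon
    e_hat = np.clip(e_hat, eps, 1.0 - eps)
    ids = row_ids if row_ids is not None else np.arange(len(y))
    centered = CenteredData(y_tilde=y - m_hat, w_tilde=w - e_hat, X=X,
                            row_ids=np.asarray(ids))
    return centered, NuisanceFit(m_hat=m_hat, e_hat=e_hat, params=params, clip_epsilon=eps)
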