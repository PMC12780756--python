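"""Doubly robust average effects from AIPW scores.

The per-person augmented-inverse-probability-weighted score

    Gamma_i = tau^(-i)(X_i)
              + (W_i - e_i) / (e_i (1 - e_i))
                * (Y_i - m_i - (W_i - e_i) tau^(-i)(X_i))

has conditional mean tau(x) whenever *either* the outcome surface m or the
propensity e is correct (double robustness).  Averages of Gamma therefore
estimate average effects, with standard errors from the empirical variance
of the scores.  The effect on the treated (ATT) uses propensity weights
h_i = e_i on the same scores, the standard doubly robust ATT weighting.
Confidence intervals are normal-approximation 95% bands (estimate +/-
1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import logger

__all__ = ["EffectScores", "EffectEstimate", "aipw_scores", "average_effect",
           "group_average_effect"]

_Z95 = 1.959963984540054


@dataclass
class EffectScores:
    """Per-person AIPW scores plus their components (outcome scale)."""

    gamma: np.ndarray
    tau_hat: np.ndarray
    m_hat: np.ndarray
    e_hat: np.ndarray
    w: np.ndarray
    y: np.ndarray
    row_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.gamma)


@dataclass
class EffectEstimate:
    """An average effect with its uncertainty."""

    estimate: float
    se: float
    target: str
    n: int
    group: object = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - _Z95 * self.se, self.estimate + _Z95 * self.se)


def aipw_scores(y: np.ndarray, w: np.ndarray, m_hat: np.ndarray, e_hat: np.ndarray,
                tau_hat: np.ndarray, row_ids: np.ndarray | None = None,
                score_ids: np.ndarray | None = None) -> EffectScores:
    """AIPW scores from aligned out-of-bag nuisance and CATE predictions.

    ``row_ids``/``score_ids``: when both are given they must match exactly
    (an alignment audit between the nuisance fit and the CATE fit).
    """
    arrays = [np.asarray(a, float) for a in (y, w, m_hat, e_hat, tau_hat)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("score components must have equal length")
    if row_ids is not None and score_ids is not None:
        if not np.array_equal(np.asarray(row_ids), np.asarray(score_ids)):
            raise ValueError("misaligned ids between nuisance and CATE fits")
    y, w, m_hat, e_hat, tau_hat = arrays
    if np.any((e_hat <= 0) | (e_hat >= 1)):
        raise ValueError("e_hat must lie strictly inside (0, 1); clip first")
    resid = y - m_hat - (w - e_hat) * tau_hat
    gamma = tau_hat + (w - e_hat) / (e_hat * (1.0 - e_hat)) * resid
    ids = np.asarray(row_ids) if row_ids is not None else np.arange(n)
    return EffectScores(gamma=gamma, tau_hat=tau_hat, m_hat=m_hat, e_hat=e_hat,
                        w=w, y=y, row_ids=ids)


def average_effect(scores: EffectScores, target: str = "ATE") -> EffectEstimate:
    """Average treatment effect (ATE) or effect on the treated (ATT)."""
    g = scores.gamma
    n = len(g)
    if n < 2:
        raise ValueError("need at least 2 scores")
    if target == "ATE":
        est = float(np.mean(g))
        se = float(np.std(g, ddof=1) / np.sqrt(n))
    elif target == "ATT":
        h = scores.e_hat
        sh = float(np.sum(h))
        est = float(np.sum(h * g) / sh)
        se = float(np.sqrt(np.sum(h**2 * (g - est) ** 2)) / sh)
    else:
        raise ValueError("target must be 'ATE' or 'ATT'")
    if se == 0.0:
        logger.warning("all scores identical; se = 0 for %s", target)
    return EffectEstimate(estimate=est, se=se, target=target, n=n)


def group_average_effect(scores: EffectScores, labels: np.ndarray) -> list[EffectEstimate]:
    """Per-group mean AIPW scores with normal 95% CIs, ordered by label.

    Group estimates weighted by group sizes average exactly to the overall
    ATE.  Groups with fewer than 2 rows get ``se = nan`` (warned).
    """
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("labels must align with scores")
    out = []
    for lab in np.unique(labels):
        g = scores.gamma[labels == lab]
        n = len(g)
        if n < 2:
            logger.warning("group %r has n=%d < 2; se unavailable", lab, n)
            se = float("nan")
        else:
            se = float(np.std(g, ddof=1) / np.sqrt(n))
        out.append(EffectEstimate(estimate=float(np.mean(g)), se=se,
                                  target="group-ATE", n=n, group=lab))
    return out


def effects_frame(estimates: list[EffectEstimate], outcome: str = "") -> pd.DataFrame:
    """Tidy export of effect estimates (outcome, target, group, ci bounds)."""
    rows = []
    for e in estimates:
        lo, hi = e.ci95
        rows.append({"outcome": outcome, "target": e.target, "group": e.group,
                     "estimate": e.estimate, "se": e.se, "ci_low": lo,
                     "ci_high": hi, "n": e.n})
    return pd.DataFrame(rows)
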