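"""The heterogeneity workflow.

For each outcome the pipeline mirrors the register-study analysis:

1. build the per-outcome analysis sample (mortality uses everyone;
   survivor-conditional outcomes drop the deceased; prescription/income
   outcomes additionally drop censored birth cohorts);
2. locally center outcome and treatment with out-of-bag forests;
3. train a *pilot* causal forest on all covariates, keep the covariates at
   or above mean split-frequency importance, and train the *final* forest
   on the retained set;
4. compute AIPW scores from the out-of-bag CATE and nuisance fits, giving
   the overall ATE/ATT;
5. assign cross-fitted CATE quartile ranks: 10 random folds, each ranked by
   a pilot+final pipeline trained on the other 9, cut at pooled quartiles
   (rank 1 = low effect, rank 4 = high effect);
6. profile the ranks: per-rank covariate means, per-rank AIPW effects, and
   standardized mean differences (SMD) between the high- and low-effect
   quartiles.

Quartiles are cut on the pooled cross-fitted predictions (not per fold), so
ranks are globally comparable and group sizes differ by at most 3; the
per-fold alternative is exposed via ``pooled_cut=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ForestParams, logger
from .effects import EffectEstimate, EffectScores, aipw_scores, average_effect, \
    effects_frame, group_average_effect
from .forest import CausalForest
from .nuisance import CenteredData, NuisanceFit, local_center
from .synthetic import COVARIATE_ORDER, OUTCOME_NAMES

__all__ = [
    "analysis_frame",
    "pilot_final_fit",
    "crossfit_ranks",
    "quartile_effects",
    "covariate_profile",
    "smd_extremes",
    "outcome_summary",
    "group_comparison_tests",
    "analyze_outcome",
    "AnalysisResult",
    "PilotFinalFit",
]

#: outcomes measured only for survivors ("conditional on being alive")
_SURVIVOR_CONDITIONAL = [o for o in OUTCOME_NAMES if o != "died_by_30"]
#: outcomes unobservable for censored birth cohorts
_CENSORABLE = {"antidepressant_use", "income_annual"}
_BINARY_OUTCOMES = {"died_by_30", "antidepressant_use", "no_partnership",
                    "basic_education_only"}


def analysis_frame(cohort: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-outcome analysis arrays: (X, y, w, row ids, covariate frame)."""
    if outcome not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = cohort
    if outcome in _SURVIVOR_CONDITIONAL:
        df = df[df["died_by_30"] == 0]
    df = df[np.isfinite(df[outcome].astype(float))]
    Xdf = df[COVARIATE_ORDER].astype(float)
    return (np.ascontiguousarray(Xdf.to_numpy()),
            df[outcome].to_numpy(float),
            df["treated"].to_numpy(float),
            df["person_id"].to_numpy(),
            Xdf)


def select_by_importance(importance: np.ndarray) -> np.ndarray:
    """Retain covariates at or above mean importance; all when degenerate."""
    importance = np.asarray(importance, float)
    if importance.sum() <= 0:
        return np.ones(len(importance), bool)
    return importance >= importance.mean()


@dataclass
class PilotFinalFit:
    """Pilot-screened final causal forest plus its provenance."""

    selected: np.ndarray          # boolean mask over the covariate columns
    forest: CausalForest          # trained on the retained covariates only
    pilot_importance: np.ndarray
    final_importance: np.ndarray
    centered: CenteredData
    nuisance: NuisanceFit

    def predict_cate(self, X: np.ndarray, oob_rows: np.ndarray | None = None) -> np.ndarray:
        return self.forest.predict_cate(np.ascontiguousarray(X[:, self.selected]),
                                        oob_rows=oob_rows)


def pilot_final_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    params: ForestParams | None = None, seed: int = 0,
                    use_pilot: bool = True) -> PilotFinalFit:
    """Two-forest scheme: pilot screens modifiers, final forest re-fits.

    The pilot forest is trained on all covariates; covariates whose
    split-frequency importance is at or above the mean importance are
    retained (with a uniform importance vector everything is retained), and
    the final forest is trained on the retained set with the same
    hyperparameters.
    """
    params = params or ForestParams()
    if X.shape[1] < 2 and use_pilot:
        raise ValueError("pilot selection needs >= 2 covariates")
    ss = np.random.SeedSequence([int(seed)]).generate_state(3) % (2**31)
    centered, nuis = local_center(X, y, w, params, seed=int(ss[0]))
    p = X.shape[1]
    if use_pilot:
        pilot = CausalForest(params).fit(X, centered.y_tilde, centered.w_tilde,
                                         seed=int(ss[1]))
        imp = pilot.variable_importance()
        if imp.sum() <= 0:
            logger.warning("pilot forest has no splits; retaining all covariates")
        selected = select_by_importance(imp)
        if not selected.any():  # unreachable under the >=-mean rule; belt+braces
            selected = np.ones(p, bool)
            logger.warning("empty pilot selection; retaining all covariates")
    else:
        imp = np.zeros(p)
        selected = np.ones(p, bool)
    final = CausalForest(params).fit(np.ascontiguousarray(X[:, selected]),
                                     centered.y_tilde, centered.w_tilde,
                                     seed=int(ss[2]))
    return PilotFinalFit(selected=selected, forest=final, pilot_importance=imp,
                         final_importance=_expand(final.variable_importance(), selected),
                         centered=centered, nuisance=nuis)


def _expand(imp_sel: np.ndarray, selected: np.ndarray) -> np.ndarray:
    out = np.zeros(len(selected))
    out[selected] = imp_sel
    return out


def crossfit_ranks(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                   params: ForestParams | None = None, K: int = 10, seed: int = 0,
                   use_pilot: bool = True, pooled_cut: bool = True,
                   row_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Cross-fitted CATE quartile ranks.

    The sample is split into ``K`` random folds; each fold's CATEs are
    predicted by the full pilot+final pipeline trained on the other K-1
    folds, so no person influences the forest that ranks them.  The pooled
    predictions are cut into quartiles (rank 1 = lowest quarter of the
    estimated effect, "low effect group"; rank 4 = "high effect group"),
    with ties broken deterministically by row order so group sizes differ
    by at most 3.

    Returns a DataFrame with person_id, fold, tau_hat_crossfit and rank.
    """
    n = len(y)
    if K > n / 4:
        raise ValueError(f"K={K} too large for n={n} (need n >= 4K)")
    params = params or ForestParams()
    ids = np.asarray(row_ids) if row_ids is not None else np.arange(n)
    rng = np.random.default_rng([int(seed), 404])
    fold = np.repeat(np.arange(1, K + 1), int(np.ceil(n / K)))[:n]
    rng.shuffle(fold)
    tau = np.full(n, np.nan)
    fold_seeds = np.random.SeedSequence([int(seed), 405]).generate_state(K) % (2**31)
    for k in range(1, K + 1):
        test = fold == k
        fit = pilot_final_fit(np.ascontiguousarray(X[~test]), y[~test], w[~test],
                              params, seed=int(fold_seeds[k - 1]), use_pilot=use_pilot)
        tau[test] = fit.predict_cate(np.ascontiguousarray(X[test]))
    if pooled_cut:
        rank = _quartile_rank(tau)
    else:
        rank = np.zeros(n, np.int64)
        for k in range(1, K + 1):
            m = fold == k
            rank[m] = _quartile_rank(tau[m])
    return pd.DataFrame({"person_id": ids, "fold": fold,
                         "tau_hat_crossfit": tau, "rank": rank})


def _quartile_rank(tau: np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 from empirical quartiles, ties by row order."""
    n = len(tau)
    order = np.lexsort((np.arange(n), tau))
    rank = np.empty(n, np.int64)
    rank[order] = np.arange(n) * 4 // n + 1
    return rank


def quartile_effects(ranks: pd.DataFrame, scores: EffectScores) -> pd.DataFrame:
    """AIPW effects per CATE rank group plus the overall ATT and ATE."""
    if len(ranks) != len(scores):
        raise ValueError("ranks and scores must align")
    if not np.array_equal(np.asarray(ranks["person_id"]), np.asarray(scores.row_ids)):
        raise ValueError("ranks and scores have misaligned person ids")
    ests: list[EffectEstimate] = group_average_effect(scores, ranks["rank"].to_numpy())
    ests.append(average_effect(scores, "ATT"))
    ests.append(average_effect(scores, "ATE"))
    return effects_frame(ests)


def covariate_profile(ranks: pd.DataFrame, Xdf: pd.DataFrame) -> pd.DataFrame:
    """Mean of every covariate within each CATE rank group."""
    if len(ranks) != len(Xdf):
        raise ValueError("ranks and covariates must align")
    grp = Xdf.groupby(ranks["rank"].to_numpy())
    return grp.mean()


def smd_extremes(ranks: pd.DataFrame, Xdf: pd.DataFrame) -> pd.DataFrame:
    """Standardized mean differences, high-effect (rank 4) minus low (rank 1).

    ``smd = (mean_4 - mean_1) / sqrt((s_1^2 + s_4^2) / 2)``; positive values
    mean the covariate is higher/more prevalent in the most vulnerable
    group.  Zero pooled sd yields a missing SMD.
    """
    r = ranks["rank"].to_numpy()
    lo, hi = Xdf[r == 1], Xdf[r == 4]
    m1, m4 = lo.mean(), hi.mean()
    s1, s4 = lo.std(ddof=1), hi.std(ddof=1)
    pooled = np.sqrt((s1**2 + s4**2) / 2.0)
    smd = (m4 - m1) / pooled.replace(0.0, np.nan)
    return pd.DataFrame({"mean_rank1": m1, "mean_rank4": m4,
                         "sd_rank1": s1, "sd_rank4": s4, "smd": smd})


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------


def _outcome_groups(matched: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    sub = matched
    if outcome in _SURVIVOR_CONDITIONAL:
        sub = sub[sub["died_by_30"] == 0]
    vals = sub[outcome].astype(float)
    ok = np.isfinite(vals)
    is_t = sub["treated"].to_numpy(bool) & ok.to_numpy()
    is_c = ~sub["treated"].to_numpy(bool) & ok.to_numpy()
    if not is_t.any() or not is_c.any():
        raise ValueError(f"empty group for outcome {outcome!r}")
    return vals[is_t].to_numpy(), vals[is_c].to_numpy()


def outcome_summary(matched: pd.DataFrame) -> pd.DataFrame:
    """Group means/fractions of the six outcomes, one row per outcome."""
    rows = []
    for outcome in OUTCOME_NAMES:
        yt, yc = _outcome_groups(matched, outcome)
        rows.append({"outcome": outcome, "treated_mean": yt.mean(),
                     "control_mean": yc.mean(), "n_treated": len(yt),
                     "n_control": len(yc)})
    return pd.DataFrame(rows)


def group_comparison_tests(matched: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-matched tests: Welch t (continuous), chi-square (binary).

    The chi-square test is Pearson's without continuity correction.
    """
    rows = []
    for outcome in OUTCOME_NAMES:
        yt, yc = _outcome_groups(matched, outcome)
        if outcome in _BINARY_OUTCOMES:
            table = np.array([[yt.sum(), len(yt) - yt.sum()],
                              [yc.sum(), len(yc) - yc.sum()]])
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
            test = "chi2"
        else:
            p = float(stats.ttest_ind(yt, yc, equal_var=False).pvalue)
            test = "welch-t"
        rows.append({"outcome": outcome, "test": test, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Everything the per-outcome analysis produces."""

    outcome: str
    fit: PilotFinalFit
    tau_hat_oob: np.ndarray
    scores: EffectScores
    ranks: pd.DataFrame
    rank_effects: pd.DataFrame
    profile: pd.DataFrame
    smd: pd.DataFrame
    row_ids: np.ndarray
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_ORDER))

    def cate_distribution(self) -> pd.DataFrame:
        return pd.DataFrame({"person_id": self.row_ids, "outcome": self.outcome,
                             "tau_hat": self.tau_hat_oob})


def analyze_outcome(matched: pd.DataFrame, outcome: str,
                    params: ForestParams | None = None, seed: int = 0,
                    K: int = 10, use_pilot: bool = True) -> AnalysisResult:
    """Full per-outcome heterogeneity analysis on a matched sample."""
    params = params or ForestParams()
    X, y, w, ids, Xdf = analysis_frame(matched, outcome)
    ss = np.random.SeedSequence([int(seed), 500]).generate_state(2) % (2**31)
    fit = pilot_final_fit(X, y, w, params, seed=int(ss[0]), use_pilot=use_pilot)
    tau_oob = fit.predict_cate(X, oob_rows=np.arange(len(y)))
    scores = aipw_scores(y, w, fit.nuisance.m_hat, fit.nuisance.e_hat, tau_oob,
                         row_ids=ids)
    ranks = crossfit_ranks(X, y, w, params, K=K, seed=int(ss[1]),
                           use_pilot=use_pilot, row_ids=ids)
    rank_eff = quartile_effects(ranks, scores)
    rank_eff["outcome"] = outcome
    profile = covariate_profile(ranks, Xdf.reset_index(drop=True))
    smd = smd_extremes(ranks, Xdf.reset_index(drop=True))
    logger.info("analyzed %s: n=%d, ATT=%.4g", outcome, len(y),
                rank_eff.loc[rank_eff["target"] == "ATT", "estimate"].iloc[0])
    return AnalysisResult(outcome=outcome, fit=fit, tau_hat_oob=tau_oob,
                          scores=scores, ranks=ranks, rank_effects=rank_eff,
                          profile=profile, smd=smd, row_ids=ids)
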