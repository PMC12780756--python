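"""Exclusion rules and stratified control matching.

The register design first removes persons diagnosed before age 7, with
missing parental/household covariates, or who died/emigrated before 18,
then matches each case with up to 26 controls sharing region of residence,
sex and birth year.  Matching is done by *stratum-level pooled sampling*:
within each (region, sex, birth-year) stratum holding ``c`` cases,
``min(26 c, available)`` controls are drawn uniformly without replacement.
When controls are exchangeable within a stratum this is equivalent in
distribution to per-case draws and is simpler to make deterministic.

Each stratum uses its own RNG stream keyed by ``(seed, region, sex,
birth_year)``, so results are invariant to stratum ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import logger
from .synthetic import EXCLUSION_ORDER

__all__ = ["MatchedSample", "apply_exclusions", "match_controls"]

STRATUM_KEYS = ["region_code", "female", "birth_year"]


@dataclass
class MatchedSample:
    """Cases plus stratum-matched controls.

    ``data`` holds the retained rows; ``stratum_counts`` one row per stratum
    with case/control/selected counts; ``max_per_case`` the matching ratio
    cap applied.
    """

    data: pd.DataFrame
    stratum_counts: pd.DataFrame
    max_per_case: int

    @property
    def n_cases(self) -> int:
        return int(self.data["treated"].sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.data["treated"]).sum())


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop flagged rows; count each person once, at its first matching rule.

    Returns the retained rows and a per-reason count table in the fixed
    precedence order (pre-7 diagnosis, missing covariates, death before 18,
    emigration before 18).
    """
    flag_cols = [f"excl_{r}" for r in EXCLUSION_ORDER]
    missing = [c for c in flag_cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks exclusion flag columns: {missing}")
    flags = cohort[flag_cols].to_numpy(bool)
    any_flag = flags.any(axis=1)
    first = np.argmax(flags, axis=1)
    counts = pd.DataFrame({
        "reason": EXCLUSION_ORDER,
        "n_excluded": [int(((first == i) & any_flag).sum()) for i in range(len(EXCLUSION_ORDER))],
    })
    kept = cohort.loc[~any_flag].copy()
    logger.info("exclusions: removed %d of %d rows", int(any_flag.sum()), len(cohort))
    return kept, counts


def match_controls(cohort: pd.DataFrame, max_per_case: int = 26, seed: int = 0) -> MatchedSample:
    """Stratified control matching on (region, sex, birth year).

    Every case is retained.  Per stratum with ``c`` cases, ``min(max_per_case
    * c, available)`` controls are sampled uniformly without replacement;
    strata without cases contribute no controls.  A stratum with cases but
    no controls is logged and its cases kept unmatched.  Deterministic under
    ``seed`` and invariant to row/stratum ordering.
    """
    if max_per_case < 1:
        raise ValueError("max_per_case must be >= 1")
    treated = cohort["treated"].to_numpy(bool)
    if not treated.any() or treated.all():
        raise ValueError("matching needs both treated and untreated rows")

    take_mask = treated.copy()
    records = []
    for key, grp in cohort.groupby(STRATUM_KEYS, sort=True):
        is_case = grp["treated"].to_numpy(bool)
        n_cases = int(is_case.sum())
        ctrl = grp.loc[~is_case]
        if n_cases == 0:
            continue
        n_take = min(max_per_case * n_cases, len(ctrl))
        if len(ctrl) == 0:
            logger.warning("stratum %s has %d case(s) but no controls", key, n_cases)
        elif n_take > 0:
            key_ints = [int(seed)] + [int(k) for k in key]
            rng = np.random.default_rng(key_ints)
            # draw in person-id order so the result is row-order invariant
            order = np.argsort(ctrl["person_id"].to_numpy(), kind="stable")
            chosen_labels = ctrl.index.to_numpy()[order[rng.permutation(len(ctrl))[:n_take]]]
            take_mask[cohort.index.get_indexer(chosen_labels)] = True
        records.append({
            "region_code": key[0], "female": key[1], "birth_year": key[2],
            "n_cases": n_cases, "n_controls_available": len(ctrl),
            "n_controls_selected": int(n_take),
        })

    data = cohort.loc[take_mask].copy()
    sample = MatchedSample(data=data, stratum_counts=pd.DataFrame(records),
                           max_per_case=max_per_case)
    logger.info("matched sample: %d cases, %d controls in %d strata",
                sample.n_cases, sample.n_controls, len(records))
    return sample
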