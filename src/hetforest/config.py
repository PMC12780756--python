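"""Shared configuration objects, serialization helpers and logging.

All tunable hyperparameters of the forest machinery live in
:class:`ForestParams`.  The defaults (500 trees, 50% subsampling, 50%
honesty split, minimum node size 5, ``mtry = ceil(sqrt(p))``) follow the
standard generalized-random-forest construction; automatic cross-validated
tuning is deliberately out of scope and replaced by these fixed,
config-overridable values.  ``LARGE_COHORT`` is the preset used for
full-size (~80k row) register-style runs, where fewer, coarser trees give
essentially the same rankings at a fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Any

import yaml

logger = logging.getLogger("hetforest")
if not logger.handlers:  # pragma: no cover - import-time wiring
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters shared by regression and causal forests.

    Attributes
    ----------
    n_trees:
        Number of trees ``B``.
    subsample_fraction:
        Fraction of rows drawn (without replacement) per tree.
    honesty_fraction:
        Fraction of each subsample used for split selection (the J1 half);
        the remainder (J2) populates leaf estimates.
    min_node_size:
        Minimum number of rows a child must hold *in both honest halves*
        for a split to be admissible.
    mtry:
        Number of candidate covariates per split; ``None`` means
        ``ceil(sqrt(p))``.
    clip_epsilon:
        Propensity predictions are clipped to ``[eps, 1 - eps]``.
    """

    n_trees: int = 500
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    min_node_size: int = 5
    mtry: int | None = None
    clip_epsilon: float = 0.01

    def resolve_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(n_features))
        return max(1, min(int(m), n_features))

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.honesty_fraction < 1:
            raise ValueError("honesty_fraction must be in (0, 1)")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not 0 < self.clip_epsilon < 0.5:
            raise ValueError("clip_epsilon must be in (0, 0.5)")


#: Preset for full-size register-style cohorts (~80k rows): fewer but
#: coarser trees keep the CATE ranking stable while fitting a single CPU.
LARGE_COHORT = ForestParams(n_trees=200, min_node_size=50)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def config_hash(obj: Any) -> str:
    """Stable sha256 hash of any (nested) dataclass/dict configuration."""
    payload = json.dumps(_to_jsonable(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def dump_yaml(obj: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_jsonable(obj), fh, sort_keys=True)


def load_yaml(path: str) -> Any:
    with open(path) as fh:
        return yaml.safe_load(fh)
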