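"""Honest subsampled forests: regression (nuisance) and causal (CATE).

The causal forest estimates the conditional average treatment effect
tau(x) = E[Y(1) - Y(0) | X = x] from locally centered data: residuals
y~ = Y - m(X), w~ = W - e(X).  Trees are grown on a random half (J1) of
each subsample by recursively maximizing the between-child heterogeneity of
node-level residual-on-residual effect estimates (gradient pseudo-outcome
splitting); leaf estimates come from the held-out half (J2), the honesty
device that removes adaptive-split bias.  Predictions combine adaptive
forest weights — each J2 co-leaf member of the query point gets weight
1/(B' |leaf|) — into a weighted residual-on-residual regression.

Predictions for rows that participated in training are out-of-bag: only
trees whose subsample excluded the row contribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _trees
from ._trees import MODE_CAUSAL, MODE_REGRESSION
from .config import ForestParams, logger

__all__ = [
    "SplitCandidate",
    "RegressionForest",
    "CausalForest",
    "node_pseudo_outcomes",
    "best_split",
    "grow_tree",
    "Tree",
]


def node_pseudo_outcomes(y_tilde: np.ndarray, w_tilde: np.ndarray) -> tuple[float, np.ndarray]:
    """Node-level effect solution and gradient pseudo-outcomes.

    Returns ``(tau_P, rho)`` with ``tau_P = sum(w~ y~) / sum(w~^2)``,
    ``A_P = mean(w~^2)`` and ``rho_i = w~_i (y~_i - w~_i tau_P) / A_P``.
    The pseudo-outcomes sum to zero exactly.

    Raises ``ValueError`` when the node has no residual treatment variation
    (``sum(w~^2) = 0``); callers turn such nodes into leaves.
    """
    y_tilde = np.asarray(y_tilde, float)
    w_tilde = np.asarray(w_tilde, float)
    if y_tilde.shape != w_tilde.shape or y_tilde.ndim != 1 or y_tilde.size < 2:
        raise ValueError("node needs >= 2 aligned rows")
    sw2 = float(np.sum(w_tilde**2))
    if sw2 <= 0.0:
        raise ValueError("no residual treatment variation in node (sum w~^2 = 0)")
    tau = float(np.sum(w_tilde * y_tilde)) / sw2
    a_p = sw2 / y_tilde.size
    rho = w_tilde * (y_tilde - w_tilde * tau) / a_p
    return tau, rho


@dataclass(frozen=True)
class SplitCandidate:
    feature: int
    threshold: float
    gain: float


def best_split(
    X: np.ndarray,
    rho: np.ndarray,
    min_node_size: int,
    features: np.ndarray | None = None,
    X_est: np.ndarray | None = None,
) -> SplitCandidate | None:
    """Best admissible axis-aligned split for one node.

    Maximizes ``(sum_L rho)^2 / n_L + (sum_R rho)^2 / n_R`` over the given
    candidate ``features`` (default: all) and all midpoints between
    consecutive sorted splitting-half values, requiring ``min_node_size``
    rows per child in the splitting rows *and* in the estimation rows
    ``X_est`` (default: same as ``X``).  Ties break toward the lowest
    feature index, then the lowest threshold.  Returns ``None`` when no
    admissible split improves on zero.
    """
    X = np.ascontiguousarray(X, float)
    rho = np.asarray(rho, float) - np.mean(rho)  # criterion assumes zero-sum
    if X_est is None:
        X_est = X
    else:
        X_est = np.ascontiguousarray(X_est, float)
    if features is None:
        features = np.arange(X.shape[1])
    features = np.sort(np.asarray(features, np.int64))
    # reuse the grower's kernel by stacking split/estimation rows
    if X_est is X:
        Xall = X
        j1 = np.arange(X.shape[0], dtype=np.int64)
        j2 = j1
    else:
        Xall = np.vstack([X, X_est])
        j1 = np.arange(X.shape[0], dtype=np.int64)
        j2 = np.arange(X_est.shape[0], dtype=np.int64) + X.shape[0]
    p = Xall.shape[1]
    sidx1 = np.vstack([j1[np.argsort(Xall[j1, v], kind="stable")] for v in range(p)]).astype(np.int32)
    sidx2 = np.vstack([j2[np.argsort(Xall[j2, v], kind="stable")] for v in range(p)]).astype(np.int32)
    val1 = np.vstack([Xall[sidx1[v], v] for v in range(p)])
    val2 = np.vstack([Xall[sidx2[v], v] for v in range(p)])
    rho_row = np.zeros(Xall.shape[0])
    rho_row[j1] = rho
    f, t, g = _trees._scan_node(sidx1, val1, 0, len(j1), val2, 0, len(j2),
                                rho_row, features, len(features), min_node_size)
    if f < 0:
        return None
    return SplitCandidate(feature=int(f), threshold=float(t), gain=float(g))


@dataclass
class Tree:
    """A single honest tree over externally supplied J1/J2 halves."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    depth: np.ndarray
    leaf_value_a: np.ndarray
    leaf_value_b: np.ndarray
    leaf_member_start: np.ndarray
    leaf_member_count: np.ndarray
    members: np.ndarray
    n_nodes: int

    def leaf_members(self, node: int) -> np.ndarray:
        s = self.leaf_member_start[node]
        return self.members[s: s + self.leaf_member_count[node]]

    def structure(self) -> tuple:
        """Hashable (feature, threshold) structure for honesty checks."""
        n = self.n_nodes
        return (tuple(self.feature[:n].tolist()), tuple(np.round(self.threshold[:n], 12).tolist()))


def grow_tree(
    X: np.ndarray,
    y_tilde: np.ndarray,
    w_tilde: np.ndarray,
    j1: np.ndarray,
    j2: np.ndarray,
    params: ForestParams,
    mode: int = MODE_CAUSAL,
    rng: np.random.Generator | None = None,
) -> Tree:
    """Grow one honest tree on explicit splitting (J1) / estimation (J2) halves."""
    params.validate()
    X = np.ascontiguousarray(X, float)
    y_tilde = np.asarray(y_tilde, float)
    w_tilde = np.asarray(w_tilde, float) if w_tilde is not None else np.zeros_like(y_tilde)
    j1 = np.asarray(j1, np.int64).copy()
    j2 = np.asarray(j2, np.int64).copy()
    if np.intersect1d(j1, j2).size:
        raise ValueError("J1 and J2 must be disjoint")
    n, p = X.shape
    mtry = params.resolve_mtry(p)
    cap = 2 * (min(j1.size, j2.size) // max(params.min_node_size, 1)) + 4
    feat = np.full(cap, _trees.LEAF, np.int64)
    thr = np.zeros(cap)
    left = np.full(cap, -1, np.int64)
    right = np.full(cap, -1, np.int64)
    depth = np.zeros(cap, np.int64)
    va = np.zeros(cap)
    vb = np.zeros(cap)
    lms = np.zeros(cap, np.int64)
    lmc = np.zeros(cap, np.int64)
    members = np.zeros(j2.size, np.int64)
    seed = int((rng or np.random.default_rng(0)).integers(2**31 - 1))
    _trees._seed_kernel(np.uint32(seed))  # feature subsampling inside the kernel
    sidx1 = np.vstack([j1[np.argsort(X[j1, v], kind="stable")] for v in range(p)]).astype(np.int32)
    sidx2 = np.vstack([j2[np.argsort(X[j2, v], kind="stable")] for v in range(p)]).astype(np.int32)
    val1 = np.vstack([X[sidx1[v], v] for v in range(p)])
    val2 = np.vstack([X[sidx2[v], v] for v in range(p)])
    nn = _trees._grow_tree(y_tilde, w_tilde, mode, params.min_node_size, mtry, p,
                           sidx1, val1, sidx2, val2, j1.size, j2.size,
                           np.zeros(n), np.zeros(n, np.uint8),
                           np.empty(j1.size, np.int32), np.empty(j1.size),
                           np.empty(j2.size, np.int32), np.empty(j2.size),
                           np.empty(p, np.int64),
                           feat, thr, left, right, depth, va, vb,
                           lms, lmc, members, 0, 0)
    return Tree(feat, thr, left, right, depth, va, vb, lms, lmc, members, nn)


class _ForestBase:
    """Shared fitting, routing and bookkeeping for honest forests."""

    mode: int = MODE_REGRESSION

    def __init__(self, params: ForestParams | None = None):
        self.params = params or ForestParams()
        self.params.validate()
        self._fitted = False

    # -- fitting ---------------------------------------------------------

    def _fit(self, X: np.ndarray, g: np.ndarray, w: np.ndarray | None, seed: int) -> None:
        X = np.ascontiguousarray(X, float)
        g = np.asarray(g, float)
        w = np.asarray(w, float) if w is not None else np.zeros_like(g)
        n, p = X.shape
        if g.shape[0] != n or w.shape[0] != n:
            raise ValueError("X, targets and treatment residuals must align")
        pr = self.params
        s = max(2, int(round(pr.subsample_fraction * n)))
        s = min(s, n)
        s1 = int(round(pr.honesty_fraction * s))
        s1 = min(max(s1, 1), s - 1)
        if min(s1, s - s1) < pr.min_node_size:
            logger.warning("honest halves (%d/%d) smaller than min_node_size=%d; trees are stumps",
                           s1, s - s1, pr.min_node_size)
        B = pr.n_trees
        mtry = pr.resolve_mtry(p)
        nodes_cap = 2 * (min(s1, s - s1) // max(pr.min_node_size, 1)) + 4
        seeds = np.random.SeedSequence([int(seed)]).generate_state(B).astype(np.uint32)

        self.feature = np.full(B * nodes_cap, _trees.LEAF, np.int64)
        self.threshold = np.zeros(B * nodes_cap)
        self.left = np.full(B * nodes_cap, -1, np.int64)
        self.right = np.full(B * nodes_cap, -1, np.int64)
        self.depth = np.zeros(B * nodes_cap, np.int64)
        self.val_a = np.zeros(B * nodes_cap)
        self.val_b = np.zeros(B * nodes_cap)
        self.leaf_member_start = np.zeros(B * nodes_cap, np.int64)
        self.leaf_member_count = np.zeros(B * nodes_cap, np.int64)
        self.members = np.zeros(B * (s - s1), np.int64)
        self.tree_n_nodes = np.zeros(B, np.int64)
        self.in_sample = np.zeros((B, n), np.bool_)
        self.roots = (np.arange(B) * nodes_cap).astype(np.int64)

        gsort = np.ascontiguousarray(np.argsort(X, axis=0, kind="stable").T)
        XT = np.ascontiguousarray(X.T)
        _trees._grow_forest(XT, g, w, gsort, self.mode, B, s, s1, pr.min_node_size, mtry,
                            seeds, nodes_cap, self.feature, self.threshold,
                            self.left, self.right, self.depth, self.val_a,
                            self.val_b, self.leaf_member_start,
                            self.leaf_member_count, self.members,
                            self.tree_n_nodes, self.in_sample)
        self.n_train = n
        self.n_features = p
        self.X_train = X
        self.g_train = g
        self.w_train = w
        self.seed = int(seed)
        self._fitted = True

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise ValueError("forest is not fitted")

    def _leafmat(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.ascontiguousarray(Xq, float)
        out = np.zeros((Xq.shape[0], self.params.n_trees), np.int64)
        _trees._route(Xq, self.feature, self.threshold, self.left, self.right,
                      self.roots, out)
        return out

    @staticmethod
    def _train_rows(nq: int, oob_rows: np.ndarray | None) -> np.ndarray:
        if oob_rows is None:
            return np.full(nq, -1, np.int64)
        tr = np.asarray(oob_rows, np.int64)
        if tr.shape[0] != nq:
            raise ValueError("oob_rows must align with the query rows")
        return tr

    # -- introspection ---------------------------------------------------

    def variable_importance(self, decay_exponent: float = 2.0, max_depth: int = 4) -> np.ndarray:
        """Depth-weighted split-frequency importance, normalized to sum 1.

        ``importance_v = sum_{d<=max_depth} d^-decay * splits(v, d) /
        total_splits(d)``, a weighted count of how often each covariate is
        used to split, discounting deeper splits.  Zero vector when the
        forest contains no splits.
        """
        self._check_fitted()
        counts = np.zeros((max_depth, self.n_features))
        for b in range(self.params.n_trees):
            base = self.roots[b]
            nn = self.tree_n_nodes[b]
            f = self.feature[base: base + nn]
            d = self.depth[base: base + nn] + 1  # root split has depth 1
            sel = (f >= 0) & (d <= max_depth)
            np.add.at(counts, (d[sel] - 1, f[sel]), 1.0)
        totals = counts.sum(axis=1)
        imp = np.zeros(self.n_features)
        for d in range(max_depth):
            if totals[d] > 0:
                imp += (d + 1.0) ** (-decay_exponent) * counts[d] / totals[d]
        tot = imp.sum()
        return imp / tot if tot > 0 else imp

    def to_json(self) -> str:
        """Serialize params and tree structures to a documented JSON string."""
        self._check_fitted()
        trees = []
        for b in range(self.params.n_trees):
            base = self.roots[b]
            nn = int(self.tree_n_nodes[b])
            sl = slice(base, base + nn)
            trees.append({
                "feature": self.feature[sl].tolist(),
                "threshold": self.threshold[sl].tolist(),
                "left": (self.left[sl] - base).tolist(),
                "right": (self.right[sl] - base).tolist(),
                "leaf_members": [
                    self.members[self.leaf_member_start[base + k]:
                                 self.leaf_member_start[base + k]
                                 + self.leaf_member_count[base + k]].tolist()
                    if self.feature[base + k] < 0 else None
                    for k in range(nn)
                ],
            })
        payload = {
            "mode": "causal" if self.mode == MODE_CAUSAL else "regression",
            "params": {
                "n_trees": self.params.n_trees,
                "subsample_fraction": self.params.subsample_fraction,
                "honesty_fraction": self.params.honesty_fraction,
                "min_node_size": self.params.min_node_size,
                "mtry": self.params.mtry,
            },
            "seed": self.seed,
            "n_train": self.n_train,
            "trees": trees,
        }
        return json.dumps(payload)


class RegressionForest(_ForestBase):
    """Honest regression forest with variance-reduction splitting."""

    mode = MODE_REGRESSION

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "RegressionForest":
        y = np.asarray(y, float)
        if np.ptp(y) == 0.0 and y.size:  # constant target: no structure to learn
            self._constant = float(y[0])
        else:
            self._constant = None
        self._fit(X, y, None, seed)
        return self

    def predict(self, Xq: np.ndarray, oob_rows: np.ndarray | None = None) -> np.ndarray:
        """Predict E[Y|X]; ``oob_rows[i]`` = training-row id for OOB queries."""
        self._check_fitted()
        if self._constant is not None:
            return np.full(np.asarray(Xq).shape[0], self._constant)
        leafmat = self._leafmat(Xq)
        out = np.zeros(leafmat.shape[0])
        n_used = np.zeros(leafmat.shape[0], np.int64)
        _trees._predict_regression(leafmat, self.val_a, self.leaf_member_count,
                                   self.in_sample, self._train_rows(leafmat.shape[0], oob_rows),
                                   out, n_used)
        bad = ~np.isfinite(out)
        if bad.any():
            logger.warning("%d rows had no out-of-bag trees; filled with training mean",
                           int(bad.sum()))
            out[bad] = float(np.mean(self.g_train))
        return out

    def predict_oob(self) -> np.ndarray:
        return self.predict(self.X_train, oob_rows=np.arange(self.n_train))


class CausalForest(_ForestBase):
    """Honest causal forest on locally centered data."""

    mode = MODE_CAUSAL

    def fit(self, X: np.ndarray, y_tilde: np.ndarray, w_tilde: np.ndarray,
            seed: int = 0) -> "CausalForest":
        self._fit(X, np.asarray(y_tilde, float), np.asarray(w_tilde, float), seed)
        sw2 = float(np.sum(self.w_train**2))
        self._tau_global = float(np.sum(self.w_train * self.g_train)) / sw2 if sw2 > 0 else 0.0
        return self

    def predict_cate(self, Xq: np.ndarray, oob_rows: np.ndarray | None = None) -> np.ndarray:
        """tau(x) via forest-weighted residual-on-residual regression.

        Queries with zero weighted treatment variance fall back to the
        forest-wide residual regression estimate (logged).
        """
        self._check_fitted()
        leafmat = self._leafmat(Xq)
        out = np.zeros(leafmat.shape[0])
        n_used = np.zeros(leafmat.shape[0], np.int64)
        _trees._predict_cate(leafmat, self.val_a, self.val_b, self.leaf_member_count,
                             self.in_sample, self._train_rows(leafmat.shape[0], oob_rows),
                             out, n_used)
        if oob_rows is not None and (n_used == 0).any():
            raise ValueError("no out-of-bag trees for row(s) %s"
                             % np.nonzero(n_used == 0)[0][:5])
        bad = ~np.isfinite(out)
        if bad.any():
            logger.warning("%d queries had zero weighted treatment variance; "
                           "using forest-wide estimate", int(bad.sum()))
            out[bad] = self._tau_global
        return out

    def predict_cate_oob(self) -> np.ndarray:
        return self.predict_cate(self.X_train, oob_rows=np.arange(self.n_train))

    def forest_weights(self, Xq: np.ndarray, oob_rows: np.ndarray | None = None) -> np.ndarray:
        """Dense adaptive weights alpha_i(x) over the training rows.

        ``alpha_i(x) = (1/B') sum_b 1[i in J2_b leaf_b(x)] / |leaf_b(x)|``
        where only trees excluding the query's training row count (B' of
        them) for OOB queries.  Rows of the result sum to 1 whenever every
        counted tree has a non-empty leaf at x.  Dense and O(n_query * n):
        intended for inspection and tests, not bulk prediction.
        """
        self._check_fitted()
        leafmat = self._leafmat(Xq)
        nq = leafmat.shape[0]
        tr = self._train_rows(nq, oob_rows)
        alpha = np.zeros((nq, self.n_train))
        for q in range(nq):
            used = 0
            for b in range(self.params.n_trees):
                if tr[q] >= 0 and self.in_sample[b, tr[q]]:
                    continue
                used += 1
                leaf = leafmat[q, b]
                cnt = self.leaf_member_count[leaf]
                if cnt == 0:
                    continue
                s = self.leaf_member_start[leaf]
                alpha[q, self.members[s: s + cnt]] += 1.0 / cnt
            if used == 0:
                raise ValueError(f"no out-of-bag trees for row {tr[q]}")
            alpha[q] /= used
        return alpha
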