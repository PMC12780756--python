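"""Numba kernels for honest subsampled trees.

One tree engine serves two splitting rules:

* ``MODE_REGRESSION``: per-row gradient is the node-centered target; the
  split criterion is the classical variance-reduction rule.
* ``MODE_CAUSAL``: per-row gradient is the pseudo-outcome
  ``rho_i = w~_i (y~_i - w~_i tau_P) / A_P`` of the node-level
  residual-on-residual solution ``tau_P = sum(w~ y~) / sum(w~^2)``,
  ``A_P = mean(w~^2)``; the criterion then maximizes the between-child
  heterogeneity of the local effect estimates.

Both rules reduce to maximizing ``(sum_L rho)^2 / n_L + (sum_R rho)^2 /
n_R`` over candidate splits (gradients sum to zero within a node, so the
parent term is constant).  Candidate thresholds are midpoints between
consecutive sorted splitting-half (J1) values; a split is admissible only
if both children keep at least ``min_node`` rows in *both* honest halves.
Ties break toward the lowest covariate index, then the lowest threshold,
via strict-improvement scanning in ascending order.

Growth is presort-based: each covariate's global sort order is computed
once per forest; per tree, per-feature sorted index *and value* lists of
both honest halves are extracted in one linear pass and kept sorted through
stable partitions, so node scans are sequential passes (no per-node
sorting).

Trees are stored in flat pre-allocated arrays (one block per tree):
``feat < 0`` marks a leaf; leaves record their estimation-half (J2) member
slice plus the leaf aggregates needed for prediction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_REGRESSION = 0
MODE_CAUSAL = 1

LEAF = -1


@njit(cache=True)
def _seed_kernel(seed):
    # numba's np.random state is separate from numpy's
    np.random.seed(seed)


@njit(cache=True)
def _draw_features(p, mtry, feat_buf):
    """Partial Fisher-Yates draw of mtry distinct features, sorted ascending."""
    for j in range(p):
        feat_buf[j] = j
    for j in range(mtry):
        k = j + np.random.randint(0, p - j)
        t = feat_buf[j]
        feat_buf[j] = feat_buf[k]
        feat_buf[k] = t
    for a in range(1, mtry):
        key = feat_buf[a]
        b = a - 1
        while b >= 0 and feat_buf[b] > key:
            feat_buf[b + 1] = feat_buf[b]
            b -= 1
        feat_buf[b + 1] = key


@njit(cache=True)
def _scan_node(sidx1, val1, a1, b1, val2, a2, b2, rho_row, feats, nf, min_node):
    """Best admissible split for the node slice [a1,b1) x [a2,b2).

    ``sidx1``/``val1`` (p, .) hold the node's J1 row ids and covariate
    values, each feature row in ascending value order; ``val2`` likewise for
    J2 values.  ``rho_row`` holds the node's (zero-sum) gradients indexed
    by row id.  Returns ``(feature, threshold, gain)``; ``feature = -1``
    when no admissible split improves on zero gain.
    """
    n1 = b1 - a1
    n2 = b2 - a2
    best_gain = 0.0
    best_feat = -1
    best_thr = 0.0
    for fi in range(nf):
        v = feats[fi]
        sl = 0.0
        j2 = a2
        for i in range(1, n1):
            sl += rho_row[sidx1[v, a1 + i - 1]]
            xa = val1[v, a1 + i - 1]
            xb = val1[v, a1 + i]
            if xa == xb:
                continue
            if i < min_node or n1 - i < min_node:
                continue
            thr = 0.5 * (xa + xb)
            if thr >= xb:  # midpoint rounded up to xb: fall back to left value
                thr = xa
            while j2 < b2 and val2[v, j2] <= thr:
                j2 += 1
            nL2 = j2 - a2
            if nL2 < min_node or n2 - nL2 < min_node:
                continue
            gain = sl * sl / i + sl * sl / (n1 - i)
            if gain > best_gain:
                best_gain = gain
                best_feat = v
                best_thr = thr
    return best_feat, best_thr, best_gain


@njit(cache=True)
def _node_gradients(g, w, mode, sidx1, a1, b1, rho_row):
    """Fill rho_row for the node's J1 rows; return success flag.

    Fails (False) only in causal mode when the node has no residual
    treatment variation, in which case it must become a leaf.
    """
    n1 = b1 - a1
    if mode == MODE_CAUSAL:
        sw2 = 0.0
        swy = 0.0
        for k in range(a1, b1):
            i = sidx1[0, k]
            sw2 += w[i] * w[i]
            swy += w[i] * g[i]
        if sw2 <= 0.0:
            return False
        tau = swy / sw2
        A = sw2 / n1
        for k in range(a1, b1):
            i = sidx1[0, k]
            rho_row[i] = w[i] * (g[i] - w[i] * tau) / A
        return True
    s = 0.0
    for k in range(a1, b1):
        s += g[sidx1[0, k]]
    mu = s / n1
    for k in range(a1, b1):
        i = sidx1[0, k]
        rho_row[i] = g[i] - mu
    return True


@njit(cache=True)
def _mark_left(sidx, val, a, b, bf, bt, goes_left):
    """Flag each node row by split side; return the left count."""
    nl = 0
    for k in range(a, b):
        if val[bf, k] <= bt:
            goes_left[sidx[bf, k]] = 1
            nl += 1
        else:
            goes_left[sidx[bf, k]] = 0
    return nl


@njit(cache=True)
def _partition_all(sidx, val, a, b, p, nl, goes_left, sidx_scr, val_scr):
    """Stably partition every feature's slice [a,b) by goes_left."""
    n = b - a
    for v in range(p):
        l = 0
        r = nl
        for k in range(a, b):
            i = sidx[v, k]
            if goes_left[i] == 1:
                sidx_scr[l] = i
                val_scr[l] = val[v, k]
                l += 1
            else:
                sidx_scr[r] = i
                val_scr[r] = val[v, k]
                r += 1
        for k in range(n):
            sidx[v, a + k] = sidx_scr[k]
            val[v, a + k] = val_scr[k]


@njit(cache=True)
def _grow_tree(g, w, mode, min_node, mtry, p,
               sidx1, val1, sidx2, val2, n1t, n2t,
               rho_row, goes_left, si_scr1, vv_scr1, si_scr2, vv_scr2, feat_buf,
               feat, thr, left, right, depth, val_a, val_b,
               leaf_mstart, leaf_mcount, members,
               node_base, mem_base):
    """Grow one honest tree; returns the number of nodes written.

    ``sidx*/val*`` are the per-feature sorted index/value lists of the
    splitting (J1) and estimation (J2) halves, partitioned in place.  Nodes
    go to ``node_base + local``; J2 leaf members to ``mem_base + offset``.
    For causal mode ``val_a``/``val_b`` hold leaf sums of ``w~ y~`` and
    ``w~^2`` over J2; for regression ``val_a`` holds the J2 leaf mean.
    """
    cap = 2 * (min(n1t, n2t) // max(min_node, 1)) + 4

    st_a1 = np.empty(cap, np.int64)
    st_b1 = np.empty(cap, np.int64)
    st_a2 = np.empty(cap, np.int64)
    st_b2 = np.empty(cap, np.int64)
    st_parent = np.empty(cap, np.int64)
    st_side = np.empty(cap, np.int64)
    st_depth = np.empty(cap, np.int64)

    st_a1[0] = 0
    st_b1[0] = n1t
    st_a2[0] = 0
    st_b2[0] = n2t
    st_parent[0] = -1
    st_side[0] = 0
    st_depth[0] = 0
    sp = 1

    nn = 0
    mem_off = 0
    while sp > 0:
        sp -= 1
        a1 = st_a1[sp]; b1 = st_b1[sp]; a2 = st_a2[sp]; b2 = st_b2[sp]
        parent = st_parent[sp]; side = st_side[sp]; dep = st_depth[sp]
        node = node_base + nn
        nn += 1
        if parent >= 0:
            if side == 0:
                left[parent] = node
            else:
                right[parent] = node
        depth[node] = dep
        left[node] = -1
        right[node] = -1
        n1 = b1 - a1
        n2 = b2 - a2

        make_leaf = n1 < 2 * min_node or n2 < 2 * min_node
        bf = -1
        bt = 0.0
        if not make_leaf:
            if not _node_gradients(g, w, mode, sidx1, a1, b1, rho_row):
                make_leaf = True
            else:
                mtry_eff = mtry if mtry < p else p
                _draw_features(p, mtry_eff, feat_buf)
                bf, bt, _gain = _scan_node(sidx1, val1, a1, b1, val2, a2, b2,
                                           rho_row, feat_buf, mtry_eff, min_node)
                if bf < 0:
                    make_leaf = True

        if make_leaf:
            feat[node] = LEAF
            thr[node] = 0.0
            if mode == MODE_CAUSAL:
                sa = 0.0
                sb = 0.0
                for k in range(a2, b2):
                    i = sidx2[0, k]
                    sa += w[i] * g[i]
                    sb += w[i] * w[i]
                val_a[node] = sa
                val_b[node] = sb
            else:
                s = 0.0
                for k in range(a2, b2):
                    s += g[sidx2[0, k]]
                if n2 > 0:
                    val_a[node] = s / n2
                else:  # degenerate tiny subsample: fall back to J1 mean
                    s1 = 0.0
                    for k in range(a1, b1):
                        s1 += g[sidx1[0, k]]
                    val_a[node] = s1 / n1 if n1 > 0 else 0.0
                val_b[node] = float(n2)
            leaf_mstart[node] = mem_base + mem_off
            leaf_mcount[node] = n2
            for k in range(a2, b2):
                members[mem_base + mem_off] = sidx2[0, k]
                mem_off += 1
            continue

        feat[node] = bf
        thr[node] = bt
        l1 = _mark_left(sidx1, val1, a1, b1, bf, bt, goes_left)
        _partition_all(sidx1, val1, a1, b1, p, l1, goes_left, si_scr1, vv_scr1)
        l2 = _mark_left(sidx2, val2, a2, b2, bf, bt, goes_left)
        _partition_all(sidx2, val2, a2, b2, p, l2, goes_left, si_scr2, vv_scr2)

        # push right then left (left is processed next, preorder)
        st_a1[sp] = a1 + l1; st_b1[sp] = b1
        st_a2[sp] = a2 + l2; st_b2[sp] = b2
        st_parent[sp] = node; st_side[sp] = 1; st_depth[sp] = dep + 1
        sp += 1
        st_a1[sp] = a1; st_b1[sp] = a1 + l1
        st_a2[sp] = a2; st_b2[sp] = a2 + l2
        st_parent[sp] = node; st_side[sp] = 0; st_depth[sp] = dep + 1
        sp += 1
    return nn


@njit(cache=True)
def _grow_forest(XT, g, w, gsort, mode, n_trees, s, s1, min_node, mtry, tree_seeds,
                 nodes_cap, feat, thr, left, right, depth, val_a, val_b,
                 leaf_mstart, leaf_mcount, members, tree_n_nodes, in_sample):
    """Grow all trees; subsamples are drawn without replacement per tree.

    ``XT`` is the (p, n) transposed covariate matrix; ``gsort`` the (p, n)
    global presort (row v = all training rows ascending in covariate v).
    """
    n = XT.shape[1]
    p = XT.shape[0]
    s2 = s - s1
    perm = np.empty(n, np.int64)
    half = np.zeros(n, np.uint8)
    sidx1 = np.empty((p, s1), np.int32)
    val1 = np.empty((p, s1))
    sidx2 = np.empty((p, s2), np.int32)
    val2 = np.empty((p, s2))
    rho_row = np.zeros(n)
    goes_left = np.zeros(n, np.uint8)
    si_scr1 = np.empty(s1, np.int32)
    vv_scr1 = np.empty(s1)
    si_scr2 = np.empty(s2, np.int32)
    vv_scr2 = np.empty(s2)
    feat_buf = np.empty(p, np.int64)
    for b in range(n_trees):
        np.random.seed(tree_seeds[b])
        for i in range(n):
            perm[i] = i
        for j in range(s):
            k = j + np.random.randint(0, n - j)
            t = perm[j]
            perm[j] = perm[k]
            perm[k] = t
        for j in range(s1):
            half[perm[j]] = 1
            in_sample[b, perm[j]] = True
        for j in range(s1, s):
            half[perm[j]] = 2
            in_sample[b, perm[j]] = True
        for v in range(p):
            c1 = 0
            c2 = 0
            for i in range(n):
                r = gsort[v, i]
                h = half[r]
                if h == 1:
                    sidx1[v, c1] = r
                    val1[v, c1] = XT[v, r]
                    c1 += 1
                elif h == 2:
                    sidx2[v, c2] = r
                    val2[v, c2] = XT[v, r]
                    c2 += 1
        nn = _grow_tree(g, w, mode, min_node, mtry, p,
                        sidx1, val1, sidx2, val2, s1, s2,
                        rho_row, goes_left, si_scr1, vv_scr1, si_scr2, vv_scr2,
                        feat_buf, feat, thr, left, right, depth, val_a, val_b,
                        leaf_mstart, leaf_mcount, members,
                        b * nodes_cap, b * s2)
        tree_n_nodes[b] = nn
        for j in range(s):
            half[perm[j]] = 0


@njit(cache=True)
def _route(Xq, feat, thr, left, right, roots, out):
    """Leaf node index for every (query, tree) pair."""
    nq = Xq.shape[0]
    nb = roots.shape[0]
    for q in range(nq):
        for b in range(nb):
            node = roots[b]
            while feat[node] >= 0:
                if Xq[q, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[q, b] = node


@njit(cache=True)
def _predict_regression(leafmat, val_a, leaf_mcount, in_sample, train_rows, out, n_used):
    """Average of J2 leaf means over usable trees (OOB for training rows)."""
    nq, nb = leafmat.shape
    for q in range(nq):
        tr = train_rows[q]
        s = 0.0
        c = 0
        for b in range(nb):
            if tr >= 0 and in_sample[b, tr]:
                continue
            leaf = leafmat[q, b]
            if leaf_mcount[leaf] == 0:
                continue
            s += val_a[leaf]
            c += 1
        n_used[q] = c
        out[q] = s / c if c > 0 else np.nan


@njit(cache=True)
def _predict_cate(leafmat, val_a, val_b, leaf_mcount, in_sample, train_rows,
                  out, n_used):
    """Forest-weighted residual-on-residual CATE.

    tau(x) = sum_i alpha_i(x) w~_i y~_i / sum_i alpha_i(x) w~_i^2 where the
    forest weights alpha put mass 1/(B' |leaf|) on each estimation-half
    member of the leaf containing x (the 1/B' normalization cancels).
    NaN marks queries with zero weighted treatment variance (caller applies
    the forest-wide fallback).
    """
    nq, nb = leafmat.shape
    for q in range(nq):
        tr = train_rows[q]
        num = 0.0
        den = 0.0
        c = 0
        for b in range(nb):
            if tr >= 0 and in_sample[b, tr]:
                continue
            leaf = leafmat[q, b]
            cnt = leaf_mcount[leaf]
            if cnt == 0:
                continue
            num += val_a[leaf] / cnt
            den += val_b[leaf] / cnt
            c += 1
        n_used[q] = c
        out[q] = num / den if den > 0.0 else np.nan
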