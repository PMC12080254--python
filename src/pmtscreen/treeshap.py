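"""Exact interventional Shapley values for sklearn tree ensembles.

For a decision tree, the interventional coalition game against one background
sample ``b`` is ``v(S) = f(x_S, b_{\\bar S})`` — features in the coalition are
read from the explained compound, the rest from the background.  A tree's
output is a sum over leaves of ``w_leaf * prod(path conditions)``, and for a
fixed ``(x, b)`` each path condition on a feature ``j`` is satisfied either by
the x-value, the b-value, both, or neither.  Per leaf this reduces the game to
a unanimity-type game "all x-required features in S, no b-required feature in
S", whose Shapley values (and pairwise Shapley interaction values) have closed
forms.  Summing over leaves, trees and a background set gives exact
attributions: ``base + sum(phi) == model output`` to float precision.

Only binary classifiers (attributions on the positive-class probability) and
regressors are supported; that is all the screening model needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, inf

import numpy as np
from scipy.special import gammaln


@dataclass
class TreeLeaves:
    """Flattened leaf table of one tree: value + box constraints per leaf."""

    values: np.ndarray          # (n_leaves,)
    cond_feats: list[np.ndarray]  # per leaf, feature indices (q,)
    cond_lo: list[np.ndarray]     # per leaf, strict lower bounds (q,)
    cond_hi: list[np.ndarray]     # per leaf, inclusive upper bounds (q,)


def _leaf_value(raw: np.ndarray) -> float:
    val = np.asarray(raw, dtype=float).ravel()
    if val.size == 1:  # regressor
        return float(val[0])
    if val.size == 2:  # binary classifier: positive-class fraction
        total = val.sum()
        return float(val[1] / total) if total > 0 else 0.0
    raise ValueError("only binary classifiers / single-output regressors supported")


def extract_leaves(tree) -> TreeLeaves:
    """Walk a fitted sklearn tree, merging split thresholds into per-feature
    intervals ``lo < x[f] <= hi`` along each root-to-leaf path."""
    t = tree.tree_
    values: list[float] = []
    feats: list[np.ndarray] = []
    los: list[np.ndarray] = []
    his: list[np.ndarray] = []

    box: dict[int, list[float]] = {}

    def rec(node: int) -> None:
        if t.children_left[node] == -1:
            values.append(_leaf_value(t.value[node]))
            items = sorted(box.items())
            feats.append(np.array([f for f, _ in items], dtype=np.intp))
            los.append(np.array([b[0] for _, b in items]))
            his.append(np.array([b[1] for _, b in items]))
            return
        f = int(t.feature[node])
        thr = float(t.threshold[node])
        prev = box.get(f)
        lo, hi = (prev[0], prev[1]) if prev else (-inf, inf)
        # left branch: x[f] <= thr
        box[f] = [lo, min(hi, thr)]
        rec(int(t.children_left[node]))
        # right branch: x[f] > thr
        box[f] = [max(lo, thr), hi]
        rec(int(t.children_right[node]))
        if prev is None:
            del box[f]
        else:
            box[f] = prev

    rec(0)
    return TreeLeaves(np.array(values), feats, los, his)


def _estimators(model) -> list:
    if hasattr(model, "estimators_"):
        return list(np.ravel(model.estimators_))
    return [model]


def model_output(model, X: np.ndarray) -> np.ndarray:
    """Raw output the attributions decompose: P(positive) or regression value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


_MAX_PATH = 64  # factorials stay exact in float well beyond tree depths used
_FACT = np.array([float(factorial(k)) for k in range(_MAX_PATH + 1)])


def _phi_coeffs(max_q: int) -> tuple[np.ndarray, np.ndarray]:
    """G[a, c] = (a-1)! c! / (a+c)!  and  H[a, c] = -a! (c-1)! / (a+c)!."""
    n = max_q + 1
    G = np.zeros((n, n))
    H = np.zeros((n, n))
    for a in range(n):
        for c in range(n):
            if a + c == 0 or a + c > _MAX_PATH:
                continue
            if a >= 1:
                G[a, c] = _FACT[a - 1] * _FACT[c] / _FACT[a + c]
            if c >= 1:
                H[a, c] = -_FACT[a] * _FACT[c - 1] / _FACT[a + c]
    return G, H


def _satisfaction(leaves: TreeLeaves, i: int, X: np.ndarray) -> np.ndarray:
    f, lo, hi = leaves.cond_feats[i], leaves.cond_lo[i], leaves.cond_hi[i]
    v = X[:, f]
    return (v > lo[None, :]) & (v <= hi[None, :])


def shap_values(
    model, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values.

    Returns ``(phi, base)`` with ``phi`` of shape (n_x, n_features) and
    ``base`` the expected model output over the background set;
    ``base + phi.sum(axis=1)`` equals ``model_output(model, X)`` exactly.
    """
    # sklearn evaluates trees on float32-cast inputs; mirror that so the
    # attributions decompose the model's actual output
    X = np.asarray(X, dtype=np.float32).astype(np.float64)
    B = np.asarray(background, dtype=np.float32).astype(np.float64)
    n_x, n_feat = X.shape
    n_b = B.shape[0]
    if n_b == 0:
        raise ValueError("background set must be nonempty")

    trees = _estimators(model)
    phi = np.zeros((n_x, n_feat))
    max_q = 0
    all_leaves = [extract_leaves(t) for t in trees]
    for lv in all_leaves:
        for f in lv.cond_feats:
            max_q = max(max_q, len(f))
    G, H = _phi_coeffs(max_q)

    for lv in all_leaves:
        for i in range(len(lv.values)):
            w = lv.values[i]
            feats = lv.cond_feats[i]
            q = len(feats)
            if w == 0.0 or q == 0:
                continue
            sat_x = _satisfaction(lv, i, X)          # (n_x, q)
            sat_b = _satisfaction(lv, i, B)          # (n_b, q)
            # per (x, b) pair condition classification
            x_only = sat_x[:, None, :] & ~sat_b[None, :, :]   # (n_x, n_b, q)
            b_only = ~sat_x[:, None, :] & sat_b[None, :, :]
            dead = (~sat_x[:, None, :] & ~sat_b[None, :, :]).any(axis=2)
            a = x_only.sum(axis=2)
            c = b_only.sum(axis=2)
            live = ~dead
            coef_a = np.where(live & (a > 0), w * G[a, c], 0.0)
            coef_c = np.where(live & (c > 0), w * H[a, c], 0.0)
            # phi[x, feats[j]] += mean_b( coef_a * x_only + coef_c * b_only )
            contrib = (
                np.einsum("xb,xbj->xj", coef_a, x_only.astype(np.float64))
                + np.einsum("xb,xbj->xj", coef_c, b_only.astype(np.float64))
            ) / n_b
            np.add.at(phi, (slice(None), feats), contrib)

    phi /= len(trees)
    base = np.full(n_x, float(np.mean(model_output(model, B))))
    return phi, base


def _interaction_weights(n_feat: int, r: int) -> np.ndarray:
    """W[t] = sum_e C(n_feat - r, e) * (t+e)! (n_feat - t - e - 2)! / (2 (n_feat-1)!)

    for coalition sizes t of relevant features, marginalizing the
    ``n_feat - r`` features the leaf never tests.  Computed in log space.
    """
    outside = n_feat - r
    W = np.zeros(max(r - 1, 1))
    lg = gammaln
    log_norm = lg(n_feat)  # log((n_feat-1)!)
    for t in range(len(W)):
        e = np.arange(outside + 1)
        s = t + e
        terms = (
            lg(outside + 1) - lg(e + 1) - lg(outside - e + 1)   # log C(outside, e)
            + lg(s + 1) + lg(n_feat - s - 1) - log_norm
        )
        W[t] = 0.5 * np.exp(terms).sum()
    return W


def shap_interaction_values(
    model, X: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact interventional Shapley interaction matrices, shape (n_x, M, M).

    Off-diagonal entries are the pairwise Shapley interaction index of the
    interventional game; the diagonal absorbs the remainder so each row sums
    to the feature's Shapley value (hence the whole matrix sums to
    ``output - base``).  Matrices are symmetric.
    """
    X = np.asarray(X, dtype=np.float32).astype(np.float64)
    B = np.asarray(background, dtype=np.float32).astype(np.float64)
    n_x, n_feat = X.shape
    n_b = B.shape[0]
    trees = _estimators(model)
    inter = np.zeros((n_x, n_feat, n_feat))
    wcache: dict[int, np.ndarray] = {}
    rows = np.arange(n_x)[:, None, None]

    for tree in trees:
        lv = extract_leaves(tree)
        for i in range(len(lv.values)):
            w = lv.values[i]
            feats = lv.cond_feats[i]
            q = len(feats)
            if w == 0.0 or q < 2:
                continue
            sat_x = _satisfaction(lv, i, X)
            sat_b = _satisfaction(lv, i, B)
            x_only = (sat_x[:, None, :] & ~sat_b[None, :, :]).astype(np.float64)
            b_only = (~sat_x[:, None, :] & sat_b[None, :, :]).astype(np.float64)
            live = ~(~sat_x[:, None, :] & ~sat_b[None, :, :]).any(axis=2)
            a = x_only.sum(axis=2).astype(np.intp)
            c = b_only.sum(axis=2).astype(np.intp)
            r = a + c  # relevant feature count per (x, b)
            for rr in np.unique(r):
                if rr >= 2 and rr not in wcache:
                    wcache[rr] = _interaction_weights(n_feat, int(rr))
            # closed-form pair deltas of the per-leaf unanimity game:
            #   both in A: +W[a-2]; one in A one in C: -W[a-1]; both in C: +W[a]
            coef_aa = np.zeros_like(a, dtype=np.float64)
            coef_ac = np.zeros_like(coef_aa)
            coef_cc = np.zeros_like(coef_aa)
            mask = live & (r >= 2)
            for (ai, ci) in {(int(p), int(s)) for p, s in zip(a[mask], c[mask])}:
                rr = ai + ci
                Wt = wcache[rr]
                sel = mask & (a == ai) & (c == ci)
                if ai >= 2:
                    coef_aa[sel] = w * Wt[ai - 2]
                if ai >= 1 and ci >= 1:
                    coef_ac[sel] = -w * Wt[ai - 1]
                if ci >= 2:
                    coef_cc[sel] = w * Wt[ai]
            pair = (
                np.einsum("xb,xbi,xbj->xij", coef_aa, x_only, x_only)
                + np.einsum("xb,xbi,xbj->xij", coef_ac, x_only, b_only)
                + np.einsum("xb,xbi,xbj->xij", coef_ac, b_only, x_only)
                + np.einsum("xb,xbi,xbj->xij", coef_cc, b_only, b_only)
            ) / n_b
            idx = np.arange(q)
            pair[:, idx, idx] = 0.0  # self-pairs are not interactions
            np.add.at(inter, (rows, feats[None, :, None], feats[None, None, :]), pair)

    inter /= len(trees)
    phi, _ = shap_values(model, X, background)
    diag = phi - inter.sum(axis=2)
    inter[:, np.arange(n_feat), np.arange(n_feat)] = diag
    return inter
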