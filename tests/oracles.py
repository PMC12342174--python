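"""Independent brute-force oracles used across the test suite.

Everything here is written as plain scalar loops, deliberately avoiding
the package's vectorized code paths so each check is a genuine dual
route.
"""

from __future__ import annotations

import math

import numpy as np


def squared_distance_loops(X):
    n, d = X.shape
    rho = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            rho[i, j] = sum((X[i, m] - X[j, m]) ** 2 for m in range(d))
    return rho


def scaling_factor_loops(rho, k):
    n = rho.shape[0]
    local = []
    for i in range(n):
        dists = sorted(rho[i, j] for j in range(n) if j != i)
        local.append(sum(dists[:k]) / k)
    nu = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            nu[i, j] = (local[i] + local[j] + rho[i, j]) / 3.0
    return nu


def affinity_loops(X, k, mu):
    rho = squared_distance_loops(X)
    nu = scaling_factor_loops(rho, k)
    n = rho.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 1.0 if i == j else math.exp(-rho[i, j] / (mu * nu[i, j]))
    return A


def elu_scalar(x, alpha=1.0):
    return x if x > 0 else alpha * (math.exp(x) - 1.0)


def gcn_forward_loops(H0, L, W0, b0, W1, b1, W2, b2, alpha=1.0):
    """Per-node message-passing oracle for the two-conv + linear GCN."""
    n = H0.shape[0]
    h = W0.shape[1]

    def conv(H, W, b):
        out = np.zeros((n, W.shape[1]))
        for i in range(n):
            agg = np.zeros(H.shape[1])
            for j in range(n):
                agg += L[i, j] * H[j]
            pre = agg @ W + b
            out[i] = [elu_scalar(v, alpha) for v in pre]
        return out

    H1 = conv(H0, W0, b0)
    H2 = conv(H1, W1, b1)
    Y = np.zeros((n, W2.shape[1]))
    for i in range(n):
        Y[i] = H2[i] @ W2 + b2
    return H1, H2, Y


def leaky_scalar(x, slope=0.2):
    return x if x > 0 else slope * x


def attention_loops(H, P, W, a, slope=0.2):
    """Scalar softmax-attention oracle for one head."""
    n = H.shape[0]
    G = np.array([H[i] @ W for i in range(n)])
    dh = G.shape[1]
    alpha = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in range(n) if P[i, j] > 0]
        scores = []
        for j in nbrs:
            concat = np.concatenate([G[i], G[j]])
            scores.append(leaky_scalar(float(a @ concat), slope))
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        tot = sum(exps)
        for j, e in zip(nbrs, exps):
            alpha[i, j] = e / tot
    return alpha


def gat_forward_loops(H, P, W_list, a_list, Wcls, bcls, slope=0.2,
                      elu_alpha=1.0):
    """Scalar oracle for the two-head attention layer + softmax head."""
    n = H.shape[0]
    outs = []
    for W, a in zip(W_list, a_list):
        alpha = attention_loops(H, P, W, a, slope)
        G = np.array([H[i] @ W for i in range(n)])
        head = np.zeros_like(G)
        for i in range(n):
            agg = np.zeros(G.shape[1])
            for j in range(n):
                agg += alpha[i, j] * G[j]
            head[i] = [elu_scalar(v, elu_alpha) for v in agg]
        outs.append(head)
    H_att = np.hstack(outs)
    H_cls = np.zeros((n, Wcls.shape[1]))
    for i in range(n):
        logits = H_att[i] @ Wcls + bcls
        mx = logits.max()
        e = np.exp(logits - mx)
        H_cls[i] = e / e.sum()
    return H_att, H_cls


def macro_metrics_loops(y_true, y_pred, n_classes):
    """Contingency-table oracle for accuracy and macro P/R/F1
    (zero-division resolved as 0)."""
    acc = sum(int(t == p) for t, p in zip(y_true, y_pred)) / len(y_true)
    precs, recs, f1s = [], [], []
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    k = n_classes
    return acc, sum(precs) / k, sum(recs) / k, sum(f1s) / k


def min_p_full_rank_loops(A, p0, step):
    """Exhaustive grid scan for the smallest retention fraction whose
    sparsified matrix leaves no node without a retained entry."""
    n = A.shape[0]
    p = p0
    while p <= 1.0 + 1e-12:
        p_eff = min(p, 1.0)
        m = max(1, int(math.floor(p_eff * n * n)))
        eps = sorted(A.flatten(), reverse=True)[m - 1]
        ok = True
        for i in range(n):
            deg = sum(1 for j in range(n)
                      if A[i, j] >= eps or A[j, i] >= eps)
            if deg == 0:
                ok = False
                break
        if ok:
            return p_eff
        p += step
    return None
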