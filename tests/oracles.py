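"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive loops and direct formulas, sharing no code with
the package's implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def wa_predict_bruteforce(X_cal, y_cal, X_new, deshrinking="inverse"):
    """Weighted averaging by direct loops."""
    X_cal = np.asarray(X_cal, float)
    y_cal = np.asarray(y_cal, float)
    n, m = X_cal.shape
    optima = []
    for k in range(m):
        num = sum(X_cal[i, k] * y_cal[i] for i in range(n))
        den = sum(X_cal[i, k] for i in range(n))
        optima.append(num / den)

    def raw(row):
        num = sum(row[k] * optima[k] for k in range(m))
        den = sum(row)
        return num / den

    raw_cal = np.array([raw(X_cal[i]) for i in range(n)])
    if deshrinking == "inverse":
        b, a = np.polyfit(raw_cal, y_cal, 1)
        return np.array([a + b * raw(r) for r in np.asarray(X_new, float)])
    b, a = np.polyfit(y_cal, raw_cal, 1)
    return np.array([(raw(r) - a) / b for r in np.asarray(X_new, float)])


def scd_bruteforce(p, q):
    return sum((math.sqrt(pi) - math.sqrt(qi)) ** 2 for pi, qi in zip(p, q))


def mat_predict_bruteforce(X_cal, y_cal, X_new, k, weighting="inverse_distance"):
    """kNN under squared chord distance with naive double loops."""

    def props(M):
        M = np.asarray(M, float)
        return M / M.sum(axis=1, keepdims=True)

    Pc, Pn = props(X_cal), props(X_new)
    out = []
    for row in Pn:
        d = np.array([scd_bruteforce(row, c) for c in Pc])
        order = np.argsort(d, kind="stable")
        kth = d[order[k - 1]]
        sel = [j for j in range(len(d)) if d[j] <= kth + 1e-12]
        if weighting == "none":
            w = [1.0] * len(sel)
        else:
            if any(d[j] <= 1e-12 for j in sel):
                w = [1.0 if d[j] <= 1e-12 else 0.0 for j in sel]
            else:
                w = [1.0 / d[j] for j in sel]
        out.append(sum(wi * y_cal[j] for wi, j in zip(w, sel)) / sum(w))
    return np.array(out)


def min_scd_bruteforce(X_fossil, X_cal):
    def props(M):
        M = np.asarray(M, float)
        return M / M.sum(axis=1, keepdims=True)

    Pf, Pc = props(X_fossil), props(X_cal)
    return np.array([min(scd_bruteforce(f, c) for c in Pc) for f in Pf])


def rda_ve_bruteforce(Y, c):
    """Variance-weighted mean per-taxon regression R^2."""
    Y = np.asarray(Y, float)
    c = np.asarray(c, float)
    total = 0.0
    explained = 0.0
    for k in range(Y.shape[1]):
        yk = Y[:, k]
        var_k = ((yk - yk.mean()) ** 2).sum()
        if var_k == 0:
            continue
        b, a = np.polyfit(c, yk, 1)
        fit = a + b * c
        ss_fit = ((fit - yk.mean()) ** 2).sum()
        total += var_k
        explained += ss_fit
    return explained / total


def best_segmentation_bruteforce(Y, max_segments):
    """Exhaustive search over contiguous segmentations of rows of Y.

    Returns (best_total_within_SS, cut index tuples) over all segmentations
    into at most ``max_segments`` contiguous blocks.
    """
    Y = np.asarray(Y, float)
    n = Y.shape[0]

    def seg_ss(a, b):
        block = Y[a:b]
        return float(((block - block.mean(axis=0)) ** 2).sum())

    best = (seg_ss(0, n), ())
    for m in range(2, max_segments + 1):
        for cuts in itertools.combinations(range(1, n), m - 1):
            edges = (0, *cuts, n)
            ss = sum(seg_ss(a, b) for a, b in zip(edges[:-1], edges[1:]))
            if ss < best[0] - 1e-12:
                best = (ss, cuts)
    return best
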