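"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written in the most literal way possible — plain loops over
definitions — and kept free of any code path shared with the package
(except the Gaussian order-statistic moment table, which is an input to
the MOST definition rather than part of its search).
"""

from __future__ import annotations

import numpy as np

from mirscreen.descreen import MAD_SCALE, _gaussian_topk_moments


def nod_oracle(edges: set[tuple[str, str]], mirna: str) -> int:
    """Count targets of `mirna` whose only regulator is `mirna`."""
    count = 0
    for m, g in edges:
        if m != mirna:
            continue
        regulators = {m2 for m2, g2 in edges if g2 == g}
        if regulators == {mirna}:
            count += 1
    return count


def tfp_oracle(edges: set[tuple[str, str]], mirna: str, tfs: set[str]) -> float:
    targets = {g for m, g in edges if m == mirna}
    return len([g for g in targets if g in tfs]) / len(targets)


def auc_oracle(scores, labels) -> float:
    """Probability a random positive outranks a random negative, ties ½."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def most_oracle(disease, control) -> float:
    """MOST by explicit loop over every top-k subset of disease values."""
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    med = float(np.median(control))
    scale = MAD_SCALE * float(np.median(np.abs(control - np.median(control))))
    z = sorted(((x - med) / scale for x in disease), reverse=True)
    expect, sd = _gaussian_topk_moments(len(z))
    best = -np.inf
    for k in range(1, len(z) + 1):
        stat = (sum(z[:k]) - expect[k - 1]) / sd[k - 1]
        best = max(best, stat)
    return best


def lsoss_oracle(disease, control) -> float:
    """LSOSS by explicit enumeration of every split point."""
    d = sorted(disease, reverse=True)
    control = list(control)
    n = len(d)

    def ss(vals):
        m = sum(vals) / len(vals)
        return sum((v - m) ** 2 for v in vals)

    best_k, best = None, float("inf")
    for k in range(1, n):
        total = ss(d[:k]) + ss(d[k:])
        if total < best:
            best, best_k = total, k
    hi = d[:best_k]
    s2 = (ss(control) + best) / (len(control) + n - 3)
    return (sum(hi) / len(hi) - sum(control) / len(control)) / np.sqrt(s2)


def knn_impute_oracle(X: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive nearest-feature search for every missing cell."""
    out = X.copy()
    n_feat, n_samp = X.shape
    for f in range(n_feat):
        for s in range(n_samp):
            if not np.isnan(X[f, s]):
                continue
            dists = []
            for j in range(n_feat):
                if j == f or np.isnan(X[j, s]):
                    continue
                shared = [
                    t
                    for t in range(n_samp)
                    if not np.isnan(X[f, t]) and not np.isnan(X[j, t])
                ]
                if not shared:
                    continue
                d = np.sqrt(sum((X[f, t] - X[j, t]) ** 2 for t in shared))
                dists.append((d, j))
            dists.sort()
            chosen = [j for _, j in dists[:k]]
            out[f, s] = np.mean([X[j, s] for j in chosen])
    return out
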