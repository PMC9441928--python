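"""Independent reference implementations used only as test oracles.

Each oracle is deliberately naive (exhaustive enumeration, double loops,
textbook formulas) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def euclidean_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return D


def brute_force_pam_cost(X: np.ndarray, k: int) -> float:
    """Global optimum of the k-medoids objective by medoid-set enumeration."""
    D = euclidean_matrix(X)
    best = np.inf
    for medoids in itertools.combinations(range(len(D)), k):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def double_loop_silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths by the definition, computed with explicit loops."""
    D = euclidean_matrix(X)
    labels = np.asarray(labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = np.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(D[i, j] for j in members) / len(members))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def anova_ss_oracle(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Balanced two-way crossed ANOVA sums of squares from cell means."""
    y, a, b = map(np.asarray, (y, a, b))
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_a = sum(
        (y[a == lv].size) * (y[a == lv].mean() - grand) ** 2 for lv in np.unique(a)
    )
    ss_b = sum(
        (y[b == lv].size) * (y[b == lv].mean() - grand) ** 2 for lv in np.unique(b)
    )
    ss_cells = sum(
        (y[(a == la) & (b == lb)].size) * (y[(a == la) & (b == lb)].mean() - grand) ** 2
        for la in np.unique(a)
        for lb in np.unique(b)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_resid = ss_total - ss_cells
    return dict(a=float(ss_a), b=float(ss_b), ab=float(ss_ab),
                resid=float(ss_resid), total=float(ss_total))


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r via the raw covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def welch_t_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t statistic from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return float((a.mean() - b.mean()) / np.sqrt(va / len(a) + vb / len(b)))


def label_agreement(labels, truth) -> float:
    """Best fraction of matching assignments over label permutations."""
    labels, truth = list(labels), list(truth)
    cl = sorted(set(labels))
    tl = sorted(set(truth))
    best = 0.0
    for perm in itertools.permutations(tl, len(cl)):
        mapping = dict(zip(cl, perm))
        frac = np.mean([mapping.get(l) == t for l, t in zip(labels, truth)])
        best = max(best, float(frac))
    return best
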