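"""Independent brute-force oracles shared by the acceptance suite.

Every function here recomputes a statistic by explicit enumeration or
textbook formula, independently of the package's implementation paths.
"""

import numpy as np


def auc_pairs(y, s):
    y = np.asarray(y, bool)
    s = np.asarray(s, float)
    num = den = 0.0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            den += 1
            num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
    return num / den


def glcm_stats_loops(P):
    G = P.shape[0]
    px = P.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(G))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(G))
    out = {k: 0.0 for k in (
        "joint_energy", "contrast", "correlation", "joint_entropy",
        "inverse_difference_moment", "dissimilarity", "cluster_shade",
        "cluster_prominence", "sum_average", "difference_entropy")}
    pdiff = np.zeros(G)
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            a, b = i + 1, j + 1
            out["joint_energy"] += p * p
            out["contrast"] += (a - b) ** 2 * p
            out["inverse_difference_moment"] += p / (1 + (a - b) ** 2)
            out["dissimilarity"] += abs(a - b) * p
            out["cluster_shade"] += (a + b - 2 * mu) ** 3 * p
            out["cluster_prominence"] += (a + b - 2 * mu) ** 4 * p
            out["sum_average"] += (a + b) * p
            if p > 0:
                out["joint_entropy"] -= p * np.log2(p)
            pdiff[abs(a - b)] += p
    out["correlation"] = (
        sum((i + 1 - mu) * (j + 1 - mu) * P[i, j] for i in range(G) for j in range(G))
        / sigma2 if sigma2 > 1e-12 else 1.0)
    out["difference_entropy"] = -sum(q * np.log2(q) for q in pdiff if q > 0)
    return out


def glrlm_stats_loops(R, n_voxels):
    Nr = R.sum()
    out = {}
    out["short_run_emphasis"] = sum(
        R[g, l] / (l + 1) ** 2 for g in range(R.shape[0]) for l in range(R.shape[1])) / Nr
    out["long_run_emphasis"] = sum(
        R[g, l] * (l + 1) ** 2 for g in range(R.shape[0]) for l in range(R.shape[1])) / Nr
    out["gray_level_nonuniformity"] = sum(R[g, :].sum() ** 2 for g in range(R.shape[0])) / Nr
    out["run_length_nonuniformity"] = sum(R[:, l].sum() ** 2 for l in range(R.shape[1])) / Nr
    out["run_percentage"] = Nr / n_voxels
    out["high_gray_level_run_emphasis"] = sum(
        R[g, l] * (g + 1) ** 2 for g in range(R.shape[0]) for l in range(R.shape[1])) / Nr
    return out


def logrank_hand_table(time, event, group):
    """Two-sample log-rank statistic via the event-time table."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    O1 = E1 = V = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def spearman_rank_formula(x, y):
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pca_eigen_solution(X):
    """Z-score, eigen-decompose the correlation matrix, fix signs."""
    X = np.asarray(X, float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    C = Z.T @ Z / (len(X) - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return w, V, Z @ V
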