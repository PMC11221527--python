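"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by direct enumeration or an O(n^2)/O(n^3)
definition-level algorithm, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exhaustive_local_moran_p(values, neighbors, weights, alternative="folded",
                             pseudo=True):
    """Exhaustive conditional-permutation pseudo p per spot.

    For spot i the focal value is held fixed and all (n-1)! arrangements
    of the remaining values over the other spots are enumerated; the
    pseudo p is (1 + #extreme) / (1 + (n-1)!) with the same tail rule as
    the implementation (folded: smaller of the two strict tails).

    With ``pseudo=False`` the exact tail fraction #extreme / (n-1)! is
    returned instead — the large-n_perm limit of the Monte-Carlo pseudo
    p, which is the comparable quantity when (n-1)! is small (the +1
    pseudo correction then differs between enumeration sizes by
    construction).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    xbar = x.mean()
    m2 = ((x - xbar) ** 2).mean()
    z = (x - xbar) / math.sqrt(m2)
    out = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        other_vals = z[others]
        nb_pos = [others.index(j) for j in neighbors[i]]
        w = np.asarray(weights[i], dtype=float)
        obs = z[i] * float(np.dot(w, z[neighbors[i]]))
        geq = leq = total = 0
        eps = 1e-9  # count rounding-level ties as "at least as extreme"
        for perm in itertools.permutations(other_vals):
            lag = sum(wk * perm[p] for wk, p in zip(w, nb_pos))
            sim = z[i] * lag
            geq += sim >= obs - eps
            leq += sim <= obs + eps
            total += 1
        if alternative == "greater":
            extreme = geq
        elif alternative == "less":
            extreme = leq
        else:  # folded / two-sided share the min-tail count
            extreme = min(geq, total - geq)
        if pseudo:
            out[i] = (extreme + 1.0) / (total + 1.0)
        else:
            out[i] = extreme / total
        if alternative == "two-sided":
            out[i] = min(1.0, 2.0 * out[i])
    return out


def global_moran(values, w_dense):
    """Global Moran's I from its textbook definition."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    xc = x - x.mean()
    s0 = w_dense.sum()
    return (n / s0) * (xc @ w_dense @ xc) / (xc @ xc)


def brute_wilcoxon_p(x, y):
    """Two-sided rank-sum p by enumerating all group assignments.

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over the exact
    permutation distribution of the Mann-Whitney U of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    m = len(x)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), m):
        a = pooled[list(comb)]
        b = np.delete(pooled, list(comb))
        us.append(sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def brute_overlap_mask(a_df, b_df):
    """All-pairs O(n^2) test: does each record of a overlap any record of b."""
    mask = np.zeros(len(a_df), dtype=bool)
    a_ch = a_df["chrom"].to_numpy()
    a_s = a_df["start"].to_numpy()
    a_e = a_df["end"].to_numpy()
    for ch, s, e in zip(b_df["chrom"], b_df["start"], b_df["end"]):
        mask |= (a_ch == ch) & (a_s < e) & (a_e > s)
    return mask


def brute_ks_d(a, b):
    """sup |ECDF_a - ECDF_b| over all pooled evaluation points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pts = np.concatenate([a, b])
    fa = np.searchsorted(a, pts, side="right") / len(a)
    fb = np.searchsorted(b, pts, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def brute_average_linkage(points):
    """O(n^3) naive average-linkage agglomeration.

    Returns the cophenetic distance matrix: entry (i, j) is the
    inter-cluster average Euclidean distance at which i and j merged.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if avg < best[0]:
                    best = (avg, i, j)
        avg, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = avg
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def pearson_power(slope, noise_sd, x, alpha=0.05):
    """Exact rejection probability of the two-sided Pearson test for a
    linear-plus-Gaussian gene given fixed covariate values ``x``.

    t = r sqrt((n-2)/(1-r^2)) follows a noncentral t with n-2 df and
    noncentrality slope * sqrt(SS_x) / noise_sd.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    n = len(x)
    ssx = ((x - x.mean()) ** 2).sum()
    delta = slope * math.sqrt(ssx) / noise_sd
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(stats.nct.sf(tcrit, n - 2, delta) + stats.nct.cdf(-tcrit, n - 2, delta))
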