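"""Independent brute-force oracles used by the test suite.

Each function here recomputes a statistic by direct enumeration or explicit
loops, deliberately sharing no code with the package implementation.
"""

import itertools
import math

import numpy as np


def brute_force_deviations(X, members, mappings):
    """Loop-based deviation pipeline on a dense matrix.

    ``X`` is a dense peaks x cells array, ``members`` a list of peak indices,
    ``mappings`` a (B, n_peaks) array of background mappings. Returns
    (y, d, z) per cell; z is NaN where the background sd is zero.
    """
    X = np.asarray(X, dtype=float)
    n_peaks, n_cells = X.shape
    total = X.sum()
    E = np.empty_like(X)
    for i in range(n_peaks):
        for j in range(n_cells):
            E[i, j] = X[i].sum() * X[:, j].sum() / total

    def set_dev(idx):
        out = np.empty(n_cells)
        for j in range(n_cells):
            obs = sum(X[i, j] for i in idx)
            exp = sum(E[i, j] for i in idx)
            out[j] = (obs - exp) / exp if exp > 0 else np.nan
        return out

    y = set_dev(members)
    B = mappings.shape[0]
    member_set = set(int(i) for i in members)
    bg = np.empty((B, n_cells))
    for b in range(B):
        reflected = [i for i in range(n_peaks) if int(mappings[b, i]) in member_set]
        bg[b] = set_dev(reflected) if reflected else np.full(n_cells, np.nan)
    d = y - bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    z = np.where(sd > 0, d / sd, np.nan)
    return y, d, z


def hypergeom_sf_enumeration(overlap, population, accessible, type_size):
    """P(X >= overlap) by summing the hypergeometric pmf with math.comb."""
    lo, hi = overlap, min(accessible, type_size)
    total = math.comb(population, type_size)
    return sum(
        math.comb(accessible, j) * math.comb(population - accessible, type_size - j)
        for j in range(lo, hi + 1)
    ) / total


def wilcoxon_greater_enumeration(x, y):
    """Exact one-sided (greater) rank-sum p by enumerating all C(n+m, n)
    assignments of the pooled tie-free sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    n = len(x)
    observed = ranks[:n].sum()
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(combo)].sum() >= observed:
            count += 1
    return count / total


def km_product_limit(times, events):
    """Hand product-limit estimator at distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_chi2(times_a, events_a, times_b, events_b):
    """Table-by-table log-rank statistic: (sum O - E)^2 / sum V."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in event_times:
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        n = n1 + n2
        d = ((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum()
        O += ((ta == t) & (ea == 1)).sum()
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def spearman_rank_pearson(x, y):
    """Spearman rho as Pearson correlation of (average) ranks."""
    def ranks(v):
        v = np.asarray(v, float)
        order = v.argsort(kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
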