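"""Independent brute-force / definition-level oracles used only by tests.

These deliberately use different algorithms (triple loops, Floyd–Warshall,
networkx) than the package's implementations so that agreement is a real
cross-check, not a tautology.
"""

import numpy as np


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    """Nodal clustering by exhaustive enumeration of node triples."""
    n = a.shape[0]
    ncp = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbrs[x], nbrs[y]]:
                    tri += 1
        ncp[i] = 2 * tri / (k * (k - 1))
    return ncp


def floyd_warshall_oracle(a: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by Floyd–Warshall."""
    n = a.shape[0]
    d = np.where(a, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def lp_oracle(a: np.ndarray) -> float:
    d = floyd_warshall_oracle(a)
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d)) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def efficiency_oracle(a: np.ndarray):
    """(Eg, Ne, NLe, Eloc) straight from the definitions via Floyd–Warshall."""
    n = a.shape[0]
    d = floyd_warshall_oracle(a)
    inv = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                inv[i, j] = 1.0 / d[i, j]
    eg = inv.sum() / (n * (n - 1))
    ne = inv.sum(axis=1) / (n - 1)
    nle = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        nle[i] = efficiency_oracle_eg_only(sub)
    return eg, ne, nle, float(nle.mean())


def efficiency_oracle_eg_only(a: np.ndarray) -> float:
    n = a.shape[0]
    d = floyd_warshall_oracle(a)
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                tot += 1.0 / d[i, j]
    return tot / (n * (n - 1))


def assortativity_oracle(a: np.ndarray) -> float:
    """Newman's degree assortativity via networkx."""
    import networkx as nx

    g = nx.from_numpy_array(a.astype(int))
    try:
        r = nx.degree_assortativity_coefficient(g)
    except Exception:
        return float("nan")
    return float(r)


def betweenness_oracle(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via networkx (independent implementation)."""
    import networkx as nx

    g = nx.from_numpy_array(a.astype(int))
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def betweenness_path_enumeration_oracle(a: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths (small n)."""
    import networkx as nx

    g = nx.from_numpy_array(a.astype(int))
    n = a.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def ols_slope_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form simple-regression slope from the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())


def fisher_exact_enumeration_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    from math import comb

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(ntot, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (midranks for ties) then Pearson."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def binarize_oracle(z: np.ndarray, sparsity: float) -> np.ndarray:
    """Sort-and-cut edge selection with the documented tie-break."""
    n = z.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            w = max(z[i, j], 0.0)
            pairs.append((w, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    k = int(sparsity * n * (n - 1) / 2)
    adj = np.zeros((n, n), dtype=bool)
    taken = 0
    for w, i, j in pairs:
        if taken >= k or w <= 0:
            break
        adj[i, j] = adj[j, i] = True
        taken += 1
    return adj


def artifact_window_oracle(od: np.ndarray, fs: float, window_s: float, k_sd: float) -> np.ndarray:
    """Per-window flag decisions computed straightforwardly, channel by channel."""
    n_ch, n_wl, n_t = od.shape
    win = int(round(window_s * fs))
    n_win = int(np.ceil(n_t / win))
    flags = np.zeros((n_ch, n_win), dtype=bool)
    for ch in range(n_ch):
        for wl in range(n_wl):
            sd = od[ch, wl].std()
            if sd <= 0:
                continue
            for w in range(n_win):
                seg = od[ch, wl, w * win : (w + 1) * win]
                if seg.max() - seg.min() > k_sd * sd:
                    flags[ch, w] = True
    return flags
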