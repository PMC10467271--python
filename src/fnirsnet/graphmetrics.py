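"""Binary-network graph metrics, implemented from first principles.

Nine global metrics — clustering coefficient (Cp), characteristic path
length (Lp), small-world Gamma/Lambda/Sigma against degree-preserving
rewired null networks, local efficiency (Eloc), global efficiency (Eg),
assortativity (r) and hierarchy (b) — and five nodal metrics — nodal
clustering (NCp), nodal efficiency (Ne), nodal local efficiency (NLe),
degree centrality (Dc) and betweenness centrality (Bc). Each metric is
summarised over the sparsity sweep by its area under the curve (AUC).

Conventions for disconnected graphs (unavoidable at low sparsity): Lp
averages over connected ordered pairs only; efficiencies use 1/∞ = 0.
Undefined quantities (assortativity of a regular graph, hierarchy with no
eligible nodes) are reported as NaN and propagate to a NaN AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork, ConnectivityMatrix, SPARSITY_GRID, threshold_sweep

GLOBAL_METRICS = ("Cp", "Lp", "Gamma", "Lambda", "Sigma", "Eloc", "Eg", "r", "b")
NODAL_METRICS = ("NCp", "Ne", "NLe", "Dc", "Bc")
DEFAULT_N_RAND = 100


def _adj(net) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(bool)


def degrees(net) -> np.ndarray:
    """Degree centrality Dc: the number of neighbours of each node."""
    return _adj(net).sum(axis=1).astype(int)


def clustering(net) -> tuple[np.ndarray, float]:
    """Nodal clustering NCp_i = 2·t_i / (k_i(k_i−1)) and global Cp = mean NCp.

    t_i is the number of triangles through node i; nodes with degree < 2
    have NCp = 0.
    """
    a = _adj(net).astype(np.int64)
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2
    denom = k * (k - 1)
    ncp = np.where(denom > 0, 2 * tri / np.where(denom > 0, denom, 1), 0.0)
    return ncp, float(ncp.mean())


def shortest_paths(net) -> np.ndarray:
    """All-pairs hop counts by breadth-first search; unreachable pairs are inf."""
    a = _adj(net)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    frontier = a.copy()
    d = 1
    while d <= n:
        update = frontier & np.isinf(dist)
        if not update.any():
            break
        dist[update] = d
        frontier = (frontier.astype(np.uint8) @ a.astype(np.uint8)) > 0  # one hop longer
        d += 1
    return dist


def char_path_length(net, dist: np.ndarray | None = None) -> float:
    """Characteristic path length Lp: mean distance over connected pairs.

    Disconnected pairs are excluded; NaN when no pair is connected.
    """
    d = shortest_paths(net) if dist is None else dist
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def efficiencies(net) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(Eg, Ne, NLe, Eloc): global, nodal, nodal-local and local efficiency.

    Eg is the mean of 1/d over ordered pairs (0 for disconnected pairs);
    Ne_i restricts the mean to pairs involving i; NLe_i is the Eg of the
    subgraph induced by i's neighbours (0 when degree < 2); Eloc = mean NLe.
    """
    a = _adj(net)
    n = a.shape[0]
    d = shortest_paths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    ne = inv.sum(axis=1) / (n - 1)
    eg = float(inv.sum() / (n * (n - 1)))
    nle = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        ds = shortest_paths(sub)
        with np.errstate(divide="ignore"):
            invs = 1.0 / ds
        np.fill_diagonal(invs, 0.0)
        invs[np.isinf(ds)] = 0.0
        m = len(nbrs)
        nle[i] = invs.sum() / (m * (m - 1))
    return eg, ne, nle, float(nle.mean())


def betweenness(net) -> np.ndarray:
    """Betweenness centrality Bc by Brandes' accumulation, unnormalized.

    Each unordered source-target pair contributes once; shortest paths are
    counted within connected components only.
    """
    a = _adj(net)
    n = a.shape[0]
    nbrs = [np.flatnonzero(a[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        stack: list[int] = []
        queue = [s]
        preds: list[list[int]] = [[] for _ in range(n)]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # undirected: each pair visited from both endpoints


def assortativity(net) -> float:
    """Degree assortativity: Pearson correlation of degrees across edges.

    Each edge is counted in both orientations (Newman's r). NaN when the
    graph has < 2 edges or zero degree variance over edge endpoints.
    """
    a = _adj(net)
    i, j = np.nonzero(np.triu(a, k=1))
    if len(i) < 2:
        return float("nan")
    k = a.sum(axis=1)
    x = np.concatenate([k[i], k[j]]).astype(float)
    y = np.concatenate([k[j], k[i]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy_slope(ncp: np.ndarray, k: np.ndarray) -> float:
    """b in C ∝ k^(−b): minus the OLS slope of log NCp on log Dc.

    Eligible nodes have degree ≥ 2 and NCp > 0 (the log-log regression
    domain); NaN with < 2 eligible nodes or no degree variance among them.
    """
    ncp = np.asarray(ncp, dtype=float)
    k = np.asarray(k, dtype=float)
    elig = (k >= 2) & (ncp > 0)
    if elig.sum() < 2:
        return float("nan")
    x = np.log(k[elig])
    y = np.log(ncp[elig])
    if np.ptp(x) == 0:
        return float("nan")
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope)


def hierarchy(net) -> float:
    ncp, _ = clustering(net)
    return hierarchy_slope(ncp, degrees(net))


def random_references(
    net, n_rand: int = DEFAULT_N_RAND, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Degree-preserving rewired surrogates via seeded double-edge swaps.

    Each surrogate attempts 10 × E swaps; connectedness is not enforced. A
    graph admitting no valid swap is returned unchanged with a warning.
    """
    a = _adj(net)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    iu, ju = np.nonzero(np.triu(a, k=1))
    n_edges = len(iu)
    if n_edges < 2:
        raise ValueError("at least 2 edges are required for rewiring")
    base_edges = list(zip(iu.tolist(), ju.tolist()))
    n = a.shape[0]
    out = []
    n_attempts = 10 * n_edges
    for _ in range(n_rand):
        edges = base_edges.copy()
        present = set(edges)
        pairs = rng.integers(0, n_edges, size=(n_attempts, 2))
        coins = rng.random(n_attempts)
        swapped = 0
        for (e1, e2), coin in zip(pairs, coins):
            if e1 == e2:
                continue
            x1, y1 = edges[e1]
            x2, y2 = edges[e2]
            if coin < 0.5:
                u, v, s, t = x1, y2, x2, y1   # (x1,y1),(x2,y2) -> (x1,y2),(x2,y1)
            else:
                u, v, s, t = x1, x2, y1, y2   # -> (x1,x2),(y1,y2)
            if u == v or s == t or len({u, v, s, t}) < 4:
                continue
            new1 = (u, v) if u < v else (v, u)
            new2 = (s, t) if s < t else (t, s)
            if new1 in present or new2 in present:
                continue
            present.discard(edges[e1])
            present.discard(edges[e2])
            present.add(new1)
            present.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swapped += 1
        if swapped == 0:
            warnings.warn("no valid double-edge swap found; surrogate equals original", RuntimeWarning)
        adj = np.zeros((n, n), dtype=bool)
        idx = np.array(list(present))
        adj[idx[:, 0], idx[:, 1]] = True
        adj |= adj.T
        out.append(adj)
    return out


def small_world(net, refs: list[np.ndarray]) -> tuple[float, float, float]:
    """(Gamma, Lambda, Sigma) against the mean of the rewired references.

    Gamma = Cp / mean(Cp_rand), Lambda = Lp / mean(Lp_rand),
    Sigma = Gamma / Lambda. NaN when the normalizer is degenerate.
    """
    if not refs:
        raise ValueError("refs must be nonempty")
    _, cp = clustering(net)
    lp = char_path_length(net)
    cp_rand = np.array([clustering(r)[1] for r in refs])
    lp_rand = np.array([char_path_length(r) for r in refs])
    cp_bar = float(np.nanmean(cp_rand)) if np.isfinite(cp_rand).any() else float("nan")
    lp_bar = float(np.nanmean(lp_rand)) if np.isfinite(lp_rand).any() else float("nan")
    gamma = cp / cp_bar if cp_bar and np.isfinite(cp_bar) else float("nan")
    lam = lp / lp_bar if lp_bar and np.isfinite(lp_bar) and np.isfinite(lp) else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan")
    return float(gamma), float(lam), float(sigma)


def auc_over_thresholds(values, thresholds) -> float:
    """Trapezoidal area of a metric curve over the sparsity sweep.

    A missing (NaN) value at any threshold makes the AUC missing.
    """
    values = np.asarray(values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) < 2 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("need >= 2 ascending thresholds")
    if np.isnan(values).any():
        return float("nan")
    return float(np.trapezoid(values, thresholds))


@dataclass
class MetricSet:
    """Per-threshold metric curves and their AUC summaries for one network state.

    79 AUC values per subject per state: 9 global + 5 nodal × 14 channels.
    """

    subject_id: str | None
    state: str
    thresholds: np.ndarray
    global_curves: pd.DataFrame          # index: threshold, columns: GLOBAL_METRICS
    nodal_curves: dict[str, np.ndarray]  # metric -> (n_thresholds, n_channels)
    global_auc: pd.Series                # index: GLOBAL_METRICS
    nodal_auc: pd.DataFrame              # index: channel (0-based), columns: NODAL_METRICS


def network_metrics(net, n_rand: int = DEFAULT_N_RAND, seed=0) -> dict:
    """All global and nodal metrics of one binary network."""
    a = _adj(net)
    k = degrees(a)
    ncp, cp = clustering(a)
    dist = shortest_paths(a)
    lp = char_path_length(a, dist)
    eg, ne, nle, eloc = efficiencies(a)
    bc = betweenness(a)
    r = assortativity(a)
    b = hierarchy_slope(ncp, k)
    if a.sum() >= 4 and n_rand > 0:  # >= 2 edges
        refs = random_references(a, n_rand=n_rand, seed=seed)
        gamma, lam, sigma = small_world(a, refs)
    else:
        gamma = lam = sigma = float("nan")
    return {
        "global": {"Cp": cp, "Lp": lp, "Gamma": gamma, "Lambda": lam, "Sigma": sigma,
                   "Eloc": eloc, "Eg": eg, "r": r, "b": b},
        "nodal": {"NCp": ncp, "Ne": ne, "NLe": nle, "Dc": k.astype(float), "Bc": bc},
    }


def compute_metric_set(
    cm: ConnectivityMatrix,
    sparsities=SPARSITY_GRID,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | np.random.Generator = 0,
) -> MetricSet:
    """Metric curves over the sparsity sweep and their AUCs for one subject/state."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nets = threshold_sweep(cm, sparsities)
    n_ch = cm.n_channels
    thr = np.asarray(sparsities, dtype=float)
    gcurves = pd.DataFrame(index=thr, columns=list(GLOBAL_METRICS), dtype=float)
    ncurves = {m: np.full((len(thr), n_ch), np.nan) for m in NODAL_METRICS}
    for t, net in enumerate(nets):
        res = network_metrics(net, n_rand=n_rand, seed=rng)
        for m, v in res["global"].items():
            gcurves.loc[thr[t], m] = v
        for m, v in res["nodal"].items():
            ncurves[m][t] = v
    gauc = pd.Series({m: auc_over_thresholds(gcurves[m].to_numpy(), thr) for m in GLOBAL_METRICS})
    nauc = pd.DataFrame(
        {m: [auc_over_thresholds(ncurves[m][:, c], thr) for c in range(n_ch)] for m in NODAL_METRICS}
    )
    return MetricSet(
        subject_id=cm.subject_id,
        state=cm.state,
        thresholds=thr,
        global_curves=gcurves,
        nodal_curves=ncurves,
        global_auc=gauc,
        nodal_auc=nauc,
    )
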