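"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (adjacency matrices, BFS
and explicit path enumeration) so it shares no code path with the package's
networkx- and sklearn-based implementations.
"""

import numpy as np

INF = 10 ** 6


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = len(a)
    d = np.where(a > 0, 1, INF).astype(float)
    np.fill_diagonal(d, 0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def brute_status_closeness_ecc(a: np.ndarray):
    d = floyd_warshall(a)
    n = len(a)
    status = np.zeros(n)
    closeness = np.zeros(n)
    ecc = np.zeros(n)
    for i in range(n):
        comp = d[i] < INF
        size = int(comp.sum())
        status[i] = d[i][comp].sum()
        ecc[i] = d[i][comp].max() if size > 1 else 0
        closeness[i] = (size - 1) / status[i] if status[i] > 0 else 0.0
    return status, closeness, ecc


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Raw (unnormalized, undirected) betweenness by enumerating every
    shortest path with a pruned DFS."""
    n = len(a)
    d = floyd_warshall(a)
    adj = [np.nonzero(a[i])[0] for i in range(n)]
    bet = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if d[s, t] >= INF:
                continue
            paths = []
            stack = [(s, (s,))]
            while stack:
                v, path = stack.pop()
                if v == t:
                    paths.append(path)
                    continue
                for w in adj[v]:
                    if d[s, w] == d[s, v] + 1 and d[s, v] + 1 + d[w, t] == d[s, t]:
                        stack.append((w, path + (w,)))
            total = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / total
    return bet


def brute_clustering(a: np.ndarray) -> np.ndarray:
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[u, v] for x, u in enumerate(nbrs) for v in nbrs[x + 1:])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_coreness(a: np.ndarray) -> np.ndarray:
    n = len(a)
    deg = a.sum(axis=1).astype(int)
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n, dtype=int)
    k = 0
    while alive.any():
        while True:
            drop = alive & (deg <= k)
            if not drop.any():
                break
            for v in np.nonzero(drop)[0]:
                core[v] = k
                alive[v] = False
                deg[np.nonzero(a[v])[0]] -= 1
        k += 1
    return core


def brute_cocitation(a: np.ndarray) -> np.ndarray:
    n = len(a)
    shared = a @ a
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs):
            out[i] = shared[i, nbrs].mean()
    return out


def brute_constraint(a: np.ndarray) -> np.ndarray:
    """Burt's constraint with equal tie weights; 0 for isolated nodes."""
    n = len(a)
    deg = a.sum(axis=1)
    p = np.zeros((n, n))
    for i in range(n):
        if deg[i] > 0:
            p[i] = a[i] / deg[i]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        for j in nbrs:
            indirect = sum(p[i, q] * p[q, j] for q in range(n) if q not in (i, j))
            out[i] += (p[i, j] + indirect) ** 2
    return out


def brute_cyclic(a: np.ndarray) -> np.ndarray:
    """Mean of 1/(smallest cycle length) over neighbor pairs, by BFS in the
    graph with the focal node deleted."""
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            continue
        sub = a.copy()
        sub[i, :] = 0
        sub[:, i] = 0
        total = 0.0
        pairs = 0
        for x, u in enumerate(nbrs):
            for v in nbrs[x + 1:]:
                pairs += 1
                # BFS u -> v in the deleted graph
                dist = {u: 0}
                frontier = [u]
                while frontier and v not in dist:
                    nxt = []
                    for w in frontier:
                        for z in np.nonzero(sub[w])[0]:
                            if z not in dist:
                                dist[z] = dist[w] + 1
                                nxt.append(z)
                    frontier = nxt
                if v in dist:
                    total += 1.0 / (dist[v] + 2)
        out[i] = total / pairs
    return out


def power_iteration_eigenvector(a: np.ndarray, iters: int = 5000) -> np.ndarray:
    """Principal eigenvector by power iteration on the shifted matrix
    A + (n+1)·I, which makes the dominant eigenvalue unique in sign (handles
    bipartite graphs whose spectrum is symmetric)."""
    n = len(a)
    if a.sum() == 0:
        return np.zeros(n)
    shifted = a + (n + 1) * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = shifted @ v
        v = w / np.linalg.norm(w)
    return np.abs(v)


def spectral_gap_simple(a: np.ndarray, tol: float = 1e-8) -> bool:
    """True when the largest adjacency eigenvalue is simple."""
    w = np.linalg.eigvalsh(a)
    return len(w) < 2 or (w[-1] - w[-2]) > tol


def pairwise_auc(scores, labels) -> float:
    """Mann–Whitney AUC by exhaustive pair comparison (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mcc_formula(tp, tn, fp, fn) -> float:
    num = tp * tn - fp * fn
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    return 0.0 if den == 0 else num / den
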