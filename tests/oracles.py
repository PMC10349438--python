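"""Brute-force oracles, independent of the library code paths they check.

Shortest-path quantities are recomputed from first principles: distances by
min-plus matrix closure, shortest-path counts by dynamic programming over
the distance matrix, betweenness by the pair-dependency identity
sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t).  Wilcoxon
null distributions are fully enumerated.  HITS is checked against a dense
eigen-decomposition.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata

INF = math.inf


def _edge_costs(weights: np.ndarray, mode: str) -> np.ndarray:
    n = weights.shape[0]
    cost = np.full((n, n), INF)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                if mode == "unweighted":
                    cost[i, j] = 1.0
                elif mode == "weight_as_distance":
                    cost[i, j] = float(weights[i, j])
                else:  # inverse_weight
                    cost[i, j] = 1.0 / float(weights[i, j])
    return cost


def path_oracle(weights: np.ndarray, mode: str) -> dict:
    """Diameter, betweenness and closeness of a weighted digraph by brute force.

    ``weights`` is the dense weighted adjacency (0 = no edge).
    """
    n = weights.shape[0]
    cost = _edge_costs(weights, mode)
    # min-plus closure
    dist = np.full((n, n), INF)
    np.fill_diagonal(dist, 0.0)
    for _ in range(n):
        for s in range(n):
            for t in range(n):
                best = dist[s, t]
                for u in range(n):
                    cand = dist[s, u] + cost[u, t]
                    if cand < best:
                        best = cand
                dist[s, t] = best
    # shortest-path counts sigma[s, t]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(
            (t for t in range(n) if t != s and dist[s, t] < INF),
            key=lambda t: dist[s, t],
        )
        for t in order:
            total = 0.0
            for u in range(n):
                if cost[u, t] < INF and math.isclose(
                    dist[s, u] + cost[u, t], dist[s, t], rel_tol=0, abs_tol=1e-9
                ):
                    total += sigma[s, u]
            sigma[s, t] = total
    betweenness = np.zeros(n)
    for v in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or dist[s, t] == INF or sigma[s, t] == 0:
                    continue
                if math.isclose(
                    dist[s, v] + dist[v, t], dist[s, t], rel_tol=0, abs_tol=1e-9
                ):
                    acc += sigma[s, v] * sigma[v, t] / sigma[s, t]
        betweenness[v] = acc
    closeness = np.zeros(n)
    for v in range(n):
        total = sum(
            dist[v, u] if dist[v, u] < INF else float(n)
            for u in range(n)
            if u != v
        )
        closeness[v] = 1.0 / total if total > 0 else 0.0
    finite = dist[(dist < INF) & (dist > 0)]
    diameter = float(finite.max()) if finite.size else 0.0
    return {
        "diameter": diameter,
        "betweenness": betweenness,
        "closeness": closeness,
    }


def hits_eig_oracle(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hub/authority as dominant eigenvectors of A A^T and A^T A, max-normed.

    Only well-defined when the dominant eigenvalue is simple (use
    :func:`hits_spectral_gap` to filter degenerate draws, where the HITS
    fixed point depends on the starting vector).
    """

    def dominant(m: np.ndarray) -> np.ndarray:
        eigval, eigvec = np.linalg.eigh(m)
        v = np.abs(eigvec[:, np.argmax(eigval)])
        return v / v.max() if v.max() > 0 else v

    return dominant(weights @ weights.T), dominant(weights.T @ weights)


def hits_spectral_gap(weights: np.ndarray) -> float:
    """Relative gap between the two largest eigenvalues of A A^T."""
    eigval = np.sort(np.linalg.eigvalsh(weights @ weights.T))
    if eigval[-1] <= 0:
        return 0.0
    return float((eigval[-1] - eigval[-2]) / eigval[-1]) if len(eigval) > 1 else 1.0


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in product((0, 1), repeat=n)
        ]
    )
    p = 2 * min((dist <= w_obs + 1e-12).mean(), (dist >= w_obs - 1e-12).mean())
    return float(min(p, 1.0))


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    dist = np.array(
        [sum(ranks[i] for i in combo) for combo in combinations(range(len(pooled)), nx)]
    )
    p = 2 * min((dist <= w_obs + 1e-12).mean(), (dist >= w_obs - 1e-12).mean())
    return float(min(p, 1.0))
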