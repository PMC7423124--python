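"""Independent oracles used by the test suite.

Deliberately written from the definitions, in plain Python loops, sharing
no code with the package: a brute-force geNorm (pairwise log-ratio SDs,
M values, iterative exclusion, V series) and a numerical REML fit of the
heteroscedastic two-way model that NormFinder's moment estimator targets.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


# -- brute-force geNorm -------------------------------------------------------


def sd_n1(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def pairwise_v(q: dict[str, list[float]], j: str, k: str) -> float:
    a = [math.log2(x / y) for x, y in zip(q[j], q[k])]
    return sd_n1(a)


def m_value(q: dict[str, list[float]], j: str) -> float:
    others = [k for k in q if k != j]
    return sum(pairwise_v(q, j, k) for k in others) / len(others)


def genorm_ranking(q: dict[str, list[float]]):
    """(final_m, ranks) by iterative exclusion, lexicographic tie-break."""
    current = dict(q)
    final_m: dict[str, float] = {}
    ranks: dict[str, float] = {}
    while len(current) > 2:
        ms = {g: m_value(current, g) for g in current}
        worst_m = max(ms.values())
        worst = sorted(g for g, m in ms.items() if m == worst_m)[-1]
        final_m[worst] = ms[worst]
        ranks[worst] = float(len(current))
        del current[worst]
    g1, g2 = sorted(current)
    v = pairwise_v(current, g1, g2)
    for g in (g1, g2):
        final_m[g] = v
        ranks[g] = 1.5
    return final_m, ranks


def v_series(q: dict[str, list[float]], order: list[str]) -> dict[int, float]:
    """V(n/n+1) along a most-stable-first gene order."""
    n_samples = len(next(iter(q.values())))
    out = {}
    for n in range(2, len(order)):
        ratios = []
        for s in range(n_samples):
            nf_n = math.prod(q[g][s] for g in order[:n]) ** (1.0 / n)
            nf_n1 = math.prod(q[g][s] for g in order[: n + 1]) ** (1.0 / (n + 1))
            ratios.append(math.log2(nf_n / nf_n1))
        out[n] = sd_n1(ratios)
    return out


# -- REML oracle for the heteroscedastic two-way model ------------------------


def reml_gene_variances(y: np.ndarray) -> np.ndarray:
    """REML estimates of per-gene error variances in y_ij = a_i + b_j + e_ij.

    Maximises the error-contrast (REML) likelihood of the fixed-effects
    two-way layout with Var(e_ij) = sigma_i^2 by direct numerical
    optimisation over log-variances.
    """
    l, n = y.shape
    p = l + n - 1
    # design: gene dummies (l, reference-free) + sample dummies (n-1)
    x = np.zeros((l * n, p))
    yv = np.empty(l * n)
    for i in range(l):
        for j in range(n):
            r = i * n + j
            x[r, i] = 1.0
            if j > 0:
                x[r, l + j - 1] = 1.0
            yv[r] = y[i, j]

    def neg_reml(log_s2: np.ndarray) -> float:
        s2 = np.exp(log_s2)
        w = np.repeat(1.0 / s2, n)
        xtwx = x.T @ (x * w[:, None])
        xtwy = x.T @ (w * yv)
        sign, logdet = np.linalg.slogdet(xtwx)
        beta = np.linalg.solve(xtwx, xtwy)
        rss = float(w @ yv**2 - beta @ xtwy)
        return 0.5 * (n * float(np.sum(log_s2)) + logdet + rss)

    # start from the naive per-gene residual variances
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + y.mean()
    start = np.log(np.maximum((resid**2).mean(axis=1), 1e-6))
    res = minimize(neg_reml, start, method="L-BFGS-B")
    return np.exp(res.x)
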