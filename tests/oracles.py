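"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (math.comb / math.lgamma,
explicit enumeration, repeated deletion) so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math


def log_nb_pmf(k: int, mu: float, var: float) -> float:
    """log P(K = k) for an NB with mean mu and variance var (Poisson if var <= mu)."""
    if mu <= 0:
        return 0.0 if k == 0 else -math.inf
    if var <= mu * (1 + 1e-12):
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return (
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log1p(-p)
    )


def nb_exact_p_brute(k_a: int, k_b: int, mu_a: float, mu_b: float,
                     var_a: float, var_b: float) -> float:
    """Two-sided conditional p by full enumeration of every split of the total."""
    total = k_a + k_b
    if total == 0:
        return 1.0
    logp = [log_nb_pmf(a, mu_a, var_a) + log_nb_pmf(total - a, mu_b, var_b)
            for a in range(total + 1)]
    obs = logp[k_a]
    probs = [math.exp(x) for x in logp if x > -math.inf]
    kept = [math.exp(x) for x in logp if -math.inf < x <= obs + 1e-7]
    return min(sum(kept) / sum(probs), 1.0)


def binomial_two_sided_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p: total probability of outcomes no more
    likely than the observed one."""
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    return min(sum(q for q in pmf if q <= pmf[k] * (1 + 1e-9)), 1.0)


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, n_degs: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom by direct combinatorial summation."""
    denom = math.comb(universe, set_size)
    total = 0.0
    for k in range(overlap, min(set_size, n_degs) + 1):
        if set_size - k > universe - n_degs:
            continue
        total += math.comb(n_degs, k) * math.comb(universe - n_degs, set_size - k) / denom
    return min(total, 1.0)


def bh_brute(p_values) -> list[float]:
    """Benjamini-Hochberg by the literal min-over-suffix definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        # q_(i) = min over j >= i of p_(j) * m / j
        suffix = [
            p_values[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[i] = min(min(suffix), 1.0)
    return q


def kcore_brute(adjacency: dict) -> dict:
    """Core numbers by testing every k with repeated deletion.

    For each k, iteratively delete all nodes of degree < k until stable; a
    node's core number is the largest k at which it survives.
    """
    nodes = set(adjacency)
    core = {n: 0 for n in nodes}
    k = 1
    while True:
        survivors = set(nodes)
        changed = True
        while changed:
            changed = False
            for n in list(survivors):
                deg = len(adjacency[n] & survivors)
                if deg < k:
                    survivors.discard(n)
                    changed = True
        if not survivors:
            break
        for n in survivors:
            core[n] = k
        k += 1
    return core


def pearson_brute(x, y) -> float:
    """Product-moment correlation by the direct formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
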