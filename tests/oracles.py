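"""Independent brute-force / hand-calculation oracles used by the tests.

Everything here is deliberately naive (enumeration, closed forms, explicit
running sums) and shares no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def hypergeom_tail_exact(overlap: int, N: int, K: int, n: int) -> float:
    """P(X >= overlap) by exact rational enumeration."""
    total = Fraction(comb(N, n))
    p = Fraction(0)
    for k in range(overlap, min(K, n) + 1):
        p += Fraction(comb(K, k) * comb(N - K, n - k))
    return float(p / total)


def ranksum_perm_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    vals = np.array(a + b, dtype=float)
    n1, n = len(a), len(a) + len(b)

    def u_stat(x, y):
        return float(sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y))

    mu = n1 * (n - n1) / 2.0
    dev = abs(u_stat(a, b) - mu)
    cnt = tot = 0
    for idx in combinations(range(n), n1):
        ga = vals[list(idx)]
        gb = np.delete(vals, list(idx))
        tot += 1
        if abs(u_stat(ga, gb) - mu) >= dev - 1e-12:
            cnt += 1
    return cnt / tot


def welch_t_stat(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / len(x) + v2 / len(y)
    if se2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(se2))


def welch_perm_p_exact(values, n1: int) -> float:
    """Exact permutation p of |Welch t| over all distinct splits of one gene."""
    values = np.asarray(values, float)
    n = len(values)
    idx_obs = tuple(range(n1))
    t_obs = abs(welch_t_stat(values[list(idx_obs)], np.delete(values, list(idx_obs))))
    cnt = tot = 0
    for idx in combinations(range(n), n1):
        ga = values[list(idx)]
        gb = np.delete(values, list(idx))
        tot += 1
        if abs(welch_t_stat(ga, gb)) >= t_obs - 1e-12:
            cnt += 1
    return cnt / tot


def gsea_es_bruteforce(stats_by_gene: dict, gene_set, weight: float) -> float:
    """Signed max deviation of the weighted KS running sum, computed naively."""
    ordered = sorted(stats_by_gene.items(), key=lambda kv: (-kv[1], kv[0]))
    in_set = set(gene_set)
    hits = [(g, s) for g, s in ordered if g in in_set]
    n, nh = len(ordered), len(hits)
    if weight > 0:
        denom = sum(abs(s) ** weight for _, s in hits)
    else:
        denom = float(nh)
    if denom == 0:
        denom = float(nh)
        weight = 0
    run = 0.0
    best = 0.0
    for g, s in ordered:
        if g in in_set:
            run += (abs(s) ** weight if weight > 0 else 1.0) / denom
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def km_product_limit(times, events):
    """Hand product-limit estimator; returns {event_time: S(t)}."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def logrank_chi2_hand(times, events, groups):
    """Two-group log-rank: (O-E)^2 / V with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    gs = np.unique(groups)
    assert len(gs) == 2
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == gs[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == gs[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def logrank_perm_p(times, events, groups, n_perm: int, seed: int) -> float:
    """Monte-Carlo permutation p of the two-group log-rank statistic."""
    chi2_obs, _ = logrank_chi2_hand(times, events, groups)
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    cnt = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        chi2, _ = logrank_chi2_hand(times, events, perm)
        if chi2 >= chi2_obs - 1e-12:
            cnt += 1
    return (1 + cnt) / (1 + n_perm)


def chi2_hand(table) -> tuple[float, int]:
    """Pearson chi-square Sum (O-E)^2 / E and df for a contingency table."""
    T = np.asarray(table, float)
    row = T.sum(axis=1, keepdims=True)
    col = T.sum(axis=0, keepdims=True)
    E = row @ col / T.sum()
    chi2 = float(((T - E) ** 2 / E).sum())
    return chi2, (T.shape[0] - 1) * (T.shape[1] - 1)


def consensus_bruteforce(D, k, n_resamples, subsample_frac, seed):
    """Replay of the consensus co-clustering indicators with scipy primitives.

    Replays exactly the resample stream the implementation documents: one
    ``choice`` draw per resample from ``default_rng(seed)``.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = D.shape[0]
    m = int(np.ceil(subsample_frac * n))
    rng = np.random.default_rng(seed)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = D[np.ix_(idx, idx)]
        lab = fcluster(linkage(squareform(sub, checks=False), "average"),
                       t=k, criterion="maxclust")
        for i_pos, i in enumerate(idx):
            for j_pos, j in enumerate(idx):
                den[i, j] += 1
                if lab[i_pos] == lab[j_pos]:
                    num[i, j] += 1
    with np.errstate(invalid="ignore"):
        c = num / den
    np.fill_diagonal(c, 1.0)
    return c
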