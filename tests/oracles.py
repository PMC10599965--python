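"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively in pure Python (loops, sorting, pairwise
comparison) and shares no code with the package.  Tie conventions match the
documented contracts: average ranks for tied values, and lowest-gene-index
ordering where a total order of genes is needed (ssGSEA / RBO walks).
"""

from __future__ import annotations

import math


def naive_rank(values):
    """Ascending ranks with average tie handling, by direct counting."""
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2)
    assert abs(sum(ranks) - n * (n + 1) / 2) < 1e-9
    return ranks


def naive_summed_up(values, up, dn=()):
    r = naive_rank(values)
    return sum(r[i] for i in up) - sum(r[i] for i in dn)


def naive_average(values, up, dn=()):
    s = sum(values[i] for i in up) / len(up) if up else 0.0
    if dn:
        s -= sum(values[i] for i in dn) / len(dn)
    return s


def _median(xs):
    xs = sorted(xs)
    m = len(xs) // 2
    return xs[m] if len(xs) % 2 else (xs[m - 1] + xs[m]) / 2


def naive_median(values, up, dn=()):
    s = _median([values[i] for i in up]) if up else 0.0
    if dn:
        s -= _median([values[i] for i in dn])
    return s


def naive_mean_z(values, up, dn, gene_mean, gene_sd):
    terms = []
    for idx, sign in ((up, 1.0), (dn, -1.0)):
        keep = [i for i in idx if gene_sd[i] > 0]
        if keep:
            terms.append(
                sign * sum((values[i] - gene_mean[i]) / gene_sd[i] for i in keep) / len(keep)
            )
    return sum(terms) if terms else float("nan")


def naive_overlap(values, members, threshold=0.0, as_fraction=False):
    c = sum(1 for i in members if values[i] > threshold)
    return c / len(members) if as_fraction else float(c)


def naive_singscore(values, up, dn=()):
    """Normalized mean-rank score built directly from the extremes formula."""
    n_genes = len(values)

    def direction(idx, ranks):
        n = len(idx)
        if n == n_genes:  # degenerate: extremes coincide, contract says 0
            return 0.5
        mean_rank = sum(ranks[i] for i in idx) / n
        lo = (n + 1) / 2
        hi = n_genes - (n - 1) / 2
        return (mean_rank - lo) / (hi - lo)

    total = 0.0
    if up:
        total += direction(up, naive_rank(values)) - 0.5
    if dn:
        total += direction(dn, naive_rank([-v for v in values])) - 0.5
    return total


def desc_order(values):
    """Decreasing-expression order, ties toward the lower gene index."""
    return [i for _, i in sorted(((-v, i) for i, v in enumerate(values)))]


def naive_ssgsea_one(values, idx, alpha):
    """Integrated running sum walked position by position."""
    n_genes = len(values)
    n = len(idx)
    if n == 0 or n == n_genes:
        return float("nan")
    order = desc_order(values)
    in_set = [i in set(idx) for i in order]
    weights = [(n_genes - pos) ** alpha for pos in range(n_genes)]  # |N - pos + 1|^alpha
    denom = sum(w for w, h in zip(weights, in_set) if h)
    running, total = 0.0, 0.0
    for pos in range(n_genes):
        if in_set[pos]:
            running += weights[pos] / denom
        else:
            running -= 1 / (n_genes - n)
        total += running
    return total


def naive_ssgsea(values, up, dn=(), alpha=0.75):
    if up and dn:
        return naive_ssgsea_one(values, up, alpha) - naive_ssgsea_one(values, dn, alpha)
    if up:
        return naive_ssgsea_one(values, up, alpha)
    return -naive_ssgsea_one(values, dn, alpha)


def naive_rbo_one(values, idx, p, depth):
    order = desc_order(values)
    d_max = min(depth if depth is not None else len(idx), len(values))
    target = set(idx)
    num, den = 0.0, 0.0
    for d in range(1, d_max + 1):
        agreement = len(set(order[:d]) & target) / d
        num += p ** (d - 1) * agreement
        den += p ** (d - 1)
    return num / den


def naive_rbo(values, up, dn=(), p=0.9, depth=None):
    s = 0.0
    if up:
        s += naive_rbo_one(values, up, p, depth)
    if dn:
        s -= naive_rbo_one(values, dn, p, depth)
    return s


def naive_auc(scores, labels):
    """Exhaustive pairwise comparison of every (positive, negative) pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        return 0.5
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp in pos for sn in neg)
    return wins / (len(pos) * len(neg))


def naive_knn(points, K):
    """All-pairs nearest neighbors, ties toward the lower index."""
    n = len(points)
    out = []
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(points[i], points[j])))
            dists.append((d, j))
        dists.sort()
        out.append(dists[: min(K, n - 1)])
    return out
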