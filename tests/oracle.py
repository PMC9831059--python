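"""Independent brute-force re-implementations used as test oracles.

Everything here is written with plain Python loops, directly from the metric
definitions, and deliberately shares no code with the package.
"""

import math


def crossings(Ia, Ib):
    """List of (interval, support) for two courses given as T lists of R lists."""
    T = len(Ia)
    R = len(Ia[0])
    out = []
    for s in range(T - 1):
        n = 0
        for r in range(R):
            d0 = Ia[s][r] - Ib[s][r]
            d1 = Ia[s + 1][r] - Ib[s + 1][r]
            sign0 = (d0 > 0) - (d0 < 0)
            sign1 = (d1 > 0) - (d1 < 0)
            crossed = sign0 * sign1 < 0
            crossed = crossed or (sign1 == 0 and sign0 != 0)
            if s == 0:
                crossed = crossed or (sign0 == 0 and sign1 != 0)
            if crossed:
                n += 1
        out.append((s, n / R))
    return out


def switch_points(Ia, Ib, min_support):
    return [(s, sup) for s, sup in crossings(Ia, Ib) if sup >= min_support]


def interval_bounds(s, qualifying, T):
    prev = -1
    for q in qualifying:
        if q < s and q > prev:
            prev = q
    nxt = T - 1
    for q in sorted(qualifying, reverse=True):
        if q > s and q < nxt:
            nxt = q
    return list(range(prev + 1, s + 1)), list(range(s + 1, nxt + 1))


def switch_probability(Ia, Ib, T1, T2):
    """Ia is the pre-switch dominant isoform's course (T lists of R lists)."""
    pre = [Ia[t][r] > Ib[t][r] for t in T1 for r in range(len(Ia[0]))]
    post = [Ia[t][r] < Ib[t][r] for t in T2 for r in range(len(Ia[0]))]
    return (sum(pre) / len(pre) + sum(post) / len(post)) / 2


def diff_abundance(Ia, Ib, s):
    R = len(Ia[0])
    da = abs(sum(Ia[s + 1]) / R - sum(Ia[s]) / R)
    db = abs(sum(Ib[s + 1]) / R - sum(Ib[s]) / R)
    return (da + db) / 2


def event_importance(Ia, Ib, all_isoforms, s):
    """all_isoforms: list of courses (each T lists of R lists) incl. a and b."""
    R = len(Ia[0])
    total = 0.0
    for r in range(R):
        m0 = max(course[s][r] for course in all_isoforms)
        m1 = max(course[s + 1][r] for course in all_isoforms)
        total += (Ia[s][r] / m0 + Ia[s + 1][r] / m1 + Ib[s][r] / m0 + Ib[s + 1][r] / m1) / 4
    return total / R


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def dissimilarity(Ia, Ib):
    R = len(Ia[0])
    x = [sum(v) / R for v in Ia]
    y = [sum(v) / R for v in Ib]
    return 1 - pearson(x, y) ** 2


def total_usage_change(isoform_courses):
    """Courses are per-isoform T lists of R lists of raw expression."""
    T = len(isoform_courses[0])
    R = len(isoform_courses[0][0])
    # fractions are computed per replicate first, then averaged over replicates
    fractions = []
    for t in range(T):
        per_iso = []
        for i, course in enumerate(isoform_courses):
            vals = []
            for r in range(R):
                tot = sum(c[t][r] for c in isoform_courses)
                vals.append(course[t][r] / tot if tot > 0 else 0.0)
            per_iso.append(sum(vals) / R)
        fractions.append(per_iso)
    return [
        sum(abs(fractions[t + 1][i] - fractions[t][i]) for i in range(len(isoform_courses)))
        for t in range(T - 1)
    ]


def bh(pvalues):
    m = len(pvalues)
    indexed = sorted(enumerate(pvalues), key=lambda kv: kv[1])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        running = min(running, p * m / rank)
        adj[idx] = running
    return adj
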