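"""Independent brute-force reference implementations for the test suite.

These deliberately avoid the library's code paths and scipy's correlation
routines: plain-Python loops, the textbook sum formula for the product-
moment coefficient, and the two-sided t-test assembled by hand.  They are
slow and only meant for tiny instances.
"""

import math

from scipy.stats import t as t_dist


def pearson_oracle(x, y):
    """Product-moment coefficient by the sum formula, p by the t-test."""
    n = len(x)
    assert n == len(y) and n >= 3
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    if dx == 0 or dy == 0:
        return None, None
    r = num / math.sqrt(dx * dy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * t_dist.sf(abs(t), n - 2)


def rank_oracle(v):
    """Average ranks (1-based) with ties shared."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def window_oracle(sort_values, alpha, beta):
    """Positional indices of the rank window, by explicit enumeration."""
    m = len(sort_values)
    order = sorted(range(m), key=lambda i: (sort_values[i], i))
    lo = max(int(math.floor((alpha - beta) * m + 0.5)), 1)
    hi = min(int(math.floor((alpha + beta) * m + 0.5)), m)
    return sorted(order[lo - 1 : hi])


def grid_oracle(r):
    """(alpha, beta) grid by double loop, apex appended."""
    pts = []
    for j in range(1, r // 2 + 1):
        beta = j / r
        alpha = beta
        while alpha <= 1 - beta + 1e-12:
            pts.append((round(alpha, 12), round(beta, 12)))
            alpha += 1 / r
    pts.append((0.5, 0.5))
    return pts


def surface_oracle(frame, pair, sorter, resolution, min_n=3):
    """Cell-by-cell surface: sort, slice, sum-formula coefficient, t-test.

    Returns {(alpha, beta): (n, r, p)} with r/p None for invalid cells.
    """
    sort_values = list(frame[sorter])
    xs = list(frame[pair[0]])
    ys = list(frame[pair[1]])
    out = {}
    for alpha, beta in grid_oracle(resolution):
        idx = window_oracle(sort_values, alpha, beta)
        if len(idx) < min_n:
            out[(alpha, beta)] = (len(idx), None, None)
            continue
        r, p = pearson_oracle([xs[i] for i in idx], [ys[i] for i in idx])
        out[(alpha, beta)] = (len(idx), r, p)
    return out
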