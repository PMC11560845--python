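"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths: exact rational
arithmetic for the recursion, full enumeration for the signed-rank test,
and a from-scratch rank computation for Spearman correlation.
"""

from decimal import Decimal, getcontext
from fractions import Fraction
from itertools import product


def iterate_highprec(p_init, g, e, p0, n_rounds, precision=50):
    """Recursion re-implemented with 50-digit decimal arithmetic."""
    getcontext().prec = precision
    p = Decimal(p_init)
    g, e, p0 = Decimal(g), Decimal(e), Decimal(p0)
    one = Decimal(1)
    values = [p]
    for _ in range(n_rounds):
        denominator = p * g + (one - p) * e
        p = (p * g * p0) / denominator if denominator != 0 else Decimal(0)
        values.append(p)
    return [float(v) for v in values]


def step_exact(p, g, e, p0):
    """One recursion round in exact rational arithmetic.

    Floats convert to Fraction exactly, so this reproduces the printed
    formula with no rounding at all.
    """
    p, g, e, p0 = (Fraction(v) for v in (p, g, e, p0))
    denominator = p * g + (1 - p) * e
    if denominator == 0:
        return Fraction(0)
    return (p * g * p0) / denominator


def iterate_exact(p_init, g, e, p0, n_rounds):
    """Repeated exact application of the recursion; returns n_rounds+1 values."""
    p = Fraction(p_init)
    values = [p]
    for _ in range(n_rounds):
        p = step_exact(p, g, e, p0)
        values.append(p)
    return values


def washout_exact(p_init, g, e, p0, threshold, max_rounds=100_000):
    """First round with p < threshold by exact iteration, or None."""
    threshold = Fraction(threshold)
    p = Fraction(p_init)
    for x in range(max_rounds + 1):
        if p < threshold:
            return x
        p = step_exact(p, g, e, p0)
    return None


def wilcoxon_enumerate(differences):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Returns (w_positive, p_two_sided). Zero differences must already be
    removed. Uses midranks for tied absolute differences.
    """
    d = [x for x in differences if x != 0]
    n = len(d)
    abs_d = [abs(x) for x in d]
    ranks = _midranks(abs_d)
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    all_w = []
    for signs in product((0, 1), repeat=n):
        all_w.append(sum(r for r, s in zip(ranks, signs) if s))
    n_total = len(all_w)
    p_le = sum(1 for w in all_w if w <= w_obs + 1e-12) / n_total
    p_ge = sum(1 for w in all_w if w >= w_obs - 1e-12) / n_total
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """Spearman rho as the Pearson correlation of midranks, from scratch."""
    rx = _midranks(list(x))
    ry = _midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
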