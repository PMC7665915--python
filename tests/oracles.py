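"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — explicit loops, exact integer
combinatorics — and shares no code with the package.
"""

from __future__ import annotations

from math import comb


def brute_force_pair_rules(transactions, min_support, min_confidence, min_lift):
    """All ordered pair rules by scanning every transaction per pair.

    Returns {(antecedent, consequent): (support, confidence, lift)} with the
    same metric conventions as the package (percent support/confidence).
    """
    transactions = [set(t) for t in transactions]
    n = len(transactions)
    items = sorted({i for t in transactions for i in t})
    out = {}
    for a in items:
        for b in items:
            if a == b:
                continue
            n_a = sum(1 for t in transactions if a in t)
            n_b = sum(1 for t in transactions if b in t)
            n_ab = sum(1 for t in transactions if a in t and b in t)
            if n_ab == 0:
                continue
            supp = 100.0 * n_ab / n
            conf = 100.0 * n_ab / n_a
            lift = (n_ab * n) / (n_a * n_b)
            if supp >= min_support and conf >= min_confidence and lift >= min_lift:
                out[(a, b)] = (supp, conf, lift)
    return out


def chi_square_bruteforce(table):
    """Pearson chi-square by explicit observed/expected loops."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat


def hypergeom_tail_enumeration(N, K, n, k):
    """P(X >= k) by summing exact binomial coefficients."""
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return numerator / comb(N, n)


def bh_stepup_bruteforce(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted
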