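"""Independent reference implementations used only as test oracles.

Deliberately written with different mechanics than the package (dense dict
distributions computed top-down; exact rational arithmetic for the Fisher
test) so agreement is informative.
"""

import math
from fractions import Fraction
from itertools import product


def _level_counts(seqs, order):
    d = {}
    for seq in seqs:
        for m in range(order, len(seq)):
            ctx = tuple(seq[m - order : m])
            d.setdefault(ctx, {})
            d[ctx][seq[m]] = d[ctx].get(seq[m], 0) + 1
    return d


def wb_distribution(seqs, order, context, vocab):
    """Witten-Bell discounted, Katz-backoff conditional distribution.

    Counts every model order directly from the sequences; redistributes the
    reserved mass T/(N+T) over unseen continuations proportionally to the
    next-shorter context's distribution, ending in a uniform terminal.
    """
    vocab = sorted(vocab)
    if order < 0:
        return {v: 1.0 / len(vocab) for v in vocab}
    ctx = tuple(context)[-order:] if order else ()
    table = _level_counts(seqs, order).get(ctx)
    lower = wb_distribution(seqs, order - 1, ctx[1:], vocab)
    if not table:
        return lower
    n = sum(table.values())
    t = len(table)
    if t == len(vocab):
        return {v: table.get(v, 0) / n for v in vocab}
    unseen_lower = sum(p for v, p in lower.items() if v not in table)
    out = {}
    for v in vocab:
        if v in table:
            out[v] = table[v] / (n + t)
        else:
            out[v] = (t / (n + t)) * lower[v] / unseen_lower
    return out


def fisher_2xc_oracle(table) -> float:
    """Exact two-sided p-value for a 2xC table by full enumeration with
    rational arithmetic (tables as or less probable than the observed one)."""
    rows = [list(map(int, r)) for r in table]
    cols = [a + b for a, b in zip(rows[0], rows[1])]
    keep = [j for j, c in enumerate(cols) if c > 0]
    cols = [cols[j] for j in keep]
    top = [rows[0][j] for j in keep]
    n = sum(cols)
    r = sum(top)
    if len(cols) <= 1 or r == 0 or r == n:
        return 1.0

    def weight(alloc):
        out = 1
        for cj, aj in zip(cols, alloc):
            out *= math.comb(cj, aj)
        return out

    w_obs = weight(top)
    total = 0
    for alloc in product(*(range(c + 1) for c in cols)):
        if sum(alloc) == r and weight(alloc) <= w_obs:
            total += weight(alloc)
    return float(Fraction(total, math.comb(n, r)))
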