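"""Fisher's-exact screens for higher-order sequential dependencies.

A first-order process fixes the next-phrase distribution given the ultimate
phrase type; a second-order process lets it vary with the penultimate type as
well.  The screen therefore asks, for each phrase type (order 2) or observed
bigram (order 3), whether the next-phrase distributions conditioned on the
two best-sampled extended contexts differ: the two contexts sharing the
suffix but differing in the added preceding type, chosen as the two with the
most observations.  Each comparison is a 2×C contingency table tested with a
Fisher-Freeman-Halton exact test, falling back to a chi-square test of
independence when the exact enumeration exceeds a configurable work bound.
Significance is controlled per individual with a Bonferroni threshold
0.05/n over the n comparisons performed at that order.

Targets with only a single observed extended context cannot be compared and
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma

import numpy as np
from scipy import stats

from .corpus import Corpus
from .markov import CountModel, fit_counts
from .simulate import simulate_corpus

ALPHA = 0.05


class ExactWorkExceeded(Exception):
    """The exact enumeration would exceed the configured work bound."""


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_2xc(
    table: np.ndarray,
    max_total: int = 500,
    max_cols: int = 12,
    max_work: int = 2_000_000,
) -> float:
    """Two-sided exact p-value for independence in a 2×C table.

    With margins fixed, the top-row allocation follows a multivariate
    hypergeometric law whose table probability is proportional to
    W = Π_j C(col_j, a_j); the p-value is the total probability of tables
    with W ≤ W_observed (tolerance 1e-9 on log W, so ties count as extreme).
    Enumeration is depth-first over columns with feasibility pruning;
    :class:`ExactWorkExceeded` is raised when the table is too large
    (total count, column count, or visited-node budget), signalling the
    caller to fall back to a chi-square test.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise ValueError("table must have exactly 2 rows")
    cols = table.sum(axis=0)
    keep = cols > 0
    table, cols = table[:, keep], cols[keep]
    ncols = table.shape[1]
    n = int(table.sum())
    r = int(table[0].sum())
    if ncols <= 1 or r == 0 or r == n:
        return 1.0
    if n > max_total or ncols > max_cols:
        raise ExactWorkExceeded(f"table too large for exact test (n={n}, C={ncols})")

    order = np.argsort(cols)[::-1]  # big columns first tightens the bounds
    cols = cols[order].tolist()
    obs = table[0, order].tolist()
    log_w_obs = sum(_log_binom(c, a) for c, a in zip(cols, obs))
    suffix_cap = [0] * (ncols + 1)
    for j in range(ncols - 1, -1, -1):
        suffix_cap[j] = suffix_cap[j + 1] + cols[j]
    log_denom = _log_binom(n, r)
    threshold = log_w_obs + 1e-9
    work = 0
    p = 0.0

    def visit(j: int, rrem: int, log_w: float) -> None:
        nonlocal work, p
        work += 1
        if work > max_work:
            raise ExactWorkExceeded("exact enumeration exceeded the work budget")
        if j == ncols:
            if log_w <= threshold:
                p += exp(log_w - log_denom)
            return
        lo = max(0, rrem - suffix_cap[j + 1])
        hi = min(cols[j], rrem)
        for a in range(lo, hi + 1):
            visit(j + 1, rrem - a, log_w + _log_binom(cols[j], a))

    visit(0, r, 0.0)
    return min(p, 1.0)


@dataclass
class DependencyTestResult:
    """Outcome of one extended-context comparison."""

    target_context: tuple[str, ...]
    compared_contexts: tuple[tuple[str, ...], tuple[str, ...]]
    columns: tuple[str, ...]
    contingency: np.ndarray
    test_used: str  # "fisher" or "chi-square"
    p_value: float
    n_comparisons: int = 0  # filled once all tests for the order are done
    significant_at_05: bool = False
    significant_bonferroni: bool = False

    @property
    def row_totals(self) -> tuple[int, int]:
        return tuple(int(x) for x in self.contingency.sum(axis=1))


def _run_one(
    contexts: list[tuple[tuple[str, ...], dict]],
    exact_kwargs: dict,
) -> tuple[str, float, tuple, np.ndarray]:
    (c1, nc1), (c2, nc2) = contexts
    columns = tuple(sorted(set(nc1) | set(nc2)))
    table = np.array(
        [[nc1.get(x, 0) for x in columns], [nc2.get(x, 0) for x in columns]],
        dtype=np.int64,
    )
    try:
        return "fisher", fisher_exact_2xc(table, **exact_kwargs), columns, table
    except ExactWorkExceeded:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return "chi-square", float(p), columns, table


def higher_order_tests(
    corpus: Corpus,
    order: int,
    min_context_n: int = 0,
    counts: CountModel | None = None,
    **exact_kwargs,
) -> list[DependencyTestResult]:
    """Screen for order-``order`` dependencies (2 or 3) in a corpus.

    ``min_context_n`` optionally drops poorly sampled extended contexts
    before choosing the two largest (no minimum is imposed by default).
    Results carry the per-order comparison count and both significance
    flags (raw 0.05 and Bonferroni 0.05/n).
    """
    if order not in (2, 3):
        raise ValueError("dependency screens are defined for orders 2 and 3")
    if counts is None:
        counts = fit_counts(corpus, order)
    by_target: dict[tuple[str, ...], list] = {}
    for ctx, nc in counts.context_counts.items():
        if sum(nc.values()) >= min_context_n:
            by_target.setdefault(ctx[1:], []).append((ctx, nc))
    results = []
    for target in sorted(by_target):
        group = by_target[target]
        if len(group) < 2:
            continue  # single extended context: comparison unfeasible
        group.sort(key=lambda it: (-sum(it[1].values()), it[0]))
        top_two = group[:2]
        test_used, p, columns, table = _run_one(top_two, exact_kwargs)
        results.append(
            DependencyTestResult(
                target_context=target,
                compared_contexts=(top_two[0][0], top_two[1][0]),
                columns=columns,
                contingency=table,
                test_used=test_used,
                p_value=p,
            )
        )
    n = len(results)
    for res in results:
        res.n_comparisons = n
        res.significant_at_05 = res.p_value < ALPHA
        res.significant_bonferroni = n > 0 and res.p_value < ALPHA / n
    return results


def null_calibration(
    corpus: Corpus, order: int, seed: int, **kwargs
) -> list[DependencyTestResult]:
    """Run the order-``order`` screen on a corpus simulated from a lower-order
    model fitted to the complete corpus.

    The generator order is ``order - 1`` (a first-order generator for the
    second-order screen, second-order for the third-order screen), so any
    Bonferroni-significant result on the simulate is a false positive; none
    are expected.
    """
    generator = fit_counts(corpus, order - 1)
    simulated = simulate_corpus(generator, corpus, seed)
    return higher_order_tests(simulated, order, **kwargs)


def summarize_tests(results_by_individual: dict) -> "pd.DataFrame":
    """Count-table summary, one row per individual × order.

    ``results_by_individual`` maps individual -> {order: [results]}.
    Columns: individual, order, n_comparisons, n_sig_05, n_sig_bonferroni.
    """
    import pandas as pd

    rows = []
    for ind in sorted(results_by_individual):
        for order in sorted(results_by_individual[ind]):
            res = results_by_individual[ind][order]
            rows.append(
                {
                    "individual": ind,
                    "order": order,
                    "n_comparisons": len(res),
                    "n_sig_05": sum(r.significant_at_05 for r in res),
                    "n_sig_bonferroni": sum(r.significant_bonferroni for r in res),
                }
            )
    return pd.DataFrame(rows)
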