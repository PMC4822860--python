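import numpy as np
import pytest
from scipy import stats

from vireosyntax.dependencies import (
    ExactWorkExceeded,
    fisher_exact_2xc,
    higher_order_tests,
    null_calibration,
    summarize_tests,
)
from vireosyntax.synthetic import GroundTruthModel, GroundTruthSpec

from oracles import fisher_2xc_oracle


def test_hand_hypergeometric_example():
    """Rows {x:3, y:0} vs {x:0, y:3}: p = 2*C(3,3)*C(3,0)/C(6,3) = 0.1."""
    assert fisher_exact_2xc(np.array([[3, 0], [0, 3]])) == pytest.approx(0.1, abs=1e-12)


def test_identical_rows_give_p_one():
    assert fisher_exact_2xc(np.array([[2, 3, 1], [2, 3, 1]])) == pytest.approx(1.0)


def test_degenerate_tables():
    assert fisher_exact_2xc(np.array([[5], [3]])) == 1.0  # single column
    assert fisher_exact_2xc(np.array([[4, 2], [0, 0]])) == 1.0  # empty row


def test_2x2_matches_scipy():
    rng = np.random.default_rng(0)
    for _ in range(50):
        table = rng.integers(0, 15, size=(2, 2))
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            continue
        ours = fisher_exact_2xc(table)
        _, ref = stats.fisher_exact(table, alternative="two-sided")
        assert ours == pytest.approx(ref, abs=1e-12)


def test_2xc_matches_exact_rational_oracle():
    rng = np.random.default_rng(1)
    for ncols in (3, 4, 5):
        for _ in range(15):
            table = rng.integers(0, 7, size=(2, ncols))
            if table.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_2xc(table)
            ref = fisher_2xc_oracle(table)
            assert ours == pytest.approx(ref, abs=1e-12)


def test_work_bounds_raise():
    big = np.full((2, 6), 100)
    with pytest.raises(ExactWorkExceeded):
        fisher_exact_2xc(big)  # total > 500
    wide = np.ones((2, 13), dtype=int)
    with pytest.raises(ExactWorkExceeded):
        fisher_exact_2xc(wide)  # too many columns


def test_chi_square_fallback_agrees_with_exact_on_large_counts():
    """On well-filled 2x3 tables the fallback and the exact engine agree in
    their alpha=0.05 rejection decision at least 95% of the time."""
    rng = np.random.default_rng(2)
    agree = total = 0
    while total < 200:
        table = rng.poisson(20, size=(2, 3)) + 10
        p_exact = fisher_exact_2xc(table, max_total=10_000)
        _, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
        agree += (p_exact < 0.05) == (p_chi < 0.05)
        total += 1
    assert agree / total >= 0.95


def test_screen_picks_two_largest_contexts_and_skips_singletons(mk):
    corpus = mk(
        [
            # ultimate 'b' follows both 'a' and 'c' (comparable);
            # ultimate 'z' only ever follows 'q' (must be skipped)
            list("abxabxabycby") + list("qzr") * 3,
        ]
    )
    results = higher_order_tests(corpus, 2)
    targets = {r.target_context for r in results}
    assert ("z",) not in targets
    for r in results:
        assert r.compared_contexts[0] != r.compared_contexts[1]
        assert r.contingency.shape[0] == 2
        assert r.n_comparisons == len(results)
        # compared contexts are the two best-sampled for the target
        assert r.row_totals[0] >= r.row_totals[1]
        if r.significant_bonferroni:
            assert r.significant_at_05


def test_min_context_n_filters(mk):
    corpus = mk([list("abxabxabyczcby" * 3)])
    all_results = higher_order_tests(corpus, 2)
    filtered = higher_order_tests(corpus, 2, min_context_n=3)
    assert len(filtered) <= len(all_results)


def test_order_validation(mk):
    with pytest.raises(ValueError):
        higher_order_tests(mk([list("abab")]), 1)


def test_planted_second_order_structure_detected():
    """The default truth plants L1-separated second-order contrasts; the
    screen must find Bonferroni-significant dependencies."""
    spec = GroundTruthSpec(recording_lengths=(2000,) * 10, seed=3)
    model = GroundTruthModel(spec, seed=78)
    corpus = model.generate_corpus(list(spec.recording_lengths), 89, "POW")
    results = higher_order_tests(corpus, 2)
    assert sum(r.significant_bonferroni for r in results) >= 1
    assert len(results) <= len(corpus.vocabulary)


def test_first_order_null_shows_no_bonferroni_hits():
    """A single first-order corpus screened at order 2 (and its simulated
    null twin) yields no Bonferroni-significant dependencies."""
    spec = GroundTruthSpec(
        recording_lengths=(2000,) * 10, frac_second_order=0.0, seed=3
    )
    model = GroundTruthModel(spec, seed=77)
    corpus = model.generate_corpus(list(spec.recording_lengths), 88, "NUL")
    direct = higher_order_tests(corpus, 2)
    assert sum(r.significant_bonferroni for r in direct) == 0
    null = null_calibration(corpus, 2, seed=4)
    assert sum(r.significant_bonferroni for r in null) == 0


def test_summary_table_schema(mk):
    corpus = mk([list("abxabxabycz" * 5)])
    res = {"T": {2: higher_order_tests(corpus, 2)}}
    tab = summarize_tests(res)
    assert list(tab.columns) == [
        "individual",
        "order",
        "n_comparisons",
        "n_sig_05",
        "n_sig_bonferroni",
    ]
    assert (tab.n_sig_bonferroni <= tab.n_sig_05).all()
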