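import math

import numpy as np
import pytest

from vireosyntax.corpus import train_test_split
from vireosyntax.selection import (
    InterpolatedModel,
    classify_states,
    evaluate_all,
    forward_selection,
    sequence_nll,
)
from vireosyntax.smoothing import SmoothedModel
from vireosyntax.synthetic import GroundTruthModel, GroundTruthSpec


def test_uniform_zero_order_nll_is_log_vocab(mk):
    """Equal phrase-type frequencies with full coverage give exactly ln C."""
    corpus = mk([list("abcd" * 10)])
    sm = SmoothedModel.from_corpus(corpus, 0)
    assert sequence_nll(sm, corpus) == pytest.approx(math.log(4), abs=1e-12)


def test_near_deterministic_chain_nll_small(mk):
    corpus = mk([list("ab" * 50)])
    sm = SmoothedModel.from_corpus(corpus, 1)
    assert sequence_nll(sm, corpus) < 0.2


def test_first_two_phrases_excluded(mk):
    """Recordings of length <= 2 contribute no scored positions."""
    sm = SmoothedModel.from_corpus(mk([list("abab")]), 0)
    with pytest.raises(ValueError):
        sequence_nll(sm, mk([["a", "b"], ["a"]]))
    # a 3-phrase recording scores exactly one position
    corpus3 = mk([list("aba")])
    sm3 = SmoothedModel.from_corpus(corpus3, 0)
    val = sequence_nll(sm3, corpus3)
    assert val == pytest.approx(-math.log(sm3.prob((), "a")), abs=1e-12)


def test_interpolated_model_dispatch_and_normalization(mk):
    corpus = mk([list("abacabbacba" * 3)])
    sm = [SmoothedModel.from_corpus(corpus, k) for k in range(3)]
    model = InterpolatedModel(*sm, {"a", "b"}, {("c", "a")})
    # deepest match wins
    assert model.prob(("c", "a"), "b") == sm[2].prob(("c", "a"), "b")
    assert model.prob(("b", "a"), "b") == sm[1].prob(("a",), "b")
    assert model.prob(("a", "c"), "b") == sm[0].prob((), "b")
    for ctx in [("c", "a"), ("b", "a"), ("a", "c")]:
        total = sum(model.prob(ctx, v) for v in sm[0].vocabulary)
        assert total == pytest.approx(1.0, abs=1e-9)


def test_second_order_state_requires_parent():
    with pytest.raises(ValueError, match="parent"):
        InterpolatedModel(None, None, None, {"a"}, {("a", "b")})


def test_greedy_first_step_matches_exhaustive_search(mk):
    """The first selected state equals the argmin over all single-state
    models of the smoothed training NLL."""
    train = mk([list("abacabbacbaabcabca")])
    test = mk([list("bacabbacab")])
    vocab = train.vocabulary | test.vocabulary
    _model, trace = forward_selection(train, test, vocab)
    sms = [SmoothedModel.from_corpus(train, k, vocab) for k in range(3)]
    candidates = {
        (j,): sequence_nll(InterpolatedModel(*sms, {j}, set()), train)
        for (j,) in sms[1].base.contexts()
    }
    best = min(candidates, key=lambda k: (candidates[k], k))
    assert trace.states[1] == best
    assert trace.train_nll[1] == pytest.approx(candidates[best], abs=1e-12)


def test_trace_properties_and_argmin_model(big_truth):
    model, corpus = big_truth
    split = train_test_split(corpus)
    train, test = split.apply(corpus)
    interp, trace = forward_selection(train, test)
    diffs = np.diff(trace.train_nll)
    # training NLL is non-increasing through (and past) the selected step;
    # the forced tail of negative-gain additions may rise
    assert (diffs[: trace.chosen_step] <= 1e-9).all()
    # the returned model sits at the test-NLL minimum of the whole trace
    assert trace.test_nll[trace.chosen_step] == min(trace.test_nll)
    assert trace.test_nll[trace.chosen_step] <= trace.test_nll[0]
    assert trace.test_nll[trace.chosen_step] <= trace.test_nll[-1]
    # trace NLLs are the real scores of the reconstructed model
    assert sequence_nll(interp, test) == pytest.approx(
        trace.test_nll[trace.chosen_step], abs=1e-9
    )
    frame = trace.to_frame()
    assert frame.chosen.sum() == 1


def test_classify_states_trivial_cases():
    vocab = {"a", "b", "c", "d"}
    empty = InterpolatedModel.__new__(InterpolatedModel)
    empty.included_first = frozenset()
    empty.included_second = frozenset()
    assert classify_states(empty, vocab) == (1.0, 0.0, 0.0)
    allfirst = InterpolatedModel.__new__(InterpolatedModel)
    allfirst.included_first = frozenset(vocab)
    allfirst.included_second = frozenset()
    assert classify_states(allfirst, vocab) == (0.0, 1.0, 0.0)
    mixed = InterpolatedModel.__new__(InterpolatedModel)
    mixed.included_first = frozenset({"a", "b"})
    mixed.included_second = frozenset({("c", "b")})
    assert classify_states(mixed, vocab) == (0.5, 0.25, 0.25)


def test_zero_order_truth_yields_no_spurious_gain():
    """On data with no sequential structure the selected model's test NLL
    sits within 0.02 of the zero-order model's."""
    spec = GroundTruthSpec(
        recording_lengths=(400,) * 6, frac_second_order=0.0, frac_zero_order=1.0, seed=31
    )
    model = GroundTruthModel(spec, seed=32)
    corpus = model.generate_corpus(list(spec.recording_lengths), 33, "ZERO")
    train, test = train_test_split(corpus).apply(corpus)
    _interp, trace = forward_selection(train, test)
    assert trace.test_nll[trace.chosen_step] >= trace.test_nll[0] - 0.02


def test_evaluate_all_schema_and_consistency(mk):
    corpus = mk([list("abacabbacba" * 6) for _ in range(4)])
    tab = evaluate_all(corpus)
    assert list(tab.method) == ["train-test", "LOOCV"]
    for col in ["L0", "L1", "L2", "LInt", "P0", "P1", "P2", "PInt"]:
        assert col in tab.columns
        assert np.isfinite(tab[col]).all()
    assert (tab.filter(like="P") <= 100).all().all()
    tab_tt = evaluate_all(corpus, loocv=False)
    assert list(tab_tt.method) == ["train-test"]
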