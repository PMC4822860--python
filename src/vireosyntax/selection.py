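"""Model likelihood and greedy forward selection of a mixed-order model.

Candidate models are scored by the average per-phrase negative log-likelihood
(natural log) of a held-out corpus: −(1/M) Σ_m ln P(x_m | context), with the
first two phrases of every recording excluded so that all model orders score
exactly the same positions.

The interpolated model sits between the zero-, first- and second-order
models: it is a set of selected first-order states (single phrase types) and
second-order states (phrase-type pairs) over a zero-order fallback, with
deepest-match dispatch — a context ending in the pair (i, j) uses the
second-order state if (i, j) was selected, else the first-order state of j if
selected, else the fallback.  A second-order state is admissible only once
its first-order parent (its ultimate type) is in the model.  States are added
greedily, each step taking the state with the greatest reduction in training
NLL, until every observed second-order state is included; the returned model
is the trace point with minimum testing NLL.

Because a scored position's probability depends only on the deepest selected
state for its own context, each candidate state's training-NLL gain is a
fixed sum over the positions it governs; the greedy order is computed with a
priority queue over these static gains, which makes selection linear in
corpus size rather than quadratic in the number of states.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import pandas as pd

from .corpus import Corpus, SplitSpec, loocv_folds, train_test_split
from .smoothing import SmoothedModel

SKIP_INITIAL = 2  # phrases per recording excluded from scoring


def _scored_positions(corpus: Corpus):
    for seq in corpus.labels():
        for m in range(SKIP_INITIAL, len(seq)):
            yield seq, m


def sequence_nll(model, testing: Corpus) -> float:
    """Average per-phrase negative log-likelihood of a corpus under a model.

    ``model`` is anything with ``prob(context, next)`` (a
    :class:`~vireosyntax.smoothing.SmoothedModel` of any order, or an
    :class:`InterpolatedModel`); contexts longer than the model's order are
    truncated to the relevant suffix.
    """
    total = 0.0
    n = 0
    for seq, m in _scored_positions(testing):
        total -= math.log(model.prob(tuple(seq[m - 2 : m]), seq[m]))
        n += 1
    if n == 0:
        raise ValueError("no scorable positions: every recording has <= 2 phrases")
    return total / n


class InterpolatedModel:
    """A mixed-order model: selected first/second-order states over a
    zero-order fallback, each state scored with the smoothed estimate of the
    corresponding order."""

    order = 2

    def __init__(
        self,
        sm0: SmoothedModel,
        sm1: SmoothedModel,
        sm2: SmoothedModel,
        included_first: set[str],
        included_second: set[tuple[str, str]],
    ):
        bad = {ij for ij in included_second if ij[1] not in included_first}
        if bad:
            raise ValueError(
                f"second-order states without their first-order parent: {sorted(bad)}"
            )
        self.sm0, self.sm1, self.sm2 = sm0, sm1, sm2
        self.included_first = frozenset(included_first)
        self.included_second = frozenset(included_second)

    @classmethod
    def from_corpus(
        cls,
        training: Corpus,
        included_first: set[str],
        included_second: set[tuple[str, str]],
        vocabulary: set[str] | None = None,
    ) -> "InterpolatedModel":
        """Re-parametrize a fixed state set on (new) training data."""
        sms = [
            SmoothedModel.from_corpus(training, k, vocabulary) for k in range(3)
        ]
        return cls(*sms, included_first, included_second)

    @property
    def n_states(self) -> int:
        # the shared zero-order fallback counts as one state
        return 1 + len(self.included_first) + len(self.included_second)

    def _dispatch(self, context: tuple[str, ...]):
        ctx = tuple(context)[-2:]
        if len(ctx) == 2 and ctx in self.included_second:
            return self.sm2, ctx
        if ctx and ctx[-1] in self.included_first:
            return self.sm1, ctx[-1:]
        return self.sm0, ()

    def prob(self, context: tuple[str, ...], nxt: str) -> float:
        sm, ctx = self._dispatch(context)
        return sm.prob(ctx, nxt)

    def distribution(self, context: tuple[str, ...]) -> dict[str, float]:
        sm, ctx = self._dispatch(context)
        return sm.distribution(ctx)

    def __repr__(self) -> str:
        return (
            f"InterpolatedModel(first={len(self.included_first)}, "
            f"second={len(self.included_second)})"
        )


@dataclass
class SelectionTrace:
    """The forward-selection path: the state added at each step and the
    per-phrase train/test NLL after adding it (step 0 is the bare
    zero-order model)."""

    states: list  # None, then ("j",) or ("i", "j") per step
    train_nll: list[float]
    test_nll: list[float]
    chosen_step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.states)),
                "state": ["" if s is None else "-".join(s) for s in self.states],
                "train_nll": self.train_nll,
                "test_nll": self.test_nll,
                "chosen": [i == self.chosen_step for i in range(len(self.states))],
            }
        )


def forward_selection(
    training: Corpus, testing: Corpus, vocabulary: set[str] | None = None
) -> tuple[InterpolatedModel, SelectionTrace]:
    """Greedy construction of the interpolated model.

    Returns the model at the testing-NLL minimum of the trace together with
    the full trace.  Ties in training gain break lexicographically on the
    state's context labels, for determinism.
    """
    if vocabulary is None:
        vocabulary = training.vocabulary | testing.vocabulary
    sm0 = SmoothedModel.from_corpus(training, 0, vocabulary)
    sm1 = SmoothedModel.from_corpus(training, 1, vocabulary)
    sm2 = SmoothedModel.from_corpus(training, 2, vocabulary)

    # static per-state gains (train) and deltas (test)
    gain1: dict[tuple[str], float] = {c: 0.0 for c in sm1.base.contexts()}
    gain2: dict[tuple[str, str], float] = {ij: 0.0 for ij in sm2.base.contexts()}
    tdelta1 = {k: 0.0 for k in gain1}
    tdelta2 = {k: 0.0 for k in gain2}

    def accumulate(corpus, into1, into2):
        base = 0.0
        count = 0
        for seq, m in _scored_positions(corpus):
            x = seq[m]
            j = (seq[m - 1],)
            ij = (seq[m - 2], seq[m - 1])
            lp0 = math.log(sm0.prob((), x))
            base -= lp0
            count += 1
            if j in into1:
                lp1 = math.log(sm1.prob(j, x))
                into1[j] += lp1 - lp0
                if ij in into2:
                    into2[ij] += math.log(sm2.prob(ij, x)) - lp1
        return base, count

    train_base, n_train = accumulate(training, gain1, gain2)
    test_base, n_test = accumulate(testing, tdelta1, tdelta2)
    if n_train == 0 or n_test == 0:
        raise ValueError("no scorable positions in training or testing corpus")

    children: dict[str, list[tuple[str, str]]] = {}
    for ij in gain2:
        children.setdefault(ij[1], []).append(ij)

    # max-heap on gain; ties break on the state's context tuple
    heap = [(-g, j) for j, g in gain1.items()]
    heapq.heapify(heap)
    states: list = [None]
    train_path = [train_base]
    test_path = [test_base]
    included_first: set[str] = set()
    included_second: set[tuple[str, str]] = set()
    order_added: list[tuple] = []
    while heap:
        negg, state = heapq.heappop(heap)
        if len(state) == 1:
            included_first.add(state[0])
            for child in children.get(state[0], ()):
                heapq.heappush(heap, (-gain2[child], child))
            tdelta = tdelta1[state]
        else:
            included_second.add(state)
            tdelta = tdelta2[state]
        order_added.append(state)
        states.append(state)
        train_path.append(train_path[-1] + negg)  # negg = -gain
        test_path.append(test_path[-1] - tdelta)
    chosen = min(range(len(test_path)), key=lambda i: (test_path[i], i))

    chosen_first = {s[0] for s in order_added[:chosen] if len(s) == 1}
    chosen_second = {s for s in order_added[:chosen] if len(s) == 2}
    model = InterpolatedModel(sm0, sm1, sm2, chosen_first, chosen_second)
    trace = SelectionTrace(
        states=states,
        train_nll=[v / n_train for v in train_path],
        test_nll=[v / n_test for v in test_path],
        chosen_step=chosen,
    )
    return model, trace


def classify_states(
    model: InterpolatedModel, vocabulary: set[str]
) -> tuple[float, float, float]:
    """Proportions of the repertoire with zero-, first-, second-order
    properties under an interpolated model.

    A type is second-order if some selected second-order state conditions on
    it as ultimate symbol, else first-order if its first-order state was
    selected, else it sits in the zero-order fallback category.
    """
    second = {j for _, j in model.included_second} & vocabulary
    first = (set(model.included_first) & vocabulary) - second
    n = len(vocabulary)
    if n == 0:
        raise ValueError("empty vocabulary")
    return (
        (n - len(first) - len(second)) / n,
        len(first) / n,
        len(second) / n,
    )


def evaluate_all(
    corpus: Corpus, split: SplitSpec | None = None, loocv: bool = True
) -> pd.DataFrame:
    """The model-comparison table for one individual.

    Runs the train-test paradigm (chronological midpoint split; this split
    also selects the interpolated model's state set) and, optionally, the
    LOOCV paradigm, in which every model — including the interpolated model,
    whose state set stays fixed from the train-test selection — is
    re-parametrized on each leave-one-recording-out fold and scored on the
    held-out recording, pooling NLL and accuracy over folds.

    Columns: individual, method, sample_size, L0, L1, L2, LInt,
    P0, P1, P2, PInt (accuracies in percent).
    """
    from .prediction import prediction_accuracy

    if split is None:
        split = train_test_split(corpus)
    train, test = split.apply(corpus)
    vocab = train.vocabulary | test.vocabulary
    sms = [SmoothedModel.from_corpus(train, k, vocab) for k in range(3)]
    interp, _trace = forward_selection(train, test, vocab)
    models = sms + [interp]
    rows = [
        {
            "individual": corpus.individual_id,
            "method": "train-test",
            "sample_size": train.n_phrases,
            **{f"L{k}": sequence_nll(m, test) for k, m in zip(("0", "1", "2", "Int"), models)},
            **{f"P{k}": prediction_accuracy(m, test) for k, m in zip(("0", "1", "2", "Int"), models)},
        }
    ]
    if loocv:
        totals = {k: 0.0 for k in ("0", "1", "2", "Int")}
        hits = {k: 0 for k in totals}
        n_scored = 0
        for fold in loocv_folds(corpus):
            ftrain, ftest = fold.apply(corpus)
            fvocab = ftrain.vocabulary | ftest.vocabulary
            fsms = [SmoothedModel.from_corpus(ftrain, k, fvocab) for k in range(3)]
            fint = InterpolatedModel(
                *fsms, set(interp.included_first), set(interp.included_second)
            )
            fmodels = dict(zip(("0", "1", "2", "Int"), fsms + [fint]))
            m_scored = sum(
                max(0, len(r) - SKIP_INITIAL) for r in ftest.recordings
            )
            if m_scored == 0:
                continue
            n_scored += m_scored
            for key, m in fmodels.items():
                totals[key] += sequence_nll(m, ftest) * m_scored
                hits[key] += prediction_accuracy(m, ftest) / 100.0 * m_scored
        mean_len = corpus.n_phrases / len(corpus)
        rows.append(
            {
                "individual": corpus.individual_id,
                "method": "LOOCV",
                "sample_size": round(corpus.n_phrases - mean_len),
                **{f"L{k}": totals[k] / n_scored for k in totals},
                **{f"P{k}": hits[k] / n_scored * 100.0 for k in hits},
            }
        )
    return pd.DataFrame(rows)
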