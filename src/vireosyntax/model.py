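"""Model/Results front end over the estimation modules.

``MarkovModel(corpus, order).fit()`` and
``InterpolatedMarkov(training, testing).fit()`` wrap fitting, smoothing,
selection, scoring, prediction and simulation behind the familiar
model-object / results-object pattern; the underlying operations live in
:mod:`~vireosyntax.markov`, :mod:`~vireosyntax.smoothing`,
:mod:`~vireosyntax.selection`, :mod:`~vireosyntax.prediction` and
:mod:`~vireosyntax.simulate` and remain usable directly.
"""

from __future__ import annotations

from .corpus import Corpus, train_test_split
from .markov import fit_counts
from .prediction import predict_next, prediction_accuracy, rate_stratified_accuracy
from .selection import (
    InterpolatedModel,
    classify_states,
    forward_selection,
    sequence_nll,
)
from .simulate import replicate_simulations, simulate_corpus
from .smoothing import SmoothedModel


class MarkovModel:
    """An order-k Markov model specification for one individual's corpus.

    Parameters
    ----------
    corpus : Corpus
        Training data; transitions are counted within recordings only.
    order : int
        Context length (0, 1, 2; 3 is accepted for dependency screening).
    vocabulary : set[str], optional
        Scoring vocabulary; pass the train∪test union when the fitted model
        will score held-out data containing unseen phrase types.
    """

    def __init__(self, corpus: Corpus, order: int, vocabulary: set[str] | None = None):
        self.corpus = corpus
        self.order = order
        self.vocabulary = vocabulary

    def fit(self) -> "MarkovResults":
        counts = fit_counts(self.corpus, self.order)
        smoothed = SmoothedModel(counts, self.vocabulary)
        return MarkovResults(self, counts, smoothed)


class MarkovResults:
    """A fitted Markov model: raw counts plus the smoothed likelihood engine."""

    def __init__(self, model: MarkovModel, counts, smoothed: SmoothedModel):
        self.model = model
        self.counts = counts
        self.smoothed = smoothed

    # estimation surface
    def prob(self, context, nxt) -> float:
        return self.smoothed.prob(context, nxt)

    def distribution(self, context) -> dict[str, float]:
        return self.smoothed.distribution(context)

    def predict(self, context) -> str:
        return predict_next(self.smoothed, context)

    # evaluation surface
    def nll(self, testing: Corpus) -> float:
        return sequence_nll(self.smoothed, testing)

    def accuracy(self, testing: Corpus) -> float:
        return prediction_accuracy(self.smoothed, testing)

    def accuracy_by_rate(self, testing: Corpus, **kwargs):
        return rate_stratified_accuracy(self.smoothed, testing, **kwargs)

    # simulation surface (unsmoothed counts, per the simulation protocol)
    def simulate(self, template: Corpus | None = None, n_reps: int = 1, seed: int = 0):
        template = template if template is not None else self.model.corpus
        if n_reps == 1:
            return simulate_corpus(self.counts, template, seed)
        return replicate_simulations(self.counts, template, n_reps, seed)

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"Order-{c.order} Markov model — individual "
            f"{self.model.corpus.individual_id!r}",
            f"  recordings: {len(self.model.corpus):4d}   "
            f"phrases: {self.model.corpus.n_phrases}",
            f"  repertoire: {len(c.vocabulary):4d}   "
            f"observed contexts: {len(c.context_counts)}",
            f"  transitions counted: {c.n_observations}",
        ]
        return "\n".join(lines)


class InterpolatedMarkov:
    """Greedy mixed-order model selection between a training and testing corpus."""

    def __init__(
        self, training: Corpus, testing: Corpus, vocabulary: set[str] | None = None
    ):
        self.training = training
        self.testing = testing
        self.vocabulary = (
            vocabulary
            if vocabulary is not None
            else training.vocabulary | testing.vocabulary
        )

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "InterpolatedMarkov":
        """Split a full corpus at the chronological midpoint and set up selection."""
        train, test = train_test_split(corpus).apply(corpus)
        return cls(train, test)

    def fit(self) -> "InterpolatedResults":
        model, trace = forward_selection(self.training, self.testing, self.vocabulary)
        return InterpolatedResults(self, model, trace)


class InterpolatedResults:
    """A selected interpolated model with its full selection trace."""

    def __init__(self, spec: InterpolatedMarkov, model: InterpolatedModel, trace):
        self.spec = spec
        self.model = model
        self.trace = trace

    def prob(self, context, nxt) -> float:
        return self.model.prob(context, nxt)

    def predict(self, context) -> str:
        return predict_next(self.model, context)

    def nll(self, testing: Corpus | None = None) -> float:
        return sequence_nll(self.model, testing or self.spec.testing)

    def accuracy(self, testing: Corpus | None = None) -> float:
        return prediction_accuracy(self.model, testing or self.spec.testing)

    def accuracy_by_rate(self, testing: Corpus | None = None, **kwargs):
        return rate_stratified_accuracy(
            self.model, testing or self.spec.testing, **kwargs
        )

    def state_proportions(self) -> tuple[float, float, float]:
        """(zero, first, second)-order shares of the repertoire."""
        return classify_states(self.model, self.spec.vocabulary)

    def summary(self) -> str:
        p0, p1, p2 = self.state_proportions()
        tr = self.trace
        lines = [
            "Interpolated (mixed-order) Markov model",
            f"  states: {self.model.n_states} "
            f"(first-order {len(self.model.included_first)}, "
            f"second-order {len(self.model.included_second)}, "
            "+ zero-order fallback)",
            f"  repertoire shares — zero: {p0:.0%}  first: {p1:.0%}  second: {p2:.0%}",
            f"  selection: step {tr.chosen_step} of {len(tr.states) - 1}; "
            f"test NLL/phrase {tr.test_nll[tr.chosen_step]:.3f} "
            f"(zero-order start {tr.test_nll[0]:.3f})",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Selection-path plot: train and test NLL per step, minimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        steps = range(len(self.trace.states))
        ax.plot(steps, self.trace.train_nll, ls=":", label="training")
        ax.plot(steps, self.trace.test_nll, ls="-", label="testing")
        ax.plot(
            self.trace.chosen_step,
            self.trace.test_nll[self.trace.chosen_step],
            "ko",
            label="selected model",
        )
        ax.set_xlabel("states added")
        ax.set_ylabel("negative log-likelihood per phrase")
        ax.legend()
        return ax
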