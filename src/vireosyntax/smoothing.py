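"""Witten-Bell discounting with recursive (Katz-style) backoff.

Zero transition probabilities make held-out likelihoods meaningless, so every
context must assign positive probability to every phrase type in the scoring
vocabulary.  In each context with N observations and T distinct observed
continuations, observed probabilities are deflated by the factor N/(N+T) and
the reserved mass T/(N+T) is redistributed over the *unseen* continuations in
proportion to their probabilities under the next-shorter context, normalized
over the unseen set so each context sums exactly to one.  The chain ends in a
uniform distribution over the vocabulary below the zero-order level.

Two conventions the discounting rule alone does not fix:

* a context that has already produced every vocabulary type has no unseen set
  and is left at its maximum-likelihood estimate (no mass to redistribute);
* a testing set may contain phrase types never seen in training, so a model
  may be built over any vocabulary that is a superset of the training
  repertoire (pass the train∪test union when scoring held-out data) — the
  uniform terminal level keeps every such type's probability positive.
"""

from __future__ import annotations

from collections import Counter

from .corpus import Corpus
from .markov import CountModel, fit_counts


class OutOfVocabularyError(KeyError):
    """Raised when a probability is requested for a label outside the vocabulary."""


def _marginal_lower(model: CountModel) -> CountModel:
    # Derived backoff chain for a bare CountModel without one: drop the
    # leading context symbol and aggregate.  Differs from a direct fit only
    # at the k recording-initial positions each recording contributes.
    counts: dict[tuple[str, ...], Counter] = {}
    for ctx, nc in model.context_counts.items():
        tgt = counts.setdefault(ctx[1:], Counter())
        tgt.update(nc)
    return CountModel(model.order - 1, counts, model.vocabulary)


class SmoothedModel:
    """Strictly positive, exactly normalized conditional distributions.

    Wraps an order-k :class:`~vireosyntax.markov.CountModel` chain; contexts
    longer than k are truncated to their length-k suffix.
    """

    def __init__(self, counts: CountModel, vocabulary: set[str] | None = None):
        if vocabulary is None:
            vocabulary = counts.vocabulary
        if not vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if not counts.vocabulary <= vocabulary:
            raise ValueError("vocabulary must cover the training repertoire")
        self.base = counts
        self.order = counts.order
        self.vocabulary = frozenset(vocabulary)
        self._vocab_sorted = sorted(vocabulary)
        # materialize the backoff chain, deepest first
        self._levels: list[CountModel] = [counts]
        level = counts
        while level.order > 0:
            level = level.lower if level.lower is not None else _marginal_lower(level)
            self._levels.append(level)
        self._alpha_cache: dict[tuple[int, tuple[str, ...]], float] = {}
        self._dist_cache: dict[tuple[str, ...], dict[str, float]] = {}

    @classmethod
    def from_corpus(
        cls, corpus: Corpus, order: int, vocabulary: set[str] | None = None
    ) -> "SmoothedModel":
        return cls(fit_counts(corpus, order), vocabulary)

    # -- probability lookup -------------------------------------------------

    def prob(self, context: tuple[str, ...], nxt: str) -> float:
        """P(next | context) with discounting and backoff; always > 0.

        Contexts longer than the model order are truncated to their suffix;
        shorter contexts enter the chain at the matching lower-order level.
        """
        if nxt not in self.vocabulary:
            raise OutOfVocabularyError(f"label {nxt!r} not in the model vocabulary")
        ctx = tuple(context)[-self.order :] if self.order else ()
        return self._prob(self.order - len(ctx), ctx, nxt)

    def _prob(self, depth: int, context: tuple[str, ...], nxt: str) -> float:
        if depth == len(self._levels):  # below zero order: uniform terminal
            return 1.0 / len(self.vocabulary)
        level = self._levels[depth]
        nc = level.context_counts.get(context)
        if not nc:  # entirely unseen context: full backoff
            return self._prob(depth + 1, context[1:], nxt)
        n = level.total(context)
        t = len(nc)
        if t == len(self.vocabulary):  # nothing unseen: plain MLE
            return nc.get(nxt, 0) / n
        c = nc.get(nxt)
        if c is not None:
            return c / (n + t)
        key = (depth, context)
        alpha = self._alpha_cache.get(key)
        if alpha is None:
            seen_lower = sum(self._prob(depth + 1, context[1:], s) for s in nc)
            alpha = (t / (n + t)) / (1.0 - seen_lower)
            self._alpha_cache[key] = alpha
        return alpha * self._prob(depth + 1, context[1:], nxt)

    def distribution(self, context: tuple[str, ...]) -> dict[str, float]:
        """The full conditional distribution over the vocabulary (cached)."""
        ctx = tuple(context)[-self.order :] if self.order else ()
        dist = self._dist_cache.get(ctx)
        if dist is None:
            depth = self.order - len(ctx)
            dist = {x: self._prob(depth, ctx, x) for x in self._vocab_sorted}
            self._dist_cache[ctx] = dist
        return dist

    def __repr__(self) -> str:
        return f"SmoothedModel(order={self.order}, vocabulary={len(self.vocabulary)})"


def smooth(model: CountModel, vocabulary: set[str] | None = None) -> SmoothedModel:
    """Build the discounted backoff chain over an order-k count model."""
    return SmoothedModel(model, vocabulary)


def backoff_prob(sm: SmoothedModel, context: tuple[str, ...], nxt: str) -> float:
    """P(next | context) under the smoothed model (module-level convenience)."""
    return sm.prob(context, nxt)
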