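"""Maximum-likelihood Markov models of phrase sequences.

An order-k model is a table of context -> next-phrase counts, where a context
is the tuple of the k preceding phrase types.  Counts are accumulated within
recordings only: a (k+1)-gram contributes only if it lies entirely inside one
recording, because the silence between files is unobserved.  A consequence is
that the context total n_c may be slightly less than the unigram count of the
context's symbols when those symbols terminate a recording.

Orders 0-2 are used for likelihood modelling; order 3 exists to feed the
higher-order dependency screens (sample sizes rule out an order-3 likelihood
model).
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

from .corpus import Corpus

MAX_ORDER = 3


class UnknownContextError(KeyError):
    """Raised when an MLE probability is requested for an unseen context."""


class CountModel:
    """Transition counts for an order-k Markov model.

    Attributes
    ----------
    order : int
        Context length k (0 through 3).
    context_counts : dict[tuple[str, ...], Counter]
        Sparse map context -> Counter of next-phrase counts.  For k=0 the
        single context is the empty tuple.
    vocabulary : set[str]
        All phrase types observed in the training corpus.
    lower : CountModel | None
        The order-(k-1) model fitted from the same corpus; ``None`` at k=0.
        The chain serves backoff smoothing and simulation dead-end recovery.
    """

    def __init__(
        self,
        order: int,
        context_counts: dict[tuple[str, ...], Counter],
        vocabulary: set[str],
        lower: "CountModel | None" = None,
    ):
        self.order = order
        self.context_counts = context_counts
        self.vocabulary = vocabulary
        self.lower = lower
        self._totals = {c: sum(nc.values()) for c, nc in context_counts.items()}

    def total(self, context: tuple[str, ...]) -> int:
        return self._totals.get(tuple(context), 0)

    def contexts(self):
        return self.context_counts.keys()

    @property
    def n_observations(self) -> int:
        return sum(self._totals.values())

    def __repr__(self) -> str:
        return (
            f"CountModel(order={self.order}, contexts={len(self.context_counts)}, "
            f"vocabulary={len(self.vocabulary)})"
        )


def fit_counts(corpus: Corpus, order: int) -> CountModel:
    """Fit order-k transition counts (and the full lower-order chain).

    Every order from k down to 0 is fitted from the same corpus so that the
    returned model carries its own backoff chain via ``.lower``.
    """
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 0..{MAX_ORDER}, got {order}")
    if corpus.n_phrases == 0:
        raise ValueError("cannot fit a model on an empty corpus")
    vocabulary = corpus.vocabulary
    sequences = corpus.labels()
    lower = fit_counts(corpus, order - 1) if order > 0 else None
    counts: dict[tuple[str, ...], Counter] = {}
    for seq in sequences:
        for m in range(order, len(seq)):
            ctx = tuple(seq[m - order : m])
            nc = counts.get(ctx)
            if nc is None:
                nc = counts[ctx] = Counter()
            nc[seq[m]] += 1
    return CountModel(order, counts, vocabulary, lower)


def mle_prob(model: CountModel, context: tuple[str, ...], nxt: str) -> float:
    """Maximum-likelihood conditional probability count(c, x) / total(c).

    Unseen next types in a seen context score 0; an entirely unseen context
    raises :class:`UnknownContextError` (the caller must smooth or back off).
    """
    context = tuple(context)
    if len(context) != model.order:
        raise ValueError(
            f"context length {len(context)} != model order {model.order}"
        )
    nc = model.context_counts.get(context)
    if nc is None:
        raise UnknownContextError(f"context {context!r} not observed in training")
    return nc.get(nxt, 0) / model._totals[context]


def prune_counts(model: CountModel, min_count: int) -> CountModel:
    """Drop transitions observed fewer than ``min_count`` times (whole chain).

    Yields a model whose every transition probability is well resolved at the
    corpus size — the resolution a simulation-based null needs: thinly
    estimated transitions make corpora simulated from a fitted model
    under-dispersed in their N-gram distributions relative to the data.
    Contexts left without any surviving transition are removed (the
    simulator's dead-end backoff covers them).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[tuple[str, ...], Counter] = {}
    for ctx, nc in model.context_counts.items():
        kept = Counter({x: c for x, c in nc.items() if c >= min_count})
        if kept:
            counts[ctx] = kept
    lower = prune_counts(model.lower, min_count) if model.lower is not None else None
    return CountModel(model.order, counts, model.vocabulary, lower)


# ---------------------------------------------------------------------------
# Serialization: {order, vocabulary, contexts: [{context, next_counts}], lower}


def _to_dict(model: CountModel) -> dict:
    return {
        "order": model.order,
        "vocabulary": sorted(model.vocabulary),
        "contexts": [
            {"context": list(c), "next_counts": dict(sorted(nc.items()))}
            for c, nc in sorted(model.context_counts.items())
        ],
        "lower": _to_dict(model.lower) if model.lower is not None else None,
    }


def _from_dict(doc: dict) -> CountModel:
    counts = {
        tuple(entry["context"]): Counter(entry["next_counts"])
        for entry in doc["contexts"]
    }
    lower = _from_dict(doc["lower"]) if doc.get("lower") else None
    return CountModel(doc["order"], counts, set(doc["vocabulary"]), lower)


def save_model(model: CountModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_dict(model), indent=1))


def load_model(path: str | Path) -> CountModel:
    return _from_dict(json.loads(Path(path).read_text()))
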