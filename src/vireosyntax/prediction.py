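"""Next-phrase prediction accuracy, overall and by inter-phrase interval.

Each model predicts the modal phrase type of its conditional distribution
given the immediately preceding sequence; accuracy is the fraction of scored
positions (the first two phrases of every recording are excluded, mirroring
likelihood scoring) where the prediction matches the observed phrase.  Ties
in the conditional distribution resolve to the lexicographically first label.

Rate stratification assigns each scored position to a time bin by the silent
gap between the previous phrase's end and the current phrase's start (the
onset-to-onset interval is available as an alternative); song delivered at
high rates is expected to be more predictable than phrases across long
pauses.
"""

from __future__ import annotations

import math

import pandas as pd

from .corpus import Corpus
from .selection import SKIP_INITIAL


def predict_next(model, context: tuple[str, ...]) -> str:
    """The model's modal next phrase for a context (deterministic under ties)."""
    dist = model.distribution(tuple(context))
    best, best_p = None, -1.0
    for lab in sorted(dist):
        p = dist[lab]
        if p > best_p:
            best, best_p = lab, p
    return best


class _PredictionCache:
    def __init__(self, model):
        self.model = model
        self._cache: dict[tuple[str, ...], str] = {}

    def __call__(self, context: tuple[str, ...]) -> str:
        pred = self._cache.get(context)
        if pred is None:
            pred = self._cache[context] = predict_next(self.model, context)
        return pred


def _positions(testing: Corpus):
    for rec in testing.recordings:
        seq = rec.labels
        for m in range(SKIP_INITIAL, len(seq)):
            yield rec, seq, m


def prediction_accuracy(model, testing: Corpus) -> float:
    """Percent of scored positions whose observed phrase is the model's mode."""
    predict = _PredictionCache(model)
    hits = n = 0
    for _rec, seq, m in _positions(testing):
        hits += predict(tuple(seq[m - 2 : m])) == seq[m]
        n += 1
    if n == 0:
        raise ValueError("no scorable positions in the testing corpus")
    return hits / n * 100.0


def disagreement_accuracy(models: list, testing: Corpus) -> tuple[list[float], int]:
    """Per-model percent accuracy restricted to positions where the models'
    predictions are not unanimous, plus the count of such positions.

    Models that mostly coincide differ little in overall accuracy; the
    restriction isolates the positions that actually discriminate them.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to disagree")
    predictors = [_PredictionCache(m) for m in models]
    hits = [0] * len(models)
    n = 0
    for _rec, seq, m in _positions(testing):
        ctx = tuple(seq[m - 2 : m])
        preds = [p(ctx) for p in predictors]
        if len(set(preds)) == 1:
            continue
        n += 1
        for i, pred in enumerate(preds):
            hits[i] += pred == seq[m]
    if n == 0:
        return [math.nan] * len(models), 0
    return [h / n * 100.0 for h in hits], n


DEFAULT_BIN_EDGES = tuple(float(x) for x in range(11))  # 0-1, 1-2, ..., 9-10, >10 s


def rate_stratified_accuracy(
    model,
    testing: Corpus,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    gap: str = "silence",
) -> pd.DataFrame:
    """Prediction accuracy per inter-phrase-interval bin.

    ``bin_edges`` are increasing; bins are [e0,e1), ..., [e_last, inf).
    ``gap`` is "silence" (previous end to current start) or "onset"
    (onset to onset).  Non-positive gaps clamp into the first bin.
    Columns: bin_low, bin_high, accuracy (percent; NaN for empty bins), n.
    """
    if gap not in ("silence", "onset"):
        raise ValueError("gap must be 'silence' or 'onset'")
    edges = list(bin_edges)
    if edges != sorted(edges) or len(edges) < 1:
        raise ValueError("bin_edges must be increasing")
    bins = list(zip(edges, edges[1:])) + [(edges[-1], math.inf)]
    hits = [0] * len(bins)
    counts = [0] * len(bins)
    predict = _PredictionCache(model)
    for rec, seq, m in _positions(testing):
        prev, cur = rec.events[m - 1], rec.events[m]
        g = cur.start - (prev.end if gap == "silence" else prev.start)
        idx = 0
        for i, (lo, hi) in enumerate(bins):
            if lo <= g < hi:
                idx = i
                break
        correct = predict(tuple(seq[m - 2 : m])) == seq[m]
        hits[idx] += correct
        counts[idx] += 1
    return pd.DataFrame(
        {
            "bin_low": [b[0] for b in bins],
            "bin_high": [b[1] for b in bins],
            "accuracy": [
                h / c * 100.0 if c else math.nan for h, c in zip(hits, counts)
            ],
            "n": counts,
        }
    )
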