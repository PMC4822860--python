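"""Sequence simulation from fitted (unsmoothed) Markov models.

A simulation is a synthetic corpus equivalent to a template corpus in file
structure, per-recording length, initial state and timing: one simulated
recording per template recording, the first k phrase types copied from the
template (k = model order), and every later phrase drawn from the model's
maximum-likelihood conditional given the running context.  No smoothing is
applied, so every simulated (k+1)-gram lies in the training support.

A running context can be a dead end: a k-gram observed in training only at a
recording end has no outgoing counts.  The draw then backs off to the MLE of
the next-shorter context, down to the zero-order distribution if necessary,
so a simulation never halts mid-recording.
"""

from __future__ import annotations

from bisect import bisect_right
from itertools import accumulate

import numpy as np

from .corpus import Corpus, PhraseEvent, Recording
from .markov import CountModel


class _Sampler:
    """Cached inverse-CDF categorical sampling over a count-model chain."""

    def __init__(self, model: CountModel):
        self.chain = []
        level = model
        while level is not None:
            self.chain.append(level)
            level = level.lower
        self._tables: dict[tuple[int, tuple[str, ...]], tuple[list[str], list[int]]] = {}

    def draw(self, context: tuple[str, ...], rng: np.random.Generator) -> str:
        for depth, level in enumerate(self.chain):
            ctx = context[len(context) - level.order :] if level.order else ()
            key = (depth, ctx)
            table = self._tables.get(key)
            if table is None:
                nc = level.context_counts.get(ctx)
                if not nc:
                    continue
                labels = sorted(nc)
                table = labels, list(accumulate(nc[x] for x in labels))
                self._tables[key] = table
            labels, cum = table
            u = rng.random() * cum[-1]
            return labels[bisect_right(cum, u)]
        raise RuntimeError("empty model: nothing to sample from")  # pragma: no cover


def simulate_corpus(
    model: CountModel, template: Corpus, seed: int | np.random.SeedSequence
) -> Corpus:
    """Simulate one corpus matching the template's structure and initial state.

    Timestamps and phrase boundaries are copied from the template (timed
    synthesis is not the simulator's job); only the labels are redrawn.
    Recordings shorter than the model order are copied verbatim.
    """
    rng = np.random.default_rng(seed)
    sampler = _Sampler(model)
    k = model.order
    out = []
    for rec in template.recordings:
        labels = rec.labels
        new = labels[: min(k, len(labels))]
        while len(new) < len(labels):
            new.append(sampler.draw(tuple(new[len(new) - k :]) if k else (), rng))
        events = [
            PhraseEvent(lab, ev.start, ev.end) for lab, ev in zip(new, rec.events)
        ]
        out.append(
            Recording(
                individual_id=rec.individual_id,
                events=events,
                source=rec.source,  # same file identity: split specs stay applicable
                recorded_at=rec.recorded_at,
            )
        )
    return Corpus(template.individual_id, out)


def replicate_simulations(
    model: CountModel,
    template: Corpus,
    n_reps: int,
    seed: int | np.random.SeedSequence,
) -> list[Corpus]:
    """n_reps independent simulations with per-replicate child seed streams."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    return [simulate_corpus(model, template, child) for child in master.spawn(n_reps)]
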