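from datetime import datetime, timedelta

import pytest

from vireosyntax.corpus import Corpus, PhraseEvent, Recording
from vireosyntax.synthetic import GroundTruthModel, GroundTruthSpec


def corpus_from_seqs(seqs, individual="T", dur=0.5, gap=0.5):
    """Build a corpus from plain label sequences with regular fabricated timing."""
    recs = []
    for i, seq in enumerate(seqs):
        events = []
        t = 0.0
        for lab in seq:
            events.append(PhraseEvent(lab, t, t + dur))
            t += dur + gap
        recs.append(
            Recording(
                individual_id=individual,
                events=events,
                source=f"{individual}_{i:03d}",
                recorded_at=datetime(2013, 5, 1) + timedelta(days=i),
            )
        )
    return Corpus(individual, recs)


@pytest.fixture
def mk():
    return corpus_from_seqs


@pytest.fixture(scope="session")
def big_truth():
    """One default-truth individual with ~5e4 training phrases after the
    chronological split; shared across selection/recovery tests."""
    spec = GroundTruthSpec(recording_lengths=(7200,) * 14, seed=11)
    model = GroundTruthModel(spec, seed=123)
    corpus = model.generate_corpus(
        list(spec.recording_lengths), 456, individual_id="BIG"
    )
    return model, corpus
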