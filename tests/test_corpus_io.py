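import pytest

from vireosyntax.corpus import (
    TextGridParseError,
    TierNotFoundError,
    filter_short_recordings,
    load_corpora,
    loocv_folds,
    read_textgrid,
    train_test_split,
    write_textgrid,
)
from vireosyntax.synthetic import GroundTruthSpec, generate_study

LONG_TG = """File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0
xmax = 1.9
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "phrases"
        xmin = 0
        xmax = 1.9
        intervals: size = 3
        intervals [1]:
            xmin = 0.0
            xmax = 0.8
            text = "ai"
        intervals [2]:
            xmin = 0.8
            xmax = 1.2
            text = ""
        intervals [3]:
            xmin = 1.2
            xmax = 1.9
            text = "en"
"""

SHORT_TG = """File type = "ooTextFile"
Object class = "TextGrid"

0
1.9
<exists>
1
"IntervalTier"
"phrases"
0
1.9
3
0
0.8
"ai"
0.8
1.2
""
1.2
1.9
"en"
"""


@pytest.mark.parametrize("text", [LONG_TG, SHORT_TG], ids=["long", "short"])
@pytest.mark.parametrize("encoding", ["utf-8", "utf-16"])
def test_read_textgrid_both_dialects(tmp_path, text, encoding):
    """Both Praat text dialects parse; blank (silence) intervals are skipped."""
    p = tmp_path / "r.TextGrid"
    p.write_bytes(text.encode(encoding))
    rec = read_textgrid(p, "phrases")
    assert [e.label for e in rec.events] == ["ai", "en"]
    assert rec.events[0].start == 0.0 and rec.events[0].end == 0.8
    assert rec.events[1].start == 1.2


def test_read_textgrid_all_silent(tmp_path):
    p = tmp_path / "r.TextGrid"
    p.write_text(LONG_TG.replace('"ai"', '""').replace('"en"', '""'))
    assert len(read_textgrid(p, "phrases").events) == 0


def test_missing_tier_and_malformed_file(tmp_path):
    p = tmp_path / "r.TextGrid"
    p.write_text(LONG_TG)
    with pytest.raises(TierNotFoundError, match="notes"):
        read_textgrid(p, "notes")
    bad = tmp_path / "bad.TextGrid"
    bad.write_text("not a textgrid at all\n1 2 3\n")
    with pytest.raises(TextGridParseError):
        read_textgrid(bad, "phrases")


def test_write_read_round_trip(tmp_path, mk):
    """Writing fills silence gaps; re-reading recovers labels and boundaries."""
    corpus = mk([["ai", "en", "ds", "ai"], ["bq", "cg"]])
    for rec in corpus.recordings:
        path = tmp_path / f"{rec.source}.TextGrid"
        write_textgrid(rec, path, "phrases")
        back = read_textgrid(path, "phrases")
        assert [e.label for e in back.events] == rec.labels
        for a, b in zip(back.events, rec.events):
            assert abs(a.start - b.start) < 1e-6
            assert abs(a.end - b.end) < 1e-6


def test_study_round_trip_through_metadata(tmp_path):
    """A written synthetic study reloads into identical label sequences, in
    chronological order."""
    spec = GroundTruthSpec(recording_lengths=(60, 55, 70), seed=4)
    corpora, _ = generate_study(spec, n_individuals=2, out_dir=tmp_path)
    loaded = load_corpora(tmp_path / "metadata.csv", "phrases")
    assert set(loaded) == set(corpora)
    for ind in corpora:
        assert loaded[ind].labels() == corpora[ind].labels()
        assert [r.source for r in loaded[ind].recordings] == [
            r.source for r in corpora[ind].recordings
        ]


def test_filter_short_recordings_boundary(mk):
    corpus = mk([["a"] * 49, ["b"] * 50, ["c"] * 51])
    kept = filter_short_recordings(corpus, 50)
    assert [len(r) for r in kept.recordings] == [50, 51]
    assert kept.vocabulary == {"b", "c"}
    # identity when nothing is short
    again = filter_short_recordings(kept, 50)
    assert [r.source for r in again.recordings] == [r.source for r in kept.recordings]


def test_filter_rejects_bad_threshold(mk):
    with pytest.raises(ValueError):
        filter_short_recordings(mk([["a"] * 3]), 0)


@pytest.mark.parametrize(
    "lengths,expect_train",
    [
        ([60, 60, 60], 2),  # midpoint phrase 90 falls in recording 2
        ([100, 10], 1),  # midpoint falls in recording 1
    ],
)
def test_train_test_split_hand_traces(mk, lengths, expect_train):
    corpus = mk([["a"] * n for n in lengths])
    split = train_test_split(corpus)
    assert len(split.train) == expect_train
    assert len(split.train) + len(split.test) == len(lengths)
    train, test = split.apply(corpus)
    assert train.n_phrases + test.n_phrases == corpus.n_phrases


def test_train_test_split_degenerate_moves_last_recording(mk):
    """Midpoint in the final recording would empty the testing set; the final
    recording moves to test with a warning."""
    corpus = mk([["a"] * 10, ["a"] * 100])
    with pytest.warns(UserWarning, match="final recording"):
        split = train_test_split(corpus)
    assert split.train == (corpus.recordings[0].source,)
    assert split.test == (corpus.recordings[1].source,)


def test_train_test_split_single_recording_errors(mk):
    with pytest.raises(ValueError):
        train_test_split(mk([["a"] * 5]))


def test_loocv_folds_partition(mk):
    corpus = mk([["a"] * 4, ["b"] * 4, ["c"] * 4])
    folds = loocv_folds(corpus)
    assert len(folds) == 3
    held = [f.test for f in folds]
    assert sorted(h for (h,) in held) == sorted(r.source for r in corpus.recordings)
    for f in folds:
        assert len(f.train) == 2
        assert set(f.train) | set(f.test) == {r.source for r in corpus.recordings}
    with pytest.raises(ValueError):
        loocv_folds(mk([["a"] * 4]))


def test_chronological_order_from_metadata(mk):
    corpus = mk([["a", "b"], ["c", "d"], ["e", "f"]])
    # shuffle construction order; Corpus must restore chronology
    from vireosyntax.corpus import Corpus

    shuffled = Corpus(corpus.individual_id, corpus.recordings[::-1])
    assert [r.source for r in shuffled.recordings] == [
        r.source for r in corpus.recordings
    ]
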