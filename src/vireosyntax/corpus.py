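"""Containers and I/O for annotated song-recording corpora.

A recording is an ordered list of timed, labelled phrases; a corpus is one
individual's chronologically ordered recordings.  Annotations travel as Praat
TextGrid files (one interval tier holds the phrase-type labels) plus a CSV
metadata table mapping each file to an individual and a recording timestamp.
Both the long ("verbose") and short TextGrid text dialects are read, in UTF-8
or UTF-16; files are written in the long dialect.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path


class TextGridParseError(ValueError):
    """Raised when a TextGrid file cannot be parsed; message carries line context."""


class TierNotFoundError(KeyError):
    """Raised when the requested interval tier is absent from a TextGrid."""


@dataclass(frozen=True)
class PhraseEvent:
    """One phrase: a type label with its start/end boundaries in seconds."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("phrase label must be non-empty")
        if not self.end > self.start:
            raise ValueError(
                f"phrase end must exceed start (got [{self.start}, {self.end}])"
            )


@dataclass
class Recording:
    """An annotated recording: ordered phrase events from one individual."""

    individual_id: str
    events: list[PhraseEvent]
    source: str
    recorded_at: datetime | None = None

    def __post_init__(self) -> None:
        starts = [e.start for e in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError(f"events of {self.source!r} are not in time order")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class Corpus:
    """One individual's recordings, kept in chronological order.

    Ordering uses the recording timestamps when every recording has one,
    falling back to lexicographic source (filename) order otherwise.
    """

    individual_id: str
    recordings: list[Recording] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.recordings = sorted(self.recordings, key=_chronology_key(self.recordings))

    @property
    def vocabulary(self) -> set[str]:
        """The repertoire: all phrase-type labels observed in the corpus."""
        return {e.label for r in self.recordings for e in r.events}

    @property
    def n_phrases(self) -> int:
        return sum(len(r) for r in self.recordings)

    def labels(self) -> list[list[str]]:
        """Per-recording label sequences, in chronological order."""
        return [r.labels for r in self.recordings]

    def subset(self, sources: list[str]) -> "Corpus":
        """Sub-corpus containing the named recordings (chronological order kept)."""
        wanted = set(sources)
        missing = wanted - {r.source for r in self.recordings}
        if missing:
            raise KeyError(f"unknown recording(s): {sorted(missing)}")
        return Corpus(
            self.individual_id, [r for r in self.recordings if r.source in wanted]
        )

    def __len__(self) -> int:
        return len(self.recordings)


def _chronology_key(recordings: list[Recording]):
    if recordings and all(r.recorded_at is not None for r in recordings):
        return lambda r: (r.recorded_at, r.source)
    return lambda r: r.source


@dataclass(frozen=True)
class SplitSpec:
    """A whole-recording train/test partition of a corpus."""

    train: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test must be disjoint")

    def apply(self, corpus: Corpus) -> tuple[Corpus, Corpus]:
        return corpus.subset(list(self.train)), corpus.subset(list(self.test))


# ---------------------------------------------------------------------------
# TextGrid reading


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8")


def _unquote(s: str) -> str:
    return s.replace('""', '"')


_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")
_STR_RE = re.compile(r'"((?:[^"]|"")*)"')


def _tokenize(text: str):
    """Yield (lineno, kind, value) tokens: numbers and quoted strings.

    Key names, brackets and flags like ``<exists>`` are layout, not data, in
    both TextGrid dialects, so a single token stream serves both.  On lines of
    the form ``key = value`` only the value is emitted.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if "=" in line:
            line = line.split("=", 1)[1].strip()
        if '"' not in line:
            # bracket indices ("item [1]:", "intervals [2]:") are layout,
            # not data; only stripped on unquoted lines so labels keep any
            # bracketed text
            line = re.sub(r"\[\s*\d*\s*\]", "", line)
        if line.startswith("<"):  # <exists> flag
            continue
        pos = 0
        while pos < len(line):
            ch = line[pos]
            if ch == '"':
                m = _STR_RE.match(line, pos)
                if not m:
                    raise TextGridParseError(
                        f"line {lineno}: unterminated string in {line!r}"
                    )
                yield lineno, "str", _unquote(m.group(1))
                pos = m.end()
            else:
                m = _NUM_RE.match(line, pos)
                if not m:
                    # bare word (e.g. "intervals:" headers in long format)
                    pos += 1
                    continue
                yield lineno, "num", float(m.group(0))
                pos = m.end()


class _TokenStream:
    def __init__(self, text: str):
        self._toks = list(_tokenize(text))
        self._i = 0

    def next(self, kind: str):
        while self._i < len(self._toks):
            lineno, k, v = self._toks[self._i]
            self._i += 1
            if k == kind:
                return v
        raise TextGridParseError(f"unexpected end of file (wanted a {kind} token)")


def parse_textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    """Parse TextGrid text into ``{tier_name: [(xmin, xmax, label), ...]}``.

    Interval tiers are returned; point (Text) tiers are consumed and skipped.
    """
    if "ooTextFile" not in text.split("\n", 3)[0] and "ooTextFile" not in text[:200]:
        raise TextGridParseError("not an ooTextFile TextGrid (bad header)")
    ts = _TokenStream(text)
    ts.next("num")  # global xmin
    ts.next("num")  # global xmax
    n_tiers = int(ts.next("num"))
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    for _ in range(n_tiers):
        tier_class = ts.next("str")
        name = ts.next("str")
        ts.next("num")  # tier xmin
        ts.next("num")  # tier xmax
        n_items = int(ts.next("num"))
        if tier_class == "IntervalTier":
            ivs = []
            for _ in range(n_items):
                xmin = ts.next("num")
                xmax = ts.next("num")
                label = ts.next("str")
                ivs.append((xmin, xmax, label))
            tiers[name] = ivs
        else:  # TextTier: points are (time, mark)
            for _ in range(n_items):
                ts.next("num")
                ts.next("str")
    return tiers


def read_textgrid(
    path: str | Path,
    tier_name: str,
    individual_id: str = "",
    recorded_at: datetime | None = None,
) -> Recording:
    """Read one recording from the named interval tier of a TextGrid file.

    Non-empty intervals become :class:`PhraseEvent`s in time order; intervals
    with blank text (silence) are skipped.  Labels are whitespace-stripped and
    case-sensitive.
    """
    path = Path(path)
    tiers = parse_textgrid_tiers(_read_text(path))
    if tier_name not in tiers:
        raise TierNotFoundError(
            f"tier {tier_name!r} not found in {path.name} "
            f"(available: {sorted(tiers)})"
        )
    events = [
        PhraseEvent(label.strip(), xmin, xmax)
        for xmin, xmax, label in tiers[tier_name]
        if label.strip()
    ]
    return Recording(
        individual_id=individual_id,
        events=sorted(events, key=lambda e: e.start),
        source=path.name,
        recorded_at=recorded_at,
    )


def write_textgrid(recording: Recording, path: str | Path, tier_name: str) -> None:
    """Write a recording as a long-format TextGrid with one interval tier.

    Praat requires contiguous intervals, so gaps between phrases are filled
    with empty (silence) intervals; reading the file back recovers the
    original event list.
    """
    ev = recording.events
    xmax = ev[-1].end if ev else 1.0
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for e in ev:
        if e.start > cursor:
            intervals.append((cursor, e.start, ""))
        intervals.append((e.start, e.end, e.label))
        cursor = e.end
    if not intervals:
        intervals.append((0.0, xmax, ""))

    def fnum(x: float) -> str:
        return repr(float(x))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {fnum(xmax)}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {fnum(xmax)}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (a, b, lab) in enumerate(intervals, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {fnum(a)}",
            f"            xmax = {fnum(b)}",
            f'            text = "{lab.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Metadata and corpus assembly

METADATA_COLUMNS = ["recording_id", "individual_id", "datetime", "path"]


def write_metadata(rows: list[dict], path: str | Path) -> None:
    """Write a recording metadata table (recording_id, individual_id, datetime, path)."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=METADATA_COLUMNS)
        w.writeheader()
        for row in rows:
            w.writerow({k: row[k] for k in METADATA_COLUMNS})


def load_corpora(
    metadata_csv: str | Path, tier_name: str, base_dir: str | Path | None = None
) -> dict[str, Corpus]:
    """Assemble per-individual corpora from a metadata table of TextGrid files."""
    metadata_csv = Path(metadata_csv)
    base = Path(base_dir) if base_dir is not None else metadata_csv.parent
    per_individual: dict[str, list[Recording]] = {}
    with open(metadata_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            when = datetime.fromisoformat(row["datetime"]) if row["datetime"] else None
            rec = read_textgrid(
                base / row["path"],
                tier_name,
                individual_id=row["individual_id"],
                recorded_at=when,
            )
            rec.source = row["recording_id"]
            per_individual.setdefault(row["individual_id"], []).append(rec)
    return {ind: Corpus(ind, recs) for ind, recs in sorted(per_individual.items())}


# ---------------------------------------------------------------------------
# Filtering and splitting


def filter_short_recordings(corpus: Corpus, min_phrases: int = 50) -> Corpus:
    """Drop recordings with fewer than ``min_phrases`` phrases.

    Short files carry too little sequence context to constrain transition
    estimates; the default threshold of 50 phrases mirrors common practice
    for this kind of corpus.
    """
    if min_phrases < 1:
        raise ValueError("min_phrases must be >= 1")
    return Corpus(
        corpus.individual_id,
        [r for r in corpus.recordings if len(r) >= min_phrases],
    )


def train_test_split(corpus: Corpus) -> SplitSpec:
    """Chronological midpoint split at whole-recording granularity.

    The recordings are concatenated in chronological order; the recording
    containing the phrase at position ``ceil(total/2)`` (1-based) and all
    preceding recordings form the training set, the remainder the testing
    set.  If the final recording contains the midpoint the split would leave
    the testing set empty; in that degenerate case the final recording is
    moved to the testing side (with a warning) so both sides are non-empty.
    """
    if len(corpus) < 2:
        raise ValueError("cannot split a corpus with fewer than 2 recordings")
    total = corpus.n_phrases
    midpoint = math.ceil(total / 2)  # 1-based phrase position
    cum = 0
    split_idx = len(corpus) - 1
    for i, rec in enumerate(corpus.recordings):
        cum += len(rec)
        if cum >= midpoint:
            split_idx = i
            break
    sources = [r.source for r in corpus.recordings]
    if split_idx == len(corpus) - 1:
        warnings.warn(
            f"midpoint of {corpus.individual_id!r} falls in the final recording; "
            "moving it to the testing set to keep both sides non-empty",
            stacklevel=2,
        )
        split_idx -= 1
    return SplitSpec(
        train=tuple(sources[: split_idx + 1]), test=tuple(sources[split_idx + 1 :])
    )


def loocv_folds(corpus: Corpus) -> list[SplitSpec]:
    """Leave-one-recording-out folds: fold *i* holds out recording *i*."""
    if len(corpus) < 2:
        raise ValueError("LOOCV needs at least 2 recordings")
    sources = [r.source for r in corpus.recordings]
    return [
        SplitSpec(
            train=tuple(s for s in sources if s != held_out), test=(held_out,)
        )
        for held_out in sources
    ]
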