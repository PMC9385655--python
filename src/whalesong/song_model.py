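"""Domain model for the unit -> phrase -> theme -> song hierarchy of humpback
whale song, together with annotation-file readers/writers.

A *unit* is one discrete vocal sound, labelled by call type (``CT`` plus a
number, optionally a lowercase subtype letter, e.g. ``CT3`` or ``CT3a``).
A *phrase* is a short ordered combination of units; its type is coded by
letters (unit identities) plus per-run repetition counts, e.g. ``Ab3,2``
for three units of the type lettered A/a followed by two of the type
lettered B/b.  A *theme* is a block of repeated phrases of one type; its
token is the letter part of the phrase code with the counts dropped.  A
*song* is one complete rendition of every unique theme in a singer's
sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, FormatError, ParseError, ValidationError

UNIT_TYPE_RE = re.compile(r"^CT[0-9]+[a-z]?$")

#: Default gap (minutes) of silence after which a new presumed singer is opened.
DEFAULT_SINGER_GAP_MIN = 60.0

RAVEN_COLUMNS = {
    "selection": "Selection",
    "begin": "Begin Time (s)",
    "end": "End Time (s)",
    "low": "Low Freq (Hz)",
    "high": "High Freq (Hz)",
}
DEFAULT_ANNOTATION_COLUMN = "Unit Type"

PROJECT_CSV_COLUMNS = [
    "session_id",
    "singer_id",
    "begin_s",
    "end_s",
    "low_hz",
    "high_hz",
    "unit_type",
    "phrase_id",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitAnnotation:
    """One logged vocalization: time/frequency bounds plus a unit-type label."""

    session_id: str
    begin_s: float
    end_s: float
    low_hz: float
    high_hz: float
    unit_type: str
    singer_id: str | None = None
    phrase_id: str | None = None

    def validate(self) -> "UnitAnnotation":
        problems = []
        if not self.begin_s < self.end_s:
            problems.append(f"begin_s {self.begin_s} !< end_s {self.end_s}")
        if not self.low_hz < self.high_hz:
            problems.append(f"low_hz {self.low_hz} !< high_hz {self.high_hz}")
        if not UNIT_TYPE_RE.match(self.unit_type):
            problems.append(f"malformed unit label {self.unit_type!r}")
        if problems:
            raise ValidationError("; ".join(problems))
        return self


@dataclass(frozen=True)
class PhraseInstance:
    """A contiguous slice of one singer's ordered unit stream.

    Indices are half-open ``[start, end)`` and 0-based over the stream.
    """

    session_id: str
    singer_id: str | None
    start: int
    end: int
    units: tuple[str, ...]

    def __post_init__(self):
        if not self.units:
            raise DomainError("phrase must contain at least one unit")
        if self.end - self.start != len(self.units):
            raise ValidationError("index span does not match unit count")


class LetterMap:
    """Bijection between unit types and code letters.

    Letters are assigned in order of first appearance: ``A`` .. ``Z``, then
    doubled letters ``AA`` .. ``ZZ`` once the single-letter alphabet is
    exhausted, preserving the uppercase/lowercase semantics of the code
    grammar.  Decoding tokenizes greedily, longest match first.
    """

    def __init__(self, unit_types: Iterable[str] = ()):  # insertion order kept
        self._to_letter: dict[str, str] = {}
        self._to_unit: dict[str, str] = {}
        for u in unit_types:
            self.letter_for(u)

    @staticmethod
    def _letter_at(i: int) -> str:
        k, r = divmod(i, 26)
        return chr(ord("A") + r) * (k + 1)

    def letter_for(self, unit_type: str, auto_extend: bool = True) -> str:
        if unit_type in self._to_letter:
            return self._to_letter[unit_type]
        if not auto_extend:
            raise DomainError(f"unit type {unit_type!r} not in letter map")
        letter = self._letter_at(len(self._to_letter))
        self._to_letter[unit_type] = letter
        self._to_unit[letter] = unit_type
        return letter

    def unit_for(self, letter: str) -> str:
        try:
            return self._to_unit[letter.upper()]
        except KeyError:
            raise DomainError(f"letter {letter!r} not in letter map") from None

    def __contains__(self, unit_type: str) -> bool:
        return unit_type in self._to_letter

    def __len__(self) -> int:
        return len(self._to_letter)

    def known_letters(self) -> list[str]:
        return list(self._to_unit)


@dataclass(frozen=True)
class PhraseTypeCode:
    """Coded phrase identity, e.g. ``Ab3,2``.

    ``code`` is the uppercase letter of the first unit run, lowercase letters
    for the following runs, then comma-separated run lengths (one per
    letter).  ``letter_part`` with the counts dropped is the theme token.
    """

    code: str
    letter_map: LetterMap = field(compare=False, hash=False, repr=False)

    @property
    def letter_part(self) -> str:
        m = re.match(r"^[^\d]+", self.code)
        return m.group(0) if m else ""

    @property
    def counts(self) -> tuple[int, ...]:
        digits = self.code[len(self.letter_part):]
        return tuple(int(c) for c in digits.split(",")) if digits else ()


@dataclass(frozen=True)
class ThemeSequence:
    """Ordered theme tokens of one singer/session, run-length collapsed."""

    singer_id: str | None
    session_id: str
    themes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.themes)


@dataclass(frozen=True)
class Song:
    """One song rendition; complete iff it contains every unique theme token
    of its parent sequence at least once."""

    singer_id: str | None
    themes: tuple[str, ...]
    complete: bool


@dataclass(frozen=True)
class RecordingCluster:
    """A (location, year, song-group) grouping of singers."""

    location: str
    year: int
    song_group: int = 1
    members: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.location}_{self.song_group}_{self.year}"


@dataclass(frozen=True)
class Repertoire:
    """The set of distinct phrase-type codes attributed to a cluster."""

    cluster: RecordingCluster
    phrase_types: frozenset[str]

    def __len__(self) -> int:
        return len(self.phrase_types)


# ---------------------------------------------------------------------------
# Phrase-type encoding / decoding
# ---------------------------------------------------------------------------


def run_length_encode(units: Sequence[str]) -> list[tuple[str, int]]:
    """Maximal runs of identical unit types, in order."""
    runs: list[tuple[str, int]] = []
    for u in units:
        if runs and runs[-1][0] == u:
            runs[-1] = (u, runs[-1][1] + 1)
        else:
            runs.append((u, 1))
    return runs


def encode_phrase_type(units: Sequence[str], letter_map: LetterMap,
                       auto_extend: bool = True) -> PhraseTypeCode:
    """Encode an ordered unit list into its phrase-type code.

    One letter is emitted per maximal run of a unit type (a re-entry of an
    earlier unit type opens a fresh run and a fresh letter slot), so the
    count list and the letter list stay aligned: ``[CT1,CT1,CT1,CT2,CT2]``
    with CT1->A, CT2->B codes as ``Ab3,2`` and ``[CT1,CT2,CT1]`` as
    ``Aba1,1,1``.
    """
    if not units:
        raise DomainError("cannot encode an empty phrase")
    runs = run_length_encode(units)
    letters = []
    for i, (unit, _count) in enumerate(runs):
        letter = letter_map.letter_for(unit, auto_extend=auto_extend)
        letters.append(letter.upper() if i == 0 else letter.lower())
    counts = ",".join(str(c) for _u, c in runs)
    return PhraseTypeCode(code="".join(letters) + counts, letter_map=letter_map)


def _tokenize_letters(letter_part: str, letter_map: LetterMap) -> list[str]:
    known = {l.upper() for l in letter_map.known_letters()}
    longest = max((len(l) for l in known), default=1)
    tokens, i = [], 0
    while i < len(letter_part):
        for width in range(longest, 0, -1):  # greedy longest match
            cand = letter_part[i:i + width].upper()
            if len(set(cand)) == 1 and cand in known:
                tokens.append(cand)
                i += width
                break
        else:
            raise DomainError(f"cannot tokenize code letters {letter_part!r}")
    return tokens


def decode_phrase_type(code: PhraseTypeCode | str,
                       letter_map: LetterMap | None = None) -> list[str]:
    """Invert :func:`encode_phrase_type`: recover the ordered unit list."""
    if isinstance(code, PhraseTypeCode):
        letter_map = letter_map or code.letter_map
        code_str = code.code
    else:
        code_str = code
    if letter_map is None:
        raise DomainError("decoding requires a letter map")
    m = re.match(r"^([^\d]+)([\d,]*)$", code_str)
    if m is None:
        raise DomainError(f"malformed phrase code {code_str!r}")
    letters = _tokenize_letters(m.group(1), letter_map)
    counts = [int(c) for c in m.group(2).split(",")] if m.group(2) else []
    if len(letters) != len(counts):
        raise DomainError(
            f"code {code_str!r}: {len(letters)} letters but {len(counts)} counts")
    units: list[str] = []
    for letter, count in zip(letters, counts):
        if count < 1:
            raise DomainError(f"non-positive repetition count in {code_str!r}")
        units.extend([letter_map.unit_for(letter)] * count)
    return units


# ---------------------------------------------------------------------------
# Theme transcription and song segmentation
# ---------------------------------------------------------------------------


def theme_token(code: PhraseTypeCode | str) -> str:
    """Letter part of a phrase code: the theme identity, counts dropped."""
    code_str = code.code if isinstance(code, PhraseTypeCode) else code
    m = re.match(r"^[^\d]+", code_str)
    return m.group(0) if m else ""


def transcribe_to_themes(phrases: Sequence[PhraseTypeCode | str],
                         singer_id: str | None = None,
                         session_id: str = "") -> ThemeSequence:
    """Reduce an ordered phrase list to its theme sequence.

    Each phrase keeps only its letter part; consecutive runs of the same
    letter part (repeated phrases of one theme) collapse to a single token.
    Empty input yields an empty sequence.
    """
    tokens: list[str] = []
    for p in phrases:
        tok = theme_token(p)
        if not tokens or tokens[-1] != tok:
            tokens.append(tok)
    return ThemeSequence(singer_id=singer_id, session_id=session_id,
                         themes=tuple(tokens))


def segment_songs(seq: ThemeSequence) -> list[Song]:
    """Greedy left-to-right segmentation into songs.

    A song closes at the first position where every theme token occurring
    anywhere in ``seq`` has appeared at least once since the song started;
    a trailing segment missing some token is returned with
    ``complete=False``.  The segments partition the input.
    """
    unique = set(seq.themes)
    if not unique:
        return []
    songs: list[Song] = []
    current: list[str] = []
    seen: set[str] = set()
    for tok in seq.themes:
        current.append(tok)
        seen.add(tok)
        if seen == unique:
            songs.append(Song(seq.singer_id, tuple(current), complete=True))
            current, seen = [], set()
    if current:
        songs.append(Song(seq.singer_id, tuple(current), complete=False))
    return songs


# ---------------------------------------------------------------------------
# Singer assignment and repertoires
# ---------------------------------------------------------------------------


def assign_singers(annotations: Sequence[UnitAnnotation],
                   gap_min: float = DEFAULT_SINGER_GAP_MIN) -> list[UnitAnnotation]:
    """Allocate presumed individual singers within one session.

    Annotations already carrying a ``singer_id`` (dipping-hydrophone data,
    differentiated in the field) are passed through untouched.  Unlabelled
    annotations are split whenever the silent gap to the previous unlabelled
    annotation exceeds ``gap_min`` minutes; singer ids ``s1``, ``s2``, ... are
    session-scoped and stable under re-runs.
    """
    if gap_min <= 0:
        raise DomainError(f"gap_min must be positive, got {gap_min}")
    out: list[UnitAnnotation] = []
    counter = 0
    prev_end: float | None = None
    for ann in sorted(annotations, key=lambda a: (a.begin_s, a.end_s)):
        if ann.singer_id is not None:
            out.append(ann)
            continue
        if prev_end is None or ann.begin_s - prev_end > gap_min * 60.0:
            counter += 1
        prev_end = ann.end_s
        out.append(replace(ann, singer_id=f"s{counter}"))
    return out


def build_repertoire(cluster: RecordingCluster,
                     phrases: Iterable[PhraseTypeCode | str]) -> Repertoire:
    """Pool the distinct phrase-type codes of all cluster members.

    Presence-only set semantics: how often a phrase type occurred is
    discarded.
    """
    codes = frozenset(
        p.code if isinstance(p, PhraseTypeCode) else p for p in phrases)
    if not codes:
        raise DomainError(f"cluster {cluster.label} has no phrases")
    return Repertoire(cluster=cluster, phrase_types=codes)


# ---------------------------------------------------------------------------
# Annotation-file I/O
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _parse_float(value, column: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric {column} value {value!r}", line=line) from None


def read_selection_table(path: str | Path, dialect: str = "raven",
                         annotation_column: str = DEFAULT_ANNOTATION_COLUMN,
                         session_id: str | None = None) -> list[UnitAnnotation]:
    """Read an annotation log into validated :class:`UnitAnnotation` rows.

    ``dialect="raven"`` expects a Raven Pro selection table: tab-separated
    with columns ``Selection``, ``Begin Time (s)``, ``End Time (s)``,
    ``Low Freq (Hz)``, ``High Freq (Hz)`` and the unit label in
    ``annotation_column``.  ``dialect="project_csv"`` expects the comma
    dialect ``session_id,singer_id,begin_s,end_s,low_hz,high_hz,unit_type,
    phrase_id`` (the last two optional per row).  Returned annotations are
    sorted by begin time.
    """
    path = Path(path)
    if dialect == "raven":
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(
            df, list(RAVEN_COLUMNS.values()) + [annotation_column], path)
        sid = session_id if session_id is not None else path.stem
        rows = []
        for idx, row in df.iterrows():
            line = int(idx) + 2  # header is line 1
            rows.append(UnitAnnotation(
                session_id=sid,
                begin_s=_parse_float(row[RAVEN_COLUMNS["begin"]], "begin time", line),
                end_s=_parse_float(row[RAVEN_COLUMNS["end"]], "end time", line),
                low_hz=_parse_float(row[RAVEN_COLUMNS["low"]], "low frequency", line),
                high_hz=_parse_float(row[RAVEN_COLUMNS["high"]], "high frequency", line),
                unit_type=str(row[annotation_column]).strip(),
            ))
    elif dialect == "project_csv":
        df = pd.read_csv(path, dtype=str)
        _require_columns(df, PROJECT_CSV_COLUMNS[:7], path)
        rows = []
        for idx, row in df.iterrows():
            line = int(idx) + 2
            singer = row.get("singer_id")
            phrase = row.get("phrase_id") if "phrase_id" in df.columns else None
            rows.append(UnitAnnotation(
                session_id=str(row["session_id"]),
                singer_id=None if pd.isna(singer) or singer == "" else str(singer),
                begin_s=_parse_float(row["begin_s"], "begin_s", line),
                end_s=_parse_float(row["end_s"], "end_s", line),
                low_hz=_parse_float(row["low_hz"], "low_hz", line),
                high_hz=_parse_float(row["high_hz"], "high_hz", line),
                unit_type=str(row["unit_type"]).strip(),
                phrase_id=None if phrase is None or pd.isna(phrase) else str(phrase),
            ))
    else:
        raise DomainError(f"unknown dialect {dialect!r}")

    bad = [a.unit_type for a in rows if not UNIT_TYPE_RE.match(a.unit_type)]
    if bad:
        raise ValidationError(f"{path}: malformed unit labels: {sorted(set(bad))}")
    for a in rows:
        a.validate()
    return sorted(rows, key=lambda a: (a.session_id, a.begin_s, a.end_s))


def annotations_to_frame(annotations: Sequence[UnitAnnotation]) -> pd.DataFrame:
    """Project-CSV-dialect DataFrame view of a list of annotations."""
    return pd.DataFrame(
        [{
            "session_id": a.session_id,
            "singer_id": a.singer_id if a.singer_id is not None else "",
            "begin_s": a.begin_s,
            "end_s": a.end_s,
            "low_hz": a.low_hz,
            "high_hz": a.high_hz,
            "unit_type": a.unit_type,
            "phrase_id": a.phrase_id if a.phrase_id is not None else "",
        } for a in annotations],
        columns=PROJECT_CSV_COLUMNS,
    )


def write_project_csv(annotations: Sequence[UnitAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False, float_format="%.3f")


def phrases_from_annotations(annotations: Sequence[UnitAnnotation]
                             ) -> list[PhraseInstance]:
    """Group one singer's time-ordered annotations into phrases by phrase_id.

    Rows must carry ``phrase_id``; consecutive rows sharing an id form one
    phrase.  Rows lacking an id raise, since phrase boundaries cannot be
    inferred from units alone.
    """
    phrases: list[PhraseInstance] = []
    anns = sorted(annotations, key=lambda a: (a.begin_s, a.end_s))
    start = 0
    i = 0
    while i < len(anns):
        pid = anns[i].phrase_id
        if pid is None:
            raise DomainError(
                "annotation without phrase_id: supply a phrase log or ids")
        j = i
        while j < len(anns) and anns[j].phrase_id == pid:
            j += 1
        phrases.append(PhraseInstance(
            session_id=anns[i].session_id,
            singer_id=anns[i].singer_id,
            start=start, end=start + (j - i),
            units=tuple(a.unit_type for a in anns[i:j]),
        ))
        start += j - i
        i = j
    return phrases
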