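"""Unit tests for the unit -> phrase -> theme -> song domain model."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from whalesong import song_model as sm
from whalesong.errors import (DomainError, FormatError, ParseError,
                              ValidationError)

UNITS = [f"CT{i}" for i in range(1, 9)]


def make_ann(begin, end=None, unit="CT1", session="s", singer=None, phrase=None):
    return sm.UnitAnnotation(
        session_id=session, singer_id=singer, begin_s=begin,
        end_s=end if end is not None else begin + 1.0,
        low_hz=100.0, high_hz=900.0, unit_type=unit, phrase_id=phrase)


# ---------------------------------------------------------------------------
# Phrase-type encoding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("units, expected", [
    (["CT1", "CT1", "CT1", "CT2", "CT2"], "Ab3,2"),
    (["CT1"], "A1"),
    (["CT1", "CT2", "CT1"], "Aba1,1,1"),   # re-entry opens a fresh run
    (["CT1", "CT1", "CT2", "CT3", "CT3", "CT3"], "Abc2,1,3"),
])
def test_encode_phrase_type(units, expected):
    lm = sm.LetterMap(["CT1", "CT2", "CT3"])
    assert sm.encode_phrase_type(units, lm).code == expected


def test_encode_single_unit_with_custom_map():
    lm = sm.LetterMap(["CT1", "CT2", "CT5"])
    assert sm.encode_phrase_type(["CT5"], lm).code == "C1"


def test_encode_empty_phrase_rejected():
    with pytest.raises(DomainError):
        sm.encode_phrase_type([], sm.LetterMap())


def test_encode_without_auto_extend_requires_known_units():
    lm = sm.LetterMap(["CT1"])
    with pytest.raises(DomainError):
        sm.encode_phrase_type(["CT2"], lm, auto_extend=False)


@given(st.lists(st.sampled_from(UNITS), min_size=1, max_size=15))
def test_encode_decode_round_trip(units):
    lm = sm.LetterMap()
    code = sm.encode_phrase_type(units, lm)
    assert sm.decode_phrase_type(code) == list(units)


def test_letter_alphabet_extends_past_26_types():
    lm = sm.LetterMap()
    units = [f"CT{i}" for i in range(1, 29)]
    for u in units:
        lm.letter_for(u)
    assert lm.letter_for("CT27") == "AA"
    code = sm.encode_phrase_type(["CT27", "CT27", "CT28"], lm)
    assert code.code == "AAbb2,1"
    assert sm.decode_phrase_type(code) == ["CT27", "CT27", "CT28"]


def test_phrase_code_parts():
    lm = sm.LetterMap(["CT1", "CT2"])
    code = sm.encode_phrase_type(["CT1", "CT1", "CT2"], lm)
    assert code.letter_part == "Ab"
    assert code.counts == (2, 1)


# ---------------------------------------------------------------------------
# Theme transcription and song segmentation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("phrases, expected", [
    (["Ab3,2", "Ab2,1", "C4"], ("Ab", "C")),
    (["C4"], ("C",)),
    ([], ()),
    (["Ab1,1", "C2", "Ab2,2"], ("Ab", "C", "Ab")),
])
def test_transcribe_to_themes(phrases, expected):
    assert sm.transcribe_to_themes(phrases).themes == expected


@given(st.lists(st.sampled_from(["Ab1,2", "Ab3,1", "C2", "De4,1", "F2"]),
                max_size=20))
def test_transcription_idempotent_on_letter_parts(phrases):
    once = sm.transcribe_to_themes(phrases)
    twice = sm.transcribe_to_themes(once.themes)
    assert once.themes == twice.themes


@pytest.mark.parametrize("themes, n_complete, n_total", [
    (("T1", "T2", "T1", "T2"), 2, 2),
    (("T1", "T1", "T1"), 3, 3),
    (("T1", "T2", "T1"), 1, 2),
])
def test_segment_songs_examples(themes, n_complete, n_total):
    seq = sm.ThemeSequence(singer_id="s1", session_id="x", themes=themes)
    songs = sm.segment_songs(seq)
    assert len(songs) == n_total
    assert sum(s.complete for s in songs) == n_complete
    # segments partition the input
    joined = tuple(t for s in songs for t in s.themes)
    assert joined == themes


@given(st.lists(st.sampled_from(["T1", "T2", "T3", "T4"]), min_size=1,
                max_size=30))
def test_segment_songs_properties(tokens):
    seq = sm.ThemeSequence(singer_id=None, session_id="x", themes=tuple(tokens))
    songs = sm.segment_songs(seq)
    unique = set(tokens)
    joined = tuple(t for s in songs for t in s.themes)
    assert joined == tuple(tokens)
    for s in songs[:-1]:
        assert s.complete
    for s in songs:
        if s.complete:
            assert set(s.themes) == unique
    rarest = min(tokens.count(t) for t in unique)
    assert sum(s.complete for s in songs) <= rarest


# ---------------------------------------------------------------------------
# Singer assignment
# ---------------------------------------------------------------------------


def test_assign_singers_gap_threshold():
    minutes = [0, 5, 200, 205]
    anns = [make_ann(m * 60.0) for m in minutes]
    out = sm.assign_singers(anns, gap_min=30)
    ids = [a.singer_id for a in out]
    assert ids == ["s1", "s1", "s2", "s2"]


def test_assign_singers_preserves_existing_labels():
    anns = [make_ann(0, singer="whale7"), make_ann(10000, singer="whale9")]
    out = sm.assign_singers(anns, gap_min=1)
    assert [a.singer_id for a in out] == ["whale7", "whale9"]


def test_assign_singers_single_unit():
    out = sm.assign_singers([make_ann(3.0)], gap_min=60)
    assert [a.singer_id for a in out] == ["s1"]


def test_assign_singers_rejects_nonpositive_gap():
    with pytest.raises(DomainError):
        sm.assign_singers([make_ann(0.0)], gap_min=-5)


@given(st.permutations(range(6)))
def test_assign_singers_order_invariant(order):
    base = [make_ann(m * 60.0) for m in [0, 2, 100, 103, 300, 301]]
    shuffled = [base[i] for i in order]
    expected = [(a.begin_s, a.singer_id)
                for a in sm.assign_singers(base, gap_min=30)]
    got = [(a.begin_s, a.singer_id)
           for a in sm.assign_singers(shuffled, gap_min=30)]
    assert sorted(got) == sorted(expected)


# ---------------------------------------------------------------------------
# Repertoires and phrase grouping
# ---------------------------------------------------------------------------


def test_build_repertoire_set_semantics():
    cluster = sm.RecordingCluster(location="E", year=2013)
    rep = sm.build_repertoire(cluster, ["Ab3,2", "Ab3,2", "C4"])
    assert rep.phrase_types == frozenset({"Ab3,2", "C4"})
    assert len(rep) == 2


def test_build_repertoire_empty_rejected():
    with pytest.raises(DomainError):
        sm.build_repertoire(sm.RecordingCluster("E", 2013), [])


def test_cluster_label_format():
    assert sm.RecordingCluster("ASSO", 2013, song_group=2).label == "ASSO_2_2013"


def test_phrases_from_annotations_groups_by_phrase_id():
    anns = [make_ann(i, unit=u, phrase=p, singer="s1")
            for i, (u, p) in enumerate([
                ("CT1", "p1"), ("CT1", "p1"), ("CT2", "p1"),
                ("CT3", "p2"), ("CT3", "p2")])]
    phrases = sm.phrases_from_annotations(anns)
    assert [p.units for p in phrases] == [("CT1", "CT1", "CT2"),
                                          ("CT3", "CT3")]
    assert [(p.start, p.end) for p in phrases] == [(0, 3), (3, 5)]


def test_phrases_require_phrase_ids():
    with pytest.raises(DomainError):
        sm.phrases_from_annotations([make_ann(0.0)])


# ---------------------------------------------------------------------------
# Annotation file I/O
# ---------------------------------------------------------------------------


def test_read_raven_selection_table(raven_file):
    path = raven_file([
        (1, "Spectrogram", 1, 0.0, 1.5, 100, 900, "CT1"),
        (2, "Spectrogram", 1, 2.0, 3.0, 100, 900, "CT1"),
        (3, "Spectrogram", 1, 4.0, 5.0, 150, 800, "CT2"),
    ])
    anns = sm.read_selection_table(path, dialect="raven")
    assert [a.unit_type for a in anns] == ["CT1", "CT1", "CT2"]
    assert [a.begin_s for a in anns] == [0.0, 2.0, 4.0]
    assert anns[0].session_id == "session1"


def test_read_raven_header_only_gives_empty_list(raven_file):
    assert sm.read_selection_table(raven_file([]), dialect="raven") == []


def test_read_raven_reversed_times_rejected(raven_file):
    path = raven_file([(1, "Sp", 1, 5.0, 3.0, 100, 900, "CT1")])
    with pytest.raises(ValidationError):
        sm.read_selection_table(path, dialect="raven")


def test_read_raven_missing_column_named_in_error(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("Selection\tView\n1\tSp\n")
    with pytest.raises(FormatError, match="Begin Time"):
        sm.read_selection_table(path, dialect="raven")


def test_read_raven_non_numeric_time_reports_line(raven_file):
    path = raven_file([
        (1, "Sp", 1, 0.0, 1.0, 100, 900, "CT1"),
        (2, "Sp", 1, "oops", 3.0, 100, 900, "CT1"),
    ])
    with pytest.raises(ParseError, match="line 3"):
        sm.read_selection_table(path, dialect="raven")


def test_read_raven_malformed_labels_listed(raven_file):
    path = raven_file([
        (1, "Sp", 1, 0.0, 1.0, 100, 900, "CT1"),
        (2, "Sp", 1, 2.0, 3.0, 100, 900, "notaunit"),
    ])
    with pytest.raises(ValidationError, match="notaunit"):
        sm.read_selection_table(path, dialect="raven")


def test_project_csv_round_trip(tmp_path):
    anns = [make_ann(0.0, unit="CT1", session="PA_2011_s1", singer="s1",
                     phrase="p1"),
            make_ann(2.0, unit="CT2a", session="PA_2011_s1", singer="s1",
                     phrase="p2")]
    path = tmp_path / "ann.csv"
    sm.write_project_csv(anns, path)
    back = sm.read_selection_table(path, dialect="project_csv")
    assert [(a.unit_type, a.singer_id, a.phrase_id) for a in back] == \
        [("CT1", "s1", "p1"), ("CT2a", "s1", "p2")]


def test_unit_annotation_invariants():
    with pytest.raises(ValidationError):
        make_ann(0.0, end=-1.0).validate()
    with pytest.raises(ValidationError):
        dataclasses.replace(make_ann(0.0), low_hz=900, high_hz=100).validate()
    with pytest.raises(ValidationError):
        make_ann(0.0, unit="CT3A").validate()   # uppercase subtype is invalid
    assert make_ann(0.0, unit="CT3a").validate()
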