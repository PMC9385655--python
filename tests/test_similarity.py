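"""Unit and property tests for the DCI and LSI similarity statistics."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, strategies as st

from whalesong import similarity as sim
from whalesong.errors import DomainError
from whalesong.song_model import RecordingCluster


def levenshtein_oracle(a, b):
    """Exhaustive-recursion edit distance, independent of the DP route."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(rec(i + 1, j) + 1,
                   rec(i, j + 1) + 1,
                   rec(i + 1, j + 1) + (a[i] != b[j]))

    return rec(0, 0)


# ---------------------------------------------------------------------------
# Dice Coincidence Index
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a, b, expected", [
    ({"P1", "P2", "P3", "P4", "P5"}, {"P1", "P2", "P3", "P4", "P5"}, 1.0),
    ({"P1", "P2"}, {"P3", "P4"}, 0.0),
    ({"P1", "P2", "P3"}, {"P2", "P3", "P4"}, 2 * 2 / 6),
])
def test_dice_examples(a, b, expected):
    assert sim.dice_coincidence(a, b) == pytest.approx(expected)
    assert sim.dice_coincidence(b, a) == pytest.approx(expected)


def test_dice_empty_repertoire_rejected():
    with pytest.raises(DomainError):
        sim.dice_coincidence(set(), {"P1"})


@given(st.sets(st.integers(0, 20), min_size=1, max_size=12),
       st.sets(st.integers(0, 20), min_size=1, max_size=12))
def test_dice_properties(a, b):
    d = sim.dice_coincidence(a, b)
    assert 0.0 <= d <= 1.0
    assert (d == 1.0) == (a == b)
    assert (d == 0.0) == (not a & b)
    assert d == sim.dice_coincidence(frozenset(a), frozenset(b))


# ---------------------------------------------------------------------------
# Token-level Levenshtein and LSI
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a, b, expected", [
    (["A", "B", "C"], ["A", "B", "C"], 0),
    ([], ["A", "B"], 2),
    (["A", "B", "C", "D"], ["A", "C", "D"], 1),
    (["Ab", "C"], ["A", "b", "C"], 2),   # tokens, not characters
])
def test_token_levenshtein_examples(a, b, expected):
    assert sim.token_levenshtein(a, b) == expected


@given(st.lists(st.sampled_from("WXYZ"), max_size=6),
       st.lists(st.sampled_from("WXYZ"), max_size=6))
def test_token_levenshtein_matches_recursion_oracle(a, b):
    assert sim.token_levenshtein(a, b) == levenshtein_oracle(a, b)


def test_levenshtein_agrees_with_edlib_on_character_sequences():
    # independent cross-check against an established alignment library
    edlib = pytest.importorskip("edlib")
    rng = np.random.default_rng(7)
    for _ in range(200):
        a = "".join(rng.choice(list("ACGT"), rng.integers(0, 12)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 12)))
        assert sim.token_levenshtein(a, b) == \
            edlib.align(a, b, task="distance")["editDistance"]


@pytest.mark.parametrize("a, b, expected", [
    (["A", "B"], ["A", "B"], 1.0),
    (["A"], ["B"], 0.0),
    (["A", "B", "C", "D"], ["A", "C", "D"], 0.75),
])
def test_lsi_examples(a, b, expected):
    assert sim.lsi(a, b) == pytest.approx(expected)


def test_lsi_undefined_for_two_empty_sequences():
    with pytest.raises(DomainError):
        sim.lsi([], [])


@given(st.lists(st.sampled_from(["T1", "T2", "T3"]), max_size=8),
       st.lists(st.sampled_from(["T1", "T2", "T3"]), min_size=1, max_size=8))
def test_lsi_properties(a, b):
    v = sim.lsi(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(sim.lsi(b, a))
    assert sim.lsi(b, b) == 1.0
    dist = sim.token_levenshtein(a, b)
    assert (v == 0.0) == (dist == max(len(a), len(b)))


# ---------------------------------------------------------------------------
# Set median string
# ---------------------------------------------------------------------------


def test_set_median_singleton():
    res = sim.set_median([("A", "B")])
    assert res.sequence == ("A", "B")
    assert res.ties == (("A", "B"),)


def test_set_median_majority_wins():
    s, t = ("A", "B", "C"), ("A", "B", "D")
    res = sim.set_median([s, s, t])
    assert res.sequence == s


def test_set_median_tie_broken_by_input_order():
    s, t = ("A", "B"), ("C", "D")
    res = sim.set_median([s, t])
    assert res.sequence == s
    assert set(res.ties) == {s, t}
    assert res.index == 0


def test_set_median_empty_rejected():
    with pytest.raises(DomainError):
        sim.set_median([])


@given(st.lists(
    st.lists(st.sampled_from(["T1", "T2", "T3"]), min_size=1, max_size=5),
    min_size=1, max_size=8))
def test_set_median_achieves_maximal_score(seqs):
    res = sim.set_median(seqs)
    members = [tuple(s) for s in seqs]
    assert res.sequence in members
    for cand in members:
        score = sum(sim.lsi(cand, other) for other in members)
        assert res.score >= score - 1e-12


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------


def test_similarity_matrix_identical_items():
    m = sim.similarity_matrix([{"P1"}, {"P1"}], "dice", labels=["a", "b"])
    assert np.allclose(m.values, 1.0)
    assert m.mode == "DCI"


def test_similarity_matrix_dice_values():
    reps = [{"P1", "P2", "P3"}, {"P2", "P3", "P4"}, {"P9"}]
    m = sim.similarity_matrix(reps, "dice")
    assert m.values[0, 1] == pytest.approx(2 / 3)
    assert m.values[0, 2] == 0.0
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 1.0)


def test_similarity_matrix_single_item_rejected():
    with pytest.raises(DomainError):
        sim.similarity_matrix([{"P1"}], "dice")


def test_similarity_matrix_unknown_metric_rejected():
    with pytest.raises(TypeError):
        sim.similarity_matrix([{"P1"}, {"P2"}], "cosine")


def test_similarity_matrix_metric_domain_mismatch_rejected():
    with pytest.raises(TypeError):
        sim.similarity_matrix([{"P1"}, {"P2"}], "lsi")


def test_similarity_matrix_csv_round_trip(tmp_path):
    m = sim.similarity_matrix([("A", "B"), ("A", "C")], "lsi",
                              labels=["W13_05-Jun-2013", "E_2013"])
    path = tmp_path / "m.csv"
    m.to_csv(path)
    back = sim.SimilarityMatrix.from_csv(path, mode="LSI")
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values)


# ---------------------------------------------------------------------------
# Song-group splitting
# ---------------------------------------------------------------------------


def test_split_song_groups_all_connected():
    cluster = RecordingCluster("ASSO", 2013)
    out = sim.split_song_groups(cluster, {
        "w1": {"A1", "B1"}, "w2": {"B1", "C1"}, "w3": {"C1"}})
    assert len(out) == 1
    assert out[0].song_group == 1
    assert set(out[0].members) == {"w1", "w2", "w3"}


def test_split_song_groups_two_disjoint_blocks():
    cluster = RecordingCluster("ASSO", 2013)
    out = sim.split_song_groups(
        cluster,
        {"w1": {"A1"}, "w2": {"A1", "B1"}, "w3": {"Z1"}},
        singer_dates={"w1": 1, "w2": 2, "w3": 0})
    assert [c.song_group for c in out] == [1, 2]
    assert set(out[0].members) == {"w1", "w2"}   # larger group first
    assert set(out[1].members) == {"w3"}


def test_split_song_groups_singleton():
    out = sim.split_song_groups(RecordingCluster("E", 2013), {"w1": {"A1"}})
    assert len(out) == 1 and out[0].members == ("w1",)


@given(st.dictionaries(
    st.sampled_from([f"w{i}" for i in range(6)]),
    st.sets(st.integers(0, 5), min_size=1, max_size=3),
    min_size=1, max_size=6))
def test_split_song_groups_partitions_singers(reps):
    out = sim.split_song_groups(RecordingCluster("ASSO", 2013), reps)
    all_members = [m for c in out for m in c.members]
    assert sorted(all_members) == sorted(reps)
    # zero similarity across any two distinct groups
    for i, ci in enumerate(out):
        for cj in out[i + 1:]:
            for a in ci.members:
                for b in cj.members:
                    assert not (set(reps[a]) & set(reps[b]))


def test_percentage_rounding_half_up():
    assert sim.as_percentage(2 / 3) == 66.7
    assert sim.as_percentage(0.125) == 12.5
    assert sim.as_percentage(1.0) == 100.0
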