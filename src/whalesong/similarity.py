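"""Similarity statistics for song comparison.

Two statistics drive the analyses:

* the Dice Coincidence Index over phrase repertoires,
  ``DCI = 2A / (B + C)`` with ``A`` the number of shared phrase types and
  ``B``, ``C`` the two repertoire sizes; and
* the Levenshtein Distance Similarity Index over theme sequences,
  ``LSI(a, b) = 1 - min(I + D + S) / max(L(a), L(b))`` where ``I``, ``D``
  and ``S`` are the insertions, deletions and substitutions of a cheapest
  edit script and ``L`` the sequence lengths.

The edit distance operates on theme *tokens*, not characters: themes are
multi-character labels and sequences of themes are what gets compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError
from .song_model import RecordingCluster, Repertoire, ThemeSequence


def _as_set(rep) -> frozenset:
    if isinstance(rep, Repertoire):
        return rep.phrase_types
    return frozenset(rep)


def _as_tokens(seq) -> tuple:
    if isinstance(seq, ThemeSequence):
        return seq.themes
    return tuple(seq)


def dice_coincidence(rep_a, rep_b) -> float:
    """Dice Coincidence Index ``2A/(B+C)`` between two phrase repertoires.

    Presence-only set semantics; 1 iff the sets are equal, 0 iff disjoint.
    """
    a, b = _as_set(rep_a), _as_set(rep_b)
    if not a or not b:
        raise DomainError("DCI is undefined for an empty repertoire")
    return 2.0 * len(a & b) / (len(a) + len(b))


def token_levenshtein(a: Sequence[Hashable], b: Sequence[Hashable]) -> int:
    """Unit-cost edit distance ``min(I+D+S)`` over token sequences.

    Standard dynamic programme over a (len(a)+1) x (len(b)+1) table; tokens
    are compared by equality, so multi-character theme labels count as
    single symbols.
    """
    a, b = _as_tokens(a), _as_tokens(b)
    if len(a) < len(b):  # keep the rolling row short
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, tb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1,          # deletion
                         cur[j - 1] + 1,       # insertion
                         prev[j - 1] + (ta != tb))  # substitution / match
        prev = cur
    return prev[-1]


def lsi(a, b) -> float:
    """Levenshtein Distance Similarity Index between two theme sequences.

    ``1 - editdistance / max(L(a), L(b))``; symmetric, in [0, 1], and 0
    exactly when the edit distance equals the longer length.
    """
    ta, tb = _as_tokens(a), _as_tokens(b)
    denom = max(len(ta), len(tb))
    if denom == 0:
        raise DomainError("LSI is undefined for two empty sequences")
    return 1.0 - token_levenshtein(ta, tb) / denom


@dataclass(frozen=True)
class MedianStringResult:
    """Outcome of set-median selection: the chosen member, its summed-LSI
    score, and every member achieving that score (the tie set)."""

    sequence: tuple
    score: float
    index: int
    ties: tuple[tuple, ...]


def set_median(seqs: Sequence) -> MedianStringResult:
    """Set median string: the member with the highest summed LSI to the set.

    The sum includes self-similarity (a constant +1 per candidate, so it
    cannot change the argmax).  Ties are broken by stable input order — the
    earliest sequence wins — and the full tie set is reported.
    """
    members = [_as_tokens(s) for s in seqs]
    if not members:
        raise DomainError("set median of an empty set is undefined")
    scores = []
    for cand in members:
        scores.append(sum(lsi(cand, other) for other in members))
    best = max(scores)
    ties = tuple(m for m, s in zip(members, scores) if np.isclose(s, best))
    idx = int(np.argmax(scores))
    return MedianStringResult(sequence=members[idx], score=float(scores[idx]),
                              index=idx, ties=ties)


@dataclass
class SimilarityMatrix:
    """Labelled symmetric similarity matrix with unit diagonal."""

    labels: list[str]
    values: np.ndarray
    mode: str  # "DCI" or "LSI"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DomainError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise DomainError("similarity matrix must be symmetric")
        self.values = v

    def to_distance(self) -> np.ndarray:
        return 1.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, mode: str = "DCI") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(), mode=mode)


def similarity_matrix(items: Sequence, metric: str,
                      labels: Sequence[str] | None = None) -> SimilarityMatrix:
    """All-pairs similarity matrix under ``metric`` ("dice" or "lsi").

    Each unordered pair is computed once and mirrored; the diagonal is 1.
    """
    if len(items) < 2:
        raise DomainError("similarity matrix needs at least 2 items")
    metric = metric.lower()
    if metric in ("dice", "dci"):
        if any(isinstance(it, ThemeSequence) for it in items):
            raise TypeError("theme sequences cannot enter a DCI matrix")
        prepared = [_as_set(it) for it in items]
        fn, mode = dice_coincidence, "DCI"
    elif metric == "lsi":
        if any(isinstance(it, (Repertoire, set, frozenset)) for it in items):
            raise TypeError("repertoires cannot enter an LSI matrix")
        prepared = [_as_tokens(it) for it in items]
        fn, mode = lsi, "LSI"
    else:
        raise TypeError(f"unknown metric {metric!r}")

    n = len(prepared)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fn(prepared[i], prepared[j])
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    return SimilarityMatrix(labels=list(labels), values=m, mode=mode)


def split_song_groups(cluster: RecordingCluster,
                      singer_repertoires: Mapping[str, Iterable[str]],
                      singer_dates: Mapping[str, object] | None = None,
                      ) -> list[RecordingCluster]:
    """Split a location-year cluster into song groups.

    Singers are nodes of a graph with an edge whenever their pairwise DCI
    exceeds 0 (i.e. they share at least one phrase type); connected
    components are the song groups, numbered 1..k by size descending with
    ties broken by earliest recording date (or singer label when no dates
    are given).
    """
    singers = list(singer_repertoires)
    if not singers:
        raise DomainError("cannot split an empty cluster")
    sets = {s: _as_set(singer_repertoires[s]) for s in singers}
    g = nx.Graph()
    g.add_nodes_from(singers)
    for i, si in enumerate(singers):
        for sj in singers[i + 1:]:
            if sets[si] & sets[sj]:
                g.add_edge(si, sj)
    comps = [sorted(c) for c in nx.connected_components(g)]

    def sort_key(comp):
        if singer_dates:
            earliest = min(singer_dates[s] for s in comp if s in singer_dates)
        else:
            earliest = min(comp)
        return (-len(comp), earliest, comp[0])

    comps.sort(key=sort_key)
    return [
        RecordingCluster(location=cluster.location, year=cluster.year,
                         song_group=k, members=tuple(comp))
        for k, comp in enumerate(comps, start=1)
    ]


def as_percentage(similarity: float) -> float:
    """Report-scale similarity: x100, rounded half-up to one decimal."""
    import decimal
    d = decimal.Decimal(similarity * 100).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    return float(d)
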