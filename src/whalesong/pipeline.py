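"""End-to-end orchestration of the two comparative analyses.

*Repertoire analysis*: location-year clusters (the focal feeding-ground
location additionally split into song groups that share no phrase types),
pooled phrase repertoires, pairwise Dice Coincidence Index, UPGMA on
1 - DCI, multiscale bootstrap over phrase-type columns, AU flags at 0.95.

*Structure analysis* (per focal year): theme sequences per singer reduced
to set-median strings; breeding-ground locations further reduced to one
median per location-year; focal-ground and migration-route singers enter
individually; items from the focal year plus or minus one year; pairwise
LSI, UPGMA, multiscale bootstrap over each singer's set of complete songs.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import similarity, song_model
from .clustering import (DEFAULT_NBOOT, DEFAULT_SCALES, Dendrogram,
                         bootstrap_dci, multiscale_bootstrap,
                         support_from_bootstrap, support_table, upgma)  # noqa: F401 re-exported surface
from .errors import AnalysisError, DomainError
from .similarity import SimilarityMatrix, set_median, similarity_matrix, lsi
from .song_model import (LetterMap, RecordingCluster, Song, ThemeSequence,
                         UnitAnnotation, assign_singers,
                         phrases_from_annotations, read_selection_table,
                         transcribe_to_themes, segment_songs)

log = logging.getLogger("whalesong")

MIN_DISTINCT_THEMES = 2  # sessions below this are excluded from structure


@dataclass
class AnalysisConfig:
    """Inputs and knobs for one analysis run."""

    annotations: object                      # path, DataFrame or list
    metadata: object                         # path or DataFrame
    focal_location: str
    breeding_locations: tuple[str, ...] = ()
    migration_locations: tuple[str, ...] = ()
    gap_min: float = song_model.DEFAULT_SINGER_GAP_MIN
    nboot: int = DEFAULT_NBOOT
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 0
    focal_year_window: int = 0   # extra years of focal singers in structure runs
    merge_subtypes: bool = False  # collapse CT3a -> CT3 before encoding
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.nboot < 100:
            raise DomainError("nboot must be >= 100")


@dataclass
class SingerData:
    """Everything derived from one singer's annotation stream."""

    session_id: str
    singer_id: str
    location: str
    year: int
    position: str
    date: str
    codes: list[str]
    theme_seq: ThemeSequence
    songs: list[Song]
    repertoire: frozenset[str]

    @property
    def label(self) -> str:
        return f"{self.position}_{self.date}"

    @property
    def distinct_themes(self) -> int:
        return len(set(self.theme_seq.themes))

    def complete_song_tokens(self) -> list[tuple[str, ...]]:
        """Complete songs as token tuples; falls back to the whole sequence
        when no rendition was complete (median inputs must not be empty)."""
        out = [s.themes for s in self.songs if s.complete]
        return out if out else [self.theme_seq.themes]


@dataclass
class AnalysisResult:
    kind: str
    labels: list[str]
    matrix: SimilarityMatrix
    tree: Dendrogram
    support: dict
    newick: str
    excluded: list[dict]
    info: dict = field(default_factory=dict)
    song_groups: dict[str, list[str]] | None = None

    def support_frame(self) -> pd.DataFrame:
        return support_table(self.tree, self.support)


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------


def _load_annotations(source) -> list[UnitAnnotation]:
    if isinstance(source, (str, Path)):
        return read_selection_table(source, dialect="project_csv")
    if isinstance(source, pd.DataFrame):
        rows = []
        for _, r in source.iterrows():
            singer = r.get("singer_id", "")
            phrase = r.get("phrase_id", "")
            rows.append(UnitAnnotation(
                session_id=str(r["session_id"]),
                singer_id=str(singer) if singer not in ("", None) and not pd.isna(singer) else None,
                begin_s=float(r["begin_s"]), end_s=float(r["end_s"]),
                low_hz=float(r["low_hz"]), high_hz=float(r["high_hz"]),
                unit_type=str(r["unit_type"]),
                phrase_id=str(phrase) if phrase not in ("", None) and not pd.isna(phrase) else None,
            ).validate())
        return rows
    return [a.validate() for a in source]


def _load_metadata(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        meta = pd.read_csv(source, dtype={"session_id": str, "location": str})
    else:
        meta = source.copy()
    if "position" not in meta.columns:
        meta["position"] = meta["location"].astype(str)
    if "date" not in meta.columns:
        meta["date"] = meta["year"].astype(str)
    meta["year"] = meta["year"].astype(int)
    return meta


def prepare_singers(config: AnalysisConfig
                    ) -> tuple[list[SingerData], LetterMap, list[dict]]:
    """Parse annotations, allocate singers, encode phrases, transcribe
    themes and segment songs for every singer in the dataset.

    One shared letter map is built across the dataset in order of first
    appearance, so phrase codes are comparable between locations.  Singers
    whose theme inventory has fewer than two distinct themes are flagged
    for exclusion from the structure analysis (they cannot form a rhythmic
    song), with the reason recorded.
    """
    annotations = _load_annotations(config.annotations)
    meta = _load_metadata(config.metadata)
    meta_by_session = {str(r["session_id"]): r for _, r in meta.iterrows()}

    by_session: dict[str, list[UnitAnnotation]] = {}
    for a in annotations:
        by_session.setdefault(a.session_id, []).append(a)

    letter_map = LetterMap()
    singers: list[SingerData] = []
    excluded: list[dict] = []
    for session_id in sorted(by_session):
        if session_id not in meta_by_session:
            raise AnalysisError(f"session {session_id!r} missing from metadata")
        row = meta_by_session[session_id]
        anns = assign_singers(by_session[session_id], gap_min=config.gap_min)
        per_singer: dict[str, list[UnitAnnotation]] = {}
        for a in anns:
            per_singer.setdefault(a.singer_id, []).append(a)
        for singer_id in sorted(per_singer):
            phrases = phrases_from_annotations(per_singer[singer_id])
            codes = []
            for p in phrases:
                units = p.units
                if config.merge_subtypes:
                    units = tuple(u.rstrip("abcdefghijklmnopqrstuvwxyz")
                                  for u in units)
                codes.append(
                    song_model.encode_phrase_type(units, letter_map).code)
            seq = transcribe_to_themes(codes, singer_id=singer_id,
                                       session_id=session_id)
            sd = SingerData(
                session_id=session_id, singer_id=singer_id,
                location=str(row["location"]), year=int(row["year"]),
                position=str(row["position"]), date=str(row["date"]),
                codes=codes, theme_seq=seq, songs=segment_songs(seq),
                repertoire=frozenset(codes))
            singers.append(sd)
            if sd.distinct_themes < MIN_DISTINCT_THEMES:
                excluded.append({
                    "session_id": session_id, "singer_id": singer_id,
                    "reason": f"only {sd.distinct_themes} distinct theme(s); "
                              "excluded from structure analysis"})
                log.warning("session %s singer %s: %s", session_id, singer_id,
                            excluded[-1]["reason"])
    log.info("prepared %d singers from %d sessions (%d phrases, %d unit types)",
             len(singers), len(by_session),
             sum(len(s.codes) for s in singers), len(letter_map))
    return singers, letter_map, excluded


# ---------------------------------------------------------------------------
# Repertoire analysis (Dice Coincidence Index)
# ---------------------------------------------------------------------------


def _parse_date(date: str) -> object:
    for fmt in ("%d-%b-%Y", "%Y-%m-%d"):
        try:
            return _dt.datetime.strptime(date, fmt).date()
        except ValueError:
            continue
    return date


def build_clusters(singers: Sequence[SingerData], focal_location: str
                   ) -> list[tuple[RecordingCluster, frozenset[str]]]:
    """Location-year clusters with pooled repertoires; the focal location is
    split into song groups by zero-overlap connected components."""
    groups: dict[tuple[str, int], list[SingerData]] = {}
    for s in singers:
        groups.setdefault((s.location, s.year), []).append(s)

    clusters: list[tuple[RecordingCluster, frozenset[str]]] = []
    for (loc, year) in sorted(groups):
        members = groups[(loc, year)]
        base = RecordingCluster(location=loc, year=year,
                                members=tuple(s.label for s in members))
        if loc == focal_location and len(members) > 1:
            reps = {s.label: s.repertoire for s in members}
            dates = {s.label: _parse_date(s.date) for s in members}
            split = similarity.split_song_groups(base, reps, singer_dates=dates)
            by_label = {s.label: s for s in members}
            for sub in split:
                pooled = frozenset().union(
                    *(by_label[l].repertoire for l in sub.members))
                clusters.append((sub, pooled))
        else:
            pooled = frozenset().union(*(s.repertoire for s in members))
            clusters.append((base, pooled))
    return clusters


def incidence_matrix(repertoires: Sequence[frozenset[str]]
                     ) -> tuple[np.ndarray, list[str]]:
    """Clusters x phrase-types 0/1 matrix over the sorted feature union."""
    features = sorted(frozenset().union(*repertoires))
    m = np.zeros((len(repertoires), len(features)))
    index = {f: j for j, f in enumerate(features)}
    for i, rep in enumerate(repertoires):
        for f in rep:
            m[i, index[f]] = 1.0
    return m, features


def run_repertoire_analysis(config: AnalysisConfig) -> AnalysisResult:
    """The repertoire workflow: clusters -> DCI matrix -> UPGMA -> AU."""
    singers, letter_map, excluded = prepare_singers(config)
    clusters = build_clusters(singers, config.focal_location)
    if len(clusters) < 2:
        raise AnalysisError("repertoire analysis needs at least 2 clusters")
    labels = [c.label for c, _rep in clusters]
    reps = [rep for _c, rep in clusters]
    inc, features = incidence_matrix(reps)

    matrix = similarity_matrix(reps, "dice", labels=labels)
    boot = bootstrap_dci(inc, labels, nboot=config.nboot,
                         scales=config.scales, seed=config.seed)
    support = support_from_bootstrap(boot)
    newick = boot.tree.to_newick(support)

    focal_labels = [c.label for c, _ in clusters
                    if c.location == config.focal_location]
    partners = top_partners(matrix, focal_labels)
    song_groups = {
        c.label: list(c.members) for c, _ in clusters
        if c.location == config.focal_location}
    log.info("repertoire analysis: %d clusters, %d phrase types",
             len(labels), len(features))
    return AnalysisResult(
        kind="repertoire", labels=labels, matrix=matrix, tree=boot.tree,
        support=support, newick=newick, excluded=excluded,
        song_groups=song_groups,
        info={"n_phrase_types": len(features), "n_singers": len(singers),
              "n_unit_types": len(letter_map), "top_partners": partners,
              "nboot": config.nboot, "scales": list(config.scales),
              "seed": config.seed, "gap_min": config.gap_min,
              "resampling": "phrase-type columns of the incidence matrix"})


def top_partners(matrix: SimilarityMatrix, focal_labels: Sequence[str]
                 ) -> list[dict]:
    """For each focal cluster, the highest-DCI cluster at another location —
    ranked similarity only, not a migration claim."""
    out = []
    loc = lambda label: label.split("_")[0]
    for fl in focal_labels:
        i = matrix.labels.index(fl)
        best, best_sim = None, -1.0
        for j, other in enumerate(matrix.labels):
            if j == i or loc(other) == loc(fl):
                continue
            if matrix.values[i, j] > best_sim:
                best, best_sim = other, float(matrix.values[i, j])
        if best is not None:
            out.append({"focal": fl, "partner": best,
                        "dci": best_sim,
                        "dci_pct": similarity.as_percentage(best_sim)})
    return out


# ---------------------------------------------------------------------------
# Structure analysis (Levenshtein similarity of theme sequences)
# ---------------------------------------------------------------------------


@dataclass
class StructureItem:
    """One tip of the structure dendrogram.

    ``singer_song_sets`` holds, per underlying singer, the set of complete
    songs that the bootstrap resamples; the representative sequence is the
    set median (for location-year items, the median of the singer
    medians)."""

    label: str
    singer_song_sets: list[list[tuple[str, ...]]]

    def representative(self) -> tuple[str, ...]:
        medians = [set_median(s).sequence for s in self.singer_song_sets]
        if len(medians) == 1:
            return medians[0]
        return set_median(medians).sequence


def assemble_structure_items(singers: Sequence[SingerData],
                             config: AnalysisConfig, focal_year: int,
                             excluded_keys: set[tuple[str, str]]
                             ) -> list[StructureItem]:
    window = range(focal_year - 1, focal_year + 2)
    items: list[StructureItem] = []
    breeding_groups: dict[tuple[str, int], list[SingerData]] = {}
    for s in sorted(singers, key=lambda x: (x.location, x.year, x.label)):
        if (s.session_id, s.singer_id) in excluded_keys:
            continue
        if s.location == config.focal_location:
            if abs(s.year - focal_year) > config.focal_year_window:
                continue
            items.append(StructureItem(
                label=s.label, singer_song_sets=[s.complete_song_tokens()]))
        elif s.location in config.breeding_locations:
            if s.year in window:
                breeding_groups.setdefault((s.location, s.year), []).append(s)
        else:  # migration routes / mid-latitude feeding grounds
            if (config.migration_locations
                    and s.location not in config.migration_locations):
                continue  # location with no declared role in this analysis
            if s.year in window:
                items.append(StructureItem(
                    label=s.label, singer_song_sets=[s.complete_song_tokens()]))
    for (loc, year) in sorted(breeding_groups):
        members = breeding_groups[(loc, year)]
        items.append(StructureItem(
            label=f"{loc}_{year}",
            singer_song_sets=[m.complete_song_tokens() for m in members]))
    return items


def run_structure_analysis(config: AnalysisConfig, focal_year: int
                           ) -> AnalysisResult:
    """The song-structure workflow for one focal year: set medians ->
    LSI matrix -> UPGMA -> AU, resampling each singer's song set."""
    singers, _letter_map, excluded = prepare_singers(config)
    if not any(s.location == config.focal_location and s.year == focal_year
               for s in singers):
        raise AnalysisError(
            f"no {config.focal_location} singers recorded in {focal_year}")
    excluded_keys = {(e["session_id"], e["singer_id"]) for e in excluded}
    items = assemble_structure_items(singers, config, focal_year, excluded_keys)
    if len(items) < 2:
        raise AnalysisError("structure analysis needs at least 2 items")

    labels = [it.label for it in items]
    reps = [it.representative() for it in items]
    matrix = similarity_matrix(reps, "lsi", labels=labels)
    observed = upgma(matrix.to_distance(), labels)

    def replicate(r: float, rng: np.random.Generator) -> Dendrogram:
        seqs = []
        for it in items:
            medians = []
            for songs in it.singer_song_sets:
                size = int(np.rint(r * len(songs)))
                if size < 1:
                    raise DomainError(
                        f"scale {r} gives resample size 0 for item {it.label}")
                pick = [songs[i] for i in rng.integers(0, len(songs), size)]
                medians.append(set_median(pick).sequence)
            seqs.append(medians[0] if len(medians) == 1
                        else set_median(medians).sequence)
        n = len(seqs)
        m = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = lsi(seqs[i], seqs[j])
        return upgma(1.0 - m, labels)

    boot = multiscale_bootstrap(observed, replicate, nboot=config.nboot,
                                scales=config.scales, seed=config.seed)
    support = support_from_bootstrap(boot)
    newick = observed.to_newick(support)
    log.info("structure analysis %d: %d items", focal_year, len(items))
    return AnalysisResult(
        kind="structure", labels=labels, matrix=matrix, tree=observed,
        support=support, newick=newick, excluded=excluded,
        info={"focal_year": focal_year, "nboot": config.nboot,
              "scales": list(config.scales), "seed": config.seed,
              "gap_min": config.gap_min,
              "resampling": "per-singer complete-song sets (a reasoned "
                            "choice; the resampling unit is not standardized)"})


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def parse_cluster_label(label: str) -> tuple[str, int, int]:
    """Invert repertoire labels 'LOC_group_year'."""
    loc, group, year = label.rsplit("_", 2)
    return loc, int(group), int(year)


def parse_item_label(label: str) -> tuple[str, str]:
    """Invert structure labels 'position_date' / 'LOC_year'."""
    pos, date = label.split("_", 1)
    return pos, date


def write_report(result: AnalysisResult, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix CSV, Newick, node-support CSV, JSON report and a plain
    summary.  Deterministic inputs give byte-identical JSON."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover
        raise IOError(f"cannot create output directory {out}: {e}") from e
    stem = result.kind
    if result.kind == "structure":
        stem = f"structure_{result.info.get('focal_year', 'all')}"
    paths = {
        "matrix": out / f"{stem}_similarity.csv",
        "newick": out / f"{stem}.nwk",
        "support": out / f"{stem}_support.csv",
        "report": out / f"{stem}_report.json",
        "summary": out / f"{stem}_summary.txt",
    }
    result.matrix.to_csv(paths["matrix"])
    paths["newick"].write_text(result.newick + "\n")
    sup = result.support_frame()
    sup.to_csv(paths["support"], index=False, float_format="%.6f")

    report = {
        "kind": result.kind,
        "labels": result.labels,
        "info": result.info,
        "matrix": [[round(float(v), 10) for v in row]
                   for row in result.matrix.values],
        "newick": result.newick,
        "support": [
            {k: (round(v, 10) if isinstance(v, float) and np.isfinite(v)
                 else (None if isinstance(v, float) else v))
             for k, v in rec.items()}
            for rec in sup.to_dict(orient="records")],
        "song_groups": result.song_groups,
        "excluded": result.excluded,
        "note": "AU values are reported per node without multiple-testing "
                "correction; ranked similarities are not migration claims.",
    }
    paths["report"].write_text(json.dumps(report, indent=1, sort_keys=True,
                                          allow_nan=False))

    lines = [f"{result.kind} analysis: {len(result.labels)} items"]
    likely = sup[sup["likely"]]
    lines.append(f"nodes with AU > 95%: {len(likely)} of {len(sup)}")
    for rec in result.info.get("top_partners", []):
        lines.append(f"  {rec['focal']}: highest-DCI partner "
                     f"{rec['partner']} ({rec['dci_pct']}%)")
    lines.append(f"excluded: {json.dumps(result.excluded)}")
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
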