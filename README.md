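# whalesong

Comparative analysis of humpback whale (*Megaptera novaeangliae*) song for
studying population mixing on shared feeding grounds.

Male humpbacks sing population-specific, rapidly evolving songs. When songs
recorded at a high-latitude feeding ground resemble songs from a particular
breeding population, that is evidence the two groups were in acoustic
contact — most plausibly because members of that population migrated to the
feeding area. This package implements the full desk side of that analysis
for annotation logs of song recordings (no audio processing):

1. **Transcription** — classified song units (`CT1`, `CT3a`, ...) are grouped
   into phrases, coded by unit identity and repetition (`Ab3,2`), reduced to
   theme tokens (`Ab`), and segmented into songs (one complete rendition of
   every unique theme).
2. **Repertoire similarity** — location-year(-song-group) clusters are
   compared with the Dice Coincidence Index over phrase-type sets,

   DCI = 2A / (B + C),

   with `A` the number of shared phrase types and `B`, `C` the two repertoire
   sizes.
3. **Structure similarity** — theme sequences are compared with the
   Levenshtein Distance Similarity Index,

   LSI(a, b) = 1 − min(I + D + S) / max(L(a), L(b)),

   over theme tokens (`I`, `D`, `S`: insertions, deletions, substitutions;
   `L`: sequence length), with singers represented by their set median
   string — the member sequence maximizing summed LSI to its set.
4. **Clustering with support** — UPGMA (average linkage) on 1 − similarity,
   with a multiscale bootstrap (default 10 scales × 1000 replicates)
   yielding approximately-unbiased (AU) p-values per node; nodes with
   AU > 95% are flagged as divisions likely to occur.
5. **Simulation** — a forward simulator of multi-population song evolution
   with planted feeding-ground mixing events emits annotation files plus
   ground truth, so every stage is testable end to end without field
   recordings.

## Worked example

Simulate three populations over five years in which population PA's song is
partially adopted (α = 0.8) by population PB in 2013, then run the
repertoire analysis:

```python
from whalesong import (AnalysisConfig, MixingEvent, SimulationConfig,
                       run_repertoire_analysis, simulate_song_evolution)

sim = SimulationConfig(seed=1, mixing_events=(MixingEvent("PA", "PB", 2013, 0.8),))
dataset, truth = simulate_song_evolution(sim)

config = AnalysisConfig(annotations=dataset.annotations,
                        metadata=dataset.metadata,
                        focal_location="PA", nboot=1000, seed=1)
result = run_repertoire_analysis(config)

m = result.matrix.to_frame()
print(round(m.loc["PA_1_2013", "PB_1_2013"], 4))
print(round(m.loc["PA_1_2012", "PA_1_2013"], 4))
support = result.support[frozenset({"PA_1_2013", "PB_1_2013"})]
print(round(support.au, 3), support.likely)
```

prints

```
0.8333
0.3333
1.0 True
```

The mixed pair-year (`PA_1_2013` vs `PB_1_2013`) shows a Dice overlap of
0.83 — far above the zero baseline between populations and above the 0.33
within-population carry-over from 2012 — and its node in the UPGMA
dendrogram is supported with AU = 1.0 (> 0.95, "likely"). The same
objects carry the labelled similarity matrix (CSV), the support-annotated
Newick tree and a JSON report via `write_report(result, out_dir)`.

The CLI wraps the same workflow:

```sh
whalesong simulate --out data --seed 1 --mixing PA:PB:2013:0.8
whalesong repertoire --annotations data/annotations.csv \
    --metadata data/metadata.csv --focal PA --out results
whalesong structure --annotations data/annotations.csv \
    --metadata data/metadata.csv --focal PA --year 2013 --out results
```

## Layout

- `src/whalesong/song_model.py` — domain types, annotation I/O, phrase
  encoding, theme transcription, song segmentation, singer assignment
- `src/whalesong/similarity.py` — DCI, token Levenshtein, LSI, set median,
  similarity matrices, song-group splitting
- `src/whalesong/clustering.py` — UPGMA, multiscale bootstrap, AU fitting,
  Newick export
- `src/whalesong/simulate.py` — song-evolution simulator with mixing events
- `src/whalesong/pipeline.py`, `cli.py` — the two comparative workflows
  and their command-line front end
- `src/whalesong/evaluation.py` — simulation studies (calibration, power,
  recovery)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
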