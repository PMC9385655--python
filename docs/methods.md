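# Methods

## The transcription model

The package operates on manually classified song units; everything acoustic
(spectrograms, unit classification, signal-to-noise screening) is upstream
of its inputs. The input contract assumes recordings were screened for
quality (SNR ≥ 10 dB) and contain at least two discernible themes; sessions
whose transcribed theme inventory has fewer than two distinct tokens are
flagged and excluded from structure analysis, since a single repeated
vocalization does not form a rhythmic song.

**Units → phrases.** Units are labelled `CT<number>` with an optional
lowercase subtype letter. Phrase boundaries come from the annotation source
(a `phrase_id` column or a companion phrase log); the package does not
infer them. A phrase code pairs one letter per *maximal run* of a unit type
with one repetition count per run (`Ab3,2` = three of unit-A, two of
unit-B). When a unit type recurs non-contiguously, the re-entry opens a
fresh run and a fresh letter slot (`Aba1,1,1`), keeping the letter list and
count list aligned and the code decodable. This run-based convention is a
package decision; the coding grammar it extends does not specify the
non-contiguous case. Letter maps are dataset-scoped bijections assigned in
order of first appearance; past 26 unit types the alphabet extends with
doubled letters (`AA`/`aa`), preserving case semantics. Subtypes get their
own letters by default; `merge_subtypes` collapses `CT3a → CT3` first.

**Phrases → themes → songs.** A theme token is the letter part of a phrase
code (repetition counts dropped), with consecutive repeats collapsed, so
phrases differing only in repetition belong to one theme. A song is
segmented greedily: it closes at the first position where every theme token
occurring anywhere in the singer's sequence has appeared since the song
started. Trailing material missing some token is kept as an incomplete
song: it still contributes phrase types to repertoires (presence-based) but
is excluded from set-median inputs, which should represent full renditions.
A singer with no complete rendition falls back to its full sequence so
median inputs are never empty.

**Singer assignment.** Field-differentiated singers (dipping-hydrophone
recordings) keep their labels. For autonomous recordings a new presumed
singer opens when the silent gap exceeds `gap_min` (default 60 minutes,
configurable and echoed in reports) — a deliberately simple stand-in for
the spatio-temporal assignment rules used with moored arrays.

## Similarity statistics

The Dice Coincidence Index compares pooled phrase-type *sets* per
location-year cluster: `DCI = 2A/(B+C)`. Frequencies are discarded because
the statistic counts shared phrase types. Clusters at the focal (feeding
ground) location are first split into song groups: connected components of
the singer graph with edges wherever pairwise DCI > 0, numbered by size
(ties by earliest recording date).

The Levenshtein Distance Similarity Index operates on theme *tokens*, not
characters: `LSI = 1 − min(I+D+S)/max(L(a),L(b))`, a unit-cost edit
distance computed by dynamic programming. The set median string of a set of
sequences is the member maximizing summed LSI to the set; self-similarity
is included (a constant, so it cannot change the argmax) and ties break by
stable input order, with the full tie set reported.

## Clustering and cluster support

Trees are built by UPGMA on 1 − similarity. Ties between equal-distance
pairs merge the pair with the lowest smallest original leaf index (then the
lowest second index), making every tree deterministic.

Cluster support uses the multiscale bootstrap: the data are resampled at
relative sizes r ∈ {0.5, …, 1.4} (10 scales, `nboot` replicates each;
default 1000), the tree rebuilt per replicate, and each observed node's
recurrence counted per scale, with node identity defined as exact leaf-set
equality. For the repertoire analysis the resampling unit is the
phrase-type column of the cluster × phrase-type incidence matrix. For the
structure analysis it is each singer's set of complete songs — resampling
sequence positions instead would destroy the order structure the edit
distance measures — with medians recomputed per replicate in the same
two-level order as the observed statistic (singer median, then
location-year median). Replicate streams derive from a master seed by a
(seed, scale index, replicate index) counter scheme, so results are
reproducible and independent of iteration order.

The AU p-value comes from the probit fit ψ(r) = Φ⁻¹(1 − BP_r) = v√r + c/√r
by weighted least squares (weights `nboot·φ(ψ)²/(BP(1−BP))`, the inverse
asymptotic variance of a probit-transformed proportion), giving
AU = 1 − Φ(v − c) and a bias-corrected BP = 1 − Φ(v + c). Scales whose
proportion is exactly 0 or 1 carry no quantile information and are dropped
from the fit; a node with fewer than two fittable scales is reported as
AU = BP = 1 or 0 according to which bound its counts sit at (an earlier
clamping variant biased AU downward for near-certain clades at small
`nboot` and was abandoned). With a single informative scale the raw
proportion nearest r = 1 is reported, flagged `bp_only`. Nodes with
AU > 0.95 are flagged "likely"; AU values are reported per node without
multiple-testing correction, and the report says so. `nboot = 100` is
adequate for calibration studies but cannot resolve support above ~0.99;
experiments that must distinguish AU > 0.95 for near-certain nodes use the
conventional 1000 replicates.

## The simulator

Each population carries one song per year: an ordered list of themes, each
theme a fixed run-list of globally unique unit types with canonical
repetition counts. Novel themes are never reused, so between-population
overlap is exactly zero unless a mixing event transfers themes. Defaults
and their reasoning:

- **12 themes per song** — within the range of naturally occurring song
  complexity, and enough phrase types per cluster for Dice overlap to be
  reasonably fine-grained.
- **Substitution-only drift, μ_sub = 0.7/theme/year** — humpback song
  content turns over rapidly while song size stays roughly constant.
  The rate is calibrated so simulated within-population adjacent-year
  overlap (~30%) matches the adjacent-year repertoire overlaps reported
  for the Atlantic-sector feeding ground (>27%), with near-zero overlap
  after two to three years. Insertion/deletion rates are exposed
  (`mu_ins`, `mu_del`, default 0) for exploring repertoire-size drift;
  nonzero values make population repertoire sizes random-walk apart, which
  real location-year repertoires do not show at this time scale.
- **Mixing events** replace a fraction α of the target song's positions
  with distinct source themes (α = 1 adopts the source song wholesale, so
  full adoption gives exact set equality).
- **Rendering**: 3 singers per population-year (the study-wide average),
  2–4 song renditions each, with per-singer jitter in how many times each
  phrase repeats within a theme (base 2, ±1, min 1). Jitter never touches
  unit identity or canonical counts, so phrase-type codes are stable and
  the pipeline-recovered DCI equals the planted overlap exactly — the
  basis of the exactness tests. An optional theme-omission probability
  (default 0) produces incomplete renditions for stress-testing
  segmentation.

What the simulator does *not* emulate: classification noise (unit labels
are error-free), acoustic variability, geographic movement or demography,
within-population song variants, or gradual theme blending (transfer is
whole-theme adoption). Passing recovery tests therefore demonstrate the
statistical machinery, not robustness to upstream annotation error.

## Simulation studies

- **Null calibration**: datasets of 8 items × 30 i.i.d. Bernoulli(0.5)
  phrase-type indicators (no structure); the fraction of internal nodes
  with AU > 0.95 stays below 15% (AU behaves approximately like a
  p-value; the bound is loose because node selection is data-dependent).
- **Planted power**: two populations, three years, slow drift
  (μ_sub = 0.1: within-population year-to-year overlap ~0.9 against 0
  between) — the well-separated regime; both population clades must reach
  AU > 0.95.
- **Mixing recovery**: 3 populations × 5 years at default drift, one
  α = 0.8 event in year 3, full pipeline from rendered annotations with
  nboot = 1000; the mixed pair-year must carry the maximum
  between-population DCI and AU > 0.95. The adopted song's persistence
  into later years of the target population is the main competing signal;
  it is a real feature of the model, not an artifact.
- **Degenerate exactness**: zero drift ⇒ within-population cross-year
  DCI = 1 and singer-median LSI = 1 exactly; α = 1 ⇒ mixed pair-year
  DCI = 1 exactly.

## Numerical choices and limitations

Similarity matrices are stored at full precision; report percentages are
×100 rounded half-up to one decimal. Newick output uses the ultrametric
convention (node depth = merge height / 2) with `AU|BP` percentage labels.
Bootstrap resample sizes are round(r·n) and a scale driving any size to 0
raises rather than silently degrading. Greedy longest-match tokenization of
doubled letters is exact provided a doubled letter is never adjacent to its
own single form, which the run-based encoder only violates in phrase
families with >26 unit types re-entering in specific orders — beyond any
observed repertoire. Dice similarity of two empty resampled repertoires is
defined as 1 (equal sets), of one empty against a non-empty as 0; this
only arises inside bootstrap replicates. The LSI-mode bootstrap requires
every singer to have at least one complete song per resample; with the
default scales a singer needs ≥ 2 complete songs for r = 0.5 to be valid.
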