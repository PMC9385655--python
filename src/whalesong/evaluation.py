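"""Simulation studies of the analysis pipeline.

These routines quantify, over many simulated datasets, how the AU support
behaves under a structureless null, how reliably planted population
structure is recovered, and whether the pipeline reproduces planted
overlap exactly in degenerate regimes.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .clustering import AU_LIKELY_THRESHOLD, bootstrap_dci, support_from_bootstrap
from .pipeline import AnalysisConfig, run_repertoire_analysis, prepare_singers
from .similarity import lsi, set_median
from .simulate import (MixingEvent, SimulationConfig, expected_dice,
                       simulate_song_evolution)


def _derive_seed(seed: int, stream: int, i: int) -> int:
    # keep derived seeds well below 2**31 for portability
    return int(np.random.SeedSequence([seed, stream, i]).generate_state(1)[0]
               % (2 ** 31 - 1))


def null_au_rate(n_datasets: int = 100, n_items: int = 8, n_features: int = 30,
                 nboot: int = 100, scales=None, seed: int = 0,
                 p: float = 0.5) -> dict:
    """AU false-positive rate on exchangeable i.i.d. incidence data.

    Each dataset is an items x features Bernoulli(p) incidence matrix with
    no planted structure; every internal node of its DCI/UPGMA tree is a
    true null, so the fraction of nodes with AU > 0.95 estimates the
    procedure's size (loosely, since node selection is data-dependent).
    """
    kwargs = {} if scales is None else {"scales": scales}
    hits = total = 0
    for i in range(n_datasets):
        rng = np.random.default_rng(_derive_seed(seed, 1, i))
        inc = (rng.random((n_items, n_features)) < p).astype(float)
        # guard: no all-empty rows (an empty repertoire is screened upstream)
        for r in range(n_items):
            if inc[r].sum() == 0:
                inc[r, rng.integers(0, n_features)] = 1.0
        labels = [f"it{k}" for k in range(n_items)]
        boot = bootstrap_dci(inc, labels, nboot=nboot,
                             seed=_derive_seed(seed, 2, i), **kwargs)
        for s in support_from_bootstrap(boot).values():
            if len(s.leaf_set) == n_items:
                continue  # root is not a division
            total += 1
            hits += s.au > AU_LIKELY_THRESHOLD
    return {"rate": hits / total, "n_nodes": total, "n_datasets": n_datasets}


def planted_power(n_datasets: int = 100, nboot: int = 100, scales=None,
                  seed: int = 0, n_years: int = 3,
                  mu_sub: float = 0.1) -> dict:
    """Power to support two planted, well-separated clusters with AU > 0.95.

    Two populations evolve with zero between-population overlap and slow
    drift (the well-separated condition: within-population year-to-year
    overlap stays high while between-population overlap is 0); the planted
    nodes are the two populations' year-clusters in the DCI tree built from
    the true theme sets.  A dataset counts as a success when both planted
    nodes obtain AU > 0.95.
    """
    kwargs = {} if scales is None else {"scales": scales}
    successes = 0
    for i in range(n_datasets):
        cfg = SimulationConfig(n_populations=2, n_years=n_years,
                               mu_sub=mu_sub,
                               seed=_derive_seed(seed, 3, i))
        _ds, truth = simulate_song_evolution(cfg)
        keys = sorted(truth.songs)
        labels = [f"{p}_{y}" for p, y in keys]
        features = sorted(set().union(*(truth.songs[k] for k in keys)))
        fidx = {f: j for j, f in enumerate(features)}
        inc = np.zeros((len(keys), len(features)))
        for r, k in enumerate(keys):
            for f in truth.songs[k]:
                inc[r, fidx[f]] = 1.0
        boot = bootstrap_dci(inc, labels, nboot=nboot,
                             seed=_derive_seed(seed, 4, i), **kwargs)
        support = support_from_bootstrap(boot)
        planted = [
            frozenset(l for l, k in zip(labels, keys) if k[0] == pop)
            for pop in cfg.populations
        ]
        ok = all(
            clade in support and support[clade].au > AU_LIKELY_THRESHOLD
            for clade in planted)
        successes += ok
    return {"rate": successes / n_datasets, "n_datasets": n_datasets}


def mixing_recovery(n_seeds: int = 100, nboot: int = 1000, scales=None,
                    seed: int = 0, alpha: float = 0.8) -> dict:
    """End-to-end recovery of one planted feeding-ground mixing event.

    Simulates 3 populations over 5 years with zero baseline
    between-population overlap and one mixing event (strength ``alpha``,
    third year), runs the full repertoire pipeline from rendered
    annotations, and checks that (i) the mixed pair-year has the maximum
    between-population DCI and (ii) its node is supported with AU > 0.95.
    """
    kwargs = {} if scales is None else {"scales": scales}
    max_ok = au_ok = both_ok = 0
    mixed_dci = []
    for i in range(n_seeds):
        sim_cfg = SimulationConfig(seed=_derive_seed(seed, 5, i))
        year = sim_cfg.start_year + 2
        sim_cfg = replace(sim_cfg, mixing_events=(
            MixingEvent("PA", "PB", year, alpha),))
        ds, _truth = simulate_song_evolution(sim_cfg)
        ac = AnalysisConfig(annotations=ds.annotations, metadata=ds.metadata,
                            focal_location="PA", nboot=nboot,
                            seed=_derive_seed(seed, 6, i), **kwargs)
        res = run_repertoire_analysis(ac)
        labels = res.labels
        vals = res.matrix.values
        mixed = (f"PA_1_{year}", f"PB_1_{year}")
        best, best_pair = -1.0, None
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                if labels[a].split("_")[0] == labels[b].split("_")[0]:
                    continue
                if vals[a, b] > best:
                    best, best_pair = vals[a, b], (labels[a], labels[b])
        is_max = best_pair is not None and set(best_pair) == set(mixed)
        clade = frozenset(mixed)
        s = res.support.get(clade)
        has_au = s is not None and s.au > AU_LIKELY_THRESHOLD
        max_ok += is_max
        au_ok += has_au
        both_ok += is_max and has_au
        i_a, i_b = labels.index(mixed[0]), labels.index(mixed[1])
        mixed_dci.append(float(vals[i_a, i_b]))
    return {"rate": both_ok / n_seeds, "max_rate": max_ok / n_seeds,
            "au_rate": au_ok / n_seeds,
            "mean_mixed_dci": float(np.mean(mixed_dci)),
            "n_seeds": n_seeds}


def degenerate_exactness(seed: int = 0) -> dict:
    """Exactness checks in regimes where drift and mixing degenerate.

    With zero mutation and no mixing, within-population cross-year DCI
    through the full pipeline must be exactly 1 and all singers of a
    population must have LSI exactly 1; with full adoption (alpha = 1) the
    mixed pair-year DCI must be exactly 1.
    """
    frozen = SimulationConfig(n_populations=2, n_years=3, mu_sub=0.0,
                              mu_ins=0.0, mu_del=0.0, seed=seed)
    ds, truth = simulate_song_evolution(frozen)
    ac = AnalysisConfig(annotations=ds.annotations, metadata=ds.metadata,
                        focal_location="PA", nboot=100, seed=seed)
    res = run_repertoire_analysis(ac)
    m = res.matrix.to_frame()
    within = [
        float(m.loc[f"{p}_1_{y1}", f"{p}_1_{y2}"])
        for p in ("PA", "PB")
        for y1 in frozen.years for y2 in frozen.years if y1 < y2
    ]
    singers, _lm, _ex = prepare_singers(ac)
    pa = [s for s in singers if s.location == "PA" and s.year == frozen.start_year]
    medians = [set_median(s.complete_song_tokens()).sequence for s in pa]
    lsis = [lsi(a, b) for i, a in enumerate(medians) for b in medians[i + 1:]]

    adopt_year = frozen.start_year + 1
    adopt = SimulationConfig(
        n_populations=2, n_years=2, mu_sub=0.0, mu_ins=0.0, mu_del=0.0,
        mixing_events=(MixingEvent("PA", "PB", adopt_year, 1.0),), seed=seed)
    ds2, truth2 = simulate_song_evolution(adopt)
    ac2 = AnalysisConfig(annotations=ds2.annotations, metadata=ds2.metadata,
                         focal_location="PA", nboot=100, seed=seed)
    res2 = run_repertoire_analysis(ac2)
    m2 = res2.matrix.to_frame()
    return {
        "min_within_population_dci": min(within),
        "max_within_population_dci": max(within),
        "min_singer_lsi": min(lsis),
        "full_adoption_dci": float(
            m2.loc[f"PA_1_{adopt_year}", f"PB_1_{adopt_year}"]),
        "expected_full_adoption_dci": expected_dice(
            truth2, ("PA", adopt_year), ("PB", adopt_year)),
    }
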