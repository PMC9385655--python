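"""Average-linkage (UPGMA) hierarchical clustering with multiscale-bootstrap
cluster support.

The support procedure follows the multiscale bootstrap: the data are
resampled at several relative sample sizes ``r`` (default 0.5 .. 1.4), the
tree is rebuilt for each replicate, and for every internal node of the
observed tree the fraction of replicate trees containing the same leaf set
is counted per scale.  The approximately-unbiased (AU) p-value is obtained
by fitting the probit-transformed counts

    psi(r) = Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by weighted least squares, where ``v`` estimates the signed distance of the
data from the boundary of the cluster's region and ``c`` its curvature;
then ``AU = 1 - Phi(v - c)`` and the bias-corrected bootstrap probability
at r=1 is ``1 - Phi(v + c)``.  Nodes with ``AU > 0.95`` are flagged as
divisions likely to occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConsistencyError, DomainError, ValidationError
from .similarity import SimilarityMatrix, lsi, set_median, similarity_matrix

AU_LIKELY_THRESHOLD = 0.95
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
DEFAULT_NBOOT = 1000


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    height: float
    label: str | None = None                 # leaves only
    children: tuple["DendrogramNode", ...] = ()
    leaf_set: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Heights are cophenetic distances (the average linkage value at each
    merge) and are non-decreasing from leaves to root.
    """

    root: DendrogramNode
    labels: list[str]
    merges: list[tuple[frozenset, float]] = field(default_factory=list)

    def internal_nodes(self) -> list[DendrogramNode]:
        out = []

        def walk(n):
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> dict[frozenset, float]:
        """Leaf set -> merge height for every internal node."""
        return {n.leaf_set: n.height for n in self.internal_nodes()}

    def clade_set(self) -> set[frozenset]:
        return {n.leaf_set for n in self.internal_nodes()}

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise matrix of the heights at which leaves first merge."""
        n = len(self.labels)
        idx = {l: i for i, l in enumerate(self.labels)}
        m = np.zeros((n, n))

        def walk(node):
            if node.is_leaf:
                return
            kids = node.children
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for la in kids[a].leaf_set:
                        for lb in kids[b].leaf_set:
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = node.height
            for c in kids:
                walk(c)

        walk(self.root)
        return pd.DataFrame(m, index=self.labels, columns=self.labels)

    def to_newick(self, support: Mapping[frozenset, "ClusterSupport"] | None = None
                  ) -> str:
        """Support-annotated Newick string.

        Branch lengths use the ultrametric convention (a node at merge
        height h sits at depth h/2); internal labels are "AU|BP" as
        percentages when support is given.
        """
        if support is not None:
            missing = set(support) - self.clade_set()
            if missing:
                raise ConsistencyError(
                    f"support keyed by unknown leaf sets: {sorted(map(sorted, missing))}")

        def node_label(node):
            if support is None:
                return ""
            s = support.get(node.leaf_set)
            if s is None:
                return ""
            return f"{s.au * 100:.1f}|{s.bp * 100:.1f}"

        def render(node, parent_depth):
            depth = node.height / 2.0
            branch = parent_depth - depth
            if node.is_leaf:
                return f"{node.label}:{branch:.10g}"
            inner = ",".join(render(c, depth) for c in node.children)
            return f"({inner}){node_label(node)}:{branch:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        depth = self.root.height / 2.0
        inner = ",".join(render(c, depth) for c in self.root.children)
        return f"({inner}){node_label(self.root)}:0;"


def upgma(dist: np.ndarray | pd.DataFrame,
          labels: Sequence[str] | None = None) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration.

    The distance between two clusters is the unweighted mean of all
    between-cluster leaf distances (maintained by the size-weighted update
    ``d(i+j, k) = (n_i d_ik + n_j d_jk) / (n_i + n_j)``).  Deterministic
    tie-breaking: among equal-distance pairs, merge the pair whose smallest
    original leaf index is lowest, then the one whose other index is
    smallest.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        dist = dist.to_numpy()
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix diagonal must be zero")
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValidationError("label count does not match matrix size")

    nodes: list[DendrogramNode] = [
        DendrogramNode(height=0.0, label=l, leaf_set=frozenset([l]))
        for l in labels
    ]
    if n == 1:
        return Dendrogram(root=nodes[0], labels=labels)

    sizes = np.ones(n)
    minleaf = list(range(n))           # smallest original index per cluster
    active = list(range(n))
    work = d.copy()
    merges: list[tuple[frozenset, float]] = []

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = work[i, j]
                lo, hi = sorted((minleaf[i], minleaf[j]))
                key = (dij, lo, hi)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_key, i, j) = best
        h = work[i, j]
        new = DendrogramNode(
            height=h, children=(nodes[i], nodes[j]),
            leaf_set=nodes[i].leaf_set | nodes[j].leaf_set)
        merges.append((new.leaf_set, h))
        # size-weighted distance update keeps the unweighted leaf-pair mean
        for k in active:
            if k in (i, j):
                continue
            work[i, k] = work[k, i] = (
                sizes[i] * work[i, k] + sizes[j] * work[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = new
        sizes[i] += sizes[j]
        minleaf[i] = min(minleaf[i], minleaf[j])
        active.remove(j)

    return Dendrogram(root=nodes[active[0]], labels=labels, merges=merges)


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCounts:
    """Per-node, per-scale replicate counts from a multiscale bootstrap."""

    tree: Dendrogram
    scales: tuple[float, ...]
    nboot: int
    counts: dict[frozenset, np.ndarray]      # node -> count per scale
    effective: np.ndarray                    # usable replicates per scale


def _replicate_seed(seed: int, scale_index: int, replicate: int) -> np.random.Generator:
    # counter scheme: replicate j at scale k is independent of list ordering
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), scale_index, replicate]))


def multiscale_bootstrap(observed: Dendrogram,
                         replicate_tree: Callable[[float, np.random.Generator],
                                                  Dendrogram | None],
                         nboot: int = DEFAULT_NBOOT,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         seed: int = 0) -> BootstrapCounts:
    """Count, per scale, how often each observed node recurs in replicate
    trees.

    ``replicate_tree(r, rng)`` must resample the underlying data at relative
    size ``r`` and rebuild the tree; returning ``None`` drops that replicate
    (tracked in ``effective``).  Node identity across trees is exact
    leaf-set equality.  Fully reproducible for a fixed seed.
    """
    if nboot < 1:
        raise DomainError("nboot must be >= 1")
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise DomainError("scales must be positive")
    observed_clades = list(observed.clade_set())
    counts = {c: np.zeros(len(scales)) for c in observed_clades}
    effective = np.zeros(len(scales))
    for k, r in enumerate(scales):
        for j in range(nboot):
            rng = _replicate_seed(seed, k, j)
            tree = replicate_tree(r, rng)
            if tree is None:
                continue
            effective[k] += 1
            rep_clades = tree.clade_set()
            for c in observed_clades:
                if c in rep_clades:
                    counts[c][k] += 1
    return BootstrapCounts(tree=observed, scales=scales, nboot=nboot,
                           counts=counts, effective=effective)


def _resample_size(r: float, n: int) -> int:
    m = int(np.rint(r * n))
    if m < 1:
        raise DomainError(f"scale {r} yields a resample size of 0 (n={n})")
    return m


def dci_from_incidence(incidence: np.ndarray) -> np.ndarray:
    """Pairwise DCI matrix from a clusters x phrase-types 0/1 incidence.

    Columns may repeat (bootstrap resamples); each sampled column counts as
    one feature.  A pair of all-empty rows is given similarity 1 (equal
    empty sets), an empty row against a non-empty one similarity 0.
    """
    m = np.asarray(incidence, dtype=float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(s, 1.0)
    return s


def bootstrap_dci(incidence: np.ndarray, labels: Sequence[str],
                  nboot: int = DEFAULT_NBOOT,
                  scales: Sequence[float] = DEFAULT_SCALES,
                  seed: int = 0) -> BootstrapCounts:
    """Multiscale bootstrap for repertoire (DCI) trees.

    Resamples phrase-type columns of the incidence matrix with replacement
    at size round(r * n_features), recomputes the DCI matrix and the UPGMA
    tree on 1 - DCI.
    """
    m = np.asarray(incidence, dtype=float)
    n_feat = m.shape[1]
    if n_feat < 2:
        raise DomainError("DCI bootstrap needs at least 2 phrase types")
    for r in scales:
        _resample_size(r, n_feat)  # validate all scales up front
    labels = list(labels)
    observed = upgma(1.0 - dci_from_incidence(m), labels)

    def replicate(r: float, rng: np.random.Generator) -> Dendrogram:
        size = _resample_size(r, n_feat)
        cols = rng.integers(0, n_feat, size)
        return upgma(1.0 - dci_from_incidence(m[:, cols]), labels)

    return multiscale_bootstrap(observed, replicate, nboot=nboot,
                                scales=scales, seed=seed)


def bootstrap_lsi(song_sets: Mapping[str, Sequence[Sequence[str]]],
                  nboot: int = DEFAULT_NBOOT,
                  scales: Sequence[float] = DEFAULT_SCALES,
                  seed: int = 0,
                  representatives: Mapping[str, Sequence[str]] | None = None
                  ) -> BootstrapCounts:
    """Multiscale bootstrap for song-structure (LSI) trees.

    The resampling unit is each item's set of complete songs (not sequence
    positions, which would destroy the order structure the edit distance
    measures): for each item, its songs are resampled with replacement at
    size round(r * n_songs), its set median recomputed, and the LSI matrix
    and UPGMA tree rebuilt.
    """
    labels = list(song_sets)
    if len(labels) < 2:
        raise DomainError("LSI bootstrap needs at least 2 items")
    songs = {l: [tuple(s) for s in song_sets[l]] for l in labels}
    for l, ss in songs.items():
        if not ss:
            raise DomainError(f"item {l!r} has no songs to resample")
        for r in scales:
            _resample_size(r, len(ss))
    if representatives is None:
        reps = [set_median(songs[l]).sequence for l in labels]
    else:
        reps = [tuple(representatives[l]) for l in labels]
    observed = upgma(1.0 - similarity_matrix(reps, "lsi", labels).values, labels)

    def replicate(r: float, rng: np.random.Generator) -> Dendrogram:
        medians = []
        for l in labels:
            ss = songs[l]
            size = _resample_size(r, len(ss))
            pick = [ss[i] for i in rng.integers(0, len(ss), size)]
            medians.append(set_median(pick).sequence)
        n = len(medians)
        mat = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = lsi(medians[i], medians[j])
        return upgma(1.0 - mat, labels)

    return multiscale_bootstrap(observed, replicate, nboot=nboot,
                                scales=scales, seed=seed)


# ---------------------------------------------------------------------------
# AU p-values
# ---------------------------------------------------------------------------


@dataclass
class ClusterSupport:
    """AU/BP support for one internal node.

    ``v`` and ``c`` are the signed distance and curvature of the multiscale
    fit; ``bp_raw`` is the counted replicate fraction at the scale nearest
    r = 1.  Flags: "degenerate_high"/"degenerate_low" when the fit was
    impossible because (almost) every count sat at a bound, "dropped_scales"
    when some scales had proportions of exactly 0 or 1 and were excluded
    from the fit, "bp_only" when fewer than 2 usable scales allowed no fit.
    """

    leaf_set: frozenset
    au: float
    bp: float
    v: float
    c: float
    bp_raw: float
    counts: np.ndarray
    scales: tuple[float, ...]
    nboot: float
    flags: tuple[str, ...] = ()

    @property
    def likely(self) -> bool:
        return self.au > AU_LIKELY_THRESHOLD


def au_from_counts(counts: Sequence[float], nboot: float,
                   scales: Sequence[float],
                   leaf_set: frozenset = frozenset()) -> ClusterSupport:
    """Fit the multiscale model to one node's per-scale counts.

    Scales whose bootstrap proportion is exactly 0 or 1 carry no quantile
    information and are excluded from the fit; when fewer than two scales
    remain, the node is degenerate and AU = BP = 1 (proportions mostly at
    the ceiling) or 0 (mostly at the floor).  The weighted least-squares
    fit of Phi^-1(1 - BP_k) on (sqrt(r_k), 1/sqrt(r_k)) uses weights
    nboot * phi(psi_k)^2 / (BP_k (1 - BP_k)), the inverse asymptotic
    variance of the probit of a binomial proportion.
    """
    counts = np.asarray(counts, dtype=float)
    scales = tuple(float(s) for s in scales)
    if counts.shape != (len(scales),):
        raise DomainError("one count per scale required")
    r1_idx = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    bp_raw = float(counts[r1_idx] / nboot)

    flags: list[str] = []
    bp_k = counts / nboot
    usable = (bp_k > 0) & (bp_k < 1)
    if np.any(~usable):
        flags.append("dropped_scales")
    n_usable = len(set(np.asarray(scales)[usable]))
    if n_usable == 0:
        if np.mean(bp_k) >= 0.5:
            return ClusterSupport(leaf_set, au=1.0, bp=1.0, v=np.nan,
                                  c=np.nan, bp_raw=bp_raw, counts=counts,
                                  scales=scales, nboot=nboot,
                                  flags=("degenerate_high",))
        return ClusterSupport(leaf_set, au=0.0, bp=0.0, v=np.nan, c=np.nan,
                              bp_raw=bp_raw, counts=counts, scales=scales,
                              nboot=nboot, flags=("degenerate_low",))
    if n_usable < 2:
        flags.append("bp_only")
        return ClusterSupport(leaf_set, au=bp_raw, bp=bp_raw, v=np.nan,
                              c=np.nan, bp_raw=bp_raw, counts=counts,
                              scales=scales, nboot=nboot, flags=tuple(flags))

    r = np.asarray(scales)[usable]
    bp_u = bp_k[usable]
    psi = norm.ppf(1.0 - bp_u)
    w = nboot * norm.pdf(psi) ** 2 / (bp_u * (1.0 - bp_u))
    x = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], psi * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    bp = float(1.0 - norm.cdf(v + c))
    return ClusterSupport(leaf_set, au=au, bp=bp, v=v, c=c, bp_raw=bp_raw,
                          counts=counts, scales=scales, nboot=nboot,
                          flags=tuple(flags))


def support_from_bootstrap(boot: BootstrapCounts
                           ) -> dict[frozenset, ClusterSupport]:
    """AU/BP support for every internal node of the observed tree."""
    out = {}
    for clade, counts in boot.counts.items():
        eff = np.where(boot.effective > 0, boot.effective, boot.nboot)
        # normalize per-scale counts to a common nboot when replicates dropped
        scaled = counts * (boot.nboot / eff)
        out[clade] = au_from_counts(scaled, boot.nboot, boot.scales,
                                    leaf_set=clade)
    return out


def support_table(tree: Dendrogram,
                  support: Mapping[frozenset, ClusterSupport]) -> pd.DataFrame:
    """Node table: leaf set, merge height, AU, BP, v, c, flags."""
    rows = []
    for node in tree.internal_nodes():
        s = support.get(node.leaf_set)
        if s is None:
            raise ConsistencyError(f"no support for node {sorted(node.leaf_set)}")
        rows.append({
            "leaves": "|".join(sorted(node.leaf_set)),
            "n_leaves": len(node.leaf_set),
            "height": node.height,
            "au": s.au,
            "bp": s.bp,
            "bp_raw": s.bp_raw,
            "v": s.v,
            "c": s.c,
            "likely": s.likely,
            "flags": ";".join(s.flags),
        })
    return pd.DataFrame(rows).sort_values(
        ["height", "n_leaves", "leaves"]).reset_index(drop=True)
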