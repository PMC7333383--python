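"""Statistics learned from the bulk regulome compendium.

Everything the single-cell model treats as known is estimated here from a
matrix of binned bulk read counts: the normalized signal, the catalog of
candidate regulatory elements (signal bins), per-element baseline locus
effects ``(m, s)`` via method of moments under a Poisson-lognormal model,
the stratified low-variability element set used to anchor the technical
bias function, and the multi-resolution element clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.cluster import KMeans

from screg.genome import BinCountMatrix, GenomeBinIndex

logger = logging.getLogger(__name__)

STAGE1_K = 5000
N_STRATA = 10
PER_STRATUM = 1000
SIGNAL_MIN_COUNT = 10
SIGNAL_MIN_NORM = 5.0
BG_WINDOW_BP = 100_000
#: compendium sizes printed for the two reference genomes
KNOWN_CRE_COUNTS = {"human": 522_173, "mouse": 475_865}


# ---------------------------------------------------------------------------
# normalization and signal-bin detection

@dataclass
class NormalizedMatrix:
    """Library-size-normalized, log2-transformed counts: log2(y/L + 1)."""

    values: np.ndarray
    source: BinCountMatrix | None = None


def normalize_counts(counts: BinCountMatrix) -> NormalizedMatrix:
    """log2(y/L + 1) per entry; zero counts map to exactly zero."""
    L = counts.library_factors
    bad = (L <= 0) & (counts.column_totals() > 0)
    if np.any(bad):
        raise ValueError("zero library factor with nonzero counts")
    safe_L = np.where(L > 0, L, 1.0)
    values = np.log2(counts.counts / safe_L + 1.0)
    return NormalizedMatrix(values=values, source=counts)


def detect_signal_bins(
    counts: BinCountMatrix,
    normalized: NormalizedMatrix,
    species_factor: float = 5.0,
    bg_window_bp: int = BG_WINDOW_BP,
) -> np.ndarray:
    """Flag signal bins per sample.

    Bin ``i`` is a signal bin in sample ``j`` iff (1) ``y >= 10``,
    (2) ``log2(y/L+1) >= 5``, and (3) the normalized value is at least
    ``species_factor`` times the background, defined as the mean normalized
    value over the 100-kb window centered on the bin, excluding the bin
    itself and any masked bin, clipped at chromosome ends. A background
    mean of zero satisfies condition (3). Masked bins and trailing partial
    bins are never flagged.
    """
    index = counts.index
    if bg_window_bp < index.bin_width:
        raise ValueError("background window smaller than bin width")
    y = counts.counts
    v = normalized.values
    flags = (y >= SIGNAL_MIN_COUNT) & (v >= SIGNAL_MIN_NORM)
    half_bins = bg_window_bp // (2 * index.bin_width)
    usable = ~index.blacklist_mask
    bg_mean = np.empty_like(v)
    for sl in index.chrom_slices().values():
        vals = np.where(usable[sl, None], v[sl], 0.0)
        ones = usable[sl].astype(float)
        csum = np.cumsum(np.vstack([np.zeros((1, v.shape[1])), vals]), axis=0)
        cnum = np.concatenate([[0.0], np.cumsum(ones)])
        n = sl.stop - sl.start
        lo = np.maximum(np.arange(n) - half_bins, 0)
        hi = np.minimum(np.arange(n) + half_bins + 1, n)
        wsum = csum[hi] - csum[lo]
        wnum = cnum[hi] - cnum[lo]
        # exclude the center bin itself
        wsum -= vals
        wnum -= ones
        with np.errstate(invalid="ignore"):
            bg_mean[sl] = np.where(wnum[:, None] > 0, wsum / wnum[:, None], 0.0)
    flags &= (v >= species_factor * bg_mean) | (bg_mean <= 0)
    flags[index.blacklist_mask | index.partial_mask] = False
    return flags


# ---------------------------------------------------------------------------
# catalog

@dataclass
class CRECatalog:
    """Ordered (genome-order) subset of bins flagged in >= 1 bulk sample."""

    bin_indices: np.ndarray
    sample_flags: np.ndarray
    index: GenomeBinIndex | None = None

    def __len__(self) -> int:
        return len(self.bin_indices)


def compile_cres(signal_bins: np.ndarray, index: GenomeBinIndex | None = None) -> CRECatalog:
    """Union of per-sample signal bins, in genome order."""
    any_flag = signal_bins.any(axis=1)
    bin_indices = np.flatnonzero(any_flag)
    return CRECatalog(
        bin_indices=bin_indices, sample_flags=signal_bins[bin_indices], index=index
    )


def catalog_saturation(catalog_bins: np.ndarray, new_sample_bins: np.ndarray) -> float:
    """Fraction of the updated catalog contributed by a new sample.

    ``|new \\ catalog| / |catalog ∪ new|``; 1.0 for an empty catalog with a
    nonempty new sample, 0.0 when the new sample adds nothing.
    """
    catalog = set(np.asarray(catalog_bins).tolist())
    new = set(np.asarray(new_sample_bins).tolist())
    union = catalog | new
    if not union:
        return 0.0
    return len(new - catalog) / len(union)


# ---------------------------------------------------------------------------
# locus effects (method of moments)

@dataclass
class LocusEffects:
    """Per-element baseline mean ``m`` and SD ``s`` on natural-log scale.

    ``fallback`` marks rows where the moment ratio fell below 1 and the
    degenerate branch (``s = 0``) was used. All-zero rows get ``m = -inf``.
    """

    m: np.ndarray
    s: np.ndarray
    fallback: np.ndarray

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.m)


def estimate_locus_effects(
    counts: np.ndarray, library_factors: np.ndarray
) -> LocusEffects:
    """Closed-form method-of-moments estimates of ``(m, s)`` per row.

    Under ``y ~ Poisson(L * exp(m + s*delta))`` with ``delta ~ N(0,1)``,
    the first two moments of ``y/L`` identify ``m`` and ``s``:

        s^2 = log( (E[(y/L)^2] - E[y/L^2]) / E[y/L]^2 )
        m   = log E[y/L] - s^2/2

    Rows where the log argument is below 1 (or non-finite) use the
    degenerate branch ``s = 0, m = log E[y/L]``. All-zero rows are given
    ``m = -inf`` and must be excluded from bias fitting and clustering.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a rows x samples matrix with >= 2 samples")
    L = np.asarray(library_factors, dtype=float)
    if np.any(L <= 0):
        raise ValueError("library factors must be positive")
    r = y / L
    mom1 = r.mean(axis=1)
    mom2 = (r**2).mean(axis=1)
    corr = (y / L**2).mean(axis=1)
    nonzero = mom1 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mom2 - corr) / mom1**2
        s2 = np.log(ratio)
    ok = nonzero & np.isfinite(s2) & (ratio >= 1.0)
    s = np.where(ok, np.sqrt(np.maximum(s2, 0.0)), 0.0)
    with np.errstate(divide="ignore"):
        m = np.where(nonzero, np.log(np.where(nonzero, mom1, 1.0)) - s**2 / 2.0, -np.inf)
    fallback = nonzero & ~ok
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("%d all-zero rows assigned m = -inf", n_zero)
    return LocusEffects(m=m, s=s, fallback=fallback)


# ---------------------------------------------------------------------------
# low-variability set

@dataclass
class LowVariabilitySet:
    """Indices of low-variability elements and their stratum ids."""

    members: np.ndarray
    strata: np.ndarray

    def __len__(self) -> int:
        return len(self.members)


def select_low_variability(
    effects: LocusEffects,
    n_strata: int = N_STRATA,
    per_stratum: int = PER_STRATUM,
) -> LowVariabilitySet:
    """Stratified selection of the least variable elements.

    Elements are grouped into ``n_strata`` strata by the deciles of ``m``;
    within each stratum the ``per_stratum`` elements with smallest ``s``
    are taken (ties broken stably by genome order; all members if fewer).
    """
    finite = np.flatnonzero(effects.finite_mask())
    if len(finite) < n_strata:
        raise ValueError("catalog smaller than number of strata")
    m = effects.m[finite]
    s = effects.s[finite]
    qs = np.quantile(m, np.arange(1, n_strata) / n_strata)
    stratum = np.searchsorted(qs, m, side="right")
    members, strata = [], []
    for st in range(n_strata):
        in_st = np.flatnonzero(stratum == st)
        order = in_st[np.lexsort((in_st, s[in_st]))]
        chosen = order[:per_stratum]
        members.append(finite[chosen])
        strata.append(np.full(len(chosen), st))
    members = np.concatenate(members)
    strata = np.concatenate(strata)
    order = np.argsort(members, kind="stable")
    return LowVariabilitySet(members=members[order], strata=strata[order])


# ---------------------------------------------------------------------------
# multi-resolution clustering

@dataclass
class CREHierarchy:
    """Nested element clusterings at multiple granularity levels.

    ``assignments[K]`` maps each catalog element to a cluster id in
    ``0..K-1``. Levels are nested: every finer cluster lies inside exactly
    one coarser cluster.
    """

    levels: list[int]
    assignments: dict[int, np.ndarray]

    @property
    def n_elements(self) -> int:
        return len(next(iter(self.assignments.values())))

    def clusters(self, K: int) -> list[np.ndarray]:
        """Member-index arrays of the K-level clusters (non-empty only)."""
        labels = self.assignments[K]
        order = np.argsort(labels, kind="stable")
        split_at = np.flatnonzero(np.diff(labels[order])) + 1
        return np.split(order, split_at)

    def membership_matrix(self, K: int) -> np.ndarray:
        """Dense binary element x cluster membership matrix at level K."""
        labels = self.assignments[K]
        X = np.zeros((len(labels), K), dtype=np.int8)
        X[np.arange(len(labels)), labels] = 1
        return X


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-SD per row; constant rows become all-zero (logged)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    if np.any(degenerate):
        logger.info("%d constant rows standardized to zeros", int(degenerate.sum()))
    return np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)


def halving_levels(stage1_k: int, n_halvings: int = 5) -> list[int]:
    """Coarse level sizes from repeated integer halving of ``stage1_k``.

    5000 -> [156, 312, 625, 1250, 2500].
    """
    ks = []
    k = stage1_k
    for _ in range(n_halvings):
        k //= 2
        if k < 1:
            break
        ks.append(k)
    return sorted(set(ks))


def cluster_cres(
    normalized_catalog: np.ndarray,
    stage1_k: int = STAGE1_K,
    seed: int | None = 0,
    max_fine_levels: int | None = None,
) -> CREHierarchy:
    """Three-stage multi-resolution clustering of catalog elements.

    Stage 1 partitions standardized cross-sample profiles into
    ``stage1_k`` K-means clusters (Lloyd, 10 restarts, fixed seed).
    Stage 2 groups the standardized cluster-mean profiles by
    complete-linkage hierarchical clustering and cuts the tree at the
    halving sequence of sizes to give the coarse levels. Stage 3 splits
    each Stage-1 cluster by complete linkage into ``min(2^d, size)``
    subclusters at depth ``d``; applying the same depth everywhere yields
    the global fine levels, down to singletons.
    """
    Z = standardize_rows(np.asarray(normalized_catalog, dtype=float))
    n = Z.shape[0]
    if n == 0:
        raise ValueError("empty catalog")
    k1 = min(stage1_k, n)
    if k1 < n:
        km = KMeans(
            n_clusters=k1, n_init=10, max_iter=300, algorithm="lloyd", random_state=seed
        )
        labels1 = km.fit_predict(Z)
    else:
        labels1 = np.arange(n)
        k1 = n
    assignments: dict[int, np.ndarray] = {}

    # coarse levels: complete-linkage tree over standardized cluster means
    means = np.vstack([Z[labels1 == c].mean(axis=0) for c in range(k1)])
    means = standardize_rows(means)
    coarse_ks = [k for k in halving_levels(k1) if k < k1]
    if coarse_ks and k1 >= 2:
        tree = linkage(means, method="complete")
        cuts = cut_tree(tree, n_clusters=coarse_ks)
        for col, K in enumerate(coarse_ks):
            assignments[K] = cuts[labels1, col].astype(np.int64)
    assignments[k1] = labels1.astype(np.int64)

    # fine levels: per-cluster complete-linkage subtrees at common depth
    member_lists = [np.flatnonzero(labels1 == c) for c in range(k1)]
    subtrees = {}
    for c, members in enumerate(member_lists):
        if len(members) >= 2:
            subtrees[c] = linkage(Z[members], method="complete")
    max_size = max(len(mm) for mm in member_lists)
    depth = 1
    n_fine = 0
    while (1 << (depth - 1)) < max_size:
        labels = np.empty(n, dtype=np.int64)
        offset = 0
        for c, members in enumerate(member_lists):
            n_sub = min(1 << depth, len(members))
            if n_sub == 1 or len(members) == 1:
                labels[members] = offset
            elif n_sub == len(members):
                labels[members] = offset + np.arange(len(members))
            else:
                sub = cut_tree(subtrees[c], n_clusters=n_sub)[:, 0]
                labels[members] = offset + sub
            offset += n_sub
        if offset > k1 and offset not in assignments:
            assignments[offset] = labels
            n_fine += 1
            if max_fine_levels is not None and n_fine >= max_fine_levels:
                break
        depth += 1

    levels = sorted(assignments)
    return CREHierarchy(levels=levels, assignments=assignments)


# ---------------------------------------------------------------------------
# variance explained by the mean profile

@dataclass
class MeanProfile:
    """Per-element mean of the normalized signal across compendium samples."""

    a: np.ndarray


def mean_profile(normalized: np.ndarray) -> MeanProfile:
    return MeanProfile(a=np.asarray(normalized, dtype=float).mean(axis=1))


def variance_explained(normalized: np.ndarray, profile: MeanProfile) -> float:
    """Fraction of total variance captured by the cross-sample mean profile.

    ``J * sum_i (a_i - abar)^2 / sum_ij (v_ij - vbar)^2`` with grand means
    ``abar`` and ``vbar``. Equals 1 when all columns are identical and 0
    when the mean profile is constant.
    """
    v = np.asarray(normalized, dtype=float)
    J = v.shape[1]
    a = profile.a
    denom = np.sum((v - v.mean()) ** 2)
    if denom == 0:
        return 0.0
    return float(J * np.sum((a - a.mean()) ** 2) / denom)


# ---------------------------------------------------------------------------
# worked-size helpers and tabular I/O

def mean_cluster_size(n_elements: int, k: int = STAGE1_K) -> int:
    """Integer average elements per cluster when ``n_elements`` are split
    into ``k`` clusters."""
    return n_elements // k


def write_locus_effects(
    effects: LocusEffects, catalog: CRECatalog, path, index: GenomeBinIndex | None = None
) -> None:
    """TSV with columns chrom, start, end, m, s, fallback (catalog rows)."""
    idx = index if index is not None else catalog.index
    if idx is None:
        raise ValueError("a bin index is required to write coordinates")
    b = catalog.bin_indices
    df = pd.DataFrame(
        {
            "chrom": [idx.chrom_names[c] for c in idx.bin_chrom[b]],
            "start": idx.starts[b],
            "end": idx.ends[b],
            "m": effects.m,
            "s": effects.s,
            "fallback": effects.fallback.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_locus_effects(path) -> tuple[LocusEffects, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    eff = LocusEffects(
        m=df["m"].to_numpy(float),
        s=df["s"].to_numpy(float),
        fallback=df["fallback"].to_numpy(bool),
    )
    return eff, df


def write_hierarchy(hierarchy: CREHierarchy, path) -> None:
    """TSV with one column per level, header ``K=<value>``."""
    df = pd.DataFrame({f"K={K}": hierarchy.assignments[K] for K in hierarchy.levels})
    df.to_csv(path, sep="\t", index=False)


def read_hierarchy(path) -> CREHierarchy:
    df = pd.read_csv(path, sep="\t")
    assignments = {}
    for col in df.columns:
        if not col.startswith("K="):
            raise ValueError(f"malformed hierarchy column {col!r}")
        assignments[int(col[2:])] = df[col].to_numpy(np.int64)
    return CREHierarchy(levels=sorted(assignments), assignments=assignments)
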