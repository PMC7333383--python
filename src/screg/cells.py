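"""Multi-cell pipeline: cluster cells, pool them into pseudo-cells, and
run the reconstruction model per pseudo-cell.

Cells are summarized by the average normalized activity of the elements
in each coarse (stage-1) cluster, quantile-normalized across cells,
filtered for variability, reduced by PCA + a 2-D stochastic-neighbor
embedding, and clustered with a Gaussian mixture selected by BIC. Reads
from the cells of each cluster are pooled into a pseudo-cell which is
analyzed by the single-cell model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

from screg.compendium import CRECatalog, CREHierarchy, LocusEffects, LowVariabilitySet
from screg.genome import LIBRARY_UNIT, BinCountMatrix
from screg.model import BiasSpline, ReconstructedSignal, cross_validate_K, fit_bias_function, reconstruct

logger = logging.getLogger(__name__)

FEATURE_LEVEL_TARGET = 5000
MIN_NONZERO_CELL_FRAC = 0.10
N_PCS = 50
MAX_GMM_COMPONENTS = 20


@dataclass
class CellFeatureMatrix:
    """Per-cell mean normalized activity of each element cluster."""

    features: np.ndarray  # clusters x cells
    cluster_level: int
    cluster_raw_counts: np.ndarray  # summed raw counts, clusters x cells
    retained_mask: np.ndarray | None = None


@dataclass
class CellClustering:
    labels: np.ndarray
    n_clusters: int
    method: str
    embedding: np.ndarray | None = None


@dataclass
class PseudoCell:
    """Per-bin read counts pooled over the member cells of one cluster."""

    counts: np.ndarray
    L: float
    member_ids: list[str]
    cluster_id: int


def feature_level(hierarchy: CREHierarchy, target: int = FEATURE_LEVEL_TARGET) -> int:
    """The hierarchy level closest to the stage-1 cluster count."""
    return min(hierarchy.levels, key=lambda K: (abs(K - target), K))


def build_cell_features(
    cell_counts: BinCountMatrix,
    hierarchy: CREHierarchy,
    catalog: CRECatalog,
    level: int | None = None,
) -> CellFeatureMatrix:
    """Average log2(y/L + 1) over each element cluster, per cell.

    Cells with zero total reads yield all-zero feature vectors.
    """
    if level is None:
        level = feature_level(hierarchy)
    labels = hierarchy.assignments[level]
    y = cell_counts.counts[catalog.bin_indices].astype(float)
    L = cell_counts.library_factors
    safe_L = np.where(L > 0, L, 1.0)
    norm = np.log2(y / safe_L + 1.0)
    norm[:, L <= 0] = 0.0
    n_clusters = int(labels.max()) + 1
    features = np.zeros((n_clusters, y.shape[1]))
    raw = np.zeros((n_clusters, y.shape[1]))
    np.add.at(features, labels, norm)
    np.add.at(raw, labels, y)
    sizes = np.bincount(labels, minlength=n_clusters).astype(float)
    sizes[sizes == 0] = 1.0
    features /= sizes[:, None]
    return CellFeatureMatrix(
        features=features, cluster_level=level, cluster_raw_counts=raw
    )


def quantile_normalize(features: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean of the sorted columns.

    After normalization every column's sorted values equal the reference
    distribution; tied values within a column receive the average of the
    reference values at the tied positions. Idempotent.
    """
    F = np.asarray(features, dtype=float)
    if F.shape[1] == 0 or F.shape[0] == 0:
        return F.copy()
    reference = np.sort(F, axis=0).mean(axis=1)
    out = np.empty_like(F)
    for j in range(F.shape[1]):
        order = np.argsort(F[:, j], kind="stable")
        col = np.empty(F.shape[0])
        col[order] = reference
        # average reference values over groups of tied inputs
        out[:, j] = pd.Series(col).groupby(F[:, j]).transform("mean").to_numpy()
    return out


def filter_features(
    features: np.ndarray,
    cluster_raw_counts: np.ndarray,
    min_nonzero_frac: float = MIN_NONZERO_CELL_FRAC,
) -> np.ndarray:
    """Variability filter: keep features whose SD across cells exceeds the
    cubic-polynomial trend of SD on mean, then require a nonzero summed
    read count in at least ``min_nonzero_frac`` of cells."""
    F = np.asarray(features, dtype=float)
    means = F.mean(axis=1)
    sds = F.std(axis=1)
    if F.shape[0] < 4:
        logger.warning("fewer than 4 features: skipping polynomial variability fit")
        variable = np.ones(F.shape[0], dtype=bool)
    else:
        coeffs = np.polyfit(means, sds, deg=3)
        expected = np.polyval(coeffs, means)
        variable = sds > expected
    nonzero_frac = (np.asarray(cluster_raw_counts) > 0).mean(axis=1)
    return variable & (nonzero_frac >= min_nonzero_frac)


def _canonical_cell_order(features: np.ndarray) -> np.ndarray:
    """Deterministic cell order independent of input order (feature-lex)."""
    keys = list(features[::-1]) + [np.arange(features.shape[1])]
    return np.lexsort(keys[:-1]) if features.shape[0] else np.arange(features.shape[1])


def cluster_cells(
    features_retained: np.ndarray,
    n_pcs: int = N_PCS,
    seed: int | None = 0,
    user_k: int | None = None,
    user_labels: np.ndarray | None = None,
    perplexity: float | None = None,
) -> CellClustering:
    """Cluster cells on a 2-D embedding of their feature profiles.

    PCA to ``min(n_pcs, rank)`` components, stochastic-neighbor embedding
    to 2-D at fixed seed, then Gaussian-mixture clustering on the
    embedding with the component count (1..20) and covariance family
    (full vs diagonal) chosen by BIC. ``user_labels`` bypasses everything;
    ``user_k`` forces exactly that many clusters. Cells are processed in a
    canonical order so results are invariant to input order up to label
    permutation.
    """
    if user_labels is not None:
        labels = np.asarray(user_labels)
        return CellClustering(
            labels=labels, n_clusters=len(np.unique(labels)), method="user_labels"
        )
    F = np.asarray(features_retained, dtype=float)
    n_cells = F.shape[1]
    if n_cells < 2:
        raise ValueError("need >= 2 cells to cluster")
    if user_k is not None and user_k > n_cells:
        raise ValueError("user_k exceeds the number of cells")

    order = _canonical_cell_order(F)
    X = F[:, order].T  # cells x features, canonical order
    n_comp = max(1, min(n_pcs, n_cells - 1, X.shape[1]))
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if perplexity is None:
        perplexity = min(30.0, (n_cells - 1) / 3.0)
    emb = TSNE(
        n_components=2,
        perplexity=max(perplexity, 1.0),
        random_state=seed,
        init="pca",
    ).fit_transform(pcs)

    if user_k is not None:
        labels_c = _fit_gmm(emb, user_k, "full", seed).fit_predict(emb)
        if len(np.unique(labels_c)) < user_k:  # empty components: fall back
            labels_c = KMeans(n_clusters=user_k, n_init=10, random_state=seed).fit_predict(emb)
        method = "user_k"
    else:
        best = None
        for k in range(1, min(MAX_GMM_COMPONENTS, n_cells) + 1):
            for cov in ("full", "diag"):
                gm = _fit_gmm(emb, k, cov, seed).fit(emb)
                bic = gm.bic(emb)
                if best is None or bic < best[0]:
                    best = (bic, gm)
        labels_c = best[1].predict(emb)
        method = "default"

    labels = np.empty(n_cells, dtype=np.int64)
    labels[order] = labels_c
    embedding = np.empty_like(emb)
    embedding[order] = emb
    # relabel to consecutive ids in first-appearance order
    _, labels = np.unique(labels, return_inverse=True)
    return CellClustering(
        labels=labels,
        n_clusters=len(np.unique(labels)),
        method=method,
        embedding=embedding,
    )


def _fit_gmm(emb: np.ndarray, k: int, cov: str, seed) -> GaussianMixture:
    return GaussianMixture(
        n_components=k,
        covariance_type=cov,
        random_state=seed,
        n_init=3,
        reg_covar=1e-4,
    )


def pool_cells(cell_counts: BinCountMatrix, clustering: CellClustering) -> list[PseudoCell]:
    """Sum reads over the member cells of each cluster."""
    out = []
    for cid in np.unique(clustering.labels):
        members = np.flatnonzero(clustering.labels == cid)
        pooled = cell_counts.counts[:, members].sum(axis=1)
        out.append(
            PseudoCell(
                counts=pooled,
                L=float(pooled.sum()) / LIBRARY_UNIT,
                member_ids=[cell_counts.sample_ids[i] for i in members],
                cluster_id=int(cid),
            )
        )
    return out


@dataclass
class PseudoCellResult:
    pseudo_cell: PseudoCell
    spline: BiasSpline
    chosen_K: int
    cv_scores: dict[int, float]
    signal: ReconstructedSignal
    track: np.ndarray | None = None
    source_tags: np.ndarray | None = None


@dataclass
class CompendiumArtifacts:
    """Everything the multi-cell pipeline needs from the bulk compendium."""

    catalog: CRECatalog
    effects: LocusEffects  # catalog rows
    lowvar: LowVariabilitySet  # indices into catalog rows
    hierarchy: CREHierarchy
    genome_effects: LocusEffects | None = None  # all bins, for postprocessing


def analyze_pseudo_cell(
    pseudo: PseudoCell,
    artifacts: CompendiumArtifacts,
    seed: int | None = 0,
    cv_candidates: list[int] | None = None,
) -> PseudoCellResult:
    """Single-pseudo-cell path: bias fit, CV over K, reconstruction."""
    y_cat = pseudo.counts[artifacts.catalog.bin_indices].astype(float)
    spline = fit_bias_function(y_cat, artifacts.effects, pseudo.L, lowvar=artifacts.lowvar)
    chosen_K, scores = cross_validate_K(
        y_cat,
        artifacts.hierarchy,
        artifacts.effects,
        spline,
        pseudo.L,
        candidates=cv_candidates,
        seed=seed,
    )
    signal = reconstruct(
        y_cat,
        artifacts.hierarchy,
        chosen_K,
        artifacts.effects,
        spline,
        pseudo.L,
        provenance={"pseudo_cell": pseudo.cluster_id, "seed": seed},
    )
    return PseudoCellResult(
        pseudo_cell=pseudo,
        spline=spline,
        chosen_K=chosen_K,
        cv_scores=scores,
        signal=signal,
    )


def run_scate(
    cell_counts: BinCountMatrix,
    artifacts: CompendiumArtifacts,
    seed: int | None = 0,
    user_k: int | None = None,
    user_labels: np.ndarray | None = None,
    cv_candidates: list[int] | None = None,
    postprocess: bool = True,
) -> tuple[CellClustering, list[PseudoCellResult]]:
    """Full multi-cell pipeline.

    Cluster cells, pool each cluster into a pseudo-cell, and for each
    pseudo-cell fit the bias function, cross-validate the resolution,
    reconstruct element activities, and (optionally) extend the signal to
    all remaining genomic bins. Deterministic given the seed.
    """
    feats = build_cell_features(cell_counts, artifacts.hierarchy, artifacts.catalog)
    qn = quantile_normalize(feats.features)
    retained = filter_features(qn, feats.cluster_raw_counts)
    if retained.sum() == 0:
        logger.warning("variability filter removed every feature; keeping all")
        retained = np.ones(len(retained), dtype=bool)
    feats.retained_mask = retained
    clustering = cluster_cells(
        qn[retained], seed=seed, user_k=user_k, user_labels=user_labels
    )
    results = []
    for pseudo in pool_cells(cell_counts, clustering):
        res = analyze_pseudo_cell(pseudo, artifacts, seed=seed, cv_candidates=cv_candidates)
        if postprocess and artifacts.genome_effects is not None:
            from screg.postprocess import assemble_track, predict_noncre_bins

            track = predict_noncre_bins(
                pseudo.counts,
                pseudo.L,
                artifacts.genome_effects,
                artifacts.catalog.bin_indices,
                res.signal,
                seed=seed,
            )
            res.track, res.source_tags = assemble_track(
                res.signal, track, artifacts.catalog.bin_indices
            )
        results.append(res)
    return clustering, results
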