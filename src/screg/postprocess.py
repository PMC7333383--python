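"""Extend reconstructed element activities to the rest of the genome.

Bins outside the element catalog fall in two classes: bins with zero
scATAC-seq reads across all cells get activity 0; the remaining bins get
a prediction from gradient-boosted regression trees trained on catalog
bins with predictors (normalized count, m, s) and the reconstructed
activity as response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from screg.compendium import LocusEffects
from screg.model import ReconstructedSignal

logger = logging.getLogger(__name__)

SOURCE_CRE = "cre"
SOURCE_PREDICTED = "predicted"
SOURCE_ZERO = "zero"

GBT_PARAMS = {"n_estimators": 100, "max_depth": 4, "learning_rate": 0.1}


@dataclass
class GenomeTrack:
    """Per-bin signal with a source tag: 'cre' | 'predicted' | 'zero'."""

    values: np.ndarray
    source: np.ndarray


def _feature_matrix(counts, L, effects: LocusEffects, rows) -> np.ndarray:
    m = effects.m[rows].copy()
    finite = np.isfinite(effects.m)
    floor = effects.m[finite].min() - 1.0 if finite.any() else -1.0
    m[~np.isfinite(m)] = floor  # bins unseen in the compendium
    return np.column_stack([counts[rows] / L, m, effects.s[rows]])


def predict_noncre_bins(
    counts: np.ndarray,
    L: float,
    effects: LocusEffects,
    catalog_bins: np.ndarray,
    reconstructed: ReconstructedSignal,
    seed: int | None = 0,
    log_scale: bool = False,
    mask: np.ndarray | None = None,
) -> GenomeTrack:
    """Predict activities for non-catalog bins.

    ``counts`` and ``effects`` cover all genome bins; ``catalog_bins``
    indexes the catalog rows of ``reconstructed``. Zero-count non-catalog
    bins are set to 0. ``log_scale=True`` regresses ``log(mu)`` instead of
    ``mu``. Masked bins (``mask``) are excluded from training and zeroed.
    Predictions are clipped at 0; fixed seed makes them reproducible.
    """
    counts = np.asarray(counts, dtype=float)
    catalog_bins = np.asarray(catalog_bins)
    if len(catalog_bins) == 0:
        raise ValueError("no catalog bins to train on")
    n = len(counts)
    values = np.zeros(n)
    source = np.full(n, SOURCE_ZERO, dtype=object)
    source[catalog_bins] = SOURCE_CRE

    train_rows = catalog_bins
    if mask is not None:
        train_rows = train_rows[~mask[train_rows]]
    response = reconstructed.mu[np.searchsorted(catalog_bins, train_rows)]
    if log_scale:
        response = np.log(np.maximum(response, 1e-300))
    if np.ptp(response) == 0:
        logger.warning("constant reconstruction response: predictions will be constant")
    X = _feature_matrix(counts, L, effects, train_rows)
    model = GradientBoostingRegressor(random_state=seed, **GBT_PARAMS)
    model.fit(X, response)

    in_catalog = np.zeros(n, dtype=bool)
    in_catalog[catalog_bins] = True
    target = ~in_catalog & (counts > 0)
    if mask is not None:
        target &= ~mask
    if target.any():
        pred = model.predict(_feature_matrix(counts, L, effects, np.flatnonzero(target)))
        if log_scale:
            pred = np.exp(pred)
        values[target] = np.clip(pred, 0.0, None)
        source[target] = SOURCE_PREDICTED
    return GenomeTrack(values=values, source=source)


def assemble_track(
    reconstructed: ReconstructedSignal,
    predictions: GenomeTrack,
    catalog_bins: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge catalog activities into the predicted track.

    Catalog bins always carry the reconstructed ``mu`` unchanged; other
    bins keep their predicted (or zero) values and tags.
    """
    values = predictions.values.copy()
    source = predictions.source.copy()
    values[catalog_bins] = reconstructed.mu
    source[catalog_bins] = SOURCE_CRE
    return values, source
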