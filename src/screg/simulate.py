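"""Generative simulator matching the model assumed by the pipeline.

Bulk compendium samples and single cells are drawn from the same
Poisson-lognormal process the estimators assume: each planted element has
baseline effects ``(m, s)``, elements in the same cluster share a
per-sample activity ``delta ~ N(0, 1)`` (bulk) or a per-cell-type cluster
activity ``beta ~ N(0, 1)`` (single cell), and counts are Poisson with a
cell-specific monotone technical bias on the single-cell side. Simulated
datasets therefore support closed-loop parameter-recovery tests with
known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from screg.genome import (
    LIBRARY_UNIT,
    BinCountMatrix,
    GenomeBinIndex,
    library_factors_from_totals,
    segment_genome,
)

DEFAULT_M_MEAN, DEFAULT_M_SD = 0.5, 1.0
DEFAULT_M_RANGE = (-2.0, 4.0)
DEFAULT_S_RANGE = (0.2, 1.2)
DEFAULT_BG_RATE = 0.05  # expected background reads per bin at L=1

BIAS_SPECS = {
    "identity": lambda x: x,
    "affine": lambda x: 0.5 + 0.8 * x,
    "smooth": lambda x: 0.5 * x + 1.2 * np.log1p(np.exp(0.8 * x)) - 0.5,
}


@dataclass
class SimulationTruth:
    """Ground truth sufficient to recompute every expected value."""

    index: GenomeBinIndex
    cre_bins: np.ndarray  # bin indices of planted elements
    m: np.ndarray  # per planted element, natural log
    s: np.ndarray
    cluster_labels: np.ndarray  # per planted element
    n_clusters: int
    bg_rate: float
    seed: int | None
    delta: np.ndarray | None = None  # clusters x bulk samples
    bias_spec: str = "identity"
    type_beta: np.ndarray | None = None  # cell types x clusters
    extras: dict = field(default_factory=dict)

    def log_mu_for_type(self, t: int) -> np.ndarray:
        """True log activity of each planted element for cell type ``t``."""
        beta = self.type_beta[t]
        return self.m + self.s * beta[self.cluster_labels]

    def to_json(self, path) -> None:
        payload = {
            "chrom_sizes": self.index.chrom_sizes,
            "bin_width": self.index.bin_width,
            "cre_bins": self.cre_bins.tolist(),
            "m": self.m.tolist(),
            "s": self.s.tolist(),
            "cluster_labels": self.cluster_labels.tolist(),
            "n_clusters": self.n_clusters,
            "bg_rate": self.bg_rate,
            "seed": self.seed,
            "bias_spec": self.bias_spec,
            "delta": None if self.delta is None else self.delta.tolist(),
            "type_beta": None if self.type_beta is None else self.type_beta.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            index=segment_genome(p["chrom_sizes"], p["bin_width"]),
            cre_bins=np.array(p["cre_bins"]),
            m=np.array(p["m"]),
            s=np.array(p["s"]),
            cluster_labels=np.array(p["cluster_labels"]),
            n_clusters=p["n_clusters"],
            bg_rate=p["bg_rate"],
            seed=p["seed"],
            bias_spec=p["bias_spec"],
            delta=None if p["delta"] is None else np.array(p["delta"]),
            type_beta=None if p["type_beta"] is None else np.array(p["type_beta"]),
        )


def _draw_effects(rng, n, m_dist, s_dist):
    if m_dist is None:
        lo, hi = DEFAULT_M_RANGE
        a = (lo - DEFAULT_M_MEAN) / DEFAULT_M_SD
        b = (hi - DEFAULT_M_MEAN) / DEFAULT_M_SD
        m = truncnorm.rvs(
            a, b, loc=DEFAULT_M_MEAN, scale=DEFAULT_M_SD, size=n, random_state=rng
        )
    else:
        m = rng.uniform(m_dist[0], m_dist[1], size=n)
    if s_dist is None:
        s_dist = DEFAULT_S_RANGE
    s = rng.uniform(s_dist[0], s_dist[1], size=n)
    return m, s


def simulate_compendium(
    n_bins: int = 2000,
    n_samples: int = 20,
    n_cres: int = 500,
    n_clusters: int = 10,
    m_dist: tuple[float, float] | None = None,
    s_dist: tuple[float, float] | None = None,
    library_sizes: np.ndarray | None = None,
    bg_rate: float = DEFAULT_BG_RATE,
    bin_width: int = 200,
    seed: int | None = 0,
) -> tuple[BinCountMatrix, SimulationTruth]:
    """Simulate a bulk compendium from the Poisson-lognormal model.

    ``n_cres`` planted elements (random bins) get ``(m, s)`` draws and are
    assigned to ``n_clusters`` co-activation clusters; elements of one
    cluster share a per-sample ``delta ~ N(0, 1)``. Counts are
    ``Poisson(L * exp(m + s*delta))``; background bins are Poisson at a
    low constant rate. Library factors are taken as given (default 1).
    """
    rng = np.random.default_rng(seed)
    index = segment_genome({"chr1": n_bins * bin_width}, bin_width)
    if n_cres > n_bins:
        raise ValueError("more planted elements than bins")
    cre_bins = np.sort(rng.choice(n_bins, size=n_cres, replace=False))
    m, s = _draw_effects(rng, n_cres, m_dist, s_dist)
    labels = rng.integers(0, n_clusters, size=n_cres)
    delta = rng.standard_normal((n_clusters, n_samples))
    if library_sizes is None:
        library_sizes = np.ones(n_samples)
    L = np.asarray(library_sizes, dtype=float)
    mu = np.exp(m[:, None] + s[:, None] * delta[labels])  # elements x samples
    counts = np.zeros((n_bins, n_samples), dtype=np.int64)
    counts[cre_bins] = rng.poisson(L[None, :] * mu)
    bg = np.setdiff1d(np.arange(n_bins), cre_bins)
    counts[bg] = rng.poisson(np.broadcast_to(L * bg_rate, (len(bg), n_samples)))
    matrix = BinCountMatrix(
        index=index,
        counts=counts,
        library_factors=L,
        sample_ids=[f"bulk{j}" for j in range(n_samples)],
    )
    truth = SimulationTruth(
        index=index,
        cre_bins=cre_bins,
        m=m,
        s=s,
        cluster_labels=labels,
        n_clusters=n_clusters,
        bg_rate=bg_rate,
        seed=seed,
        delta=delta,
    )
    return matrix, truth


def simulate_scatac(
    truth: SimulationTruth,
    n_cells_per_type: int = 50,
    reads_per_cell: float = 10_000.0,
    n_types: int = 1,
    bias_spec: str = "identity",
    seed: int | None = 0,
) -> tuple[BinCountMatrix, np.ndarray]:
    """Simulate single cells from the model, given compendium truth.

    Each cell type draws one ``beta ~ N(0, 1)`` per element cluster;
    within a cell, ``log mu = m + s * beta[cluster]`` for planted elements
    and ``log(bg_rate)`` elsewhere, distorted by the chosen monotone bias
    ``h``; the cell-level rate factor is set so the expected total read
    count equals ``reads_per_cell``. Returns the per-cell count matrix
    (cells as columns) and the cell-type label per cell.
    """
    if bias_spec not in BIAS_SPECS:
        raise ValueError(f"unknown bias_spec {bias_spec!r}")
    h = BIAS_SPECS[bias_spec]
    rng = np.random.default_rng(seed)
    index = truth.index
    n_bins = index.n_bins
    type_beta = rng.standard_normal((n_types, truth.n_clusters))
    truth.type_beta = type_beta
    truth.bias_spec = bias_spec

    log_mu = np.full((n_bins, n_types), np.log(truth.bg_rate))
    for t in range(n_types):
        log_mu[truth.cre_bins, t] = truth.log_mu_for_type(t)
    mu_sc = np.exp(h(log_mu))

    n_cells = n_cells_per_type * n_types
    labels = np.repeat(np.arange(n_types), n_cells_per_type)
    counts = np.zeros((n_bins, n_cells), dtype=np.int64)
    for c, t in enumerate(labels):
        rate_factor = reads_per_cell / mu_sc[:, t].sum()
        counts[:, c] = rng.poisson(rate_factor * mu_sc[:, t])
    matrix = BinCountMatrix(
        index=index,
        counts=counts,
        library_factors=library_factors_from_totals(counts.sum(axis=0)),
        sample_ids=[f"cell{c}" for c in range(n_cells)],
    )
    return matrix, labels


def make_fixture_suite(out_dir, scale: str = "tiny", seed: int = 0) -> dict:
    """Write a self-contained text fixture set for end-to-end runs.

    ``tiny`` is sized to run the full pipeline in well under a minute;
    ``small`` supports parameter-recovery checks. Returns the paths
    written. Regeneration with the same seed is bit-identical.
    """
    from screg import compendium as comp
    from screg.io import write_count_matrix, write_regions_bed

    sizes = {
        "tiny": dict(n_bins=400, n_samples=10, n_cres=60, n_clusters=4, cells=30),
        "small": dict(n_bins=3000, n_samples=25, n_cres=600, n_clusters=10, cells=100),
    }
    if scale not in sizes:
        raise ValueError(f"unknown scale {scale!r}")
    cfg = sizes[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bulk, truth = simulate_compendium(
        n_bins=cfg["n_bins"],
        n_samples=cfg["n_samples"],
        n_cres=cfg["n_cres"],
        n_clusters=cfg["n_clusters"],
        m_dist=(2.5, 5.0),  # bright elements so signal-bin detection fires
        seed=seed,
    )
    cells, cell_labels = simulate_scatac(
        truth, n_cells_per_type=cfg["cells"] // 2, n_types=2, seed=seed
    )

    write_count_matrix(bulk, out / "compendium", fmt="mtx")
    write_count_matrix(cells, out / "cells", fmt="mtx")
    truth.to_json(out / "truth.json")

    norm = comp.normalize_counts(bulk)
    flags = comp.detect_signal_bins(bulk, norm)
    catalog = comp.compile_cres(flags, index=bulk.index)
    effects = comp.estimate_locus_effects(
        bulk.counts[catalog.bin_indices], bulk.library_factors
    )
    comp.write_locus_effects(effects, catalog, out / "effects.tsv", index=bulk.index)
    from screg.genome import RegionSet

    cat_regions = RegionSet.from_intervals(
        [bulk.index.bins[i] for i in catalog.bin_indices]
    )
    write_regions_bed(cat_regions, out / "catalog.bed")
    hierarchy = comp.cluster_cres(
        norm.values[catalog.bin_indices], stage1_k=min(50, len(catalog)), seed=seed
    )
    comp.write_hierarchy(hierarchy, out / "hierarchy.tsv")
    np.savetxt(out / "cell_labels.tsv", cell_labels, fmt="%d")
    return {
        "compendium": out / "compendium.mtx",
        "cells": out / "cells.mtx",
        "truth": out / "truth.json",
        "effects": out / "effects.tsv",
        "catalog": out / "catalog.bed",
        "hierarchy": out / "hierarchy.tsv",
    }
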