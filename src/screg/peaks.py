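"""Moving-average empirical-FDR peak calling and TFBS ranking.

The per-bin statistic is the average signal over the bin and its 2W
neighbors (windows truncated at chromosome ends). A background
distribution is built from the means of 2W+1 bins sampled uniformly at
random (with replacement, not necessarily neighboring) from the unmasked
bins. The empirical FDR at signal level s is the background exceedance
proportion divided by the observed proportion of bins at or above s,
monotonized so that stronger bins never have larger FDR. Significant bins
are merged into maximal runs of consecutive bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from screg.genome import GenomeBinIndex, RegionSet

logger = logging.getLogger(__name__)

DEFAULT_W = 1
DEFAULT_FDR = 0.05
DEFAULT_N_BACKGROUND = 100_000


@dataclass
class PeakSet:
    """Ranked peaks with per-peak FDR and mean moving-average signal."""

    regions: RegionSet
    fdr: np.ndarray
    mean_signal: np.ndarray
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fdr)

    @property
    def window_span_bp(self) -> int:
        return self.params["window_span_bp"]


def moving_average(values: np.ndarray, W: int, circular: bool = False) -> np.ndarray:
    """Mean over each position and its W neighbors on either side.

    Windows are truncated at the array ends unless ``circular``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if W == 0:
        return values.copy()
    if circular:
        ext = np.concatenate([values[-W:], values, values[:W]])
        csum = np.concatenate([[0.0], np.cumsum(ext)])
        return (csum[2 * W + 1 :] - csum[:n]) / (2 * W + 1)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - W, 0)
    hi = np.minimum(np.arange(n) + W + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _empirical_fdr(stat: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Monotone empirical FDR per bin.

    raw(s) = [#background > s / n_bg] / [#bins >= s / #bins]; the raw
    values are then replaced by the running maximum over bins with larger
    statistics so FDR is non-increasing in s.
    """
    n = len(stat)
    bg_sorted = np.sort(background)
    stat_sorted = np.sort(stat)
    n_bg_greater = len(background) - np.searchsorted(bg_sorted, stat, side="right")
    n_obs_ge = n - np.searchsorted(stat_sorted, stat, side="left")
    raw = (n_bg_greater / len(background)) / (n_obs_ge / n)
    order = np.argsort(-stat, kind="stable")  # strongest first
    fdr = np.empty(n)
    fdr[order] = np.maximum.accumulate(raw[order])
    return np.minimum(fdr, 1.0)


def call_peaks(
    track: np.ndarray,
    index: GenomeBinIndex,
    W: int = DEFAULT_W,
    fdr_cutoff: float = DEFAULT_FDR,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int | None = 0,
) -> PeakSet:
    """Call peaks on a per-bin signal track.

    Bins with monotonized empirical FDR below ``fdr_cutoff`` are merged
    into maximal runs of consecutive unmasked bins within a chromosome.
    Peaks are ranked by (FDR ascending, mean signal descending). An
    all-constant track is degenerate and yields no peaks.
    """
    track = np.asarray(track, dtype=float)
    if track.shape[0] != index.n_bins:
        raise ValueError("track length does not match bin index")
    if index.n_bins < 2 * W + 1:
        raise ValueError("track shorter than the moving-average window")
    unmasked = ~index.blacklist_mask

    stat = np.zeros(index.n_bins)
    for sl in index.chrom_slices().values():
        stat[sl] = moving_average(track[sl], W)

    params = {
        "W": W,
        "fdr_cutoff": fdr_cutoff,
        "n_background": n_background,
        "seed": seed,
        "window_span_bp": (2 * W + 1) * index.bin_width,
    }
    pool = track[unmasked]
    if np.ptp(pool) == 0:
        logger.warning("constant track: empirical FDR is ill-posed, returning no peaks")
        return PeakSet(RegionSet.empty(), np.empty(0), np.empty(0), params)

    rng = np.random.default_rng(seed)
    background = pool[rng.integers(0, len(pool), size=(n_background, 2 * W + 1))].mean(axis=1)

    fdr = np.full(index.n_bins, 1.0)
    idx_unmasked = np.flatnonzero(unmasked)
    fdr[idx_unmasked] = _empirical_fdr(stat[idx_unmasked], background)

    # bins at the pooled minimum carry no signal; the strict-'>' numerator
    # would otherwise give them a spuriously small FDR on sparse tracks
    significant = (fdr < fdr_cutoff) & unmasked & (stat > stat[unmasked].min())
    sig = np.flatnonzero(significant)
    intervals, peak_fdr, peak_signal = [], [], []
    if len(sig):
        breaks = np.flatnonzero(
            (np.diff(sig) != 1) | (index.bin_chrom[sig[1:]] != index.bin_chrom[sig[:-1]])
        )
        for run in np.split(sig, breaks + 1):
            chrom = index.chrom_names[index.bin_chrom[run[0]]]
            intervals.append((chrom, int(index.starts[run[0]]), int(index.ends[run[-1]])))
            peak_fdr.append(float(fdr[run].min()))
            peak_signal.append(float(stat[run].mean()))
    peak_fdr = np.array(peak_fdr)
    peak_signal = np.array(peak_signal)
    order = np.lexsort((-peak_signal, peak_fdr)) if len(peak_fdr) else np.empty(0, dtype=int)
    regions = RegionSet.from_intervals(
        [intervals[i] for i in order],
        scores=peak_signal[order] if len(order) else None,
        names=np.array([f"peak{r + 1}" for r in range(len(order))], dtype=object)
        if len(order)
        else None,
    )
    # RegionSet re-sorts to genome order; keep rank-ordered arrays alongside
    return PeakSet(
        regions=regions,
        fdr=peak_fdr[order],
        mean_signal=peak_signal[order],
        params=params | {"ranked_intervals": [intervals[i] for i in order]},
    )


def peaks_to_bed(peaks: PeakSet, path) -> None:
    """BED6+2: name=rank, score=-log10 FDR capped at 1000, +mean_signal, fdr."""
    ranked = peaks.params.get("ranked_intervals", list(peaks.regions))
    with open(path, "w") as fh:
        for rank, (chrom, start, end) in enumerate(ranked, start=1):
            q = peaks.fdr[rank - 1]
            score = 1000.0 if q <= 0 else min(-np.log10(q), 1000.0)
            fh.write(
                f"{chrom}\t{start}\t{end}\tpeak{rank}\t{score:.4g}\t.\t"
                f"{peaks.mean_signal[rank - 1]:.6g}\t{q:.6g}\n"
            )


# ---------------------------------------------------------------------------
# evaluation

def _overlaps(a: tuple[str, int, int], regions: RegionSet) -> bool:
    chrom, start, end = a
    for rc, rs, re_ in regions:
        if rc == chrom and start < re_ and rs < end:
            return True
    return False


def sensitivity_fdr_curve(
    ranked: list[tuple[str, int, int]], truth: RegionSet
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sensitivity vs FDR along a ranked prediction list, plus AUC.

    At each prefix of the ranking, sensitivity is the fraction of truth
    regions overlapped (>= 1 bp) by any prediction so far and FDR the
    fraction of predictions so far that overlap no truth region. AUC is
    the trapezoid over FDR in [0, 1] along the walked curve, starting at
    (0, 0) and extended horizontally to FDR = 1 at the final sensitivity.
    """
    n_truth = len(truth)
    hit = np.zeros(n_truth, dtype=bool)
    sens, fdr = [], []
    n_false = 0
    for k, pred in enumerate(ranked, start=1):
        chrom, start, end = pred[0], int(pred[1]), int(pred[2])
        matched = False
        for t in range(n_truth):
            if (
                truth.chroms[t] == chrom
                and start < truth.ends[t]
                and truth.starts[t] < end
            ):
                hit[t] = True
                matched = True
        if not matched:
            n_false += 1
        sens.append(hit.sum() / n_truth if n_truth else 0.0)
        fdr.append(n_false / k)
    sens_arr = np.array(sens)
    fdr_arr = np.array(fdr)
    x = np.concatenate([[0.0], fdr_arr, [1.0]])
    y = np.concatenate([[0.0], sens_arr, [sens_arr[-1] if len(sens_arr) else 0.0]])
    auc = float(np.trapezoid(y, x))
    return sens_arr, fdr_arr, auc


def predict_tfbs(
    track: np.ndarray, index: GenomeBinIndex, motif_bins: RegionSet
) -> RegionSet:
    """Rank motif-containing bins by track signal, descending.

    Ties are broken by genome order (motif bins arrive genome-sorted).
    Returns a RegionSet-like ranking: scores carry the signal and names
    the rank; the returned intervals are in rank order via ``names``.
    """
    signals = []
    for chrom, start, _end in motif_bins:
        i = index.bin_of(chrom, start)
        signals.append(track[i] if i >= 0 else 0.0)
    signals = np.array(signals)
    order = np.argsort(-signals, kind="stable")
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(1, len(order) + 1)
    return RegionSet(
        motif_bins.chroms.copy(),
        motif_bins.starts.copy(),
        motif_bins.ends.copy(),
        scores=signals,
        names=np.array([f"rank{r}" for r in ranks], dtype=object),
    )


def ranked_motif_bins(ranked: RegionSet) -> list[tuple[str, int, int]]:
    """Materialize the rank order encoded by :func:`predict_tfbs`."""
    order = np.argsort([-s for s in ranked.scores], kind="stable")
    return [
        (ranked.chroms[i], int(ranked.starts[i]), int(ranked.ends[i])) for i in order
    ]
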