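"""Genome binning, region sets, and bin-level count matrices.

Coordinates are 0-based half-open (BED convention) throughout. The genome
is partitioned into fixed-width non-overlapping bins; the trailing bin of
each chromosome may be shorter and is flagged so that width-dependent
statistics can exclude it. Bins overlapping a blacklist region by at least
one bp are masked: they keep their raw counts internally (so library
factors reflect sequencing depth) but are excluded from element detection,
background sampling, and peak output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 200
#: library factors are total reads in units of one hundred million
LIBRARY_UNIT = 1e8


@dataclass
class RegionSet:
    """An ordered set of genomic intervals with optional scores.

    Intervals are half-open ``[start, end)`` and sorted by
    ``(chrom, start, end)`` on construction.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray | None = None
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
        if self.names is not None:
            self.names = np.asarray(self.names, dtype=object)
        if np.any(self.starts >= self.ends):
            raise ValueError("all intervals must satisfy start < end")
        order = np.lexsort((self.ends, self.starts, _chrom_sort_key(self.chroms)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chroms = self.chroms[order]
            self.starts = self.starts[order]
            self.ends = self.ends[order]
            if self.scores is not None:
                self.scores = self.scores[order]
            if self.names is not None:
                self.names = self.names[order]

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for i in range(len(self)):
            yield (self.chroms[i], int(self.starts[i]), int(self.ends[i]))

    @classmethod
    def from_intervals(cls, intervals, scores=None, names=None) -> "RegionSet":
        """Build from an iterable of ``(chrom, start, end)`` tuples."""
        intervals = list(intervals)
        if intervals:
            chroms, starts, ends = map(np.asarray, zip(*intervals))
        else:
            chroms = np.empty(0, dtype=object)
            starts = ends = np.empty(0, dtype=np.int64)
        return cls(chroms, starts, ends, scores=scores, names=names)

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls.from_intervals([])

    def as_tuples(self) -> list[tuple[str, int, int]]:
        return list(self)


def _chrom_sort_key(chroms: np.ndarray) -> np.ndarray:
    uniq = sorted(set(chroms.tolist()))
    lut = {c: i for i, c in enumerate(uniq)}
    return np.array([lut[c] for c in chroms.tolist()])


@dataclass
class GenomeBinIndex:
    """Fixed-width partition of a genome into bins.

    Attributes
    ----------
    chrom_sizes : dict
        Chromosome name -> length in bp.
    bin_width : int
        Nominal bin width; the last bin per chromosome may be shorter.
    chrom_names : list of str
        Chromosome order used for the bin arrays.
    bin_chrom : int array, codes into ``chrom_names`` per bin.
    starts, ends : int arrays, per-bin half-open coordinates.
    blacklist_mask : bool array, True where the bin overlaps a blacklist
        interval by >= 1 bp.
    partial_mask : bool array, True for trailing partial bins.
    """

    chrom_sizes: dict[str, int]
    bin_width: int
    chrom_names: list[str]
    bin_chrom: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    blacklist_mask: np.ndarray
    partial_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.partial_mask is None:
            self.partial_mask = (self.ends - self.starts) != self.bin_width

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def bins(self) -> list[tuple[str, int, int]]:
        return [
            (self.chrom_names[c], int(s), int(e))
            for c, s, e in zip(self.bin_chrom, self.starts, self.ends)
        ]

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous bin-index slice per chromosome, in genome order."""
        out: dict[str, slice] = {}
        for code, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.bin_chrom == code)
            if len(idx):
                out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index containing position ``pos``; -1 if off-genome."""
        if chrom not in self.chrom_sizes or not (0 <= pos < self.chrom_sizes[chrom]):
            return -1
        code = self.chrom_names.index(chrom)
        first = int(np.searchsorted(self.bin_chrom, code))
        return first + pos // self.bin_width

    def region_mask(self, regions: RegionSet) -> np.ndarray:
        """Boolean per-bin mask of >=1-bp overlap with ``regions``."""
        mask = np.zeros(self.n_bins, dtype=bool)
        offsets = {}
        counts = {}
        for code, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.bin_chrom == code)
            if len(idx):
                offsets[name] = int(idx[0])
                counts[name] = len(idx)
        for chrom, start, end in regions:
            if chrom not in offsets:
                continue
            start = max(0, start)
            end = min(self.chrom_sizes[chrom], end)
            if start >= end:
                continue
            first = start // self.bin_width
            last = (end - 1) // self.bin_width
            last = min(last, counts[chrom] - 1)
            mask[offsets[chrom] + first : offsets[chrom] + last + 1] = True
        return mask


def segment_genome(
    chrom_sizes: dict[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
    blacklist: RegionSet | None = None,
) -> GenomeBinIndex:
    """Partition a genome into fixed-width bins and apply a blacklist.

    Every genomic bp falls in exactly one bin. Bins overlapping any
    blacklist interval (>= 1 bp) are masked. Blacklist intervals outside
    chromosome bounds are clipped.
    """
    if not chrom_sizes:
        raise ValueError("no genome")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    chrom_names = list(chrom_sizes)
    codes, starts, ends = [], [], []
    for code, name in enumerate(chrom_names):
        size = chrom_sizes[name]
        if size <= 0:
            raise ValueError(f"chromosome {name} has non-positive size")
        s = np.arange(0, size, bin_width, dtype=np.int64)
        e = np.minimum(s + bin_width, size)
        codes.append(np.full(len(s), code, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    index = GenomeBinIndex(
        chrom_sizes=dict(chrom_sizes),
        bin_width=bin_width,
        chrom_names=chrom_names,
        bin_chrom=np.concatenate(codes),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        blacklist_mask=np.zeros(sum(len(s) for s in starts), dtype=bool),
    )
    if blacklist is not None and len(blacklist):
        index.blacklist_mask = index.region_mask(blacklist)
    return index


@dataclass
class BinCountMatrix:
    """Raw read counts on genome bins, one column per sample/cell.

    ``library_factors`` are per-sample total read counts divided by 1e8
    (totals include reads in masked bins, so the factor tracks depth).
    """

    index: GenomeBinIndex
    counts: np.ndarray
    library_factors: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be bins x samples")
        if self.counts.shape[0] != self.index.n_bins:
            raise ValueError("counts row count does not match bin index")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.library_factors = np.asarray(self.library_factors, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def library_factors_from_totals(totals: np.ndarray) -> np.ndarray:
    return np.asarray(totals, dtype=float) / LIBRARY_UNIT


def count_reads_in_bins(
    read_positions: list[RegionSet],
    index: GenomeBinIndex,
    sample_ids: list[str] | None = None,
) -> BinCountMatrix:
    """Tally reads into bins by their 5' start coordinate.

    Each in-genome read increments exactly one bin. Reads on chromosomes
    absent from the index, or outside chromosome bounds, are skipped and
    logged. Library factors are set from the in-genome totals (masked
    bins included).
    """
    n_samples = len(read_positions)
    if sample_ids is None:
        sample_ids = [f"sample{j}" for j in range(n_samples)]
    counts = np.zeros((index.n_bins, n_samples), dtype=np.int64)
    chrom_code = {name: i for i, name in enumerate(index.chrom_names)}
    offsets = {}
    for code, name in enumerate(index.chrom_names):
        idx = np.flatnonzero(index.bin_chrom == code)
        if len(idx):
            offsets[name] = int(idx[0])
    skipped_total = 0
    for j, reads in enumerate(read_positions):
        skipped = 0
        for chrom, start, _end in reads:
            if chrom not in chrom_code or not (0 <= start < index.chrom_sizes[chrom]):
                skipped += 1
                continue
            counts[offsets[chrom] + start // index.bin_width, j] += 1
        if skipped:
            logger.warning("sample %s: skipped %d off-genome reads", sample_ids[j], skipped)
        skipped_total += skipped
    L = library_factors_from_totals(counts.sum(axis=0))
    for j in range(n_samples):
        if L[j] == 0:
            logger.warning("sample %s has zero in-genome reads", sample_ids[j])
    return BinCountMatrix(index=index, counts=counts, library_factors=L, sample_ids=list(sample_ids))
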