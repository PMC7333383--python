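"""Readers and writers for the plain-text formats used by the pipeline.

BED and bedGraph use 0-based half-open coordinates. Count matrices are
stored either as MatrixMarket (``.mtx``) with a bin BED and a sample list,
or as a dense TSV with a header row of sample ids and a leading
``chrom:start-end`` bin column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from screg.genome import (
    BinCountMatrix,
    GenomeBinIndex,
    RegionSet,
    library_factors_from_totals,
    segment_genome,
)

logger = logging.getLogger(__name__)

_SCORE_FMT = "{:.6g}"


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3/4/5 (name and score columns if present)."""
    has_name = regions.names is not None
    has_score = regions.scores is not None
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(regions):
            fields = [str(chrom), str(start), str(end)]
            if has_name or has_score:
                fields.append(str(regions.names[i]) if has_name else f"region{i}")
            if has_score:
                fields.append(_SCORE_FMT.format(regions.scores[i]))
            fh.write("\t".join(fields) + "\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    chroms, starts, ends, names, scores = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            if len(fields) > 3:
                names.append(fields[3])
            if len(fields) > 4:
                scores.append(float(fields[4]))
    return RegionSet(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        scores=np.array(scores) if scores else None,
        names=np.array(names, dtype=object) if names else None,
    )


def write_signal_track(signal: np.ndarray, index: GenomeBinIndex, path: str | Path) -> None:
    """Write a per-bin signal as bedGraph.

    One line per unmasked bin with a nonzero value; masked bins are never
    emitted. Values are written with full float precision so that
    write/read round-trips are bit exact.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != index.n_bins:
        raise ValueError("signal length does not match bin index")
    keep = (~index.blacklist_mask) & (signal != 0)
    with open(path, "w") as fh:
        for i in np.flatnonzero(keep):
            fh.write(
                f"{index.chrom_names[index.bin_chrom[i]]}\t{index.starts[i]}\t"
                f"{index.ends[i]}\t{float(signal[i])!r}\n"
            )


def read_signal_track(path: str | Path, index: GenomeBinIndex) -> np.ndarray:
    """Read a bedGraph written by :func:`write_signal_track` onto ``index``."""
    signal = np.zeros(index.n_bins, dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, value = line.split("\t")
            i = index.bin_of(chrom, int(start))
            if i < 0:
                raise ValueError(f"bedGraph interval {chrom}:{start} not in bin index")
            signal[i] = float(value)
    return signal


def write_count_matrix(matrix: BinCountMatrix, prefix: str | Path, fmt: str = "mtx") -> None:
    """Write a count matrix as MTX + bin BED + sample list, or as TSV.

    ``fmt='mtx'`` writes ``<prefix>.mtx``, ``<prefix>.bins.bed`` and
    ``<prefix>.samples.txt``; ``fmt='tsv'`` writes ``<prefix>.tsv`` only.
    """
    prefix = Path(prefix)
    if fmt == "mtx":
        scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(matrix.counts))
        _write_bin_bed(matrix.index, str(prefix) + ".bins.bed")
        with open(str(prefix) + ".samples.txt", "w") as fh:
            for sid in matrix.sample_ids:
                fh.write(sid + "\n")
    elif fmt == "tsv":
        with open(str(prefix) + ".tsv", "w") as fh:
            fh.write("bin\t" + "\t".join(matrix.sample_ids) + "\n")
            idx = matrix.index
            for i in range(idx.n_bins):
                label = f"{idx.chrom_names[idx.bin_chrom[i]]}:{idx.starts[i]}-{idx.ends[i]}"
                fh.write(label + "\t" + "\t".join(str(int(v)) for v in matrix.counts[i]) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_bin_bed(index: GenomeBinIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(index.n_bins):
            fh.write(
                f"{index.chrom_names[index.bin_chrom[i]]}\t{index.starts[i]}\t{index.ends[i]}\n"
            )


def _index_from_bin_bed(bins: RegionSet, bin_width: int | None = None) -> GenomeBinIndex:
    """Reconstruct a bin index from a bin BED (blacklist mask unknown)."""
    widths = bins.ends - bins.starts
    if bin_width is None:
        bin_width = int(np.bincount(widths.astype(int)).argmax()) if len(widths) else 200
    chrom_sizes: dict[str, int] = {}
    for chrom, _start, end in bins:
        chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    index = segment_genome(chrom_sizes, bin_width=bin_width)
    if index.n_bins != len(bins):
        raise ValueError("bin BED is not a contiguous fixed-width segmentation")
    return index


def read_count_matrix(
    path: str | Path,
    bin_bed: str | Path | None = None,
    sample_list: str | Path | None = None,
) -> BinCountMatrix:
    """Read a count matrix written by :func:`write_count_matrix`.

    For MTX input, ``bin_bed`` is required and ``sample_list`` optional;
    for TSV input both are ignored (bins and samples come from the file).
    Library factors are recomputed from column totals.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if bin_bed is None:
            raise ValueError("bin_bed is required for MTX input")
        counts = np.asarray(scipy.io.mmread(str(path)).todense()).astype(np.int64)
        index = _index_from_bin_bed(read_regions_bed(bin_bed))
        if sample_list is not None:
            with open(sample_list) as fh:
                sample_ids = [line.strip() for line in fh if line.strip()]
        else:
            sample_ids = [f"sample{j}" for j in range(counts.shape[1])]
    elif path.suffix == ".tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "bin":
                raise ValueError("malformed TSV header: first column must be 'bin'")
            sample_ids = header[1:]
            intervals, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                chrom, span = fields[0].split(":")
                start, end = span.split("-")
                intervals.append((chrom, int(start), int(end)))
                rows.append([int(v) for v in fields[1:]])
        counts = np.array(rows, dtype=np.int64)
        index = _index_from_bin_bed(RegionSet.from_intervals(intervals))
    else:
        raise ValueError(f"unsupported count-matrix extension {path.suffix!r}")
    if counts.shape[1] != len(sample_ids):
        raise ValueError("sample list length does not match matrix columns")
    return BinCountMatrix(
        index=index,
        counts=counts,
        library_factors=library_factors_from_totals(counts.sum(axis=0)),
        sample_ids=sample_ids,
    )
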