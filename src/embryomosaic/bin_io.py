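"""Genomic bin grid, reference tracks and count-matrix I/O.

Every other module works in the coordinate frame defined here: an ordered
list of fixed-width genomic bins (default 1 Mb). Counts, GC/mappability
tracks, copy-number states and segments are all vectors aligned 1:1 with
the grid.

File dialects (all plain text):

* bin grid   — BED, three tab-separated columns ``chrom  start  end``,
  no header, 0-based half-open coordinates.
* counts     — TSV with header; first column ``bin`` holds
  ``chrom:start-end`` keys, remaining columns are cells (rows = bins).
* tracks     — TSV with header ``bin  gc  mappability``.
* metadata   — TSV with header ``cell_id  embryo_id  lineage``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

DEFAULT_BIN_WIDTH = 1_000_000

#: Approximate human chromosome lengths (hg38, rounded to 1 Mb), used by the
#: synthetic generator to build a realistically sized genome.
HUMAN_CHROM_SIZES_MB = {
    "chr1": 248, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156,
}

SEX_CHROMS = ("chrX", "chrY")


class BinIOError(ValueError):
    """Raised on malformed grid/count/track input; message names the locus."""


@dataclass(frozen=True)
class BinGrid:
    """Ordered genomic bins (0-based, half-open) at fixed width.

    Bins within a chromosome must be sorted, contiguous and non-overlapping;
    only the terminal bin of a chromosome may be shorter than ``bin_width``.
    """

    chroms: np.ndarray          # object array of chromosome labels, per bin
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise BinIOError("grid column lengths differ")
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, int] = {}
        prev_chrom = None
        for i, (c, s, e) in enumerate(zip(self.chroms, self.starts, self.ends)):
            if e <= s:
                raise BinIOError(f"bin {i} ({c}:{s}-{e}): end <= start")
            if c != prev_chrom:
                if c in seen:
                    raise BinIOError(f"bin {i}: chromosome {c} is not contiguous in the grid")
                seen[c] = i
                prev_chrom = c
            else:
                ps, pe = self.starts[i - 1], self.ends[i - 1]
                if s < pe:
                    raise BinIOError(
                        f"bin {i} ({c}:{s}-{e}) overlaps or is unsorted against previous bin {c}:{ps}-{pe}"
                    )
                if s != pe:
                    raise BinIOError(f"bin {i} ({c}:{s}-{e}): gap after {c}:{ps}-{pe}")
                if pe - ps != self.bin_width:
                    raise BinIOError(
                        f"bin {i - 1} ({c}:{ps}-{pe}): non-terminal bin width != {self.bin_width}"
                    )

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        chroms, starts, ends = [], [], []
        for chrom, size in sizes.items():
            edges = list(range(0, size, bin_width)) + [size]
            for s, e in zip(edges[:-1], edges[1:]):
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
        return cls(np.array(chroms, dtype=object),
                   np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64),
                   bin_width)

    @classmethod
    def human(cls, sex: str = "XX", bin_width: int = DEFAULT_BIN_WIDTH) -> "BinGrid":
        """Grid over the rounded human genome; chrY appended for XY."""
        sizes = {c: mb * 1_000_000 for c, mb in HUMAN_CHROM_SIZES_MB.items()}
        if sex == "XY":
            sizes["chrY"] = 57 * 1_000_000
        return cls.from_chrom_sizes(sizes, bin_width)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def chrom_names(self) -> list[str]:
        out, prev = [], None
        for c in self.chroms:
            if c != prev:
                out.append(c)
                prev = c
        return out

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Global bin indices of one chromosome (a contiguous block)."""
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        return idx

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        idx = self.chrom_index(chrom)
        return int(self.starts[idx[0]]), int(self.ends[idx[-1]])

    def is_autosome(self) -> np.ndarray:
        return ~np.isin(self.chroms.astype(str), SEX_CHROMS)

    def bin_keys(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        idx = self.chrom_index(chrom)
        lo, hi = self.chrom_span(chrom)
        if not (lo <= pos < hi):
            raise KeyError(f"position {chrom}:{pos} outside grid")
        return int(idx[0] + (pos - lo) // self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinGrid)
                and self.bin_width == other.bin_width
                and len(self.chroms) == len(other.chroms)
                and bool(np.all(self.chroms == other.chroms))
                and bool(np.all(self.starts == other.starts))
                and bool(np.all(self.ends == other.ends)))


@dataclass
class ReferenceTracks:
    """Per-bin GC fraction and mappability, aligned 1:1 with a BinGrid.

    Values outside [0, 1] are rejected; NaN marks missing and the bin is
    masked downstream.
    """

    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self):
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        if self.gc.shape != self.mappability.shape:
            raise BinIOError("gc and mappability tracks differ in length")
        for name, arr in (("gc", self.gc), ("mappability", self.mappability)):
            bad = np.flatnonzero(~np.isnan(arr) & ((arr < 0) | (arr > 1)))
            if bad.size:
                raise BinIOError(f"{name} track value out of [0,1] at bin {bad[0]}")

    def check_grid(self, grid: BinGrid) -> None:
        if len(self.gc) != grid.n_bins:
            raise BinIOError(
                f"track length {len(self.gc)} does not match grid ({grid.n_bins} bins)")


@dataclass
class CountMatrix:
    """Raw per-cell, per-bin read counts (cells x bins) on a shared grid."""

    grid: BinGrid
    counts: np.ndarray            # shape (n_cells, n_bins), non-negative ints
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.grid.n_bins:
            raise BinIOError(
                f"count matrix shape {self.counts.shape} does not match grid "
                f"({self.grid.n_bins} bins)")
        if len(self.cell_ids) != self.counts.shape[0]:
            raise BinIOError("cell_ids length does not match count matrix")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            r, c = neg[0]
            raise BinIOError(
                f"negative count for cell {self.cell_ids[r]!r} at bin {c} "
                f"({self.grid.chroms[c]}:{self.grid.starts[c]}-{self.grid.ends[c]})")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def cell(self, cell_id: str) -> np.ndarray:
        return self.counts[self.cell_ids.index(cell_id)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_bin_grid(grid: BinGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bin_grid(path, bin_width: int | None = None) -> BinGrid:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], dtype={0: str})
    if df.empty:
        raise BinIOError(f"{path}: empty bin grid")
    if bin_width is None:
        bin_width = int((df["end"] - df["start"]).max())
    return BinGrid(df["chrom"].to_numpy(dtype=object),
                   df["start"].to_numpy(dtype=np.int64),
                   df["end"].to_numpy(dtype=np.int64),
                   bin_width)


def write_counts(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.counts.T, columns=cm.cell_ids)
    df.insert(0, "bin", cm.grid.bin_keys())
    df.to_csv(path, sep="\t", index=False)


def read_counts(path, grid: BinGrid) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "bin" not in df.columns:
        raise BinIOError(f"{path}: missing 'bin' header column")
    keys = grid.bin_keys()
    if list(df["bin"]) != keys:
        raise BinIOError(f"{path}: bin keys do not match the grid")
    cells = [c for c in df.columns if c != "bin"]
    counts = df[cells].to_numpy().T
    if not np.issubdtype(counts.dtype, np.number):
        raise BinIOError(f"{path}: non-numeric count entries")
    neg = np.argwhere(counts < 0)
    if neg.size:
        r, c = neg[0]
        raise BinIOError(f"{path}: negative count at row {c + 2} (bin {keys[c]}), column {cells[r]!r}")
    return CountMatrix(grid, counts.astype(np.int64), cells)


def write_tracks(tracks: ReferenceTracks, grid: BinGrid, path) -> None:
    pd.DataFrame({"bin": grid.bin_keys(), "gc": tracks.gc,
                  "mappability": tracks.mappability}).to_csv(path, sep="\t", index=False)


def read_tracks(path, grid: BinGrid) -> ReferenceTracks:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("bin", "gc", "mappability"):
        if col not in df.columns:
            raise BinIOError(f"{path}: missing {col!r} column")
    if list(df["bin"]) != grid.bin_keys():
        raise BinIOError(f"{path}: bin keys do not match the grid")
    tr = ReferenceTracks(df["gc"].to_numpy(), df["mappability"].to_numpy())
    tr.check_grid(grid)
    return tr


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("cell_id", "embryo_id", "lineage"):
        if col not in df.columns:
            raise BinIOError(f"{path}: missing {col!r} column")
    return df


# ---------------------------------------------------------------------------
# alignment-file ingestion
# ---------------------------------------------------------------------------

def count_reads_from_alignments(alignment_path, grid: BinGrid, min_mapq: int = 30) -> np.ndarray:
    """Bin counts for one cell from a SAM/BAM file.

    Retains primary, non-duplicate, mapped alignments with MAPQ >= ``min_mapq``
    (the proxy for "uniquely mapped") and assigns each to the bin containing
    its leftmost aligned base. Alignments on contigs absent from the grid are
    skipped with a single summary warning.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    known = set(map(str, grid.chrom_names))
    skipped_contigs = 0
    with pysam.AlignmentFile(str(alignment_path), "r", check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.is_duplicate or aln.mapping_quality < min_mapq):
                continue
            chrom = aln.reference_name
            if chrom not in known:
                skipped_contigs += 1
                continue
            lo, hi = grid.chrom_span(chrom)
            pos = aln.reference_start
            if not (lo <= pos < hi):
                skipped_contigs += 1
                continue
            counts[grid.bin_of(chrom, pos)] += 1
    if skipped_contigs:
        warnings.warn(f"{skipped_contigs} alignments on contigs/positions outside the grid were skipped")
    return counts
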