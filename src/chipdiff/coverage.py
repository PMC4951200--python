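"""Read ingestion and extended-read coverage tracks.

Single-end reads are reduced to their 5' start and strand, extended a
fixed number of bases (default 150 bp) in the 5'->3' direction, and
accumulated into per-base coverage tracks.  Tracks from several samples
are made comparable by scaling every sample up to the deepest library:

    y_ij = yRAW_ij * max_j(s_j) / s_j

where s_j is the total number of aligned reads of sample j.  The sample
with the largest s_j keeps scale factor 1.0; every other factor is > 1.

All coordinates are 0-based half-open, matching BED and bedGraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeTable

logger = logging.getLogger(__name__)

DEFAULT_EXTENSION = 150

READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned single-end read.

    ``start`` is the 0-based leftmost aligned position, ``end`` the
    exclusive rightmost (defaults to ``start + 1``).  Only the 5'
    terminus and strand matter for coverage.
    """

    chrom: str
    start: int
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end is None:
            object.__setattr__(self, "end", self.start + 1)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid read coordinates [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def five_prime(self) -> int:
        """0-based position of the 5' terminus."""
        return self.start if self.strand == "+" else self.end - 1


def _empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
        }
    )


@dataclass
class SampleLibrary:
    """One sample's aligned single-end reads plus its aligned-read total.

    ``reads`` is a DataFrame with columns chrom/start/end/strand.
    ``aligned_count`` (the normalization basis s_j) defaults to the
    number of reads but may be overridden, e.g. when a library was
    filtered upstream.
    """

    sample_id: str
    condition: str
    reads: pd.DataFrame = field(default_factory=_empty_reads)
    aligned_count: int | None = None
    skipped: int = 0

    def __post_init__(self) -> None:
        if self.aligned_count is None:
            self.aligned_count = len(self.reads)
        if self.aligned_count < 0:
            raise ValueError("aligned_count must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)

    def iter_reads(self):
        for row in self.reads.itertuples(index=False):
            yield AlignedRead(row.chrom, int(row.start), int(row.end), row.strand)

    def to_bed(self, path: str | Path) -> None:
        """Write reads as BED6 (name '.', score 0)."""
        df = self.reads
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": ".",
                "score": 0,
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def reads_frame(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    """Build the reads DataFrame from :class:`AlignedRead` records."""
    if not reads:
        return _empty_reads()
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": np.array([r.start for r in reads], dtype=np.int64),
            "end": np.array([r.end for r in reads], dtype=np.int64),
            "strand": [r.strand for r in reads],
        }
    )


def _load_bed(path: str | Path, genome: GenomeTable) -> tuple[pd.DataFrame, int]:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate in {line!r}"
                ) from None
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if chrom not in genome:
                skipped += 1
                continue
            if end > genome.length(chrom):
                raise ValueError(
                    f"{path}:{lineno}: read end {end} beyond {chrom} "
                    f"length {genome.length(chrom)}"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    if not chroms:
        return _empty_reads(), skipped
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": strands,
        }
    )
    return df, skipped


def _load_sam(path: str | Path, genome: GenomeTable) -> tuple[pd.DataFrame, int]:
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                skipped += 1
                continue
            chroms.append(chrom)
            starts.append(rec.reference_start)
            end = rec.reference_end
            ends.append(end if end is not None else rec.reference_start + 1)
            strands.append("-" if rec.is_reverse else "+")
    if not chroms:
        return _empty_reads(), skipped
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": strands,
        }
    )
    return df, skipped


def load_alignments(
    path: str | Path,
    genome: GenomeTable,
    format: Literal["bed", "sam"] = "bed",
    sample_id: str | None = None,
    condition: str = "",
) -> SampleLibrary:
    """Load single-end alignments from BED6 (or SAM) into a library.

    Reads on chromosomes absent from ``genome`` are skipped and counted
    (``library.skipped``); malformed coordinates are hard errors naming
    the offending line.  Unmapped SAM records are skipped silently.
    ``aligned_count`` is set to the number of retained reads.
    """
    fmt = format.lower()
    if fmt == "bed":
        df, skipped = _load_bed(path, genome)
    elif fmt == "sam":
        df, skipped = _load_sam(path, genome)
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if skipped:
        logger.warning(
            "%s: skipped %d reads on chromosomes absent from the genome table",
            path,
            skipped,
        )
    return SampleLibrary(
        sample_id=sample_id or Path(path).stem,
        condition=condition,
        reads=df,
        aligned_count=len(df),
        skipped=skipped,
    )


def extend_read(
    read: AlignedRead,
    genome: GenomeTable,
    extension: int = DEFAULT_EXTENSION,
    strand_aware: bool = True,
) -> tuple[str, int, int]:
    """Extend a read to a half-open genomic interval of ``extension`` bp.

    The interval starts at the read's 5' terminus and proceeds in the
    read's strand direction: a forward read at p covers [p, p+ext), a
    reverse read with 5' end at q covers [q-ext+1, q+1).  Intervals are
    silently truncated at chromosome boundaries.

    With ``strand_aware=False`` every read is extended rightward from
    its leftmost coordinate regardless of strand (the literal
    "downstream in genome coordinates" reading).
    """
    length = genome.length(read.chrom)
    if strand_aware and read.strand == "-":
        q = read.end - 1
        lo, hi = q - extension + 1, q + 1
    else:
        lo, hi = read.start, read.start + extension
    return read.chrom, max(lo, 0), min(hi, length)


@dataclass
class CoverageTrack:
    """Per-base coverage scores for every chromosome of a genome.

    ``data`` maps chromosome name -> vector of non-negative scores, one
    per base.  Raw tracks (``normalized=False``) hold integer counts;
    normalized tracks hold floats scaled by ``scale_factor`` >= 1.
    """

    genome: GenomeTable
    data: dict[str, np.ndarray]
    normalized: bool = False
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        for name, length in self.genome:
            if name not in self.data:
                dtype = np.float64 if self.normalized else np.int64
                self.data[name] = np.zeros(length, dtype=dtype)
            elif len(self.data[name]) != length:
                raise ValueError(
                    f"track vector for {name} has length {len(self.data[name])}, "
                    f"expected {length}"
                )

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def sum(self) -> float:
        return float(np.sum([arr.sum() for arr in self.data.values()]))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            genome=self.genome,
            data={c: arr * float(factor) for c, arr in self.data.items()},
            normalized=True,
            scale_factor=float(factor),
        )


def compute_coverage(
    library: SampleLibrary,
    genome: GenomeTable,
    extension: int = DEFAULT_EXTENSION,
    strand_aware: bool = True,
) -> CoverageTrack:
    """Build the raw extended-read coverage track of a library.

    The score at each base is the number of extended reads whose
    interval contains it.  Implemented with an interval difference
    array and cumulative sum, equivalent to a per-base membership count.
    """
    data: dict[str, np.ndarray] = {}
    reads = library.reads
    for chrom, length in genome:
        diff = np.zeros(length + 1, dtype=np.int64)
        sub = reads[reads["chrom"] == chrom]
        if len(sub):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            minus = (sub["strand"] == "-").to_numpy()
            if strand_aware:
                p5 = np.where(minus, ends - 1, starts)
                lo = np.where(minus, p5 - extension + 1, p5)
                hi = np.where(minus, p5 + 1, p5 + extension)
            else:
                lo = starts
                hi = starts + extension
            lo = np.clip(lo, 0, length)
            hi = np.clip(hi, 0, length)
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(genome=genome, data=data, normalized=False, scale_factor=1.0)


def pool_replicates(a: SampleLibrary, b: SampleLibrary) -> SampleLibrary:
    """Pool two replicate libraries of the same condition into one sample.

    Reads are concatenated and aligned counts added; the result is
    order-independent up to the read multiset.  Differing condition
    labels are a hard error.
    """
    if a.condition != b.condition:
        raise ValueError(
            f"cannot pool libraries with different conditions: "
            f"{a.condition!r} vs {b.condition!r}"
        )
    reads = pd.concat([a.reads, b.reads], ignore_index=True)
    return SampleLibrary(
        sample_id=f"{a.sample_id}+{b.sample_id}",
        condition=a.condition,
        reads=reads,
        aligned_count=a.aligned_count + b.aligned_count,
        skipped=a.skipped + b.skipped,
    )


def pool_libraries(libraries: Sequence[SampleLibrary]) -> SampleLibrary:
    """Pool any number of replicate libraries (left fold of pairwise pooling)."""
    if not libraries:
        raise ValueError("cannot pool an empty list of libraries")
    pooled = libraries[0]
    for lib in libraries[1:]:
        pooled = pool_replicates(pooled, lib)
    return pooled


def normalize_tracks(
    tracks: Sequence[CoverageTrack], counts: Sequence[int]
) -> list[CoverageTrack]:
    """Scale raw tracks to the deepest library: y_ij = yRAW_ij * max_j(s_j)/s_j.

    ``counts`` are the aligned-read totals s_j, aligned one-to-one with
    ``tracks``.  The deepest sample gets scale factor 1.0; all others
    are scaled up.  Any s_j = 0 is a hard error (normalization
    undefined).
    """
    if len(tracks) != len(counts):
        raise ValueError("tracks and counts must align one-to-one")
    if not tracks:
        return []
    counts = [int(c) for c in counts]
    if any(c <= 0 for c in counts):
        raise ValueError("normalization undefined for aligned count s_j = 0")
    s_max = max(counts)
    return [track.scaled(s_max / s_j) for track, s_j in zip(tracks, counts)]


def _format_score(value: float, normalized: bool) -> str:
    if not normalized:
        return str(int(value))
    if float(value).is_integer():
        return str(int(value))
    return format(float(value), ".6g")


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, collapsing runs of equal score.

    Zero-score runs are omitted (absent intervals read back as 0).
    Normalized scores are written with 6 significant digits.
    """
    with open(path, "w") as fh:
        for chrom, _length in track.genome:
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # run boundaries: positions where the score changes
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{_format_score(v, track.normalized)}\n")


def read_coverage(
    path: str | Path,
    genome: GenomeTable,
    normalized: bool = False,
    scale_factor: float = 1.0,
) -> CoverageTrack:
    """Read a bedGraph written by :func:`write_coverage` back into a track.

    Raw round-trips are exact; normalized round-trips are exact to the
    written 6-significant-digit precision.  Records outside the genome
    are hard errors.
    """
    dtype = np.float64 if normalized else np.int64
    data = {name: np.zeros(length, dtype=dtype) for name, length in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line with < 4 columns")
            chrom, start, end, score = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome.length(chrom) or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside {chrom}"
                )
            data[chrom][start:end] = float(score) if normalized else int(score)
    return CoverageTrack(
        genome=genome, data=data, normalized=normalized, scale_factor=scale_factor
    )
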