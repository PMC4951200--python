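"""Overlapping window tiling and the D/A statistics.

The genome is tiled per chromosome with windows of width 500 bp at a
250 bp step (defaults), so consecutive windows overlap by 250 bp and
any signal block shorter than the step is fully contained in at least
one window.  For each window i, the total coverage score y is the sum
of per-base scores over the window; comparing two conditions A and B:

    D_i = (y_i^A - y_i^B) / (0.5 * (y_i^A + y_i^B))
    A_i = log(0.5 * (y_i^A + y_i^B))

D is a symmetric-denominator fold-change-like statistic bounded in
[-2, 2]; A is the log mean signal (natural log; the A-bin width
parameter downstream makes the base immaterial).  Windows with zero
signal in both conditions are carried with ``defined = False`` and NaN
D/A, and excluded from all downstream quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import GenomeTable

DEFAULT_WIDTH = 500
DEFAULT_STEP = 250


@dataclass(frozen=True)
class TilingParams:
    """Sliding-window geometry: width and step in base pairs."""

    width: int = DEFAULT_WIDTH
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.width):
            raise ValueError(
                f"require 0 < step <= width, got step={self.step}, width={self.width}"
            )


def make_windows(genome: GenomeTable, params: TilingParams | None = None) -> pd.DataFrame:
    """Tile the genome into overlapping windows.

    Per chromosome, starts run 0, step, 2*step, ... while start <
    length; ``end = min(start + width, length)`` so tail windows are
    truncated, never dropped.  Windows never span chromosomes.  Returns
    a DataFrame (chrom, start, end) indexed by the genome-order window
    ordinal i.
    """
    params = params or TilingParams()
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for chrom, length in genome:
        s = np.arange(0, length, params.step, dtype=np.int64)
        e = np.minimum(s + params.width, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    if not chroms:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=object),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
            }
        )
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        }
    )
    df.index.name = "index"
    return df


def window_total(track: CoverageTrack, window) -> float:
    """Sum of per-base coverage scores over one window [start, end).

    ``window`` may be anything with chrom/start/end attributes (e.g. a
    DataFrame row) or a ``(chrom, start, end)`` triple.
    """
    if hasattr(window, "chrom"):
        chrom, start, end = window.chrom, int(window.start), int(window.end)
    else:
        chrom, start, end = window[0], int(window[1]), int(window[2])
    if chrom not in track.genome:
        raise ValueError(f"window on unknown chromosome {chrom!r}")
    length = track.genome.length(chrom)
    if start < 0 or end > length or start >= end:
        raise ValueError(f"window [{start}, {end}) outside {chrom} (length {length})")
    return float(track.data[chrom][start:end].sum())


def _window_totals(track: CoverageTrack, windows: pd.DataFrame) -> np.ndarray:
    totals = np.empty(len(windows), dtype=np.float64)
    for chrom, sub in windows.groupby("chrom", sort=False):
        arr = track.data[chrom]
        csum = np.concatenate(([0.0], np.cumsum(arr, dtype=np.float64)))
        pos = windows.index.get_indexer(sub.index)
        totals[pos] = (
            csum[sub["end"].to_numpy()] - csum[sub["start"].to_numpy()]
        )
    return totals


def score_windows(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Compute per-window totals and the D/A statistics for two conditions.

    Both tracks must be normalized (mixing raw and normalized tracks is
    a hard error) and on the same genome.  Returns a DataFrame indexed
    like ``windows`` with columns chrom, start, end, y_a, y_b, D, A,
    defined.  D follows the sign convention (first condition - second
    condition).
    """
    if not (track_a.normalized and track_b.normalized):
        raise ValueError(
            "score_windows requires normalized tracks; run normalize_tracks first"
        )
    if track_a.genome != track_b.genome:
        raise ValueError("tracks are on different genomes")
    y_a = _window_totals(track_a, windows)
    y_b = _window_totals(track_b, windows)
    mean = 0.5 * (y_a + y_b)
    defined = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(defined, (y_a - y_b) / mean, np.nan)
        a = np.where(defined, np.log(np.where(defined, mean, 1.0)), np.nan)
    out = windows.copy()
    out["y_a"] = y_a
    out["y_b"] = y_b
    out["D"] = d
    out["A"] = a
    out["defined"] = defined
    return out


def write_window_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the window score table as TSV (chrom, start, end, index, ...)."""
    scores.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("index")


def write_tiling_bed(windows: pd.DataFrame, path: str | Path) -> None:
    """Export the tiling as BED3."""
    windows[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
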