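"""Model/Results surface for the two-condition differential window analysis.

:class:`DifferentialWindows` holds a pair of normalized coverage tracks
and the tiling/selection parameters; :meth:`DifferentialWindows.fit`
runs scoring, the adaptive criterion and region merging, returning a
:class:`DifferentialWindowsResults` that carries the per-window table,
the called regions, stage counts, and a ``summary()``.

Typical use::

    model = DifferentialWindows.from_libraries(reps_a, reps_b, genome)
    res = model.fit()
    print(res.summary())
    res.to_region_bed("regions.bed")
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import (
    DEFAULT_EXTENSION,
    CoverageTrack,
    SampleLibrary,
    compute_coverage,
    normalize_tracks,
    pool_libraries,
)
from .genome import GenomeTable
from .selection import (
    SelectionParams,
    evaluate_against_truth,
    merge_selected,
    select_windows,
    write_regions_bed,
)
from .windows import TilingParams, make_windows, score_windows, write_window_table


class DifferentialWindows:
    """MA-style differential enrichment model for two coverage tracks.

    Parameters
    ----------
    track_a, track_b
        Normalized coverage tracks for the two conditions.  D is
        computed as (condition A - condition B) over the symmetric
        mean, so the caller's ordering fixes the sign convention.
    genome
        The shared coordinate space.
    tiling, selection
        Window geometry and adaptive-criterion parameters; defaults are
        width 500 / step 250, 10% signal floor, 0.1 A-bin width,
        alpha = 3% one-sided (lower tail), similarity fraction 60%.
    """

    def __init__(
        self,
        track_a: CoverageTrack,
        track_b: CoverageTrack,
        genome: GenomeTable | None = None,
        tiling: TilingParams | None = None,
        selection: SelectionParams | None = None,
        labels: tuple[str, str] = ("A", "B"),
    ) -> None:
        if not (track_a.normalized and track_b.normalized):
            raise ValueError(
                "DifferentialWindows requires normalized tracks "
                "(see coverage.normalize_tracks)"
            )
        self.genome = genome or track_a.genome
        if track_a.genome != self.genome or track_b.genome != self.genome:
            raise ValueError("tracks are on different genomes")
        self.track_a = track_a
        self.track_b = track_b
        self.tiling = tiling or TilingParams()
        self.selection = selection or SelectionParams()
        self.labels = labels

    @classmethod
    def from_libraries(
        cls,
        replicates_a: Sequence[SampleLibrary],
        replicates_b: Sequence[SampleLibrary],
        genome: GenomeTable,
        extension: int = DEFAULT_EXTENSION,
        strand_aware: bool = True,
        tiling: TilingParams | None = None,
        selection: SelectionParams | None = None,
    ) -> "DifferentialWindows":
        """Pool replicates per condition, build raw coverage, normalize.

        Replicate reads within each condition are pooled into one
        sample; the two pooled samples' tracks are then scaled to the
        deeper library by aligned-read total.
        """
        pooled_a = pool_libraries(list(replicates_a))
        pooled_b = pool_libraries(list(replicates_b))
        raw_a = compute_coverage(pooled_a, genome, extension, strand_aware)
        raw_b = compute_coverage(pooled_b, genome, extension, strand_aware)
        norm_a, norm_b = normalize_tracks(
            [raw_a, raw_b], [pooled_a.aligned_count, pooled_b.aligned_count]
        )
        labels = (
            pooled_a.condition or "A",
            pooled_b.condition or "B",
        )
        model = cls(norm_a, norm_b, genome, tiling, selection, labels)
        model._pooled = (pooled_a, pooled_b)
        return model

    def fit(
        self,
        selection: SelectionParams | None = None,
    ) -> "DifferentialWindowsResults":
        """Run tiling, D/A scoring, the adaptive criterion, and merging."""
        params = selection or self.selection
        windows = make_windows(self.genome, self.tiling)
        scores = score_windows(self.track_a, self.track_b, windows)
        selected, eligible, floor_threshold, bins = select_windows(scores, params)
        scores = scores.copy()
        scores["eligible"] = scores.index.isin(eligible)
        scores["selected"] = scores.index.isin(selected)
        regions = merge_selected(scores, selected)
        return DifferentialWindowsResults(
            model=self,
            params=params,
            windows=scores,
            selected=selected,
            eligible=eligible,
            floor_threshold=floor_threshold,
            bins=bins,
            regions=regions,
        )


@dataclass
class DifferentialWindowsResults:
    """Fit output: window table, called regions, and diagnostics.

    ``windows`` is the full per-window table (chrom, start, end, y_a,
    y_b, D, A, defined, eligible, selected); ``regions`` the merged
    calls.  ``counts`` gives the funnel at every stage.
    """

    model: DifferentialWindows
    params: SelectionParams
    windows: pd.DataFrame
    selected: np.ndarray
    eligible: np.ndarray
    floor_threshold: float
    bins: list
    regions: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "windows": int(len(self.windows)),
            "defined": int(self.windows["defined"].sum()),
            "eligible": int(len(self.eligible)),
            "selected": int(len(self.selected)),
            "regions": int(len(self.regions)),
        }

    @property
    def selected_fraction(self) -> float:
        """Selected windows as a fraction of eligible windows."""
        n_el = len(self.eligible)
        return float(len(self.selected)) / n_el if n_el else float("nan")

    def evaluate(self, truth, min_overlap: int = 1) -> dict:
        """Sensitivity/precision of the called regions against a truth set."""
        return evaluate_against_truth(self.regions, truth, min_overlap)

    def ma_table(self) -> pd.DataFrame:
        """D-vs-A scatter table (defined windows only), for plotting."""
        cols = ["chrom", "start", "end", "A", "D", "eligible", "selected"]
        return self.windows.loc[self.windows["defined"], cols].copy()

    def to_window_tsv(self, path: str | Path) -> None:
        write_window_table(self.windows, path)

    def to_region_bed(self, path: str | Path) -> None:
        write_regions_bed(self.regions, path)

    def summary(self) -> str:
        """Plain-text summary of parameters and the selection funnel."""
        p = self.params
        t = self.model.tiling
        la, lb = self.model.labels
        c = self.counts
        lines = [
            "Differential ChIP-seq window analysis",
            "=" * 53,
            f"Conditions:          {la} vs {lb} (D = {la} - {lb})",
            f"Window tiling:       width {t.width} bp, step {t.step} bp",
            f"Selection mode:      {p.mode}"
            + (f" (side={p.side}, alpha={p.alpha:g})" if p.mode == "extreme" else
               f" (central fraction {p.central_fraction:g})"),
            f"Signal floor:        A > {self.floor_threshold:.4f} "
            f"(q = {p.floor_quantile:g} of defined windows)",
            f"A-bin width:         {p.bin_width:g} (log units), "
            f"{len(self.bins)} bins after sparse merging",
            "-" * 53,
            f"Windows tiled:       {c['windows']:>10d}",
            f"  defined (y>0):     {c['defined']:>10d}",
            f"  eligible (floor):  {c['eligible']:>10d}",
            f"  selected:          {c['selected']:>10d}"
            f"  ({100.0 * self.selected_fraction:.2f}% of eligible)",
            f"Merged regions:      {c['regions']:>10d}",
            "=" * 53,
        ]
        return "\n".join(lines)
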