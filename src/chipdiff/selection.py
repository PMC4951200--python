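"""Adaptive selection of differential windows and region merging.

The selection criterion has three steps:

1.  *Signal floor*: only windows whose average log signal A strictly
    exceeds the genome-wide 10% quantile (over defined windows) are
    eligible — low-signal windows produce unstable D values.
2.  *A-binning*: the eligible A range is divided into consecutive bins
    of width 0.1 log units, anchored at the minimum eligible A; the
    last bin is closed on the right so the maximum is always binned.
    Bins too sparse to express a distinct alpha-quantile (fewer than
    ceil(1/alpha) members by default) are merged into their nearest
    neighbor.
3.  *Per-bin quantile selection*: within each bin, windows at or beyond
    the lower (or upper) alpha-quantile of D are selected (alpha = 3%
    by default, inclusive of the threshold).

A *similarity* (central) mode instead keeps the middle 60% of D values
genome-wide among eligible windows, for comparisons where the two
samples are expected to agree.

Selected windows that overlap or are book-ended are merged into
maximal regions, the procedure's output unit.

All quantiles are empirical with linear interpolation between order
statistics (numpy's default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLOOR_QUANTILE = 0.10
DEFAULT_BIN_WIDTH = 0.1
DEFAULT_ALPHA = 0.03
DEFAULT_CENTRAL_FRACTION = 0.60


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the adaptive criterion.

    ``side`` chooses the tail of D flagged within each bin ("lower":
    second condition enriched; "upper": first condition enriched;
    "both": union of the two one-sided passes, each at ``alpha``).
    ``mode`` switches between "extreme" (differential) and "central"
    (similarity) selection.  ``min_bin_members`` defaults to
    ceil(1/alpha); set it to 1 to disable sparse-bin merging and
    reproduce the literal per-bin procedure.
    """

    floor_quantile: float = DEFAULT_FLOOR_QUANTILE
    bin_width: float = DEFAULT_BIN_WIDTH
    alpha: float = DEFAULT_ALPHA
    side: str = "lower"
    mode: str = "extreme"
    central_fraction: float = DEFAULT_CENTRAL_FRACTION
    min_bin_members: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor_quantile < 1.0):
            raise ValueError(f"floor_quantile must be in [0, 1), got {self.floor_quantile}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.side not in ("lower", "upper", "both"):
            raise ValueError(f"side must be lower/upper/both, got {self.side!r}")
        if self.mode not in ("extreme", "central"):
            raise ValueError(f"mode must be extreme/central, got {self.mode!r}")
        if not (0.0 < self.central_fraction <= 1.0):
            raise ValueError(
                f"central_fraction must be in (0, 1], got {self.central_fraction}"
            )
        if self.min_bin_members is None:
            object.__setattr__(self, "min_bin_members", math.ceil(1.0 / self.alpha))
        if self.min_bin_members < 1:
            raise ValueError("min_bin_members must be >= 1")


@dataclass
class ABin:
    """One A-range bin [lo, hi) and the window indices it holds."""

    lo: float
    hi: float
    members: np.ndarray

    def __len__(self) -> int:
        return len(self.members)


def apply_signal_floor(
    scores: pd.DataFrame, q0: float = DEFAULT_FLOOR_QUANTILE
) -> tuple[np.ndarray, float]:
    """Drop low-signal windows: keep those with A strictly above the floor.

    The floor is the linear-interpolation empirical ``q0``-quantile of A
    over ALL defined windows genome-wide.  Returns the eligible window
    indices (genome order) and the threshold value.  "Exceeds" is read
    strictly, so ties at the threshold are excluded.
    """
    defined = scores[scores["defined"]]
    if defined.empty:
        raise ValueError("no defined windows: cannot compute the signal floor")
    a = defined["A"].to_numpy()
    threshold = float(np.quantile(a, q0))
    eligible = defined.index.to_numpy()[a > threshold]
    if len(eligible) == 0:
        logger.warning(
            "signal floor at A=%.6g excluded every defined window "
            "(all A values tied at the threshold?)",
            threshold,
        )
    return eligible, threshold


def assign_bins(
    scores: pd.DataFrame,
    eligible: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_bin_members: int = 1,
) -> list[ABin]:
    """Partition eligible windows into consecutive A-bins.

    Bins are anchored at the minimum eligible A with the given width;
    the last bin is closed on the right so the maximum A is always
    binned.  Every eligible window lands in exactly one bin.  Bins with
    fewer than ``min_bin_members`` members are merged into their
    nearest neighbor (by bin midpoint) until none remain or a single
    bin is left.
    """
    if len(eligible) == 0:
        raise ValueError("eligible set is empty: nothing to bin")
    a = scores.loc[eligible, "A"].to_numpy()
    a_min, a_max = float(a.min()), float(a.max())
    n_bins = max(1, math.ceil((a_max - a_min) / bin_width)) if a_max > a_min else 1
    idx = np.floor((a - a_min) / bin_width).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)  # closes the last bin on the right
    bins = [
        ABin(
            lo=a_min + i * bin_width,
            hi=a_min + (i + 1) * bin_width,
            members=eligible[idx == i],
        )
        for i in range(n_bins)
    ]
    bins = [b for b in bins if len(b)]
    # sparse-bin merging: a bin with < ceil(1/alpha) members cannot express
    # an alpha-quantile distinct from its extremes and would auto-select.
    # Each sparse bin is absorbed toward its nearest non-sparse neighbor
    # (by bin midpoint), merging through adjacent bins so bins stay
    # consecutive; with no non-sparse bin left, nearest adjacent wins.
    while len(bins) > 1:
        counts = [len(b) for b in bins]
        sparse = [i for i, c in enumerate(counts) if c < min_bin_members]
        if not sparse:
            break
        i = min(sparse, key=lambda i: counts[i])
        mid = 0.5 * (bins[i].lo + bins[i].hi)
        non_sparse = [j for j in range(len(bins)) if j != i and counts[j] >= min_bin_members]
        if non_sparse:
            target = min(
                non_sparse, key=lambda j: abs(0.5 * (bins[j].lo + bins[j].hi) - mid)
            )
            j = i - 1 if target < i else i + 1
        else:
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(bins)]
            j = min(neighbors, key=lambda j: abs(0.5 * (bins[j].lo + bins[j].hi) - mid))
        lo, hi = min(i, j), max(i, j)
        logger.debug(
            "merging sparse A-bin [%.3g, %.3g) (%d members) into neighbor",
            bins[i].lo,
            bins[i].hi,
            counts[i],
        )
        merged = ABin(
            lo=bins[lo].lo,
            hi=bins[hi].hi,
            members=np.sort(np.concatenate([bins[lo].members, bins[hi].members])),
        )
        bins[lo : hi + 1] = [merged]
    return bins


def select_extreme_in_bin(
    bin: ABin, scores: pd.DataFrame, alpha: float = DEFAULT_ALPHA, side: str = "lower"
) -> np.ndarray:
    """Select windows at or beyond the bin's alpha-quantile of D.

    side="lower": D <= the alpha-quantile of D within the bin;
    side="upper": D >= the (1 - alpha)-quantile.  The threshold is
    inclusive ("or more extreme").
    """
    if len(bin) == 0:
        raise ValueError("cannot select from an empty bin")
    d = scores.loc[bin.members, "D"].to_numpy()
    if side == "lower":
        threshold = np.quantile(d, alpha)
        mask = d <= threshold
    elif side == "upper":
        threshold = np.quantile(d, 1.0 - alpha)
        mask = d >= threshold
    else:
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    return bin.members[mask]


def select_central(
    scores: pd.DataFrame,
    eligible: np.ndarray,
    central_fraction: float = DEFAULT_CENTRAL_FRACTION,
) -> np.ndarray:
    """Similarity mode: keep the middle ``central_fraction`` of D values.

    Computed genome-wide over eligible windows (no binning): windows
    with D between the (0.5 - f/2) and (0.5 + f/2) empirical quantiles,
    inclusive.
    """
    if len(eligible) == 0:
        raise ValueError("eligible set is empty")
    d = scores.loc[eligible, "D"].to_numpy()
    half = central_fraction / 2.0
    lo, hi = np.quantile(d, [0.5 - half, 0.5 + half])
    return eligible[(d >= lo) & (d <= hi)]


def select_windows(
    scores: pd.DataFrame, params: SelectionParams | None = None
) -> tuple[np.ndarray, np.ndarray, float, list[ABin]]:
    """Run the full criterion: floor -> bins -> per-bin (or central) selection.

    Returns ``(selected, eligible, floor_threshold, bins)``; ``bins`` is
    empty in central mode.  With ``side="both"`` the lower and upper
    passes are unioned, each at ``alpha``.
    """
    params = params or SelectionParams()
    eligible, threshold = apply_signal_floor(scores, params.floor_quantile)
    if len(eligible) == 0:
        return np.array([], dtype=np.int64), eligible, threshold, []
    if params.mode == "central":
        selected = select_central(scores, eligible, params.central_fraction)
        return np.sort(selected), eligible, threshold, []
    bins = assign_bins(scores, eligible, params.bin_width, params.min_bin_members)
    sides = ("lower", "upper") if params.side == "both" else (params.side,)
    chosen: list[np.ndarray] = []
    for b in bins:
        for side in sides:
            chosen.append(select_extreme_in_bin(b, scores, params.alpha, side))
    selected = np.unique(np.concatenate(chosen)) if chosen else np.array([], dtype=np.int64)
    return selected, eligible, threshold, bins


def merge_selected(scores: pd.DataFrame, selected: np.ndarray) -> pd.DataFrame:
    """Merge adjacent or overlapping selected windows into regions.

    Maximal runs of windows that overlap or are book-ended (end == next
    start) on one chromosome become one region.  Returns a DataFrame
    with chrom, start, end, n_windows, extreme_D (the most extreme
    member D by absolute value), mean_A, and member_windows (list of
    window indices).  Merging is idempotent.
    """
    cols = ["chrom", "start", "end", "n_windows", "extreme_D", "mean_A", "member_windows"]
    if len(selected) == 0:
        return pd.DataFrame(columns=cols)
    sel = scores.loc[np.sort(np.asarray(selected))]
    regions: list[dict] = []
    current: dict | None = None
    for idx, row in zip(sel.index, sel.itertuples(index=False)):
        if (
            current is not None
            and row.chrom == current["chrom"]
            and row.start <= current["end"]
        ):
            current["end"] = max(current["end"], int(row.end))
            current["member_windows"].append(int(idx))
        else:
            if current is not None:
                regions.append(current)
            current = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "member_windows": [int(idx)],
            }
    if current is not None:
        regions.append(current)
    out = pd.DataFrame(regions)
    d = scores["D"]
    a = scores["A"]
    out["n_windows"] = out["member_windows"].map(len)
    out["extreme_D"] = out["member_windows"].map(
        lambda ws: float(d.loc[ws].loc[d.loc[ws].abs().idxmax()])
    )
    out["mean_A"] = out["member_windows"].map(lambda ws: float(a.loc[ws].mean()))
    return out[cols]


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED6: name = region id, score = 1000*|extreme_D|/2
    clamped to [0, 1000], strand '.'."""
    with open(path, "w") as fh:
        for i, row in enumerate(regions.itertuples(index=False)):
            score = int(min(1000, round(1000.0 * abs(row.extreme_D) / 2.0)))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tregion_{i + 1}\t{score}\t.\n"
            )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def evaluate_against_truth(
    regions: pd.DataFrame,
    truth: Sequence,
    min_overlap: int = 1,
) -> dict:
    """Benchmark called regions against planted truth intervals.

    ``truth`` is a sequence of objects (or triples) with
    chrom/start/end.  Sensitivity = fraction of truth regions
    overlapped by >= ``min_overlap`` bp by any call; precision =
    fraction of calls overlapping any truth region.  With no calls,
    precision is reported as 0 with ``precision_defined = False``.
    """

    def _coords(t):
        if hasattr(t, "chrom"):
            return t.chrom, int(t.start), int(t.end)
        return t[0], int(t[1]), int(t[2])

    truth_list = [_coords(t) for t in truth]
    calls = [
        (row.chrom, int(row.start), int(row.end))
        for row in regions.itertuples(index=False)
    ]
    hits = [
        any(
            c[0] == t[0] and _overlap(c[1], c[2], t[1], t[2]) >= min_overlap
            for c in calls
        )
        for t in truth_list
    ]
    call_hits = [
        any(
            c[0] == t[0] and _overlap(c[1], c[2], t[1], t[2]) >= min_overlap
            for t in truth_list
        )
        for c in calls
    ]
    sensitivity = float(np.mean(hits)) if truth_list else 1.0
    precision_defined = len(calls) > 0
    precision = float(np.mean(call_hits)) if precision_defined else 0.0
    return {
        "n_truth": len(truth_list),
        "n_calls": len(calls),
        "truth_hit": hits,
        "sensitivity": sensitivity,
        "precision": precision,
        "precision_defined": precision_defined,
        "false_calls": int(len(calls) - sum(call_hits)),
    }
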