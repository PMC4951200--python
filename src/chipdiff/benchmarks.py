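"""Canonical simulation scenarios for calibration and recovery benchmarks.

These fix the study conditions under which the pipeline's statistical
behavior is assessed:

* :func:`null_experiment` — two conditions drawn from one shared
  landscape (2 Mb genome, 50 peaks at 10x background, 200,000 reads per
  pooled condition split over 2 replicates).  Used to check that the
  flagged fraction among eligible windows matches alpha and that depth
  imbalance is removed by normalization.
* :func:`recovery_experiment` — a 1 Mb genome with the same peaked
  landscape scaled so mean raw background coverage is ~5x, plus three
  planted 1-kb fold-4 regions.  Used to check that planted regions are
  recovered.

Landscape seeds are derived from the experiment seed so independent
replications use independent landscapes.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeTable
from .model import DifferentialWindows, DifferentialWindowsResults
from .selection import SelectionParams
from .simulate import (
    PlantedDifferential,
    SimulationSpec,
    random_landscape,
    simulate_experiment,
)
from .windows import TilingParams

NULL_GENOME_LENGTH = 2_000_000
NULL_N_PEAKS = 50
NULL_READS_PER_REPLICATE = 100_000

RECOVERY_GENOME_LENGTH = 1_000_000
RECOVERY_READS_PER_REPLICATE = 16_667  # ~5x mean raw coverage per pooled condition
RECOVERY_FOLD = 4.0
RECOVERY_REGION_LENGTH = 1_000


def null_experiment(
    seed: int,
    genome_length: int = NULL_GENOME_LENGTH,
    n_peaks: int = NULL_N_PEAKS,
    reads_per_replicate: int = NULL_READS_PER_REPLICATE,
    depth_imbalance: float = 1.0,
) -> SimulationSpec:
    """Paired null experiment: identical landscapes, no differentials."""
    genome = GenomeTable((("chr1", genome_length),))
    landscape = random_landscape(genome, n_peaks=n_peaks, seed=seed + 10_000)
    return SimulationSpec(
        landscape=landscape,
        differentials=(),
        reads_per_replicate=reads_per_replicate,
        replicates=2,
        depth_imbalance=depth_imbalance,
        seed=seed,
    )


def recovery_experiment(
    seed: int,
    genome_length: int = RECOVERY_GENOME_LENGTH,
    n_regions: int = 3,
    fold: float = RECOVERY_FOLD,
    reads_per_replicate: int = RECOVERY_READS_PER_REPLICATE,
) -> SimulationSpec:
    """Recovery experiment with planted 1-kb fold-`fold` regions.

    The landscape keeps the generator's peaked defaults (peaks model
    the localized enrichment the analysis expects); planted regions sit
    on background, evenly spaced, away from chromosome ends.
    """
    genome = GenomeTable((("chr1", genome_length),))
    landscape = random_landscape(genome, n_peaks=50, seed=seed + 20_000)
    spacing = genome_length // (n_regions + 1)
    differentials = tuple(
        PlantedDifferential(
            "chr1",
            (i + 1) * spacing,
            (i + 1) * spacing + RECOVERY_REGION_LENGTH,
            fold,
        )
        for i in range(n_regions)
    )
    return SimulationSpec(
        landscape=landscape,
        differentials=differentials,
        reads_per_replicate=reads_per_replicate,
        replicates=2,
        depth_imbalance=1.0,
        seed=seed,
    )


def fit_experiment(
    spec: SimulationSpec,
    selection: SelectionParams | None = None,
    tiling: TilingParams | None = None,
) -> DifferentialWindowsResults:
    """Simulate an experiment and run the full analysis on it."""
    libs_a, libs_b, _truth = simulate_experiment(spec)
    model = DifferentialWindows.from_libraries(
        libs_a,
        libs_b,
        spec.landscape.genome,
        tiling=tiling,
        selection=selection,
    )
    return model.fit()


def null_selected_fractions(
    seeds,
    depth_imbalance: float = 1.0,
    selection: SelectionParams | None = None,
    **kwargs,
) -> np.ndarray:
    """Flagged fraction of eligible windows per seeded null experiment."""
    fractions = []
    for seed in seeds:
        spec = null_experiment(int(seed), depth_imbalance=depth_imbalance, **kwargs)
        res = fit_experiment(spec, selection=selection)
        fractions.append(res.selected_fraction)
    return np.asarray(fractions)


def recovery_rates(seeds, selection: SelectionParams | None = None, **kwargs):
    """Per-seed (all_truth_hit, n_false_calls) for recovery experiments."""
    hits = []
    false_calls = []
    for seed in seeds:
        spec = recovery_experiment(int(seed), **kwargs)
        res = fit_experiment(spec, selection=selection)
        metrics = res.evaluate(spec.differentials)
        hits.append(metrics["sensitivity"] == 1.0)
        false_calls.append(metrics["false_calls"])
    return np.asarray(hits), np.asarray(false_calls)
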