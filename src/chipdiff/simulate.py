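"""Synthetic single-end ChIP-seq libraries with planted differential regions.

The simulator emulates what the analysis assumes about real data:
pooled-replicate, depth-imbalanced single-end libraries over a small
genome, with piecewise-constant enrichment (localized peaks hundreds of
bp to a few kb wide, like H3K4me2/me3 domains) and condition-specific
fold changes planted at known intervals so every pipeline stage can be
benchmarked against ground truth.

Reads are sampled by 5' start position only, with probability
proportional to the per-base enrichment rate lambda(pos); strand is
equiprobable and independent of position.  There is no fragment-length,
sequence, or PCR-duplicate model — the downstream analysis consumes
only start, strand, and the fixed extension.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import SampleLibrary
from .genome import GenomeTable

DEFAULT_READ_LENGTH = 50


@dataclass(frozen=True)
class Peak:
    """A piecewise-constant enrichment interval at ``rate`` x (absolute)."""

    chrom: str
    start: int
    end: int
    rate: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if self.rate < 0:
            raise ValueError("peak rate must be >= 0")


@dataclass(frozen=True)
class PlantedDifferential:
    """A planted condition-specific fold change on condition B.

    ``fold`` multiplies condition B's lambda inside the interval;
    fold > 1 means B-enriched, fold < 1 B-depleted.
    """

    chrom: str
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.fold <= 0 or self.fold == 1.0:
            raise ValueError("fold must be > 0 and != 1")


@dataclass(frozen=True)
class TruthSet:
    """The planted differential intervals, with folds and directions."""

    differentials: tuple[PlantedDifferential, ...]

    def __len__(self) -> int:
        return len(self.differentials)

    def __iter__(self):
        return iter(self.differentials)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [d.chrom for d in self.differentials],
                "start": [d.start for d in self.differentials],
                "end": [d.end for d in self.differentials],
                "fold": [d.fold for d in self.differentials],
                "direction": ["up" if d.fold > 1 else "down" for d in self.differentials],
            }
        )

    def to_bed(self, path: str | Path) -> None:
        """Truth BED with the fold in the score column."""
        with open(path, "w") as fh:
            for i, d in enumerate(self.differentials):
                fh.write(
                    f"{d.chrom}\t{d.start}\t{d.end}\ttruth_{i + 1}\t{d.fold:g}\t.\n"
                )


class EnrichmentLandscape:
    """Per-base sampling weight lambda over a genome.

    lambda(pos) equals the peak rate inside a peak (overlapping peaks
    take the maximum rate) and ``background`` elsewhere.
    """

    def __init__(
        self,
        genome: GenomeTable,
        background: float,
        peaks: Sequence[Peak] = (),
        _rates: dict[str, np.ndarray] | None = None,
    ) -> None:
        if background <= 0:
            raise ValueError("background rate must be > 0")
        self.genome = genome
        self.background = float(background)
        self.peaks = tuple(peaks)
        if _rates is not None:
            self._rates = _rates
        else:
            rates = {
                name: np.full(length, self.background, dtype=np.float64)
                for name, length in genome
            }
            for p in self.peaks:
                if p.chrom not in genome or p.end > genome.length(p.chrom):
                    raise ValueError(
                        f"peak [{p.start}, {p.end}) outside genome chromosome {p.chrom!r}"
                    )
                seg = rates[p.chrom][p.start : p.end]
                np.maximum(seg, p.rate, out=seg)
            self._rates = rates
        if sum(float(r.sum()) for r in self._rates.values()) <= 0:
            raise ValueError("total landscape weight must be > 0")

    def rate(self, chrom: str) -> np.ndarray:
        return self._rates[chrom]

    def with_differentials(
        self, differentials: Sequence[PlantedDifferential]
    ) -> "EnrichmentLandscape":
        """Condition-B landscape: lambda multiplied by each fold inside its
        interval, unchanged elsewhere.  Overlapping differential intervals
        are a hard error (the truth would be ambiguous)."""
        by_chrom: dict[str, list[PlantedDifferential]] = {}
        for d in differentials:
            if d.chrom not in self.genome or d.end > self.genome.length(d.chrom):
                raise ValueError(
                    f"differential [{d.start}, {d.end}) outside chromosome {d.chrom!r}"
                )
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            ds.sort(key=lambda d: d.start)
            for prev, nxt in zip(ds, ds[1:]):
                if nxt.start < prev.end:
                    raise ValueError(
                        f"overlapping differential intervals on {chrom}: "
                        f"[{prev.start}, {prev.end}) and [{nxt.start}, {nxt.end})"
                    )
        rates = {c: r.copy() for c, r in self._rates.items()}
        for d in differentials:
            rates[d.chrom][d.start : d.end] *= d.fold
        return EnrichmentLandscape(
            self.genome, self.background, self.peaks, _rates=rates
        )


def build_landscape(
    genome: GenomeTable, background: float, peaks: Sequence[Peak] = ()
) -> EnrichmentLandscape:
    """Construct a piecewise-constant enrichment landscape."""
    return EnrichmentLandscape(genome, background, peaks)


def apply_differentials(
    landscape: EnrichmentLandscape, differentials: Sequence[PlantedDifferential]
) -> EnrichmentLandscape:
    """Derive the second-condition landscape from planted fold changes."""
    return landscape.with_differentials(differentials)


def random_landscape(
    genome: GenomeTable,
    n_peaks: int = 50,
    background: float = 1.0,
    peak_fold: float = 10.0,
    width_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
) -> EnrichmentLandscape:
    """A landscape with ``n_peaks`` randomly placed peaks at
    ``peak_fold`` x background, widths uniform in ``width_range`` bp."""
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.length(n) for n in names], dtype=np.float64)
    peaks: list[Peak] = []
    for _ in range(n_peaks):
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        chrom, length = names[ci], int(lengths[ci])
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        width = min(width, length)
        start = int(rng.integers(0, length - width + 1))
        peaks.append(Peak(chrom, start, start + width, background * peak_fold))
    return build_landscape(genome, background, peaks)


def sample_reads(
    landscape: EnrichmentLandscape,
    n: int,
    seed: int,
    sample_id: str = "sim",
    condition: str = "",
    read_length: int = DEFAULT_READ_LENGTH,
) -> SampleLibrary:
    """Draw ``n`` reads with 5' starts proportional to lambda.

    Strand is +/- with probability 1/2, independent of position.  The
    recorded BED interval is the read_length-bp alignment footprint
    whose 5' terminus is the sampled position, clipped at chromosome
    boundaries; downstream coverage uses only the 5' end and strand.
    Identical seeds give identical libraries.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    names = landscape.genome.names
    weights = np.concatenate([landscape.rate(c) for c in names])
    cumw = np.cumsum(weights)
    total = cumw[-1]
    u = rng.random(n) * total
    global_pos = np.searchsorted(cumw, u, side="right")
    offsets = np.cumsum([0] + [landscape.genome.length(c) for c in names])
    ci = np.searchsorted(offsets, global_pos, side="right") - 1
    pos = global_pos - offsets[ci]
    minus = rng.random(n) < 0.5
    lengths = np.array([landscape.genome.length(c) for c in names])[ci]
    start = np.where(minus, np.maximum(pos + 1 - read_length, 0), pos)
    end = np.where(minus, pos + 1, np.minimum(pos + read_length, lengths))
    # keep genome order, then position, for byte-stable output
    order = np.lexsort((start, ci))
    chrom_arr = np.array(names, dtype=object)[ci[order]]
    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": start[order].astype(np.int64),
            "end": end[order].astype(np.int64),
            "strand": np.where(minus[order], "-", "+"),
        }
    )
    return SampleLibrary(sample_id=sample_id, condition=condition, reads=df)


@dataclass(frozen=True)
class SimulationSpec:
    """A two-condition experiment specification.

    Condition A replicates are drawn from ``landscape``; condition B
    replicates from the landscape with ``differentials`` applied, with
    ``depth_imbalance`` x ``reads_per_replicate`` reads each.  Two
    replicates per condition by default, mirroring typical pooled
    duplicates.  Per-replicate seeds are derived deterministically from
    ``seed`` so adding a replicate never perturbs existing ones.
    """

    landscape: EnrichmentLandscape
    differentials: tuple[PlantedDifferential, ...] = ()
    reads_per_replicate: int = 100_000
    replicates: int = 2
    depth_imbalance: float = 1.0
    seed: int = 0
    condition_a: str = "A"
    condition_b: str = "B"

    def __post_init__(self) -> None:
        if self.reads_per_replicate <= 0:
            raise ValueError("reads_per_replicate must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth_imbalance <= 0:
            raise ValueError("depth_imbalance must be > 0")
        object.__setattr__(self, "differentials", tuple(self.differentials))

    def to_dict(self) -> dict:
        """JSON-serializable sidecar (landscape summarized, not per-base)."""
        return {
            "genome": list(self.landscape.genome.entries),
            "background": self.landscape.background,
            "peaks": [
                {"chrom": p.chrom, "start": p.start, "end": p.end, "rate": p.rate}
                for p in self.landscape.peaks
            ],
            "differentials": [
                {"chrom": d.chrom, "start": d.start, "end": d.end, "fold": d.fold}
                for d in self.differentials
            ],
            "reads_per_replicate": self.reads_per_replicate,
            "replicates": self.replicates,
            "depth_imbalance": self.depth_imbalance,
            "seed": self.seed,
            "conditions": [self.condition_a, self.condition_b],
        }


def replicate_seed(seed: int, condition: str, replicate: int) -> int:
    """Stable per-replicate seed: sha256 of (seed, condition, replicate)."""
    digest = hashlib.sha256(f"{seed}:{condition}:{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_experiment(
    spec: SimulationSpec,
) -> tuple[list[SampleLibrary], list[SampleLibrary], TruthSet]:
    """Generate both conditions' replicate libraries and the truth set."""
    landscape_b = spec.landscape.with_differentials(spec.differentials)
    n_b = int(round(spec.reads_per_replicate * spec.depth_imbalance))
    libs_a = [
        sample_reads(
            spec.landscape,
            spec.reads_per_replicate,
            replicate_seed(spec.seed, spec.condition_a, r),
            sample_id=f"{spec.condition_a}_rep{r + 1}",
            condition=spec.condition_a,
        )
        for r in range(spec.replicates)
    ]
    libs_b = [
        sample_reads(
            landscape_b,
            n_b,
            replicate_seed(spec.seed, spec.condition_b, r),
            sample_id=f"{spec.condition_b}_rep{r + 1}",
            condition=spec.condition_b,
        )
        for r in range(spec.replicates)
    ]
    return libs_a, libs_b, TruthSet(spec.differentials)


def write_experiment(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize an experiment on disk.

    Emits one BED6 per replicate, chrom.sizes for the synthetic genome,
    a truth BED with the fold in the score column, and the spec as a
    JSON sidecar.  Identical specs produce byte-identical trees.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    libs_a, libs_b, truth = simulate_experiment(spec)
    paths: dict[str, Path] = {}
    genome_path = outdir / "genome.chrom.sizes"
    spec.landscape.genome.to_file(genome_path)
    paths["genome"] = genome_path
    for lib in libs_a + libs_b:
        p = outdir / f"{lib.sample_id}.bed"
        lib.to_bed(p)
        paths[lib.sample_id] = p
    truth_path = outdir / "truth.bed"
    truth.to_bed(truth_path)
    paths["truth"] = truth_path
    spec_path = outdir / "simulation.json"
    with open(spec_path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
        fh.write("\n")
    paths["spec"] = spec_path
    return paths
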