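"""End-to-end pipeline orchestration behind a YAML run configuration.

Stage order: load alignments -> pool replicates per condition -> raw
coverage -> normalize across the two pooled samples -> tile -> D/A
score -> signal floor -> A-bins -> selection -> merge -> write outputs
(normalized bedGraphs, window TSV, regions BED, summary JSON).  Any
stage failure aborts with a stage-named message and removes partial
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coverage import DEFAULT_EXTENSION, load_alignments, write_coverage
from .genome import read_genome_table
from .model import DifferentialWindows
from .selection import SelectionParams
from .windows import TilingParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """A two-condition comparison run.

    ``conditions`` maps exactly two condition labels (ordered: first is
    the D-positive condition) to lists of replicate alignment paths.
    """

    genome: str
    conditions: dict[str, list[str]]
    output_dir: str
    extension: int = DEFAULT_EXTENSION
    strand_aware: bool = True
    format: str = "bed"
    tiling: TilingParams = field(default_factory=TilingParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError(
                f"a comparison run requires exactly two conditions, "
                f"got {len(self.conditions)}"
            )
        for label, paths in self.conditions.items():
            if not paths:
                raise ValueError(f"condition {label!r} lists no alignment files")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"condition {label!r}: missing input {p}")
        if not Path(self.genome).exists():
            raise FileNotFoundError(f"missing genome table {self.genome}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tiling = TilingParams(**raw.pop("tiling", {}))
        selection = SelectionParams(**raw.pop("selection", {}))
        return cls(tiling=tiling, selection=selection, **raw)

    def to_dict(self) -> dict:
        return {
            "genome": str(self.genome),
            "conditions": {k: [str(p) for p in v] for k, v in self.conditions.items()},
            "output_dir": str(self.output_dir),
            "extension": self.extension,
            "strand_aware": self.strand_aware,
            "format": self.format,
            "tiling": {"width": self.tiling.width, "step": self.tiling.step},
            "selection": {
                "floor_quantile": self.selection.floor_quantile,
                "bin_width": self.selection.bin_width,
                "alpha": self.selection.alpha,
                "side": self.selection.side,
                "mode": self.selection.mode,
                "central_fraction": self.selection.central_fraction,
                "min_bin_members": self.selection.min_bin_members,
            },
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured comparison; returns the summary dict.

    Outputs land in ``config.output_dir``: ``coverage_<label>.bedgraph``
    (normalized) per condition, ``windows.tsv``, ``regions.bed`` and
    ``summary.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load genome"
        genome = read_genome_table(config.genome)

        stage = "load alignments"
        (label_a, paths_a), (label_b, paths_b) = config.conditions.items()
        reps_a = [
            load_alignments(p, genome, config.format, condition=label_a)
            for p in paths_a
        ]
        reps_b = [
            load_alignments(p, genome, config.format, condition=label_b)
            for p in paths_b
        ]
        skipped = sum(l.skipped for l in reps_a + reps_b)

        stage = "pool, coverage, normalize"
        model = DifferentialWindows.from_libraries(
            reps_a,
            reps_b,
            genome,
            extension=config.extension,
            strand_aware=config.strand_aware,
            tiling=config.tiling,
            selection=config.selection,
        )

        stage = "write coverage"
        for label, track in ((label_a, model.track_a), (label_b, model.track_b)):
            p = outdir / f"coverage_{label}.bedgraph"
            write_coverage(track, p)
            written.append(p)

        stage = "score and select"
        results = model.fit()

        stage = "write results"
        windows_path = outdir / "windows.tsv"
        results.to_window_tsv(windows_path)
        written.append(windows_path)
        regions_path = outdir / "regions.bed"
        results.to_region_bed(regions_path)
        written.append(regions_path)

        summary = {
            "config": config.to_dict(),
            "conditions": [label_a, label_b],
            "aligned_counts": {
                label_a: sum(l.aligned_count for l in reps_a),
                label_b: sum(l.aligned_count for l in reps_b),
            },
            "skipped_reads": skipped,
            "scale_factors": {
                label_a: model.track_a.scale_factor,
                label_b: model.track_b.scale_factor,
            },
            "floor_threshold": results.floor_threshold,
            "n_bins": len(results.bins),
            "counts": results.counts,
            "selected_fraction_of_eligible": results.selected_fraction,
            "outputs": {
                "windows": str(windows_path),
                "regions": str(regions_path),
            },
        }
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
        logger.info(
            "pipeline complete: %d windows, %d selected, %d regions",
            results.counts["windows"],
            results.counts["selected"],
            results.counts["regions"],
        )
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
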