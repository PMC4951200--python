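# chipdiff

Differential ChIP-seq window analysis with an adaptive per-bin quantile
criterion, plus a seeded synthetic read simulator for end-to-end
benchmarking against planted ground truth.

The package is for analysts comparing a histone mark or factor (e.g.
H3K4me2/H3K4me3) between two conditions from single-end ChIP-seq
alignments over a small genome. It implements the whole comparison as a
reproducible pipeline: extended-read coverage, cross-sample depth
normalization, overlapping-window scoring, adaptive selection of
differential windows, and merging into candidate regions.

## The method

For sample *j* with $s_j$ aligned reads, each single-end read is reduced
to its 5′ start and strand and extended 150 bp in the 5′→3′ direction;
the **raw coverage score** $y^{RAW}_{ij}$ at base *i* counts the
extended reads covering it. Replicates of a condition are pooled into
one sample. Tracks are made comparable by scaling every sample **up**
to the deepest library:

$$y_{ij} = y^{RAW}_{ij} \cdot \frac{\max_j s_j}{s_j}.$$

The genome is tiled with overlapping windows (width 500 bp, step
250 bp), so any signal block shorter than 250 bp lies wholly inside at
least one window. With $y_i^{A}, y_i^{B}$ the window totals in the two
conditions, each window *i* gets an MA-style pair of statistics:

$$D_i = \frac{y_i^{A} - y_i^{B}}{\tfrac12 (y_i^{A}+y_i^{B})} \in [-2, 2],
\qquad
A_i = \log\!\left(\tfrac12 (y_i^{A}+y_i^{B})\right).$$

Because the same $D$ is less trustworthy at low signal, selection is
adaptive in $A$:

1. **Signal floor** — keep only windows whose $A_i$ exceeds the
   genome-wide 10% quantile;
2. **A-binning** — split the remaining $A$ range into consecutive
   0.1-log-unit bins;
3. **Per-bin tail selection** — within each bin flag windows at or
   beyond the lower (or upper) $\alpha$-quantile of $D$, $\alpha=3\%$.

Flagged windows that overlap or are book-ended merge into the reported
regions. A *similarity* mode instead keeps the middle 60% of $D$
values, for pairs of samples expected to agree.

The simulator draws read 5′ positions from a piecewise-constant
enrichment landscape (localized peaks over background), applies planted
multiplicative fold changes to one condition, and emits BED replicates,
a chrom.sizes file, and a truth BED — so sensitivity, precision, and
calibration are all measurable.

## Worked example

```python
from chipdiff import (GenomeTable, SimulationSpec, PlantedDifferential,
                      random_landscape, simulate_experiment, DifferentialWindows)

genome = GenomeTable((("chr1", 500_000),))
landscape = random_landscape(genome, n_peaks=25, seed=1)
spec = SimulationSpec(
    landscape=landscape,
    differentials=(PlantedDifferential("chr1", 240_000, 241_000, 4.0),),
    reads_per_replicate=25_000,
    seed=1,
)
reps_a, reps_b, truth = simulate_experiment(spec)

model = DifferentialWindows.from_libraries(reps_a, reps_b, genome)
res = model.fit()
print(res.summary())
```

prints

```
Differential ChIP-seq window analysis
=====================================================
Conditions:          A vs B (D = A - B)
Window tiling:       width 500 bp, step 250 bp
Selection mode:      extreme (side=lower, alpha=0.03)
Signal floor:        A > 8.3191 (q = 0.1 of defined windows)
A-bin width:         0.1 (log units), 6 bins after sparse merging
-----------------------------------------------------
Windows tiled:             2000
  defined (y>0):           2000
  eligible (floor):        1800
  selected:                  58  (3.22% of eligible)
Merged regions:              40
=====================================================
```

The funnel reads top to bottom: 2,000 windows tile the 500 kb
chromosome; all have signal in at least one condition; the 10% floor
leaves 1,800 eligible; the per-bin 3% lower-tail criterion flags 58
windows (3.22% of eligible — close to α, as expected since the
criterion flags the extreme tail whether or not true differences
exist); merging yields 40 candidate regions. Checking against the
planted truth, `res.evaluate(truth)` reports `sensitivity: 1.0` — the
planted fold-4 region at 240–241 kb is recovered (its windows carry
the most extreme D ≈ −1.1); the remaining calls are the tail of the
null distribution, ranked by `extreme_D` in `res.regions`.

The same analysis runs from the shell:

```sh
chipdiff simulate --genome-length 500000 --reads 25000 --seed 1 \
    --differential chr1:240000-241000:4.0 --out exp/
chipdiff run config.yaml          # YAML naming the genome, replicates, output dir
chipdiff evaluate out/regions.bed exp/truth.bed
```

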