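# Methods

## Model and procedure

The pipeline compares two ChIP-seq conditions over a shared genome
table (an ordered chromosome → length map; all coordinates 0-based
half-open, as in BED/bedGraph).

**Coverage.** Each aligned single-end read is reduced to its 5′ start
and strand; its aligned length is ignored. The read is extended
`extension` bp (default 150, approximating the sequenced fragment) in
the 5′→3′ direction — forward reads extend rightward from their start,
reverse reads leftward from their 5′ terminus — and clipped at
chromosome boundaries rather than discarded, so the aligned-read total
keeps its meaning. The raw coverage score at a base is the number of
extended reads covering it. A `strand_aware=False` switch extends every
read rightward from its leftmost coordinate instead, for comparison
with naive "downstream in genome coordinates" implementations.

**Pooling and normalization.** Replicates of a condition are pooled
into one sample (read multisets concatenated, aligned totals added).
With $s_j$ the aligned-read total of pooled sample $j$, tracks are
scaled **up** to the deepest library, $y = y^{RAW} \cdot \max_j s_j /
s_j$: the deepest sample is untouched and every factor is ≥ 1. Scaling
up (rather than the more common down-scaling) preserves the deepest
sample's integer counts and makes the two normalized tracks directly
comparable. A depth imbalance between conditions is thereby removed as
a driver of the difference statistic — the test suite verifies that a
2× imbalance leaves the flagged fraction at α.

**Window statistics.** Windows of width 500 bp at step 250 bp tile
each chromosome from 0; tail windows are truncated, never dropped
(dropping them would blind the method near chromosome ends), and
windows never span chromosomes. For window $i$,
$D_i = (y_i^A - y_i^B) / \tfrac12(y_i^A + y_i^B)$ and
$A_i = \log \tfrac12 (y_i^A + y_i^B)$. $D$ is bounded in $[-2, 2]$,
hitting a bound exactly when one condition has zero signal, and is
antisymmetric under condition swap; the caller's condition order fixes
its sign. Windows with zero signal in both conditions are carried as
`defined = False` with NaN statistics ($D$ is 0/0 there) and excluded
from every downstream quantile. The logarithm is natural: the base
only rescales the A-bin width, which is an exposed parameter.

**Adaptive selection.** All quantiles are empirical with linear
interpolation between order statistics (the numpy default; no
convention is canonical here and the choice moves thresholds by at
most one order statistic).

1. *Floor*: the 10% quantile of $A$ over defined windows genome-wide;
   "exceeds" is strict, so ties at the threshold drop out. On distinct
   $A$ values this retains a $1 - q_0$ fraction to within $1/m$.
2. *Bins*: consecutive 0.1-wide bins anchored at the minimum eligible
   $A$; the last bin is right-closed so the maximum is binned. A bin
   with fewer than ⌈1/α⌉ members cannot express an α-quantile distinct
   from its own extremes and would auto-select its members; by default
   such bins are absorbed toward their nearest non-sparse neighbor
   (merging through adjacent bins, keeping bins consecutive).
   `min_bin_members=1` disables this and runs the literal per-bin rule.
3. *Selection*: within each bin, windows with $D$ at or beyond the
   lower (or upper) α-quantile, threshold inclusive ("or more
   extreme"). `side="both"` unions the two one-sided passes, each at
   α. The similarity mode instead keeps windows between the
   $(0.5 \pm f/2)$ quantiles of $D$ genome-wide over eligible windows
   (no binning), $f = 0.6$ by default.

**Merging.** Selected windows that overlap or are book-ended on one
chromosome merge into maximal regions (idempotent); each region
reports its member count, most extreme member $D$, and mean $A$. BED
output scores regions as $1000 \cdot |D_{ext}| / 2$.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `extension` | 150 | bp | read extension; the score's footprint per read |
| `width` / `step` | 500 / 250 | bp | window geometry; step < width guarantees sub-step signal falls wholly in one window |
| `floor_quantile` | 0.10 | — | genome-wide A-quantile below which windows are ignored |
| `bin_width` | 0.1 | log units | A-bin width for the adaptive threshold |
| `alpha` | 0.03 | — | per-bin flagged tail fraction of D |
| `side` | lower | — | D tail to flag; "lower" = second condition enriched |
| `central_fraction` | 0.60 | — | retained middle D mass in similarity mode |
| `min_bin_members` | ⌈1/α⌉ = 34 | windows | sparse-bin merge threshold; 1 = literal procedure |

## The simulator

Reads are sampled independently by 5′ start position with probability
proportional to a piecewise-constant enrichment rate λ: a background
level everywhere, peak levels on localized intervals (overlaps take
the maximum), and a multiplicative fold on condition B inside each
planted differential interval. Strand is equiprobable and independent
of position. Per-replicate seeds are derived by hashing
(seed, condition, replicate), so adding a replicate never perturbs
existing ones and identical specifications produce byte-identical
output trees.

Default scenario conditions used by the benchmark helpers: null
calibration uses a 2 Mb genome with 50 peaks at 10× background
(widths uniform in 500–2000 bp, the scale of H3K4me2/me3 domains) and
200,000 reads per pooled condition over 2 replicates; the recovery
scenario uses a 1 Mb genome with the same peaked landscape, depth set
so mean raw coverage of a pooled condition is ≈5×, and three planted
1-kb fold-4 regions. These sizes keep a 20-seed replication under a
minute while leaving ~8,000 (respectively ~4,000) windows per run.

What the simulator deliberately omits — fragment-length variation,
sequence and mappability bias, PCR duplicates, strand asymmetry
around peaks, biological replicate variability beyond resampling —
bounds what passing tests show: they validate the pipeline's
arithmetic, calibration, and invariances under the stated sampling
model, not robustness to artifacts of real libraries.

## Design choices where the design was open

- **Reverse-strand extension** is 5′→3′ in read orientation (standard
  practice); the literal "always rightward" reading is available via a
  flag since either convention is defensible for legacy comparisons.
- **$s_j$** is the retained aligned-read count before extension or
  clipping (overridable), matching a normalization by library depth
  rather than coverage mass.
- **Floor strictness** (`>`, not `≥`): with continuous scores the
  difference is measure-zero; with heavy ties it degenerates to
  retaining nothing, which is logged as a warning rather than guessed
  around.
- **Quantile inclusivity** in per-bin selection: ties at the threshold
  are selected, so a bin never selects fewer windows than its tail
  mass implies.
- **bedGraph output** omits zero runs and writes normalized scores to
  6 significant digits; raw round-trips are exact.

## Known limitations

- The per-bin adaptive criterion flags ~α of eligible windows
  *whether or not true differences exist* — it is a ranking rule, not
  a test with error control. Absolute call counts therefore scale with
  the window count, and downstream interpretation should treat calls
  as candidates ranked by |D|.
- A strong localized fold change raises $A$ as well as |D| (a fold
  $\phi$ shifts $A$ by $\log\tfrac{1+\phi}{2}$). If the affected
  windows dominate their $A$-bin, the bin's own quantile adapts to
  them and some are self-censored; detection of isolated strong
  regions is therefore less reliable than the same aggregate signal
  spread across well-populated bins. The similarity and global-bin
  (`bin_width` large) settings do not share this behavior.
- Input-control (local) normalization is not implemented; only the
  global depth scaling is.
- Single-end reads only; no duplicate removal or mappability
  correction — inputs are assumed pre-filtered.
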