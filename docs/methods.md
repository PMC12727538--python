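# Methods

`retainkit` implements the computational core of a study of ecDNA
"retention elements": genomic sequences that tether episomal DNA to mitotic
chromosomes and thereby raise its per-division retention probability. The
package covers four stages — the retention-screen enrichment caller, a
forward-time birth–death simulator of ecDNA copy number, retention-element
landscape analyses over classified amplicon catalogs, and bookmarking-factor
enrichment/importance — together with synthetic-data generators that give
every stage a ground truth.

## Retention-screen enrichment caller (`retainseq`)

The screen transfects a library of random genomic inserts on a plasmid
backbone, passages the cells, and sequences retained episomes at several
time points alongside the input library. Counts are summarised in 1-kb
genomic windows.

Calling proceeds as:

1. **Window filters.** Windows with fewer than `min_input_reads` (default
   10) reads in the input library are dropped (the screen cannot assay
   them), as are windows intersecting a blacklist and windows whose input
   count exceeds mean + 3 s.d. (strict `>`) of the input counts of the
   windows surviving the first two filters (PCR/mapping artifacts).
2. **Representation QC.** A sample fails when fewer than 50% of genome bins
   hold ≥ 10 reads; failed output samples are excluded from calling
   (severely under-represented libraries cannot support window-level
   inference).
3. **Normalisation.** Counts per million per sample over retained windows;
   log2 fold change of each output sample over the input. The default
   pseudocount is 0; zero-output windows would give −∞, so they are floored
   at the per-sample minimum finite log2FC, keeping the downstream z finite
   while leaving all other values untouched.
4. **Neighbour adjustment.** From each window's log2FC we subtract the
   median log2FC of retained windows whose midpoints lie within ±5 kb on the
   same chromosome (the window itself excluded; up to 10 neighbours for
   contiguous 1-kb windows). This removes background enrichment caused by
   copy-number-amplified genomic regions, which inflate both replicates
   coherently. Windows with no retained neighbour keep their log2FC and are
   flagged.

   *Tie-break.* For an even neighbour count the **upper median** (the higher
   central order statistic) is used instead of the interpolated midpoint.
   At the boundary of an amplified block the neighbourhood is an exact
   half/half mixture of two levels; the interpolated median lands halfway,
   which hands the outermost block window a spurious half-step enrichment
   large enough to survive FDR control. Siding with the locally higher
   level removes that boundary artifact deterministically, and under
   ordinary noise the resulting uniform upward shift of the background
   estimate cancels in the z-score, which is recentred on the sample mean.
5. **Significance.** Per sample, z = (x − m)/s.d. with m and s.d. the plain
   mean and (n−1)-denominator standard deviation of the adjusted log2FC over
   retained windows; upper-tail standard-normal p; Benjamini–Hochberg FDR
   within the sample.
6. **Replicate calling.** A window is called when its FDR < 0.1 (strict) in
   at least two biological replicates **at the same time point**, union over
   time points. The sentence "two biological replicates at any of the time
   points" also admits a cross-time-point reading; both are implemented
   (`same_timepoint=False` relaxes the rule) and the same-time-point reading
   is the default because replicate agreement is only meaningful within a
   condition. Called windows are merged (gap 0 by default) into retention
   elements with per-element support and minimum FDR.

Recovery of simulated spike-ins is evaluated against the spiked windows
that survive the input-side filters: windows absent from (or wildly
over-represented in) the input library are unassayable for any caller, and
the filters that remove them are part of the published procedure.

## Birth–death simulator (`evosim`)

Each cell carries an integer ecDNA copy number N. At birth it draws
competing exponential waiting times — division at rate
λ₁ = λ_base·(1 + s), with s = s₀ for N = 0 and s = s₁ for N ≥ 1, and death
at rate µ. Defaults: λ_base = 0.5, µ = 0.33 per unit time, 25 time units,
founder k_init = 10 copies. At division the ecDNA replicates to 2N copies;
each post-replication copy segregates with the chromosomes independently
with probability ν, giving a retained pool R ~ Binomial(2N, ν), split
symmetrically as n₁ ~ Binomial(R, ½), n₂ = R − n₁. So E[R] = 2Nν, and
ν = 0.9 corresponds to a 10% per-copy failure rate per mitosis. An
alternative mode retains whole pre-replication copies
(R = 2·Binomial(N, ν)) for sensitivity analysis.

Because cells never interact, the global event queue factorises over cells;
the implementation executes the identical process in vectorised unit-time
slabs (all events before the next grid time are applied, in any order) and
records population size, mean copy number and the ecDNA-positive fraction
on the unit grid. Populations exceeding `max_cells` (default 2×10⁶) either
raise or, in `downsample` mode, are uniformly subsampled with the scale
factor retained, which keeps frequencies and means unbiased in expectation
while capping memory and time.

Runs ending with fewer than `min_final_cells` (default 1,000) cells are
flagged. `simulate_population` reports them as-is by default;
`resample_min_cells=True` re-runs until the bound is met (at most 25
attempts, last attempt kept and flagged otherwise), reproducing the study's
stopping rule, and is what `sweep` uses in the headline analysis. Extinct
replicates contribute frequency 0 from their extinction time.

The sweep simulates 10 replicates per (s₁, ν) combination over
ν ∈ {0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.97, 0.98, 0.99, 1.0} and s₁ ∈ [0, 0.8]
with s₀ = 0. A combination is classified **maintained** when the final
across-replicate mean ecDNA-positive frequency is at least 50% of the
trajectory maximum. Under s₁ = 0.8 the smallest maintained grid value is
ν = 0.9; all lower grid values collapse — high-fidelity mitotic retention is
a prerequisite for selection to amplify ecDNA.

Closed-form anchors: with µ → 0, ν = 1 and s = 0 the process is a Yule
process with E[N_t] = n₀·e^(λ_base·t); with ν = 1 the per-lineage copy
number is a martingale, so the across-cell mean shows no drift.

## Amplicon landscape analyses (`amplicon`)

Catalogs of focally amplified intervals classified as ecDNA, BFB or linear
are annotated with the number of overlapping retention elements
(any-overlap, ≥ 1 bp). **Local density** of an interval is the number of
elements overlapping the 5-Mb window centred on its midpoint divided by
5 Mb (the denominator is fixed even near chromosome ends, matching the
fixed-width definition); the amplicon-level density is the width-weighted
mean over its intervals.

**Co-amplification**: among amplicons containing at least one
element-negative interval, the fraction that also contain an
element-positive interval, per class, compared one-sided (ecDNA/BFB >
linear) with the pooled two-proportion z (no continuity correction by
default; a Yates-corrected mode is available since the test-of-equal-
proportions family includes both).

**Density–size correlation**: per-class Pearson R between weighted density
and log10 amplicon size (sizes span orders of magnitude and the synthetic
link is linear in log width; raw-size mode available), CI via the Fisher
transform atanh R ± 1.96/√(n−3), and class differences via the two-sided
Fisher z-test.

**Oncogene-window enrichment**: for ecDNA intervals containing a named
oncogene, 100 random same-width intervals still containing the oncogene are
drawn per observed interval (start uniform over valid placements). Each
retention element within 500 kb of the oncogene midpoint is scored by its
observed versus random inclusion frequency: fold change, two-sided Fisher's
exact test, BH across the oncogene's elements. Elements inside the oncogene
span are necessarily included everywhere (fold change exactly 1); elements
no placement can reach are reported not estimable.

**Generic interval-set enrichment** covers origins-of-replication, motif
and circular-microDNA style comparisons: overlap at a configurable coverage
fraction (≥ by default, strict > available, since published thresholds use
both conventions), with Fisher (vs matched-size random intervals),
hypergeometric (genome bins as the urn) or log2-fold-change-only modes.

## Bookmarking factors (`bookmarking`)

Per-factor enrichment compares the fraction of query intervals covered
(≥ 50% of the interval by the factor's union peak set) against the fraction
of 1-kb genome bins covered; p is the upper-tail hypergeometric (urn: bins;
successes: covered bins; draws: query intervals), Bonferroni-adjusted. Bins
were chosen as the urn (rather than base pairs) to match the
bin-percentage background definition. Factors are ordered by descending
fold change, then ascending adjusted p, then name. The cumulative coverage
curve reports the fraction explained by the union of the first k factors.

Permutation importance draws 1,000 uniform random orderings of the top 20
factors (orderings are sampled with replacement; collisions are negligible
at these sizes) and averages each factor's incremental explained count —
the Shapley value of the set-cover increment. The telescoping identity
Σ importance = |union-covered query set| holds exactly on every run and is
asserted in tests. Scores are reported in element counts, with a fraction
mode.

## Synthetic data (`synthetic`)

* **Screen counts** — lognormal window propensities (σ = 1), per-sample
  library sizes (2×10⁶ reads over 10,000 windows; mean input depth ~200),
  5% spiked windows at 4× multiplicative enrichment per time step, one 8×
  copy-number block of ≥ 11 windows (so the ±5 kb adjustment operates
  inside the block), negative-binomial noise with dispersion 0.1 (screens
  are overdispersed; Poisson and exact-expectation modes for tests), and
  optional per-window dropout for QC tests. In expectation mode every count
  equals its rounded closed-form mean, making spike ratios exactly
  checkable.
* **Amplicon catalogs** — retention elements placed by a Gaussian-hotspot
  mixture (80% of 3,000 elements around 40 hotspots of s.d. 1.5 Mb on four
  60-Mb chromosomes); ecDNA log10 width decreases with the standardised
  local density at the interval anchor (slope 0.3, giving R ≈ −0.5 at the
  defaults, a clearly detectable but not degenerate link), linear and BFB
  widths are density-independent; 500/200/500 amplicons per class.
* **Factor peaks** — per-factor target coverage of a query set, realised by
  peaks spanning entire query intervals so ≥ 50%-coverage calls are
  unambiguous; optional nested design and random background peaks.

The generators emulate the statistical structure of the real inputs, not
their biology: no sequence content, no read-level error, no mappability
structure, no correlated replicate artifacts, and amplicon intervals are
drawn independently rather than from rearrangement graphs. Passing tests
therefore demonstrate correctness and calibration of the statistics on data
with the designed moments, not performance on real libraries.

## Numerical choices and limitations

* Coordinates are 0-based half-open throughout; strand is ignored (nothing
  in scope is stranded). Partial terminal genome bins are kept and fall to
  the count filters when under-covered.
* Matched random intervals are drawn uniformly over all valid genome-wide
  placements with rejection against an exclusion set (empty by default),
  bounded at 1,000 retries per interval.
* BH, Fisher's exact, hypergeometric tails and Pearson correlations are
  delegated to statsmodels/scipy; tests verify them against brute-force
  enumeration oracles. The pooled two-proportion z is written out (both
  with and without continuity correction) and cross-checked against
  statsmodels.
* Simulation problem sizes in the test suite are chosen for desk-scale
  runs: the threshold sweep uses the full grid at 25 time units with
  populations capped at 2×10⁶ cells (downsampling mode), closed-form checks
  use 200 replicates at 8 time units, screen recovery uses 4,000-window
  screens (20 noise replicates), and catalog recovery uses 50 catalogs of
  500 amplicons per class.
* Known limitations: the caller assumes a single input library per screen;
  the simulator has no cell–cell interaction, spatial structure or
  multi-species ecDNA; lineage recording (event log / Newick export) is
  intended for small populations.
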