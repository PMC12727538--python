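# retainkit

Analyses of **ecDNA retention elements** — genomic sequences that tether
episomal DNA (plasmids, viral episomes, oncogene-carrying ecDNA) to mitotic
chromosomes so it is carried into daughter nuclei instead of being lost.
The package is aimed at computational biologists studying extrachromosomal
oncogene amplification and episome persistence, and provides four
independently usable stages plus synthetic-data generators with known
ground truth:

* **`retainkit.retainseq`** — the retention-screen enrichment caller: from a
  windows × samples count table (input episome library + serially passaged
  output libraries) to retention-element calls. Per output sample it
  computes CPM, x = log2(CPM_out/CPM_in), subtracts the median of the ±5 kb
  neighbouring windows (copy-number background removal), standardises
  z = (x − m)/s.d., takes upper-tail normal p and Benjamini–Hochberg FDR,
  and calls windows with FDR < 0.1 in two biological replicates at a time
  point, merging them into elements.
* **`retainkit.evosim`** — a forward-time birth–death simulation of ecDNA
  copy number in a growing cell population: division at rate
  λ₁ = λ_base(1 + s) (s₁ for ecDNA-positive, s₀ for ecDNA-negative cells),
  death at rate µ, competing exponential waiting times, and binomial
  segregation with imperfect retention: R ~ Binomial(2N, ν),
  n₁ ~ Binomial(R, ½), n₂ = R − n₁.
* **`retainkit.amplicon`** — retention-element landscape analyses over
  classified amplicon catalogs (ecDNA / BFB / linear): element annotation,
  local density (elements per Mb in a 5-Mb window), per-class
  co-amplification rates with one-sided proportion tests, density–size
  Pearson correlations compared across classes by Fisher z-tests, and
  enrichment of elements in oncogene-containing intervals versus random
  same-width oncogene-containing placements.
* **`retainkit.bookmarking`** — mitotic-bookmarking-factor peak enrichment
  in retention elements (hypergeometric over 1-kb genome bins, Bonferroni),
  cumulative coverage curves, and Shapley-style permutation importance over
  random factor orderings.
* **`retainkit.synthetic`** — generators for screen counts (lognormal window
  propensities, spiked enrichment, copy-number blocks, NB noise), amplicon
  catalogs over an inhomogeneous element landscape, and factor peak sets
  with designed coverage.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```bash
python analysis/01_simulate_screen.py          # synthetic retention screen
python analysis/02_call_retention_elements.py  # enrichment calling + scoring
python analysis/03_retention_selection_sweep.py --full
python analysis/04_amplicon_landscape.py
python analysis/05_bookmarking_importance.py
```

`01` simulates a 10,000-window screen (two replicates, three time points,
5% spiked windows enriching 4× per passage, one 8× copy-number block) and
`02` calls elements on it, printing:

```
elements: 450  significant windows: 472
sensitivity (assayable spiked windows): 0.973  false-call rate (null windows): 0.0000%
```

i.e. the caller recovers 97% of the spiked windows that are assayable in
the input library while calling no unspiked window — including none inside
the amplified block, which is what the ±5 kb neighbour adjustment is for.

`03` sweeps retention rate ν and selection s₁ (10 replicates each) and
classifies each combination as maintained (final mean ecDNA-positive
frequency ≥ 50% of its trajectory maximum) or lost:

```
smallest maintained nu at s1=0.8 (t_max=15): 0.9
 s1   nu  final_mean_frac  maintained
0.8 0.80         0.243827       False
0.8 0.90         0.623301        True
0.8 0.95         0.764940        True
```

Even under strong positive selection, ecDNA-positive cells collapse once
per-division retention drops below 0.9 — and with weaker selection
(s₁ = 0.4) maintenance requires ν ≥ 0.95, while without selection no grid
value maintains.

`04` generates a classified amplicon catalog whose ecDNA sizes shrink with
local element density and recovers the designed structure:

```
 class         r    ci_low   ci_high   n            p
 ecDNA -0.636595 -0.685991 -0.581358 500 3.603427e-58
linear  0.044205 -0.043655  0.131386 500 3.239097e-01
```

with ecDNA co-amplification of element-negative segments at 76% versus 47%
for linear amplicons (one-sided z = 3.50, p = 2.3×10⁻⁴).

`05` scores 25 synthetic bookmarking factors; the permutation importance of
the top 20 telescopes exactly to the number of elements explained by their
union (800 of 800 here).

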