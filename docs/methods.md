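# Methods

## Fitness model

A pooled insertion library grows for one period during which the
population expands by a measured factor `d = Nf/N0` (viable-cell counts;
generations `G = log2(d)`). Writing `F0` and `Ff` for a mutant's insertion
frequency at the start and end of the period, its fitness is estimated as

    W = ln(Ff * d / F0) / ln((1 - Ff) * d / (1 - F0))

the mutant's realised log expansion (`Ff*d/F0` is the factor by which its
absolute abundance grew) over the log expansion of the complement of the
population. The estimator has the identities used throughout the tests:
`Ff = F0` gives `W = 1` for any `d > 1` (returned exactly, bypassing
floating-point log evaluation); `W = 0` corresponds to constant absolute
abundance (dilution by `1/d` in frequency); and `W` is strictly increasing
in `Ff` *on the model's domain* `Ff < 1 - (1 - F0)/d`, i.e. as long as the
non-mutant remainder of the population itself expands. Beyond that
boundary the denominator changes sign and the formula is meaningless; with
library-scale frequencies (`F0, Ff << 1`) the boundary is never
approached.

Assumptions: exponential growth within a period; each mutant rare enough
not to perturb the complement appreciably; `d > 1` (no fitness is defined
without net expansion). Note that `W` is fitness **relative to the
population mean growth**: when a non-negligible fraction of the pool is
deleterious, neutral mutants measure slightly above 1 (about +1.3% in
period 1 when 4% of insertions carry `W = 0.5`). This is a property of the
estimand, not a bias of the estimator, and it largely cancels in the
treatment/control ratio at the screen's realistic (~2%) deleterious mass.

Conventions for degenerate cases:

* `Ff = 0` (extinct): `W = 0` with an `extinct` flag; no pseudocount by
  default (a configurable frequency pseudocount exists for sensitivity
  analysis only).
* `F0 = 0`: the site is absent from the start sample and is excluded with
  reason `missing_*_start` (scalar API: `ValueError`).
* `W_control <= 0`: a control-extinct mutant carries no information about
  the treatment; the site is excluded with a logged reason rather than
  producing an undefined ratio.
* Sampling noise can push the raw estimate below 0 when a frequency falls
  faster than `1/d`; estimates are floored at 0, since fitness below
  "no growth at all" is not interpretable and the relative fitness must
  stay non-negative.

## From insertions to genes

Per growth period `p` (three by default), `F0` comes from the sample at
timepoint `p` and `Ff` from timepoint `p + 1` (timepoint 1 is the shared
starter culture, so period 1 starts from the starter, not the unexpanded
library). Periods are self-contained: no compounding across periods.
Sites must exceed **10 reads (strictly)** in the period's control start
sample, replicates summed — the screen's read filter. Replicate cultures
are pooled by averaging frequencies within (condition, timepoint) before
`W` is computed; a per-replicate mode (matched replicate pairs, ratios
averaged) is available and agrees closely on simulated data. `d` is the
geometric mean over a condition/period's replicate viable-count records.

Sites map to genes by coordinate containment (1-based inclusive; strand
recorded but ignored — disruption is strand-agnostic); sites inside
overlapping genes count for all of them; sites outside genes are pooled
into left-to-right numbered intergenic units (`ig_k`) so that the
multiple-testing correction spans every tested unit. A gene-period needs
at least 3 usable insertions ("sufficient data", configurable); the
estimate is the arithmetic mean of `w_rel` with the usual one-sample t
95% interval, the p-value a two-sided one-sample t-test against 1
(zero-variance genes get `p = 1` by convention, flagged), and
Benjamini–Hochberg adjustment is applied within each growth period
(delegated to `statsmodels.stats.multitest`; the step-up definition is
enforced against an exhaustive-min oracle in the tests). Candidate lists
take the genes with adjusted `p < 0.01`, sorted ascending by mean
relative fitness (ties: smaller adjusted p, then gene id), capped at 200
— the screen's selection rule; intergenic units are excluded from
candidate lists by default.

## Synthetic screens

The simulator generates the study conditions end to end and is the basis
of all pipeline-level tests. Defaults (chosen once, as the design being
emulated): 1,000 genes of mean length 900 bp (sd = mean/4, floor 150 bp),
10% intergenic sequence, 120,000 distinct insertion sites uniform over
the genome except inside essential genes (5% of genes in 2 contiguous
clusters, visible as coverage gaps), 20 treatment-sensitive genes at true
treatment fitness 0.5 (control fitness 1 everywhere), three growth
periods with nominal expansion `d = 8` per period (3 generations, e.g.
5e6 → 4e7 viable cells, a typical back-diluted outgrowth), 5 million
reads per sample, two sequencing replicates.

Growth is deterministic (`cells *= d**W`); the recorded viable counts are
the realised totals, so the treatment arm's measured expansion reflects
its deleterious load. Sequencing is a multinomial draw per sample —
the only noise source by default; an optional multinomial bottleneck
between periods emulates passaging dilution. Per-sample random streams
are derived from the master seed by stable hashing of (screen, condition,
timepoint, replicate), making outputs byte-deterministic under a seed.
Multi-screen designs (several agents screened against one library) share
the genome and library but draw independent sequencing noise, with
sensitive-gene sets composed of shared plus screen-private genes.

The simulator does **not** model PCR jackpots, transposon target-site
(TA) bias, read-mapping artifacts, or genetic drift during growth.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, not robustness to
those real-data artifacts; the read filter and replicate pooling address
them only indirectly.

## Downstream statistics

* Spectral counts: samples are normalized to the mean total
  (total-count scaling), fold change is `mean(mutant)/mean(WT)`, and the
  p-value a two-sample t-test — pooled-variance by default, Welch
  optional, since the variant is a free choice; identical groups get
  `p = 1`; a zero WT mean yields an infinite fold change, flagged but
  retained. Headline counts (significant at `p < 0.05`; of those, fold
  change > 1) ride on the result table.
* Cell length: the filamentation statistic is the proportion of cells
  **strictly** longer than 6.75 μm (three 2.25 μm cell lengths), with the
  binomial-proportion standard deviation `sqrt(p(1-p)/n)` — note this is
  the correct form of the sometimes-misprinted "p(1−p)n". Strain
  comparisons use a one-tailed two-proportion Z-test, pooled proportion
  by default (unpooled optional), alternative "second strain has more
  long cells".

## Numerical and design choices

* Coordinates 1-based inclusive everywhere (GFF3 convention); count
  tables are per-sample TSVs tied together by a YAML manifest; library
  and starter samples carry condition `both` since they precede the
  control/treatment split.
* Exact-neutrality short-circuit (`Ff == F0 -> W = 1`) avoids spurious
  1e-16-level wobble in identity tests.
* Ties in every sort are broken deterministically (mergesort + explicit
  secondary keys), making all outputs reproducible byte for byte.
* Problem sizes in the test-suite and the acceptance script: pipeline
  checks run at the full default scale (120,000 sites, 5 M reads); unit
  fixtures use a reduced screen (120 genes, 8,000 sites, 400 k reads)
  that preserves per-site read depth and per-gene insertion counts within
  a factor of ~2 of the default design.

## Known limitations

* Fitness is undefined without measured population expansion (`d > 1`);
  OD-based proxies are not supported.
* No shrinkage or variance moderation across genes: genes with few
  insertions get wide intervals rather than borrowed strength.
* Essentiality is not inferred (coverage gaps are flagged, not called);
  the gene-level test assumes approximate normality of per-insertion
  relative fitness, which the QC module reports descriptively (skewness)
  rather than testing formally.
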