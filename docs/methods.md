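# Methods

## Conversion assessment at non-CpG cytosines

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while methylated cytosine is protected. In mammalian genomes
methylation is confined almost entirely to CpG dinucleotides, so a cytosine
in CHG or CHH context ("nonCGc", H ∈ {A,C,T}) should read as fully
converted; the observed methylation ratio there estimates the *failure*
rate of the chemistry. For a site with coverage > 0 the conversion rate is
`1 − methylation ratio`; uncovered sites carry an `NA` ratio and never
enter arithmetic, so "no data" is never conflated with "fully converted".

**Chromosome level.** Over all nonCGc sites of a chromosome we report the
census `TNCGC`, the covered subset `TNCGCwC`, their ratio as a percentage
(rendered to three decimals, e.g. `1.394%` for 622,926 of 44,683,043), and
min / 25th percentile / median / mean / 75th percentile / max of the
conversion rate. All order statistics are computed **over covered sites
only**: a chromosome can show Min = 0 at 1–2% site coverage only if
uncovered sites are excluded, and the mean is over the same covered set.
Quantiles use linear interpolation between order statistics — the default
of R's `summary()`/`quantile()` — so the table is reproducible against R
tooling. The output header spells `25th_percentile` in full.

**Advisory.** Covered nonCGc sites are split at conversion 0.99 into a
high group A (≥ 0.99) and low group B (< 0.99). If the low fraction
exceeds 0.30 the verdict is *investigate* (the treatment likely failed);
below 0.05 it is *proceed* (optionally restricting downstream analysis to
CpGs near group-A sites); between the two it is *caution*. All three
cutoffs are configuration, defaulting to these conventional values.

**Region level.** For each target region (0-based half-open interval) we
count nonCGc sites `N`, covered nonCGc sites `n`, and the mean and median
conversion over the `n` covered sites. Sites in overlapping regions
contribute to each region; regions on chromosomes absent from the table
get `N = 0` and are reported, not dropped. A region spanning the whole
chromosome reproduces the chromosome-level covered-site statistics
exactly (tested).

## Region classification

Two independent axes with literal, deliberately asymmetric boundary
semantics:

| axis | high | low | default cutoffs |
|---|---|---|---|
| conversion (median over covered nonCGc) | median ≥ `B` | median ≤ `b` | `B` = 0.99, `b` = 0.6 |
| coverage (`n/N`) | `n/N` ≥ `L` | `n/N` **<** `l` (strict) | `L` = 0.5, `l` = 0.1 |

So `n/N` exactly at `l` is *neither*, while a median exactly at `b` is
*low*. This asymmetry is preserved intentionally rather than smoothed
over. With `b < B` and `l ≤ L` (validated) no region can be both high and
low on an axis. A region with `n = 0` is coverage-low (0 < `l`) but
conversion-*undefined*; `N = 0` is undefined on both axes and listed in a
separate no-nonCGc file.

A low-metric class with fewer than 10 regions, or fewer than 0.5% of all
target regions, is flagged *negligible*: the sample is probably well
sequenced on that axis and the sequence-structure comparison is skipped
for it.

## Sequence-structure comparison

Per region we report percentages (of region length) of A, C, G, T, G+C,
CpG cytosines (CGc), non-CpG cytosines (nonCGc), and repetitive bases.
Conventions, chosen where the counting rules were genuinely open:

- Base identity is case-insensitive; **repeat content** is the lowercase
  (soft-masked) fraction of the input FASTA — self-contained and
  equivalent to the "%low_count" repeat annotation for standard
  soft-masked reference distributions, rather than a lookup in external
  browser tables.
- CGc/nonCGc are counted on the **plus strand only**, so a CpG's
  reverse-strand cytosine is not double-counted; this matches counting
  directly on the reference string as distributed.
- A region-final C is classified by looking one base past the region
  boundary when the reference extends that far, else it counts as nonCGc.
- N bases count toward region length but toward no base percentage, so
  percentages can sum below 100 in N-containing regions; such regions are
  flagged in the output.

These conventions give the identities `%CGc + %nonCGc = %C` and
`%GC = %C + %G`, enforced by property tests. Group comparisons emit raw
per-region vectors and five-number summaries per metric (boxplot-ready
plot data rather than opaque figure files).

**RRBS targets.** The in-silico MspI digest cuts at every `CCGG`
occurrence (case-insensitive, overlapping occurrences included) between
the first C and the CGG; candidate fragments are the intervals between
consecutive cuts, and fragments with length in [40, 220] — both bounds
inclusive, modelling library size selection — are returned. Terminal
stretches before the first and after the last cut are not fragments.
Whether real RRBS intervals include the overhang bases at fragment ends is
a convention; the cut-coordinate convention here is fixed and tested.

## Trimming

Fixed-length trimming removes `n5` bases from the 5' end and `n3` from the
3' end (defaults 5 and 10). Quality trimming is defined as an explicit,
reproducible contract rather than a wrapper around any particular
aligner's opaque trim step: strip terminal N bases, then remove 3' bases
while quality < Q20 (configurable), iterating both rules to a fixed point
so trimming is idempotent. Reads shorter than `min_len` (default 1) after
trimming are dropped and counted; every run verifies
kept + dropped = input. Quality encodings: Sanger (Phred+33) and
Illumina-1.3 (Phred+64); a quality string that is invalid under the
declared encoding raises an error suggesting the other one.

## Coordinates and dialects

Internal coordinates are 0-based half-open everywhere. Ratio tables are
read as 1-based by default (`coord_base`), the convention of typical
per-site reports, and the writer records the same base; target files are
BED-style 0-based half-open with an opt-in 1-based-inclusive mode. The
ratio-table column order is `chrom pos strand context coverage ratio`,
with a pluggable column map for tables from other callers.

## Synthetic data generator

The generator emulates the data model of a mammalian bisulfite experiment
at desk scale; defaults (one `SimulationSpec`):

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 200,000 bp | one synthetic chromosome |
| `gc_fraction` | 0.45 | expected G+C fraction |
| `cpg_enrichment` | 3.0 | CpG dinucleotide multiplier |
| `repeat_fraction` | 0.15 | soft-masked fraction |
| `true_conversion` | 0.995 | conversion rate at nonCGc sites |
| `cpg_methylation` | 0.75 | methylation level at CpGs |
| `mean_coverage` | 10 | mean depth of covered sites |
| `covered_site_fraction` | 0.3 | probability a site has any coverage |

`true_conversion` 0.995 models a successful but not perfect treatment
(chromosome-level means near 0.996 are typical of good libraries);
GC 0.45 with most CpGs methylated is mammalian-like; 0.3 × 10× coverage
yields >10,000 covered nonCGc sites on 200 kb, enough for stable
chromosome-level statistics while the whole pipeline runs in seconds.

The reference is a first-order Markov chain with symmetric base weights
(A=T, C=G) in which P(G | previous C) is multiplied by `cpg_enrichment`;
the underlying weight is calibrated by bisection on the chain's stationary
distribution so the expected GC fraction equals the target exactly.
Infeasible combinations (enrichment forcing P(G|C) ≥ 1) raise a
configuration error. Repeats are emulated by lower-casing 200 bp blocks
chosen uniformly until the masked quota is met, so the realized lowercase
fraction is within one block of the target.

The methylation table has one record per cytosine on each strand, with
context (CG/CHG/CHH) from the strand's own two-base lookahead; a window
running off the sequence, or into an N, defaults toward CHH (an N is
treated as "not G"). Coverage is site-level Bernoulli(`covered_site_
fraction`) × zero-truncated Poisson whose rate is solved so the truncated
mean equals `mean_coverage` — the simplest model that exposes the n/N
classification axis. The methylated-read count is
Binomial(depth, 1 − `true_conversion`) at nonCGc sites and
Binomial(depth, `cpg_methylation`) at CpGs. Reads get uniform start
positions and a linearly declining quality ramp (Q38 at the 5' end, minus
`quality_decay` per base, Gaussian jitter σ = 2, clipped to [2, 40]).

All randomness flows from one seed; the ground truth is serialized in a
manifest next to the fixture files so tests never re-infer it.

**What the generator does not model** — and hence what passing tests do
not establish about real data: sequencing errors beyond the quality ramp,
PCR duplicates and amplification bias, paired-end structure, fragment-level
(rather than site-level) coverage correlation, strand-biased conversion
failure, and chromosome-scale composition heterogeneity. Recovery of the
generative conversion rate shows the estimator arithmetic is right, not
that real libraries satisfy the model's independence assumptions.

## Numerical and degenerate-input choices

- Quantiles: linear interpolation (see above), everywhere, including
  five-number summaries.
- Percent cells are formatted to 3 decimals with a trailing `%`; other
  statistics to at most 4 decimals with trailing zeros stripped.
- Empty summaries (no nonCGc sites, or none covered) carry `NA`
  statistics and a flag; they are never silently zero.
- Degenerate generator settings (GC 0 or 1, repeat fraction 0 or 1,
  covered fraction 0, conversion 1) are supported exactly.
- `mean_coverage ≤ 1` degenerates to depth exactly 1 at covered sites
  (the zero-truncated Poisson mean cannot fall below 1).

## Limitations

Non-mammalian genomes (e.g. plants) methylate CHG/CHH contexts, which
breaks the core assumption that nonCGc non-conversion measures chemistry
failure; for such genomes use spiked positive/negative controls instead.
Alignment, methylation calling, adapter trimming and FastQC-style raw-read
diagnostics are upstream of this package. Equivalence with any specific
aligner's dynamic-trim output is not claimed — the quality-trim rule here
is its own documented contract.
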