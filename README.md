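# bsqc — quality assessment for bisulfite-treated methylation sequencing

Bisulfite sequencing reads methylation at single-cytosine resolution, but
only if the chemistry worked: incomplete bisulfite conversion inflates
apparent methylation, and uneven coverage can silently bias which regions
are measurable at all. `bsqc` is a QC toolkit for analysts sitting between
alignment and downstream methylation analysis. It answers three questions
before you trust a dataset:

1. **Did the bisulfite treatment convert?** In mammals, cytosines outside
   the CpG context (CHG/CHH, "nonCGc") are essentially unmethylated, so the
   per-site conversion rate `1 − methylation ratio` at nonCGc sites
   measures conversion efficiency directly. `bsqc` summarizes its
   distribution per chromosome (site census `TNCGC`, covered subset
   `TNCGCwC`, order statistics) and per target region, and issues an
   advisory verdict from the fraction of under-converted sites.
2. **Which regions are poorly measured?** Each target region is classified
   on two axes: median nonCGc conversion against cutoffs `B` (high, ≥ 0.99)
   and `b` (low, ≤ 0.6), and covered-site fraction `n/N` against `L`
   (high, ≥ 0.5) and `l` (low, < 0.1).
3. **Is the problem sequence-structural?** For high- vs low-metric region
   groups, `bsqc` compares %A, %C, %G, %T, %G+C, CpG-cytosine and
   non-CpG-cytosine content, and repeat content (soft-masked lowercase
   fraction of the reference), as boxplot-ready five-number summaries.

It also trims FASTQ reads (fixed-length or quality-based), builds RRBS
target intervals by in-silico MspI (`C^CGG`) digestion with 40–220 bp size
selection, and ships a synthetic-data generator with known ground truth so
the whole pipeline is testable without external data.

Alignment and methylation calling are out of scope: `bsqc` consumes the
per-cytosine ratio tables those tools produce (columns
`chrom pos strand context coverage ratio`; other column orders are
remapped with a column map).

## Worked example

Generate a synthetic dataset (200 kb genome, true conversion rate 0.995,
10× mean depth at 30% of sites) and run the QC from the ratio table:

```bash
bsqc simulate -O demo --seed 1
bsqc run-partial -i demo/ratios.tsv -t demo/targets.bed \
    -r demo/reference.fa -c chrS -p demo -O demo/qc
```

The log reports the chromosome-level census and the advisory:

```
[bsqc] read 90090 cytosine records from demo/ratios.tsv
[bsqc] chrS: TNCGC=46862 TNCGCwC=14370 (30.665%)
[bsqc] advisory: proceed (4.77% of covered nonCGc below 0.99)
[bsqc] low_bs: 0 of 100 regions (negligible; structure comparison unnecessary)
[bsqc] low_coverage: 0 of 100 regions (negligible; structure comparison unnecessary)
```

Of 46,862 nonCGc sites, 14,370 have coverage (30.665%); fewer than 5% of
covered sites fall below conversion 0.99, so the verdict is *proceed* — and
both low-metric region groups are empty, so the sample shows no coverage or
conversion pathology. `demo/qc/demo.chrS.summary.table.txt` holds the
summary row:

```
chr	TNCGC	TNCGCwC	Percent	Min	25th_percentile	Median	Mean	75th_percentile	Max
chrS	46862	14370	30.665%	0.6667	1	1	0.9951	1	1
```

A mean conversion of 0.9951 recovers the generator's true rate of 0.995;
more than 75% of covered nonCGc sites are fully converted. The remaining
outputs (`*.target` classification lists, `*.seq` composition tables,
`*.tsv` histogram and comparison data) are plain TSV with headers, named
`<prefix>.<chrom>.<kind>`.

Subcommands: `trim`, `summarize`, `classify`, `seqstruct`, `digest`,
`simulate`, `run-partial`, `run-full` (see `bsqc --help`); everything is
equally usable as a library (`import bsqc`).

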