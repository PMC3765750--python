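"""Pipeline orchestration: the full and partial QC runs.

The full run trims a FASTQ file and, when a per-cytosine ratio table is
available (alignment and methylation calling happen in external tools),
continues with the QC stages.  The partial run starts directly from a
ratio table and performs conversion assessment, region classification and
sequence-structure comparison.

Output files follow a fixed naming scheme under ``<prefix>.<chrom>.``:

========================================  =======================================
``summary.table.txt``                     chromosome-level conversion summary
``BS.tsv``                                conversion-rate histogram data
``target.summary.table.txt``              per-region mean/median conversion
``mean.median.tsv``                       histogram data of region means/medians
``highBS.target`` / ``lowBS.target``      regions classed by conversion
``highCoverage.target`` / ``lowCoverage.target``  regions classed by coverage
``highBS.seq`` ... ``lowCoverage.seq``    per-region sequence composition
``seq.bisulfite.tsv`` / ``seq.coverage.tsv``  group comparison summaries
========================================  =======================================

Passing ``targets="F"`` skips all target-level analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import classify, conversion, io_formats, seqstruct, trimming
from .classify import Thresholds
from .records import ReferenceSequence, ValidationError
from .trimming import TrimConfig

log = logging.getLogger("bsqc")

SKIP_TARGETS = "F"


@dataclass
class RunConfig:
    """Everything one QC run needs; mirrors the command-line surface."""

    ratio_table: Optional[str] = None
    fastq: Optional[str] = None
    targets: Optional[str] = None  # path, or "F" to skip target analysis
    chrom: str = "chr1"
    prefix: str = "sample"
    outdir: str = "."
    reference: Optional[str] = None  # FASTA path, needed for seqstruct
    thresholds: Thresholds = field(default_factory=Thresholds)
    trim: TrimConfig = field(default_factory=TrimConfig)
    compare_bisulfite: bool = True  # -u
    compare_coverage: bool = True  # -v
    coord_base: int = 1
    fastq_encoding: str = "sanger"
    histogram_bins: int = 20

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValidationError("prefix must be non-empty")

    def out(self, suffix: str) -> Path:
        return Path(self.outdir) / f"{self.prefix}.{self.chrom}.{suffix}"


def run_partial(config: RunConfig) -> dict[str, Path]:
    """Conversion QC, classification and structure comparison from a ratio
    table; returns the mapping of logical output names to written paths."""
    if not config.ratio_table:
        raise ValidationError("partial run requires a ratio table")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records = list(
        io_formats.read_methyl_ratio_table(config.ratio_table, config.coord_base)
    )
    log.info("read %d cytosine records from %s", len(records), config.ratio_table)

    # chromosome-level conversion summary + histogram
    summary = conversion.chrom_summary(records)
    path = config.out("summary.table.txt")
    conversion.write_chrom_summary(summary, path)
    outputs["chrom_summary"] = path
    log.info(
        "%s: TNCGC=%d TNCGCwC=%d (%s)",
        summary.chrom,
        summary.tncgc,
        summary.tncgc_with_cov,
        conversion.format_percent(summary.percent),
    )

    rates = conversion.conversion_rates(records)
    edges, counts = conversion.conversion_histogram(rates, config.histogram_bins)
    path = config.out("BS.tsv")
    conversion.write_histogram(edges, counts, path)
    outputs["bs_histogram"] = path

    if rates.size:
        adv = conversion.advisory(records)
        log.info(
            "advisory: %s (%.2f%% of covered nonCGc below 0.99)",
            adv.verdict,
            100 * adv.frac_low_sites,
        )

    if not config.targets or config.targets == SKIP_TARGETS:
        return outputs

    # target-region level
    regions = io_formats.read_targets(config.targets)
    summaries = conversion.summarize_regions(records, regions)
    path = config.out("target.summary.table.txt")
    conversion.write_region_summaries(summaries, path)
    outputs["target_summary"] = path

    defined = [s for s in summaries if s.median_bs is not None]
    vals = [s.mean_bs for s in defined] + [s.median_bs for s in defined]
    edges, counts = conversion.conversion_histogram(vals, config.histogram_bins)
    path = config.out("mean.median.tsv")
    conversion.write_histogram(edges, counts, path)
    outputs["mean_median_histogram"] = path

    classifications = classify.classify_regions(summaries, config.thresholds)
    no_sites = [c.region for c in classifications if c.cov_class == "undefined"]
    if no_sites:
        path = config.out("noNonCGc.target")
        io_formats.write_targets(no_sites, path)
        outputs["no_noncgc_regions"] = path

    by_summary = {id(s.region): s for s in summaries}
    for axis, high_name, low_name in (
        ("bs", "highBS", "lowBS"),
        ("cov", "highCoverage", "lowCoverage"),
    ):
        groups = classify.partition(classifications, axis)
        for cls, name in (("high", high_name), ("low", low_name)):
            path = config.out(f"{name}.target")
            selected = [by_summary[id(r)] for r in groups[cls]]
            conversion.write_region_summaries(selected, path)
            outputs[f"{name}_regions"] = path

    flags = classify.small_group_check(classifications)
    for flag in flags.values():
        log.info(
            "%s: %d of %d regions%s",
            flag.group,
            flag.count,
            flag.total,
            " (negligible; structure comparison unnecessary)" if flag.negligible else "",
        )

    # sequence-structure comparison needs the reference
    if config.reference and (config.compare_bisulfite or config.compare_coverage):
        refs = io_formats.read_fasta(config.reference)
        ref = _pick_reference(refs, records[0].chrom if records else config.chrom)
        axes = []
        if config.compare_bisulfite:
            axes.append(("bs", "highBS", "lowBS", "seq.bisulfite.tsv"))
        if config.compare_coverage:
            axes.append(("cov", "highCoverage", "lowCoverage", "seq.coverage.tsv"))
        for axis, high_name, low_name, cmp_name in axes:
            groups = classify.partition(classifications, axis)
            for cls, name in (("high", high_name), ("low", low_name)):
                comps = [
                    seqstruct.composition(ref, r)
                    for r in groups[cls]
                    if r.chrom == ref.chrom and r.end <= len(ref.bases)
                ]
                path = config.out(f"{name}.seq")
                seqstruct.write_compositions(comps, path)
                outputs[f"{name}_seq"] = path
            high = [r for r in groups["high"] if r.chrom == ref.chrom]
            low = [r for r in groups["low"] if r.chrom == ref.chrom]
            if high and low:
                comparison = seqstruct.compare_groups(ref, high, low)
                path = config.out(cmp_name)
                seqstruct.write_comparison(comparison, path)
                outputs[f"seq_comparison_{axis}"] = path
            else:
                log.info(
                    "skipping %s structure comparison: a group is empty", axis
                )
    elif config.compare_bisulfite or config.compare_coverage:
        log.info("no reference given; skipping sequence-structure comparison")

    return outputs


def run_full(config: RunConfig) -> dict[str, Path]:
    """Trim the FASTQ input, then run the QC stages when a ratio table is
    available (alignment is performed by external tools in between)."""
    if not config.fastq:
        raise ValidationError("full run requires a FASTQ input")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.trim.mode != "none":
        trimmed = config.out("trimmed.fastq")
        report = trimming.trim_fastq(
            config.fastq, trimmed, config.trim, config.fastq_encoding
        )
        assert report.conserved(), "read conservation violated"
        outputs["trimmed_fastq"] = trimmed
        log.info(
            "trimming (%s): %d reads in, %d kept, %d dropped",
            config.trim.mode,
            report.total,
            report.kept,
            report.dropped,
        )

    if config.ratio_table:
        outputs.update(run_partial(config))
    else:
        log.info("no ratio table provided; stopping after trimming "
                 "(align externally, then use the partial run)")
    return outputs


def _pick_reference(refs: dict[str, ReferenceSequence], chrom: str) -> ReferenceSequence:
    if chrom in refs:
        return refs[chrom]
    if len(refs) == 1:
        return next(iter(refs.values()))
    raise ValidationError(
        f"chromosome {chrom!r} not found in reference ({sorted(refs)})"
    )
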