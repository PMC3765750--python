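"""DNA sequence-structure profiling of genomic regions.

Answers whether coverage or conversion problems track sequence features:
per-region percentages of A, C, G, T, combined G+C, CpG cytosines (CGc),
non-CpG cytosines (nonCGc), and repetitive bases (the soft-masked lowercase
fraction of the reference, the "%low_count" metric), compared between
high- and low-metric region groups as five-number summaries.

Also provides an in-silico MspI digest to build the target intervals of a
reduced-representation (RRBS) experiment: MspI cuts at C^CGG and library
size selection keeps fragments of roughly 40-220 bp, which concentrates
reads in CpG-dense sequence.

Counting conventions: base identity is case-insensitive; CGc/nonCGc are
counted on the plus strand only (a CpG's reverse-strand cytosine is not
double-counted); percentages are of region length, so N bases dilute all
base percentages.  A region-final C is classified by the base one past the
region boundary when the reference extends that far, else counted nonCGc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import ReferenceSequence, TargetRegion, ValidationError

METRICS = ("pct_A", "pct_C", "pct_G", "pct_T", "pct_GC", "pct_CGc", "pct_nonCGc", "pct_low_count")


@dataclass(frozen=True, slots=True)
class SeqComposition:
    """Per-region composition percentages (each of region length)."""

    region: TargetRegion
    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float
    pct_GC: float
    pct_CGc: float
    pct_nonCGc: float
    pct_low_count: float
    has_n: bool = False


@dataclass(frozen=True, slots=True)
class GroupComparison:
    """One metric compared between a high and a low region group."""

    metric: str
    high_values: tuple[float, ...]
    low_values: tuple[float, ...]
    high_summary: tuple[float, float, float, float, float]  # min q1 med q3 max
    low_summary: tuple[float, float, float, float, float]


def composition(ref: ReferenceSequence, region: TargetRegion) -> SeqComposition:
    """Composition profile of one region of the reference."""
    if region.chrom != ref.chrom:
        raise ValidationError(
            f"region on {region.chrom}, reference is {ref.chrom}"
        )
    if region.end > len(ref.bases):
        raise ValidationError(
            f"region [{region.start}, {region.end}) exceeds {ref.chrom} "
            f"length {len(ref.bases)}"
        )
    seq = ref.bases[region.start : region.end]
    length = len(seq)
    upper = seq.upper()
    n_low = sum(1 for b in seq if b.islower())
    counts = {b: upper.count(b) for b in "ACGT"}

    # CGc: plus-strand C followed by G; the final C looks one base past the
    # region when the reference allows, otherwise counts as nonCGc.
    cgc = 0
    for i, b in enumerate(upper):
        if b != "C":
            continue
        if i + 1 < length:
            nxt: Optional[str] = upper[i + 1]
        elif region.end < len(ref.bases):
            nxt = ref.bases[region.end].upper()
        else:
            nxt = None
        if nxt == "G":
            cgc += 1
    noncgc = counts["C"] - cgc

    pct = lambda c: 100.0 * c / length
    return SeqComposition(
        region=region,
        pct_A=pct(counts["A"]),
        pct_C=pct(counts["C"]),
        pct_G=pct(counts["G"]),
        pct_T=pct(counts["T"]),
        pct_GC=pct(counts["C"] + counts["G"]),
        pct_CGc=pct(cgc),
        pct_nonCGc=pct(noncgc),
        pct_low_count=pct(n_low),
        has_n=sum(counts.values()) < length,
    )


def five_number(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    q = np.percentile(np.asarray(values, dtype=float), [0, 25, 50, 75, 100], method="linear")
    return tuple(float(x) for x in q)  # type: ignore[return-value]


def compare_groups(
    ref: ReferenceSequence,
    high_regions: Sequence[TargetRegion],
    low_regions: Sequence[TargetRegion],
    metrics: Sequence[str] = METRICS,
) -> list[GroupComparison]:
    """Per-metric comparison of two region groups on one reference.

    Raises if either group is empty — callers should consult
    :func:`bsqc.classify.small_group_check` first and skip the comparison
    when a low-metric group is negligible.
    """
    if not high_regions or not low_regions:
        raise ValidationError("both region groups must be non-empty")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValidationError(f"unknown metrics {sorted(unknown)}")
    high = [composition(ref, r) for r in high_regions]
    low = [composition(ref, r) for r in low_regions]
    out = []
    for m in metrics:
        hv = tuple(getattr(c, m) for c in high)
        lv = tuple(getattr(c, m) for c in low)
        out.append(GroupComparison(m, hv, lv, five_number(hv), five_number(lv)))
    return out


def mspi_digest(
    ref: ReferenceSequence, min_len: int = 40, max_len: int = 220
) -> list[TargetRegion]:
    """In-silico MspI (C^CGG) digest with fragment size selection.

    Cut coordinates fall between the first C and the CGG of every CCGG
    occurrence (case-insensitive, overlapping occurrences included).
    Candidate fragments are the intervals between consecutive cuts; those
    with ``min_len <= length <= max_len`` (both bounds inclusive) are
    returned sorted and non-overlapping.  The terminal stretches before
    the first and after the last cut are not fragments of the digest.
    """
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    upper = ref.bases.upper()
    cuts: list[int] = []
    i = upper.find("CCGG")
    while i != -1:
        cuts.append(i + 1)
        i = upper.find("CCGG", i + 1)
    fragments = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if min_len <= hi - lo <= max_len:
            fragments.append(TargetRegion(ref.chrom, lo, hi))
    return fragments


# ---------------------------------------------------------------------------
# table writers

SEQ_HEADER = ("chrom", "start", "end") + METRICS + ("contains_N",)


def write_compositions(comps: Sequence[SeqComposition], path) -> None:
    """Per-region composition rows (the ``.seq`` file of a region group)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEQ_HEADER) + "\n")
        for c in comps:
            row = [c.region.chrom, str(c.region.start), str(c.region.end)]
            row += [f"{getattr(c, m):.4f}" for m in METRICS]
            row.append("yes" if c.has_n else "no")
            fh.write("\t".join(row) + "\n")


def write_comparison(comparisons: Sequence[GroupComparison], path) -> None:
    """Boxplot surrogate: five-number summaries per metric and group."""
    with open(path, "w") as fh:
        fh.write("metric\tgroup\tn\tmin\tq25\tmedian\tq75\tmax\n")
        for comp in comparisons:
            for group, vals, summ in (
                ("high", comp.high_values, comp.high_summary),
                ("low", comp.low_values, comp.low_summary),
            ):
                fh.write(
                    f"{comp.metric}\t{group}\t{len(vals)}\t"
                    + "\t".join(f"{x:.4f}" for x in summ)
                    + "\n"
                )
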