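"""Bisulfite conversion-rate assessment at non-CpG cytosines.

In mammalian genomes cytosines outside the CpG context (CHG/CHH, "nonCGc")
are essentially unmethylated, so any apparent methylation there measures
incomplete bisulfite treatment.  The per-site conversion rate is
``1 - methylation ratio``; this module summarizes its distribution at the
chromosome level and over user-supplied target regions, and issues an
advisory verdict when a worrying share of sites is under-converted.

Statistics are computed over *covered* nonCGc sites only: an uncovered site
contributes to the site census (TNCGC) but has no defined ratio.  Quantiles
use linear interpolation between order statistics (R's default), so the
summary tables are reproducible against R's ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import MethylRecord, TargetRegion, ValidationError


@dataclass(frozen=True, slots=True)
class ChromSummary:
    """Chromosome-level conversion summary.

    TNCGC is the total number of nonCGc sites on the chromosome, TNCGCwC
    the subset with at least 1x coverage; ``percent`` is their ratio in
    percent.  The order statistics and mean are over conversion rates of
    the covered nonCGc sites, all in [0, 1].
    """

    chrom: str
    tncgc: int
    tncgc_with_cov: int
    percent: float
    min: Optional[float] = None
    q25: Optional[float] = None
    median: Optional[float] = None
    mean: Optional[float] = None
    q75: Optional[float] = None
    max: Optional[float] = None

    @property
    def flagged(self) -> bool:
        """True when there is nothing to summarize (no covered nonCGc)."""
        return self.tncgc_with_cov == 0


@dataclass(frozen=True, slots=True)
class RegionSummary:
    """Per-region nonCGc census and conversion statistics.

    ``n_sites`` (N) counts nonCGc sites in the region, ``n_covered`` (n)
    those with coverage; ``coverage_frac`` is n/N, the region-level
    coverage axis.  Mean/median conversion are over the n covered sites
    and undefined when n == 0.
    """

    region: TargetRegion
    n_sites: int
    n_covered: int
    mean_bs: Optional[float]
    median_bs: Optional[float]

    @property
    def coverage_frac(self) -> Optional[float]:
        if self.n_sites == 0:
            return None
        return self.n_covered / self.n_sites


@dataclass(frozen=True, slots=True)
class AdvisoryReport:
    """Dataset-level advisory from the split of nonCGc sites into a
    high-conversion group A (rate >= cutoff) and low group B (< cutoff)."""

    group_a_count: int
    group_b_count: int
    frac_low_sites: float
    verdict: str  # proceed | caution | investigate


def conversion_rate(record: MethylRecord) -> float:
    """Per-site bisulfite conversion rate, ``1 - methylation ratio``."""
    return record.conversion_rate


def conversion_rates(records: Iterable[MethylRecord]) -> np.ndarray:
    """Conversion rates of the covered nonCGc sites of a record stream."""
    return np.array(
        [1.0 - r.methyl_ratio for r in records if r.is_noncg and r.coverage > 0],
        dtype=float,
    )


def chrom_summary(records: Iterable[MethylRecord], chrom: Optional[str] = None) -> ChromSummary:
    """Summarize conversion over all nonCGc sites of one chromosome.

    The stream should contain every cytosine site, covered or not, as
    produced by per-cytosine ratio callers; sites of other chromosomes are
    rejected when ``chrom`` is given.
    """
    tncgc = 0
    rates: list[float] = []
    seen_chrom = chrom
    for rec in records:
        if chrom is not None and rec.chrom != chrom:
            raise ValidationError(f"record on {rec.chrom}, expected {chrom}")
        seen_chrom = seen_chrom or rec.chrom
        if not rec.is_noncg:
            continue
        tncgc += 1
        if rec.coverage > 0:
            rates.append(1.0 - rec.methyl_ratio)  # type: ignore[operator]
    n_cov = len(rates)
    percent = 100.0 * n_cov / tncgc if tncgc else 0.0
    if n_cov == 0:
        return ChromSummary(seen_chrom or "?", tncgc, 0, percent)
    arr = np.asarray(rates)
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    return ChromSummary(
        chrom=seen_chrom or "?",
        tncgc=tncgc,
        tncgc_with_cov=n_cov,
        percent=percent,
        min=float(arr.min()),
        q25=float(q25),
        median=float(med),
        mean=float(arr.mean()),
        q75=float(q75),
        max=float(arr.max()),
    )


def format_percent(percent: float) -> str:
    """Render a coverage percentage as printed in the summary table,
    e.g. ``1.394%`` for 622926 covered of 44683043 sites."""
    return f"{percent:.3f}%"


def summarize_regions(
    records: Sequence[MethylRecord] | Iterable[MethylRecord],
    regions: Sequence[TargetRegion],
) -> list[RegionSummary]:
    """One :class:`RegionSummary` per target region.

    A site contributes to every region whose half-open interval contains
    its position (overlapping regions double-count by design).  Regions on
    chromosomes absent from the record stream get N = 0.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for rec in records:
        if not rec.is_noncg:
            continue
        by_chrom.setdefault(rec.chrom, []).append(
            (rec.pos, rec.coverage, rec.methyl_ratio if rec.coverage else np.nan)
        )

    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        cov = np.array([r[1] for r in rows], dtype=np.int64)
        conv = 1.0 - np.array([r[2] for r in rows], dtype=float)
        index[chrom] = (pos, cov, conv)

    out: list[RegionSummary] = []
    for region in regions:
        if region.chrom not in index:
            out.append(RegionSummary(region, 0, 0, None, None))
            continue
        pos, cov, conv = index[region.chrom]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        n_sites = int(hi - lo)
        covered = cov[lo:hi] > 0
        n_cov = int(covered.sum())
        if n_cov == 0:
            out.append(RegionSummary(region, n_sites, 0, None, None))
            continue
        vals = conv[lo:hi][covered]
        out.append(
            RegionSummary(
                region,
                n_sites,
                n_cov,
                float(vals.mean()),
                float(np.percentile(vals, 50, method="linear")),
            )
        )
    return out


def conversion_histogram(
    values: Sequence[float] | np.ndarray, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of conversion rates over fixed [0, 1] bin edges.

    Returns ``(edges, counts)`` with ``len(edges) == bins + 1``; counts sum
    to the number of values.  Emitted as a plot-data table so the figure
    can be regenerated by any plotting front end.
    """
    arr = np.asarray(values, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return edges, counts


def advisory(
    records: Iterable[MethylRecord],
    low_cutoff: float = 0.99,
    investigate_frac: float = 0.30,
    proceed_frac: float = 0.05,
) -> AdvisoryReport:
    """Split covered nonCGc sites at ``low_cutoff`` and issue a verdict.

    More than ``investigate_frac`` of sites under-converted suggests a
    failed bisulfite treatment (investigate, possibly discard); under
    ``proceed_frac`` the data are usable as-is, optionally restricting
    downstream analysis to CpGs near well-converted (group A) sites;
    anything between is a caution.
    """
    rates = conversion_rates(records)
    if rates.size == 0:
        raise ValidationError("advisory undefined without covered nonCGc sites")
    low = int((rates < low_cutoff).sum())
    frac = low / rates.size
    if frac > investigate_frac:
        verdict = "investigate"
    elif frac < proceed_frac:
        verdict = "proceed"
    else:
        verdict = "caution"
    return AdvisoryReport(
        group_a_count=int(rates.size - low),
        group_b_count=low,
        frac_low_sites=frac,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# table rendering

CHROM_TABLE_HEADER = (
    "chr",
    "TNCGC",
    "TNCGCwC",
    "Percent",
    "Min",
    "25th_percentile",
    "Median",
    "Mean",
    "75th_percentile",
    "Max",
)

REGION_TABLE_HEADER = (
    "chrom",
    "start",
    "end",
    "N_nonCGc",
    "n_covered",
    "coverage_frac",
    "mean_BS",
    "median_BS",
)


def _fmt_stat(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    if x == int(x):
        return str(int(x))
    return f"{x:.4f}".rstrip("0").rstrip(".")


def chrom_summary_row(s: ChromSummary) -> tuple[str, ...]:
    return (
        s.chrom,
        str(s.tncgc),
        str(s.tncgc_with_cov),
        format_percent(s.percent),
        _fmt_stat(s.min),
        _fmt_stat(s.q25),
        _fmt_stat(s.median),
        _fmt_stat(s.mean),
        _fmt_stat(s.q75),
        _fmt_stat(s.max),
    )


def write_chrom_summary(s: ChromSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CHROM_TABLE_HEADER) + "\n")
        fh.write("\t".join(chrom_summary_row(s)) + "\n")


def write_region_summaries(summaries: Sequence[RegionSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_TABLE_HEADER) + "\n")
        for s in summaries:
            cf = s.coverage_frac
            fh.write(
                "\t".join(
                    (
                        s.region.chrom,
                        str(s.region.start),
                        str(s.region.end),
                        str(s.n_sites),
                        str(s.n_covered),
                        "NA" if cf is None else f"{cf:.6g}",
                        "NA" if s.mean_bs is None else f"{s.mean_bs:.6g}",
                        "NA" if s.median_bs is None else f"{s.median_bs:.6g}",
                    )
                )
                + "\n"
            )


def write_histogram(edges: np.ndarray, counts: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{int(c)}\n")
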