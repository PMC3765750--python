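"""Read trimming: fixed-length and quality-based.

Illumina bisulfite libraries routinely show a steep quality drop at the 3'
end and runs of N calls at either end of the read; untrimmed, such reads
fail to align.  Two strategies are offered:

* **fixed** — remove a set number of bases from the 5' and 3' ends
  (defaults 5 and 10);
* **quality** — strip terminal N bases, then trim the 3' tail while the
  base quality is below a Phred cutoff (default Q20), repeating both rules
  until the read is stable, so the operation is idempotent.

Reads that fall below ``min_len`` are dropped and counted, never errors;
every trimming run conserves reads (kept + dropped == input).

Adapter trimming is out of scope: adapters are removed upstream by
dedicated tools and this module consumes their output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .records import ReadRecord, ValidationError

TRIM_MODES = ("none", "fixed", "quality")


@dataclass(frozen=True, slots=True)
class TrimConfig:
    mode: str = "quality"
    n5: int = 5  # bases removed at the 5' end in fixed mode
    n3: int = 10  # bases removed at the 3' end in fixed mode
    qual_threshold: int = 20
    min_len: int = 1

    def __post_init__(self) -> None:
        if self.mode not in TRIM_MODES:
            raise ValidationError(f"mode must be one of {TRIM_MODES}, got {self.mode!r}")
        if self.n5 < 0 or self.n3 < 0:
            raise ValidationError("trim lengths must be non-negative")
        if not 0 <= self.qual_threshold <= 93:
            raise ValidationError("quality threshold outside [0, 93]")
        if self.min_len < 1:
            raise ValidationError("min_len must be >= 1")


@dataclass
class TrimReport:
    """Aggregate bookkeeping for one trimming run."""

    total: int = 0
    kept: int = 0
    dropped: int = 0
    bases_in: int = 0
    bases_out: int = 0

    def conserved(self) -> bool:
        return self.kept + self.dropped == self.total


def fixed_trim(
    read: ReadRecord, n5: int = 5, n3: int = 10, min_len: int = 1
) -> Optional[ReadRecord]:
    """Remove ``n5`` leading and ``n3`` trailing bases (with their
    qualities); return ``None`` when fewer than ``min_len`` bases survive."""
    if n5 < 0 or n3 < 0:
        raise ValidationError("trim lengths must be non-negative")
    end = len(read) - n3
    if end - n5 < min_len:
        return None
    return ReadRecord(read.id, read.bases[n5:end], read.quals[n5:end])


def quality_trim(
    read: ReadRecord, qual_threshold: int = 20, min_len: int = 1
) -> Optional[ReadRecord]:
    """Strip terminal Ns, then trim the 3' tail below ``qual_threshold``.

    Both rules are re-applied until the read no longer changes (a trimmed
    tail may expose a terminal N), so the result is a fixed point:
    re-trimming an already-trimmed read is a no-op.
    """
    lo, hi = 0, len(read)  # surviving window [lo, hi)
    changed = True
    while changed:
        changed = False
        while lo < hi and read.bases[lo] == "N":
            lo += 1
            changed = True
        while lo < hi and read.bases[hi - 1] == "N":
            hi -= 1
            changed = True
        while lo < hi and read.quals[hi - 1] < qual_threshold:
            hi -= 1
            changed = True
    if hi - lo < min_len:
        return None
    return ReadRecord(read.id, read.bases[lo:hi], read.quals[lo:hi])


def trim_read(read: ReadRecord, config: TrimConfig) -> Optional[ReadRecord]:
    if config.mode == "none":
        return read
    if config.mode == "fixed":
        return fixed_trim(read, config.n5, config.n3, config.min_len)
    return quality_trim(read, config.qual_threshold, config.min_len)


def trim_stream(
    reads: Iterable[ReadRecord], config: TrimConfig, report: TrimReport
) -> Iterator[ReadRecord]:
    """Trim a read stream, updating ``report`` in place as reads pass."""
    for read in reads:
        report.total += 1
        report.bases_in += len(read)
        out = trim_read(read, config)
        if out is None:
            report.dropped += 1
            continue
        report.kept += 1
        report.bases_out += len(out)
        yield out


def trim_fastq(
    in_path, out_path, config: TrimConfig, encoding: str = "sanger"
) -> TrimReport:
    """Trim a FASTQ file on disk; returns the conservation report."""
    from . import io_formats

    report = TrimReport()
    reads = io_formats.read_fastq(in_path, encoding)
    io_formats.write_fastq(trim_stream(reads, config, report), out_path, encoding)
    return report
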