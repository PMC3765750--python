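"""Readers and writers for the external formats the pipeline touches.

Dialects:

* **Methylation-ratio tables** — whitespace-delimited, one cytosine site per
  line, default column order ``chrom pos strand context coverage ratio``
  (written with a header).  Tables produced by other callers with the same
  fields in a different order are handled by passing ``columns``; positions
  are 1-based on disk by default (``coord_base=1``) and 0-based in memory.
  An uncovered site carries ``NA`` in the ratio column.
* **Target-region files** — 3+ columns ``chrom start end [label]``,
  BED-style 0-based half-open by default; ``one_based=True`` reads 1-based
  inclusive coordinates.
* **FASTA** — case preserved (lowercase = soft-masked repeat).
* **FASTQ** — Sanger (Phred+33) or Illumina-1.3 (Phred+64) quality
  encodings, delegated to Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CONTEXTS,
    MethylRecord,
    ReadRecord,
    ReferenceSequence,
    TargetRegion,
    ValidationError,
)

RATIO_COLUMNS: tuple[str, ...] = ("chrom", "pos", "strand", "context", "coverage", "ratio")
NA_TOKENS = frozenset({"NA", "na", "NaN", "nan", ".", "-"})

_FASTQ_FORMATS = {"sanger": "fastq-sanger", "illumina": "fastq-illumina"}
_PHRED_OFFSETS = {"sanger": 33, "illumina": 64}


class ParseError(ValueError):
    """A line could not be parsed; the message names the offending line."""


class EncodingError(ValueError):
    """FASTQ quality string incompatible with the declared encoding."""


# ---------------------------------------------------------------------------
# methylation-ratio tables


def read_methyl_ratio_table(
    path: str | os.PathLike,
    coord_base: int = 1,
    columns: Sequence[str] = RATIO_COLUMNS,
) -> Iterator[MethylRecord]:
    """Stream :class:`MethylRecord` rows from a per-cytosine ratio table.

    ``columns`` maps the file's column order onto the canonical field names
    and must contain at least ``chrom pos strand context coverage ratio``.
    A leading header row repeating those names is skipped.  Positions are
    normalized to internal 0-based coordinates.
    """
    if coord_base not in (0, 1):
        raise ValueError(f"coord_base must be 0 or 1, got {coord_base}")
    missing = set(RATIO_COLUMNS) - set(columns)
    if missing:
        raise ValueError(f"column map lacks {sorted(missing)}")
    idx = {name: i for i, name in enumerate(columns)}
    nfields = len(columns)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if lineno == 1 and set(fields) >= set(RATIO_COLUMNS):
                continue  # header
            if len(fields) < nfields:
                raise ParseError(
                    f"{path}:{lineno}: expected {nfields} columns, got {len(fields)}"
                )
            try:
                pos = int(fields[idx["pos"]])
                coverage = int(fields[idx["coverage"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            context = fields[idx["context"]].upper()
            if context not in CONTEXTS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown cytosine context {context!r}"
                )
            ratio_tok = fields[idx["ratio"]]
            if ratio_tok in NA_TOKENS:
                ratio: Optional[float] = None
            else:
                try:
                    ratio = float(ratio_tok)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad ratio {ratio_tok!r}") from exc
                if not 0.0 <= ratio <= 1.0:
                    raise ValidationError(
                        f"{path}:{lineno}: ratio {ratio} outside [0, 1]"
                    )
            if coverage == 0:
                ratio = None
            try:
                yield MethylRecord(
                    chrom=fields[idx["chrom"]],
                    pos=pos - coord_base,
                    strand=fields[idx["strand"]],
                    context=context,
                    coverage=coverage,
                    methyl_ratio=ratio,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def write_methyl_ratio_table(
    records: Iterable[MethylRecord],
    path: str | os.PathLike,
    coord_base: int = 1,
) -> int:
    """Write records in the canonical dialect; returns the row count.

    Round-trips exactly with :func:`read_methyl_ratio_table` under the same
    ``coord_base``.
    """
    if coord_base not in (0, 1):
        raise ValueError(f"coord_base must be 0 or 1, got {coord_base}")
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(RATIO_COLUMNS) + "\n")
        for rec in records:
            ratio = "NA" if rec.methyl_ratio is None else repr(float(rec.methyl_ratio))
            fh.write(
                f"{rec.chrom}\t{rec.pos + coord_base}\t{rec.strand}\t"
                f"{rec.context}\t{rec.coverage}\t{ratio}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# target-region files


def read_targets(path: str | os.PathLike, one_based: bool = False) -> list[TargetRegion]:
    """Read a 3-column (chrom, start, end) target file.

    Coordinates are BED-style 0-based half-open unless ``one_based`` is set,
    in which case 1-based inclusive intervals are converted on input.
    Overlapping regions are permitted and preserved in file order.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3+ columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start, end = start - 1, end
            label = fields[3] if len(fields) > 3 else None
            try:
                regions.append(TargetRegion(fields[0], start, end, label))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_targets(
    regions: Iterable[TargetRegion], path: str | os.PathLike, one_based: bool = False
) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in regions:
            start = r.start + 1 if one_based else r.start
            cols = [r.chrom, str(start), str(r.end)]
            if r.label is not None:
                cols.append(r.label)
            fh.write("\t".join(cols) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, ReferenceSequence]:
    """Read a (soft-masked) FASTA file, preserving case."""
    out: dict[str, ReferenceSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ReferenceSequence(chrom=rec.id, bases=str(rec.seq))
    return out


def write_fasta(
    seqs: Iterable[ReferenceSequence], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.chrom}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_fastq(
    path: str | os.PathLike, encoding: str = "sanger"
) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file under a declared quality encoding."""
    fmt = _fastq_format(encoding)
    other = "illumina" if encoding == "sanger" else "sanger"
    try:
        for rec in SeqIO.parse(str(path), fmt):
            yield ReadRecord(
                id=rec.id,
                bases=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise EncodingError(
            f"{path}: quality string invalid for {encoding!r} encoding "
            f"(Phred+{_PHRED_OFFSETS[encoding]}); is the file {other!r}-encoded? "
            f"[{exc}]"
        ) from exc


def write_fastq(
    reads: Iterable[ReadRecord], path: str | os.PathLike, encoding: str = "sanger"
) -> int:
    fmt = _fastq_format(encoding)
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, fh, fmt)
            n += 1
    return n


def _fastq_format(encoding: str) -> str:
    try:
        return _FASTQ_FORMATS[encoding]
    except KeyError:
        raise ValueError(
            f"encoding must be one of {sorted(_FASTQ_FORMATS)}, got {encoding!r}"
        ) from None
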