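"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the I/O
layer converts to and from 1-based external conventions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CONTEXTS = frozenset({"CG", "CHG", "CHH"})
STRANDS = frozenset({"+", "-"})


class ValidationError(ValueError):
    """A record or parameter violates a documented invariant."""


@dataclass(frozen=True, slots=True)
class MethylRecord:
    """One cytosine site from a per-cytosine methylation-ratio table.

    ``methyl_ratio`` is the methylated-read fraction at the site and is
    defined only when ``coverage > 0``; an uncovered site carries ``None``
    (serialized as ``NA``), never 0, so "no data" is not conflated with
    "fully converted".
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str  # CG | CHG | CHH
    coverage: int
    methyl_ratio: Optional[float]

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown cytosine context {self.context!r}")
        if self.coverage < 0:
            raise ValidationError(f"negative coverage {self.coverage}")
        if self.coverage == 0:
            if self.methyl_ratio is not None:
                raise ValidationError("uncovered site must have undefined ratio")
        else:
            if self.methyl_ratio is None:
                raise ValidationError("covered site must have a ratio")
            if not 0.0 <= self.methyl_ratio <= 1.0:
                raise ValidationError(
                    f"methylation ratio {self.methyl_ratio} outside [0, 1]"
                )

    @property
    def is_noncg(self) -> bool:
        """True for CHG/CHH sites — the contexts assumed unmethylated in
        mammals and therefore informative about bisulfite conversion."""
        return self.context != "CG"

    @property
    def conversion_rate(self) -> float:
        """Bisulfite conversion rate, ``1 - methylation ratio``."""
        if self.coverage == 0 or self.methyl_ratio is None:
            raise ValidationError("conversion rate undefined at uncovered site")
        return 1.0 - self.methyl_ratio


@dataclass(frozen=True, slots=True)
class TargetRegion:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """A sequencing read: bases over {A,C,G,T,N} with per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValidationError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise ValidationError(f"read {self.id}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class ReferenceSequence:
    """A (soft-masked) reference chromosome.

    Case is preserved: lowercase bases mark repeat / low-complexity regions
    as annotated by the genome provider, and the lowercase fraction is the
    repetitive-content ("%low_count") metric used downstream.
    """

    chrom: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValidationError(f"empty reference sequence {self.chrom}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def masked_fraction(self) -> float:
        return sum(1 for b in self.bases if b.islower()) / len(self.bases)
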