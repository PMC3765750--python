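"""Threshold classification of target regions on two axes.

Each region is classified independently on (1) its median bisulfite
conversion over covered nonCGc sites, against cutoffs ``B`` (high, >=) and
``b`` (low, <=), and (2) its nonCGc coverage fraction n/N, against cutoffs
``L`` (high, >=) and ``l`` (low, strictly <).  The inequality directions
are intentionally asymmetric: a coverage fraction exactly at ``l`` is
"neither", while a median exactly at ``b`` is "low".

Classes: ``high`` / ``low`` / ``neither`` / ``undefined`` — undefined when
the defining statistic does not exist (no covered nonCGc sites for the
conversion axis; no nonCGc sites at all for the coverage axis).  Regions
with N == 0 are reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .conversion import RegionSummary
from .records import TargetRegion, ValidationError

CLASSES = ("high", "low", "neither", "undefined")


@dataclass(frozen=True, slots=True)
class Thresholds:
    """Classification cutoffs, all in [0, 1] (tool defaults)."""

    B: float = 0.99  # high-conversion cutoff (median >= B)
    b: float = 0.6  # low-conversion cutoff (median <= b)
    L: float = 0.5  # high-coverage cutoff (n/N >= L)
    l: float = 0.1  # low-coverage cutoff (n/N < l)

    def __post_init__(self) -> None:
        for name in ("B", "b", "L", "l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"threshold {name}={v} outside [0, 1]")
        if self.b >= self.B:
            raise ValidationError(f"need b < B, got b={self.b}, B={self.B}")
        if self.l > self.L:
            raise ValidationError(f"need l <= L, got l={self.l}, L={self.L}")


@dataclass(frozen=True, slots=True)
class RegionClassification:
    region: TargetRegion
    bs_class: str
    cov_class: str


def classify_bisulfite(summary: RegionSummary, B: float = 0.99, b: float = 0.6) -> str:
    """Conversion-axis class from the region's median conversion rate."""
    if b >= B:
        raise ValidationError(f"need b < B, got b={b}, B={B}")
    if summary.n_covered == 0 or summary.median_bs is None:
        return "undefined"
    if summary.median_bs >= B:
        return "high"
    if summary.median_bs <= b:
        return "low"
    return "neither"


def classify_coverage(summary: RegionSummary, L: float = 0.5, l: float = 0.1) -> str:
    """Coverage-axis class from the region's covered-site fraction n/N."""
    if l > L:
        raise ValidationError(f"need l <= L, got l={l}, L={L}")
    frac = summary.coverage_frac
    if frac is None:
        return "undefined"
    if frac >= L:
        return "high"
    if frac < l:
        return "low"
    return "neither"


def classify_regions(
    summaries: Sequence[RegionSummary], thresholds: Thresholds = Thresholds()
) -> list[RegionClassification]:
    return [
        RegionClassification(
            s.region,
            classify_bisulfite(s, thresholds.B, thresholds.b),
            classify_coverage(s, thresholds.L, thresholds.l),
        )
        for s in summaries
    ]


@dataclass(frozen=True, slots=True)
class GroupFlag:
    group: str  # e.g. "low_bs", "low_coverage"
    count: int
    total: int
    negligible: bool


def small_group_check(
    classifications: Sequence[RegionClassification],
    total_regions: int | None = None,
    min_count: int = 10,
    min_frac: float = 0.005,
) -> dict[str, GroupFlag]:
    """Flag low-metric classes too small to warrant structure comparison.

    A low-conversion or low-coverage class with fewer than ``min_count``
    regions, or fewer than ``min_frac`` of all target regions, is marked
    negligible: the sample is probably well sequenced on that axis and the
    sequence-structure comparison can be skipped.
    """
    total = total_regions if total_regions is not None else len(classifications)
    if total < 1:
        raise ValidationError("need at least one target region")
    out: dict[str, GroupFlag] = {}
    for group, attr in (("low_bs", "bs_class"), ("low_coverage", "cov_class")):
        count = sum(1 for c in classifications if getattr(c, attr) == "low")
        negligible = count < min_count or count < min_frac * total
        out[group] = GroupFlag(group, count, total, negligible)
    return out


def partition(
    classifications: Sequence[RegionClassification], axis: str
) -> dict[str, list[TargetRegion]]:
    """Group regions by class on one axis (``"bs"`` or ``"cov"``)."""
    attr = {"bs": "bs_class", "cov": "cov_class"}[axis]
    out: dict[str, list[TargetRegion]] = {c: [] for c in CLASSES}
    for c in classifications:
        out[getattr(c, attr)].append(c.region)
    return out
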