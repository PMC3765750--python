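"""Synthetic bisulfite-sequencing fixtures with known ground truth.

Every stage of the pipeline is testable without external data: this module
generates a soft-masked reference with controlled GC content and CpG
enrichment, a per-cytosine methylation-ratio table drawn from a known true
conversion rate, FASTQ reads with a 3'-declining quality profile, and
random target regions.  Ground truth is serialized in a manifest next to
every fixture so tests never re-infer it, and all randomness flows from a
single explicit seed.

Generative model
----------------
* **Reference** — first-order Markov chain over {A,C,G,T}.  The marginal
  base weights are symmetric (A=T, C=G) and the probability of G after a C
  is multiplied by ``cpg_enrichment``; the underlying weight is calibrated
  (bisection on the chain's stationary distribution) so the expected G+C
  fraction equals ``gc_fraction`` exactly.  Repeats are emulated by
  soft-masking fixed-size blocks chosen uniformly until ``repeat_fraction``
  of the genome is lowercase.
* **Methylation table** — one record per cytosine on each strand, context
  (CG/CHG/CHH) read from the strand's own 2-base lookahead.  A site is
  covered with probability ``covered_site_fraction``; covered sites draw
  depth from a zero-truncated Poisson whose mean is ``mean_coverage``.
  The methylated-read count is Binomial(depth, p) with p equal to
  ``1 - true_conversion`` at nonCGc sites and ``cpg_methylation`` at CpGs;
  the recorded ratio is methylated/depth.
* **Reads** — uniform start positions, qualities declining linearly toward
  the 3' end at ``quality_decay`` Phred units per base plus Gaussian jitter.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import io_formats
from .records import MethylRecord, ReadRecord, ReferenceSequence, TargetRegion, ValidationError

_BASES = "ACGT"
_MASK_BLOCK = 200  # soft-mask block size (bases)


@dataclass(frozen=True, slots=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults sketch a well-behaved mammalian bisulfite experiment at desk
    scale: near-complete conversion (0.995), mammalian-like genome
    composition (GC 0.45, most CpGs methylated), and enough covered nonCGc
    sites for stable chromosome-level statistics.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.45
    cpg_enrichment: float = 3.0
    repeat_fraction: float = 0.15
    true_conversion: float = 0.995
    cpg_methylation: float = 0.75
    mean_coverage: float = 10.0
    covered_site_fraction: float = 0.3
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "repeat_fraction",
            "true_conversion",
            "cpg_methylation",
            "covered_site_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 1:
            raise ValidationError("genome_length must be >= 1")
        if self.mean_coverage < 0:
            raise ValidationError("mean_coverage must be >= 0")
        if self.cpg_enrichment < 0:
            raise ValidationError("cpg_enrichment must be >= 0")


def _as_rng(rng: np.random.Generator | int | None, seed: int = 0) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(seed if rng is None else rng)


# ---------------------------------------------------------------------------
# reference


def _transition_rows(w: float, enrichment: float) -> tuple[list[float], list[float]]:
    """Transition probabilities (A,C,G,T) from a non-C and from a C state."""
    base = [(1 - w) / 2, w / 2, w / 2, (1 - w) / 2]
    g_after_c = enrichment * w / 2
    if g_after_c >= 1.0:
        raise ValidationError(
            f"cpg_enrichment {enrichment} with GC weight {w} forces "
            f"P(G|C) = {g_after_c:.3f} >= 1"
        )
    scale = (1 - g_after_c) / (1 - w / 2) if w < 2 else 0.0
    from_c = [base[0] * scale, base[1] * scale, g_after_c, base[3] * scale]
    return base, from_c


def _stationary_gc(w: float, enrichment: float) -> float:
    rows_other, row_c = _transition_rows(w, enrichment)
    M = np.array([rows_other, row_c, rows_other, rows_other])  # rows: from A,C,G,T
    vals, vecs = np.linalg.eig(M.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = pi / pi.sum()
    return float(pi[1] + pi[2])


def generate_reference(
    spec: SimulationSpec, rng: np.random.Generator | int | None = None
) -> ReferenceSequence:
    """Generate a soft-masked reference chromosome.

    The expected GC fraction equals ``spec.gc_fraction`` and the realized
    lowercase fraction is within one mask block of ``spec.repeat_fraction``;
    output is deterministic under a fixed seed.
    """
    rng = _as_rng(rng, spec.seed)
    L = spec.genome_length
    gc = spec.gc_fraction

    if gc in (0.0, 1.0):
        pair = "AT" if gc == 0.0 else "CG"
        seq = "".join(pair[i] for i in rng.integers(0, 2, size=L))
    else:
        # calibrate the symmetric base weight so stationary GC == target;
        # the bracket keeps P(G|C) = enrichment*w/2 below 1
        w_hi = 1.0 - 1e-9
        if spec.cpg_enrichment > 1.9:
            w_hi = min(w_hi, 1.9 / spec.cpg_enrichment)
        try:
            w = brentq(
                lambda x: _stationary_gc(x, spec.cpg_enrichment) - gc, 1e-9, w_hi
            )
        except ValueError as exc:
            raise ValidationError(
                f"gc_fraction {gc} unreachable with cpg_enrichment "
                f"{spec.cpg_enrichment} (P(G|C) would exceed 1)"
            ) from exc
        row_other, row_c = _transition_rows(w, spec.cpg_enrichment)
        cum_other = np.cumsum(row_other).tolist()
        cum_c = np.cumsum(row_c).tolist()
        u = rng.random(L)
        chars = []
        prev_is_c = False
        for i in range(L):
            cum = cum_c if prev_is_c else cum_other
            j = bisect_right(cum, u[i])
            if j > 3:
                j = 3
            chars.append(_BASES[j])
            prev_is_c = j == 1
        seq = "".join(chars)

    seq = _apply_softmask(seq, spec.repeat_fraction, rng)
    return ReferenceSequence(chrom=spec.chrom, bases=seq)


def _apply_softmask(seq: str, fraction: float, rng: np.random.Generator) -> str:
    if fraction <= 0.0:
        return seq
    L = len(seq)
    if fraction >= 1.0:
        return seq.lower()
    blocks = [(s, min(s + _MASK_BLOCK, L)) for s in range(0, L, _MASK_BLOCK)]
    order = rng.permutation(len(blocks))
    target = fraction * L
    masked = 0
    arr = list(seq)
    for bi in order:
        if masked >= target:
            break
        s, e = blocks[bi]
        arr[s:e] = seq[s:e].lower()
        masked += e - s
    return "".join(arr)


# ---------------------------------------------------------------------------
# methylation table


def cytosine_sites(ref: ReferenceSequence) -> list[tuple[int, str, str]]:
    """All cytosine sites of a reference as (pos, strand, context) triples.

    A plus-strand C at position i reads its context from bases i+1, i+2;
    a minus-strand C (a plus-strand G at i) reads leftward from i-1, i-2.
    A site whose context window runs off the sequence, or hits an N, is
    classified by what is visible: no following G means CHG or CHH, and
    an incomplete window defaults to CHH.
    """
    upper = ref.bases.upper()
    arr = np.frombuffer(upper.encode("ascii"), dtype="S1")
    L = len(arr)
    pad = np.concatenate([np.full(2, b"N"), arr, np.full(2, b"N")])

    sites: list[tuple[int, str, str]] = []
    c_pos = np.flatnonzero(arr == b"C")
    next1 = pad[c_pos + 3]
    next2 = pad[c_pos + 4]
    g_pos = np.flatnonzero(arr == b"G")
    prev1 = pad[g_pos + 1]
    prev2 = pad[g_pos + 0]

    def ctx(n1: bytes, n2: bytes) -> str:
        if n1 == b"G":
            return "CG"
        if n2 == b"G":
            return "CHG"
        return "CHH"

    def ctx_minus(n1: bytes, n2: bytes) -> str:
        # on the minus strand the neighbour is the complement of the
        # plus-strand base, so "is G" becomes "plus-strand base is C"
        if n1 == b"C":
            return "CG"
        if n2 == b"C":
            return "CHG"
        return "CHH"

    for p, n1, n2 in zip(c_pos, next1, next2):
        sites.append((int(p), "+", ctx(n1, n2)))
    for p, n1, n2 in zip(g_pos, prev1, prev2):
        sites.append((int(p), "-", ctx_minus(n1, n2)))
    sites.sort()
    return sites


def _ztp_mean_to_lambda(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0:
        raise ValidationError(f"zero-truncated Poisson mean must be > 1, got {mean}")
    return float(brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 10 * mean))


def _sample_ztp(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(lam, size=size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))
        zeros = out == 0
    return out


def generate_methyl_table(
    ref: ReferenceSequence,
    spec: SimulationSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[MethylRecord], dict]:
    """Simulate a per-cytosine ratio table over both strands of ``ref``.

    Returns the records plus a ground-truth dictionary (site census and
    the generative parameters actually used).
    """
    rng = _as_rng(rng, spec.seed)
    sites = cytosine_sites(ref)
    n = len(sites)
    noncg = np.array([ctx != "CG" for _, _, ctx in sites])

    covered = rng.random(n) < spec.covered_site_fraction
    cov = np.zeros(n, dtype=np.int64)
    n_cov = int(covered.sum())
    if n_cov:
        if spec.mean_coverage <= 1.0:
            cov[covered] = 1
        else:
            lam = _ztp_mean_to_lambda(spec.mean_coverage)
            cov[covered] = _sample_ztp(lam, n_cov, rng)

    p_meth = np.where(noncg, 1.0 - spec.true_conversion, spec.cpg_methylation)
    meth = np.zeros(n, dtype=np.int64)
    meth[covered] = rng.binomial(cov[covered], p_meth[covered])

    records = []
    for i, (pos, strand, ctx) in enumerate(sites):
        c = int(cov[i])
        records.append(
            MethylRecord(
                chrom=ref.chrom,
                pos=pos,
                strand=strand,
                context=ctx,
                coverage=c,
                methyl_ratio=(float(meth[i]) / c) if c else None,
            )
        )
    truth = {
        "n_sites": n,
        "n_noncg_sites": int(noncg.sum()),
        "n_covered_noncg_sites": int((covered & noncg).sum()),
        "true_conversion": spec.true_conversion,
        "cpg_methylation": spec.cpg_methylation,
        "covered_site_fraction": spec.covered_site_fraction,
        "mean_coverage": spec.mean_coverage,
    }
    return records, truth


# ---------------------------------------------------------------------------
# reads and targets


def generate_reads(
    ref: ReferenceSequence,
    n_reads: int = 1000,
    read_len: int = 75,
    quality_decay: float = 0.3,
    rng: np.random.Generator | int | None = None,
    q_start: int = 38,
) -> list[ReadRecord]:
    """Simulate reads with a linearly declining 3' quality profile.

    ``quality_decay`` is in Phred units per base; 0 gives a flat profile.
    """
    if read_len > len(ref.bases):
        raise ValidationError("read_len exceeds genome length")
    rng = _as_rng(rng)
    starts = rng.integers(0, len(ref.bases) - read_len + 1, size=n_reads)
    ramp = q_start - quality_decay * np.arange(read_len)
    reads = []
    for k, s in enumerate(starts):
        bases = ref.bases[s : s + read_len].upper()
        noise = rng.normal(0.0, 2.0, size=read_len)
        quals = np.clip(np.rint(ramp + noise), 2, 40).astype(int)
        reads.append(ReadRecord(f"read{k}", bases, tuple(int(q) for q in quals)))
    return reads


def generate_targets(
    ref: ReferenceSequence,
    n_regions: int = 100,
    length_range: tuple[int, int] = (200, 2000),
    rng: np.random.Generator | int | None = None,
) -> list[TargetRegion]:
    """Random target regions within the reference bounds."""
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise ValidationError(f"bad length range {length_range}")
    if hi > len(ref.bases):
        raise ValidationError("region length exceeds genome length")
    rng = _as_rng(rng)
    regions = []
    for k in range(n_regions):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(ref.bases) - length + 1))
        regions.append(TargetRegion(ref.chrom, start, start + length, f"t{k}"))
    return regions


# ---------------------------------------------------------------------------
# one-call fixture set


def simulate_dataset(
    spec: SimulationSpec,
    outdir: str | Path,
    n_regions: int = 100,
    n_reads: int = 1000,
    read_len: int = 75,
    quality_decay: float = 0.3,
) -> dict:
    """Write a complete fixture set (FASTA, ratio table, targets, FASTQ,
    manifest) under ``outdir``; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    ref = generate_reference(spec, rng)
    io_formats.write_fasta([ref], outdir / "reference.fa")
    records, truth = generate_methyl_table(ref, spec, rng)
    io_formats.write_methyl_ratio_table(records, outdir / "ratios.tsv", coord_base=1)
    targets = generate_targets(ref, n_regions, rng=rng)
    io_formats.write_targets(targets, outdir / "targets.bed")
    reads = generate_reads(ref, n_reads, read_len, quality_decay, rng)
    io_formats.write_fastq(reads, outdir / "reads.fastq", "sanger")

    manifest = {
        "spec": asdict(spec),
        "ground_truth": truth,
        "files": {
            "reference": "reference.fa",
            "ratios": "ratios.tsv",
            "targets": "targets.bed",
            "reads": "reads.fastq",
        },
        "n_regions": n_regions,
        "n_reads": n_reads,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
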