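"""Orthogonal VAF quantification: deep amplicon sequencing and ddPCR.

Amplicon mode counts alternate alleles at a single targeted position from
ultra-deep sequencing (typical depth 10^5–10^6), either from precomputed
allele counts or directly from aligned reads; SNVs are counted per base call
(with a base-quality floor), indels by a deterministic CIGAR walk requiring
the exact inserted/deleted allele at the exact (left-aligned) position.
Uncertainty is an exact (Clopper–Pearson) binomial interval.

ddPCR mode uses the standard Poisson partitioning model: the mean number of
template copies per droplet in each channel is recovered from the fraction
of droplets negative in that channel, λ = −ln(n_neg/n_total), and the
mutant allele fraction is λ_mut / (λ_mut + λ_wt). A limit-of-detection rule
(default 0.5% VAF, established from gBlocks dilution series) converts the
estimate into a detected / not-detected call.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import beta

from .core import UNDEFINED, VariantClass, VariantKey, is_undefined, vaf

__all__ = [
    "TISSUES",
    "AmpliconMeasurement",
    "DropletCounts",
    "DdpcrResult",
    "clopper_pearson",
    "amplicon_vaf_snv",
    "amplicon_vaf_from_counts",
    "amplicon_vaf_indel",
    "count_snv_in_sam",
    "left_align_indel",
    "lambda_from_droplets",
    "lambda_ci_from_droplets",
    "ddpcr_vaf",
    "apply_lod",
    "lod_from_dilution",
    "read_amplicon_counts_tsv",
    "write_amplicon_tsv",
    "read_droplet_tsv",
    "write_ddpcr_tsv",
]

TISSUES = ("blood", "buccal", "saliva", "urine", "hair", "nail")

#: Default base-quality floor for amplicon base counting.
DEFAULT_QMIN = 20

#: Default limit of detection (fraction): 0.5% VAF.
DEFAULT_LOD = 0.005


@dataclass
class AmpliconMeasurement:
    """A deep-amplicon VAF estimate with its exact binomial interval."""

    key: Optional[VariantKey]
    tissue: str
    depth: int
    alt_count: int
    vaf: float
    ci_low: float
    ci_high: float
    mode: str  # "snv_count" | "indel_cigar"
    detected: bool
    sample: str = ""
    qc_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DropletCounts:
    """Per-well droplet counts by channel positivity."""

    n_mut_only: int
    n_wt_only: int
    n_double_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        for name in ("n_mut_only", "n_wt_only", "n_double_pos", "n_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_mut_only + self.n_wt_only + self.n_double_pos + self.n_neg


@dataclass
class DdpcrResult:
    """ddPCR Poisson quantification of the mutant allele fraction."""

    lambda_mut: float
    lambda_wt: float
    vaf: float
    ci_low: float
    ci_high: float
    detected: bool
    lod: float = DEFAULT_LOD
    sample: str = ""
    tissue: str = ""
    qc_flags: list[str] = field(default_factory=list)


def clopper_pearson(
    alt_count: int, depth: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for a fraction.

    Beta-quantile closed form: lower = B(a/2; k, n−k+1), upper =
    B(1−a/2; k+1, n−k); k = 0 pins the lower bound at 0 and k = n the upper
    bound at 1.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if alt_count < 0 or depth <= 0 or alt_count > depth:
        raise ValueError(f"invalid counts alt={alt_count}, depth={depth}")
    a = 1.0 - level
    lo = 0.0 if alt_count == 0 else float(beta.ppf(a / 2, alt_count, depth - alt_count + 1))
    hi = (
        1.0
        if alt_count == depth
        else float(beta.ppf(1 - a / 2, alt_count + 1, depth - alt_count))
    )
    return lo, hi


def apply_lod(vaf_estimate: float, lod: float = DEFAULT_LOD) -> bool:
    """Detection call: detected iff the VAF estimate is at or above the LoD."""
    if is_undefined(vaf_estimate):
        raise ValueError("vaf must be defined for a detection call")
    return vaf_estimate >= lod


def amplicon_vaf_from_counts(
    alt_count: int,
    depth: int,
    key: Optional[VariantKey] = None,
    tissue: str = "blood",
    mode: str = "snv_count",
    level: float = 0.95,
    lod: float = DEFAULT_LOD,
    sample: str = "",
) -> AmpliconMeasurement:
    """Build a measurement from precomputed allele counts."""
    if depth <= 0:
        return AmpliconMeasurement(
            key=key,
            tissue=tissue,
            depth=0,
            alt_count=0,
            vaf=UNDEFINED,
            ci_low=UNDEFINED,
            ci_high=UNDEFINED,
            mode=mode,
            detected=False,
            sample=sample,
            qc_flags=["insufficient_depth"],
        )
    v = vaf(alt_count, depth)
    lo, hi = clopper_pearson(alt_count, depth, level)
    return AmpliconMeasurement(
        key=key,
        tissue=tissue,
        depth=depth,
        alt_count=alt_count,
        vaf=v,
        ci_low=lo,
        ci_high=hi,
        mode=mode,
        detected=apply_lod(v, lod),
        sample=sample,
    )


def amplicon_vaf_snv(
    base_calls: Iterable[tuple[str, int]],
    key: VariantKey,
    qmin: int = DEFAULT_QMIN,
    tissue: str = "blood",
    level: float = 0.95,
    lod: float = DEFAULT_LOD,
    sample: str = "",
) -> AmpliconMeasurement:
    """Count an SNV from per-read (base, quality) calls at the target position.

    Bases with quality below ``qmin`` are discarded before counting; depth is
    the number of retained calls.
    """
    if key.variant_class is not VariantClass.SNV:
        raise ValueError("amplicon_vaf_snv requires an SNV key")
    depth = 0
    alt = 0
    for base, qual in base_calls:
        if qual < qmin:
            continue
        depth += 1
        if base.upper() == key.alt.upper():
            alt += 1
    return amplicon_vaf_from_counts(
        alt, depth, key=key, tissue=tissue, mode="snv_count", level=level,
        lod=lod, sample=sample,
    )


# ---------------------------------------------------------------------------
# Aligned-read counting (SAM input via pysam)
# ---------------------------------------------------------------------------


def left_align_indel(
    pos: int, ref: str, alt: str, ref_seq: str, seq_start: int = 1
) -> tuple[int, str, str]:
    """Left-align a VCF-style indel against a reference sequence segment.

    ``ref_seq`` covers the locus starting at 1-based position ``seq_start``.
    The indel (shared leading base convention: e.g. ref ``T`` / alt ``TT``) is
    shifted left while the flanking reference base allows an equivalent
    representation. SNVs are returned unchanged.
    """
    if len(ref) == len(alt):
        return pos, ref, alt
    # indel body = alleles minus the shared anchor base
    long_a, short_a = (alt, ref) if len(alt) > len(ref) else (ref, alt)
    if not long_a.startswith(short_a):
        return pos, ref, alt  # complex allele: leave untouched
    body = long_a[len(short_a):]
    # shifting the event one base left is sequence-preserving iff the last
    # base of the indel body equals the current anchor base
    while pos > seq_start:
        anchor = ref_seq[pos - seq_start]  # base at pos (1-based)
        if body[-1].upper() != anchor.upper():
            break
        body = anchor.upper() + body[:-1]
        pos -= 1
    anchor = ref_seq[pos - seq_start].upper()
    if len(alt) > len(ref):
        return pos, anchor, anchor + body
    return pos, anchor + body, anchor


def _read_indel_events(read) -> list[tuple[int, str, int]]:
    """Extract indels from a pysam AlignedSegment as (1-based anchor pos,
    inserted sequence or '', deleted length)."""
    events = []
    ref_pos = read.reference_start  # 0-based
    query_pos = 0
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            ref_pos += length
            query_pos += length
        elif op == 1:  # I: insertion after ref_pos-1 (anchor = last ref base)
            events.append((ref_pos, read.query_sequence[query_pos : query_pos + length], 0))
            query_pos += length
        elif op == 2:  # D: deletion of ref bases starting at ref_pos
            events.append((ref_pos, "", length))
            ref_pos += length
        elif op == 4:  # S
            query_pos += length
        elif op == 3:  # N
            ref_pos += length
        # H, P consume nothing relevant
    return events


def amplicon_vaf_indel(
    reads,
    key: VariantKey,
    flank: int = 5,
    tissue: str = "blood",
    level: float = 0.95,
    lod: float = DEFAULT_LOD,
    sample: str = "",
    ref_seq: Optional[str] = None,
    ref_seq_start: int = 1,
) -> AmpliconMeasurement:
    """Count an insertion/deletion allele by walking read alignments.

    A read counts as alternate iff its alignment contains the exact indel
    (same inserted sequence, or same deleted length) anchored at the target
    position after left-alignment; depth counts reads that fully span the
    locus ± ``flank`` bases. Non-spanning reads are excluded from depth and
    tallied in a QC flag.

    ``reads`` is an iterable of ``pysam.AlignedSegment`` (e.g. from a SAM
    file opened with ``pysam.AlignmentFile``). When ``ref_seq`` is given the
    variant key is left-aligned against it first.
    """
    if key.variant_class is VariantClass.SNV:
        raise ValueError("amplicon_vaf_indel requires an indel key")
    pos, ref, alt = key.pos, key.ref, key.alt
    if ref_seq is not None:
        pos, ref, alt = left_align_indel(pos, ref, alt, ref_seq, ref_seq_start)
    inserting = len(alt) > len(ref)
    body = (alt if inserting else ref)[1:]
    # anchor position of the event in 0-based reference coords: the indel
    # sits immediately after `pos` (VCF shared-leading-base convention)
    event_ref_pos0 = pos  # insertion after base at pos -> first affected ref index
    span_lo = pos - flank  # 1-based
    span_hi = pos + len(ref) - 1 + flank

    depth = 0
    alt_count = 0
    n_nonspanning = 0
    for read in reads:
        if read.is_unmapped or read.cigartuples is None:
            n_nonspanning += 1
            continue
        if read.reference_name != key.chrom:
            n_nonspanning += 1
            continue
        # reference_start is 0-based; reference_end is one past the last base
        if read.reference_start > span_lo - 1 or (read.reference_end or 0) < span_hi:
            n_nonspanning += 1
            continue
        depth += 1
        for ev_pos, ins_seq, del_len in _read_indel_events(read):
            if ev_pos != event_ref_pos0:
                continue
            if inserting and del_len == 0 and ins_seq.upper() == body.upper():
                alt_count += 1
                break
            if not inserting and del_len == len(body) and not ins_seq:
                alt_count += 1
                break

    m = amplicon_vaf_from_counts(
        alt_count, depth, key=key, tissue=tissue, mode="indel_cigar",
        level=level, lod=lod, sample=sample,
    )
    if n_nonspanning:
        m.qc_flags.append(f"nonspanning_reads={n_nonspanning}")
    return m


def count_snv_in_sam(
    reads,
    key: VariantKey,
    qmin: int = DEFAULT_QMIN,
) -> tuple[int, int]:
    """Count (alt, depth) for an SNV from pysam aligned reads.

    Depth counts quality-passing base calls aligned to the target position.
    """
    if key.variant_class is not VariantClass.SNV:
        raise ValueError("count_snv_in_sam requires an SNV key")
    target0 = key.pos - 1
    depth = 0
    alt = 0
    for read in reads:
        if read.is_unmapped or read.reference_name != key.chrom:
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos == target0:
                qual = read.query_qualities[qpos] if read.query_qualities is not None else 60
                if qual < qmin:
                    break
                depth += 1
                if read.query_sequence[qpos].upper() == key.alt.upper():
                    alt += 1
                break
    return alt, depth


# ---------------------------------------------------------------------------
# ddPCR Poisson quantification
# ---------------------------------------------------------------------------


def lambda_from_droplets(n_neg_channel: int, n_total: int) -> float:
    """Mean template copies per droplet from the negative-droplet fraction.

    λ = −ln(n_neg/n_total). All droplets negative gives λ = 0; no negative
    droplets means the assay is saturated and λ is not estimable.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_neg_channel <= n_total:
        raise ValueError("n_neg_channel must be in [0, n_total]")
    if n_neg_channel == 0:
        raise ValueError("saturated assay: no negative droplets, λ not estimable")
    return -math.log(n_neg_channel / n_total)


def lambda_ci_from_droplets(
    n_neg_channel: int, n_total: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact CI for λ via the Clopper–Pearson interval on the negative
    fraction, transformed through λ = −ln p (monotone decreasing)."""
    p_lo, p_hi = clopper_pearson(n_neg_channel, n_total, level)
    lo = -math.log(p_hi) if p_hi > 0 else math.inf
    hi = -math.log(p_lo) if p_lo > 0 else math.inf
    return lo, hi


def ddpcr_vaf(
    d: DropletCounts,
    lod: float = DEFAULT_LOD,
    level: float = 0.95,
    sample: str = "",
    tissue: str = "",
) -> DdpcrResult:
    """Mutant allele fraction from droplet counts under Poisson partitioning.

    λ_mut is estimated from droplets negative in the mutant channel
    (wt-only + double-negative), λ_wt from droplets negative in the wildtype
    channel; vaf = λ_mut / (λ_mut + λ_wt). The interval propagates the exact
    per-channel λ intervals conservatively:
    [λm_lo/(λm_lo+λw_hi), λm_hi/(λm_hi+λw_lo)].
    """
    n = d.n_total
    if n == 0:
        raise ValueError("no droplets")
    neg_mut_channel = d.n_wt_only + d.n_neg
    neg_wt_channel = d.n_mut_only + d.n_neg
    qc: list[str] = []
    if neg_mut_channel == 0 or neg_wt_channel == 0:
        raise ValueError("saturated assay: a channel has no negative droplets")
    lam_m = lambda_from_droplets(neg_mut_channel, n)
    lam_w = lambda_from_droplets(neg_wt_channel, n)

    if lam_m + lam_w == 0.0:
        return DdpcrResult(
            lambda_mut=0.0,
            lambda_wt=0.0,
            vaf=UNDEFINED,
            ci_low=UNDEFINED,
            ci_high=UNDEFINED,
            detected=False,
            lod=lod,
            sample=sample,
            tissue=tissue,
            qc_flags=["no_template"],
        )

    v = lam_m / (lam_m + lam_w)
    m_lo, m_hi = lambda_ci_from_droplets(neg_mut_channel, n, level)
    w_lo, w_hi = lambda_ci_from_droplets(neg_wt_channel, n, level)
    ci_low = m_lo / (m_lo + w_hi) if (m_lo + w_hi) > 0 else 0.0
    ci_high = m_hi / (m_hi + w_lo) if (m_hi + w_lo) > 0 else 1.0
    return DdpcrResult(
        lambda_mut=lam_m,
        lambda_wt=lam_w,
        vaf=v,
        ci_low=ci_low,
        ci_high=ci_high,
        detected=apply_lod(v, lod),
        lod=lod,
        sample=sample,
        tissue=tissue,
        qc_flags=qc,
    )


def lod_from_dilution(
    series: Sequence[tuple[float, Sequence[bool]]],
) -> Optional[float]:
    """Limit of detection from a dilution series.

    ``series`` pairs each expected VAF (strictly decreasing) with the
    per-replicate detection flags at that level. The LoD is the smallest
    expected VAF in the top-down run of levels where every replicate is
    detected; ``None`` (undefined) if no level is fully detected.
    """
    if not series:
        raise ValueError("empty dilution series")
    vafs = [v for v, _ in series]
    if any(b >= a for a, b in zip(vafs, vafs[1:])):
        raise ValueError("expected_vaf must be strictly decreasing")
    lod = None
    for v, flags in series:
        if len(flags) > 0 and all(flags):
            lod = v
        else:
            break
    return lod


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_amplicon_counts_tsv(path: str | Path) -> list[dict]:
    """Read an amplicon allele-count table.

    Columns: sample, tissue, chrom, pos, ref, alt, alt_count, depth.
    """
    rows = []
    with open(path) as fh:
        lines = [line for line in fh if not line.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        rows.append(
            {
                "sample": row["sample"],
                "tissue": row["tissue"],
                "key": VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                "alt_count": int(row["alt_count"]),
                "depth": int(row["depth"]),
            }
        )
    return rows


def write_amplicon_tsv(measurements: Iterable[AmpliconMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "sample",
                "tissue",
                "chrom",
                "pos",
                "ref",
                "alt",
                "mode",
                "alt_count",
                "depth",
                "vaf_pct",
                "ci_low_pct",
                "ci_high_pct",
                "detected",
                "qc_flags",
            ]
        )
        for m in measurements:

            def pct(x: float) -> str:
                return "NA" if is_undefined(x) else f"{100 * x:.4g}"

            w.writerow(
                [
                    m.sample,
                    m.tissue,
                    m.key.chrom if m.key else "",
                    m.key.pos if m.key else "",
                    m.key.ref if m.key else "",
                    m.key.alt if m.key else "",
                    m.mode,
                    m.alt_count,
                    m.depth,
                    pct(m.vaf),
                    pct(m.ci_low),
                    pct(m.ci_high),
                    "detected" if m.detected else "ND",
                    ";".join(m.qc_flags),
                ]
            )


def read_droplet_tsv(path: str | Path) -> list[dict]:
    """Read per-well droplet counts.

    Columns: sample, tissue, well_type (sample|positive|negative|ntc),
    n_mut_only, n_wt_only, n_double_pos, n_neg.
    """
    rows = []
    with open(path) as fh:
        lines = [line for line in fh if not line.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        rows.append(
            {
                "sample": row["sample"],
                "tissue": row.get("tissue", ""),
                "well_type": row.get("well_type", "sample"),
                "counts": DropletCounts(
                    n_mut_only=int(row["n_mut_only"]),
                    n_wt_only=int(row["n_wt_only"]),
                    n_double_pos=int(row["n_double_pos"]),
                    n_neg=int(row["n_neg"]),
                ),
            }
        )
    return rows


def write_ddpcr_tsv(results: Iterable[DdpcrResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "sample",
                "tissue",
                "lambda_mut",
                "lambda_wt",
                "vaf_pct",
                "ci_low_pct",
                "ci_high_pct",
                "detected",
                "lod_pct",
                "qc_flags",
            ]
        )
        for r in results:

            def pct(x: float) -> str:
                return "NA" if is_undefined(x) else f"{100 * x:.4g}"

            w.writerow(
                [
                    r.sample,
                    r.tissue,
                    f"{r.lambda_mut:.6g}",
                    f"{r.lambda_wt:.6g}",
                    pct(r.vaf),
                    pct(r.ci_low),
                    pct(r.ci_high),
                    "detected" if r.detected else "ND",
                    f"{100 * r.lod:.4g}",
                    ";".join(r.qc_flags),
                ]
            )
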