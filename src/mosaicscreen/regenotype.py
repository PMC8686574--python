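"""Parental pileup re-genotyping and low-level mosaicism classification.

At each candidate site the parent's exome pileup is reduced to an alternate
allele fraction, and the parent is classified:

* ``candidate_mosaic`` — fraction below the 10% mosaic cutoff, with at least
  ``min_parental_alt_reads`` alternate reads and a one-sided exact binomial
  test rejecting sequencing error (P(X >= alt | depth, err) < alpha);
* ``absent`` — fraction below the cutoff but alternate evidence explainable
  by sequencing error (or fewer than the minimum alternate reads);
* ``ambiguous`` — fraction in [10%, 30%): too high for the mosaic screen, too
  low for a credible constitutional heterozygote; reported for review, never
  dropped (this band replaces the manual IGV screen);
* ``constitutional_het`` — fraction at or above 30% (fractions above 70% keep
  this status with a QC flag so that the status ordering is monotone in the
  alternate read count).
"""

from __future__ import annotations

import csv
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

from scipy.stats import binom

from .core import (
    PileupCounts,
    ScreenConfig,
    VariantKey,
    is_undefined,
    vaf,
)

__all__ = [
    "MosaicStatus",
    "MosaicClassification",
    "parental_alt_fraction",
    "binomial_error_test",
    "classify_parent",
    "classify_counts",
    "cohort_flag_rate",
    "read_pileup_tsv",
    "write_classifications_tsv",
]


class MosaicStatus(str, Enum):
    CANDIDATE_MOSAIC = "candidate_mosaic"
    ABSENT = "absent"
    CONSTITUTIONAL_HET = "constitutional_het"
    AMBIGUOUS = "ambiguous"


@dataclass
class MosaicClassification:
    """Parental status at one candidate site with supporting statistics."""

    key: Optional[VariantKey]
    parent: str  # "mother" | "father"
    alt_fraction: float
    alt_count: int
    depth: int
    error_p: float
    status: MosaicStatus
    trio_id: str = ""
    qc_flags: list[str] = field(default_factory=list)


def parental_alt_fraction(p: PileupCounts) -> tuple[float, int, int]:
    """Alternate allele fraction from stranded pileup counts.

    Returns ``(fraction, alt_count, depth)``; zero depth yields an undefined
    (NaN) fraction. Strand counts stay available on the input for QC.
    """
    depth = p.depth()
    alt = p.alt_count()
    return vaf(alt, depth), alt, depth


def binomial_error_test(alt_count: int, depth: int, err: float) -> float:
    """One-sided upper-tail exact binomial p-value against sequencing error.

    ``p = P(X >= alt_count | n=depth, p=err)``. With ``alt_count == 0`` the
    tail is the whole distribution, so p = 1.
    """
    if not 0.0 < err < 1.0:
        raise ValueError(f"err must be in (0, 1), got {err}")
    if alt_count < 0 or depth < 0 or alt_count > depth:
        raise ValueError(f"invalid counts alt={alt_count}, depth={depth}")
    if alt_count == 0:
        return 1.0
    return float(binom.sf(alt_count - 1, depth, err))


def classify_parent(
    p: PileupCounts,
    cfg: Optional[ScreenConfig] = None,
    key: Optional[VariantKey] = None,
    parent: str = "",
    trio_id: str = "",
) -> MosaicClassification:
    """Classify one parent at one candidate site from its pileup counts."""
    cfg = cfg or ScreenConfig()
    fraction, alt, depth = parental_alt_fraction(p)
    error_p = binomial_error_test(alt, depth, cfg.seq_error_rate) if depth > 0 else 1.0
    qc: list[str] = []

    if is_undefined(fraction):
        status = MosaicStatus.AMBIGUOUS
        qc.append("zero_depth")
    elif fraction < cfg.parental_mosaic_max_vaf:
        if alt >= cfg.min_parental_alt_reads and error_p < cfg.alpha:
            status = MosaicStatus.CANDIDATE_MOSAIC
        else:
            status = MosaicStatus.ABSENT
    elif fraction < cfg.het_vaf_low:
        status = MosaicStatus.AMBIGUOUS
    else:
        status = MosaicStatus.CONSTITUTIONAL_HET
        if fraction > cfg.het_vaf_high:
            qc.append("above_het_window")

    return MosaicClassification(
        key=key,
        parent=parent,
        alt_fraction=fraction,
        alt_count=alt,
        depth=depth,
        error_p=error_p,
        status=status,
        trio_id=trio_id,
        qc_flags=qc,
    )


def classify_counts(alt: int, depth: int, cfg: Optional[ScreenConfig] = None) -> MosaicStatus:
    """Classify from bare (alt, depth) counts; convenience wrapper."""
    return classify_parent(PileupCounts(alt_fwd=alt, ref_fwd=depth - alt), cfg).status


def cohort_flag_rate(
    classifications: Iterable[MosaicClassification],
    n_trios: Optional[int] = None,
) -> tuple[int, float]:
    """Cohort-level flagged-trio count and rate.

    A trio is flagged when at least one parent carries at least one
    ``candidate_mosaic`` call. ``n_trios`` defaults to the number of distinct
    trio ids seen; an empty cohort yields ``(0, nan)``.
    """
    by_trio: dict[str, bool] = defaultdict(bool)
    for c in classifications:
        by_trio[c.trio_id] |= c.status is MosaicStatus.CANDIDATE_MOSAIC
    if n_trios is None:
        n_trios = len(by_trio)
    n_flagged = sum(by_trio.values())
    rate = n_flagged / n_trios if n_trios else math.nan
    return n_flagged, rate


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PILEUP_COLS = [
    "trio_id",
    "parent",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_fwd",
    "ref_rev",
    "alt_fwd",
    "alt_rev",
    "other",
]


def read_pileup_tsv(
    path: str | Path,
) -> dict[tuple[str, str, VariantKey], PileupCounts]:
    """Read per-parent pileup allele counts.

    Columns: trio_id, parent, chrom, pos, ref, alt, ref_fwd, ref_rev,
    alt_fwd, alt_rev, other. Keyed by (trio_id, parent, variant).
    """
    out: dict[tuple[str, str, VariantKey], PileupCounts] = {}
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        out[(row["trio_id"], row["parent"], key)] = PileupCounts(
            ref_fwd=int(row["ref_fwd"]),
            ref_rev=int(row["ref_rev"]),
            alt_fwd=int(row["alt_fwd"]),
            alt_rev=int(row["alt_rev"]),
            other=int(row.get("other", 0) or 0),
        )
    return out


def write_pileup_tsv(
    pileups: Mapping[tuple[str, str, VariantKey], PileupCounts], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PILEUP_COLS)
        for (trio_id, parent, key), p in pileups.items():
            w.writerow(
                [
                    trio_id,
                    parent,
                    key.chrom,
                    key.pos,
                    key.ref,
                    key.alt,
                    p.ref_fwd,
                    p.ref_rev,
                    p.alt_fwd,
                    p.alt_rev,
                    p.other,
                ]
            )


def write_classifications_tsv(
    classifications: Iterable[MosaicClassification],
    path: str | Path,
    summary_path: Optional[str | Path] = None,
    n_trios: Optional[int] = None,
) -> None:
    """Write classifications TSV and, optionally, a cohort summary JSON."""
    classifications = list(classifications)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "trio_id",
                "parent",
                "chrom",
                "pos",
                "ref",
                "alt",
                "alt_count",
                "depth",
                "alt_fraction",
                "error_p",
                "status",
                "qc_flags",
            ]
        )
        for c in classifications:
            w.writerow(
                [
                    c.trio_id,
                    c.parent,
                    c.key.chrom if c.key else "",
                    c.key.pos if c.key else "",
                    c.key.ref if c.key else "",
                    c.key.alt if c.key else "",
                    c.alt_count,
                    c.depth,
                    f"{c.alt_fraction:.6g}",
                    f"{c.error_p:.4g}",
                    c.status.value,
                    ";".join(c.qc_flags),
                ]
            )
    if summary_path is not None:
        n_flagged, rate = cohort_flag_rate(classifications, n_trios)
        n = n_trios if n_trios is not None else len({c.trio_id for c in classifications})
        with open(summary_path, "w") as fh:
            json.dump(
                {"n_trios": n, "n_flagged": n_flagged, "flag_rate": rate},
                fh,
                indent=2,
            )
            fh.write("\n")
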