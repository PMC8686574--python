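"""Domain types and elementary variant-allele-fraction arithmetic.

Conventions used throughout the package:

* All allele fractions are held internally on the [0, 1] scale; percentages
  appear only at I/O boundaries (see :func:`as_percent` / :func:`from_percent`).
* Genomic coordinates are 1-based inclusive (VCF convention). BED inputs are
  0-based half-open and converted on read.
* An allele fraction computed at zero depth is *undefined*, represented as
  ``math.nan`` — never 0 — so that missing evidence is distinguishable from
  observed absence and propagates as a QC flag rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional

__all__ = [
    "VariantClass",
    "Genotype",
    "VariantKey",
    "SampleCall",
    "TrioSiteCall",
    "PileupCounts",
    "PopulationFrequencies",
    "ScreenConfig",
    "vaf",
    "as_percent",
    "from_percent",
    "is_undefined",
    "UNDEFINED",
]

#: Distinguished "undefined" fraction returned when depth is zero.
UNDEFINED: float = math.nan


def is_undefined(x: float) -> bool:
    """True if ``x`` is the undefined-fraction sentinel (NaN)."""
    return isinstance(x, float) and math.isnan(x)


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class Genotype(str, Enum):
    """Genotype call taken from the input VCF (no likelihood model here)."""

    REF_HOM = "ref_hom"
    HET = "het"
    HEMI = "hemi"
    ALT_HOM = "alt_hom"
    MISSING = "missing"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a candidate variant (1-based, VCF-style alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.alt) > len(self.ref):
            return VariantClass.INSERTION
        return VariantClass.DELETION

    def __str__(self) -> str:  # chrom:pos:ref>alt, used in TSV output
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def vaf(alt_count: int, depth: int) -> float:
    """Variant allele fraction ``alt_count / depth``.

    Returns :data:`UNDEFINED` (NaN) when ``depth == 0`` so downstream code can
    flag, rather than silently score, sites without coverage.

    Raises
    ------
    ValueError
        If counts are negative or ``alt_count > depth``.
    """
    if alt_count < 0 or depth < 0:
        raise ValueError(f"counts must be non-negative: alt={alt_count}, depth={depth}")
    if alt_count > depth:
        raise ValueError(f"alt_count {alt_count} exceeds depth {depth}")
    if depth == 0:
        return UNDEFINED
    return alt_count / depth


def as_percent(fraction: float) -> float:
    """Convert a fraction in [0, 1] to a percentage in [0, 100]."""
    if is_undefined(fraction):
        return UNDEFINED
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction out of [0, 1]: {fraction}")
    return fraction * 100.0


def from_percent(percentage: float) -> float:
    """Convert a percentage in [0, 100] to a fraction in [0, 1]."""
    if is_undefined(percentage):
        return UNDEFINED
    if not 0.0 <= percentage <= 100.0:
        raise ValueError(f"percentage out of [0, 100]: {percentage}")
    return percentage / 100.0


@dataclass(frozen=True)
class SampleCall:
    """Genotype call with read support for one trio member at one site."""

    genotype: Genotype
    depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_depth < 0:
            raise ValueError("depth and alt_depth must be >= 0")
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth}"
            )

    @property
    def vaf(self) -> float:
        return vaf(self.alt_depth, self.depth)


@dataclass(frozen=True)
class TrioSiteCall:
    """Per-trio genotypes, depths and allele depths at one candidate site."""

    key: VariantKey
    proband: SampleCall
    mother: SampleCall
    father: SampleCall
    trio_id: str = ""
    annotation: str = ""  # pass-through (e.g. ACMG class); never computed here

    @property
    def proband_vaf(self) -> float:
        return self.proband.vaf

    def members(self) -> dict[str, SampleCall]:
        return {"proband": self.proband, "mother": self.mother, "father": self.father}


@dataclass(frozen=True)
class PileupCounts:
    """Stranded ref/alt/other allele counts at one site for one sample."""

    ref_fwd: int = 0
    ref_rev: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    other: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def depth(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev + self.other

    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    def ref_count(self) -> int:
        return self.ref_fwd + self.ref_rev


@dataclass(frozen=True)
class PopulationFrequencies:
    """Population allele frequencies used for rarity filtering.

    ``None`` means the allele is absent from the resource; for filtering an
    absent allele is treated as frequency 0 (an unobserved allele is rare),
    but the distinction is preserved for reporting.
    """

    gnomad_af: Optional[float] = None
    internal_af: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("gnomad_af", "internal_af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")


@dataclass
class ScreenConfig:
    """Thresholds of the apparent-de-novo screen and parental re-genotyping.

    Defaults encode the clinical screening cascade: heterozygous proband VAF
    window 30–70%, trio read depth >= 20x, GnomAD AF < 0.01%, internal cohort
    AF < 0.015%, parental mosaic alternate fraction < 10%, with a one-sided
    exact binomial test against the sequencing error rate guarding the mosaic
    call.
    """

    het_vaf_low: float = 0.30
    het_vaf_high: float = 0.70
    min_depth: int = 20
    max_gnomad_af: float = 1e-4
    max_internal_af: float = 1.5e-4
    parental_mosaic_max_vaf: float = 0.10
    min_parental_alt_reads: int = 2
    seq_error_rate: float = 0.005
    alpha: float = 0.05
    hemi_vaf_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.het_vaf_low < self.het_vaf_high < 1.0:
            raise ValueError("require 0 < het_vaf_low < het_vaf_high < 1")
        if not self.parental_mosaic_max_vaf < self.het_vaf_low:
            raise ValueError("parental_mosaic_max_vaf must be < het_vaf_low")
        if self.min_depth < 0 or self.min_parental_alt_reads < 0:
            raise ValueError("count thresholds must be >= 0")
        if not 0.0 < self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
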