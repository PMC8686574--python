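"""Apparent-de-novo candidate screening of trio exome calls.

The cascade selects proband variants that look de novo (het/hemi in the
proband, hom-ref in both parents), sit inside the credible heterozygous VAF
window, are well covered, are rare in population resources, and fall outside
repetitive/pseudogene region masks. Each input record receives an auditable
:class:`ScreenDecision` listing every filter it failed; a record passes the
screen iff that list is empty. Passed records form the candidate set handed
to parental pileup re-genotyping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Optional

from intervaltree import IntervalTree

from .core import (
    Genotype,
    PopulationFrequencies,
    SampleCall,
    ScreenConfig,
    TrioSiteCall,
    VariantKey,
    is_undefined,
)

log = logging.getLogger(__name__)

__all__ = [
    "RegionMask",
    "ScreenDecision",
    "is_apparent_denovo",
    "passes_het_window",
    "passes_depth",
    "passes_popfreq",
    "passes_region_mask",
    "screen_trios",
    "read_trio_vcf",
    "read_freq_table",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "FILTER_DENOVO",
    "FILTER_HET_WINDOW",
    "FILTER_DEPTH",
    "FILTER_GNOMAD",
    "FILTER_INTERNAL_AF",
    "FILTER_REGION_MASK",
    "FILTER_INCOMPLETE_TRIO",
]

# Filter identifiers recorded in ScreenDecision.failed_filters.
FILTER_DENOVO = "denovo"
FILTER_HET_WINDOW = "het_window"
FILTER_DEPTH = "depth"
FILTER_GNOMAD = "gnomad"
FILTER_INTERNAL_AF = "internal_af"
FILTER_REGION_MASK = "region_mask"
FILTER_INCOMPLETE_TRIO = "incomplete_trio"


class RegionMask:
    """Repetitive/pseudogene interval mask with O(log n) point queries.

    Intervals are stored 0-based half-open (BED convention); queries take the
    1-based VCF position of a variant.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, label: str = "repetitive") -> None:
        if start >= end:
            raise ValueError(f"interval start {start} must be < end {end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True if the 1-based position overlaps any mask interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlaps(pos_1based - 1))

    @classmethod
    def from_bed(cls, path: str | Path, label: Optional[str] = None) -> "RegionMask":
        """Read a BED file (0-based half-open); column 4, if present, labels
        the interval (e.g. ``repetitive`` or ``pseudogene``)."""
        mask = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                name = label or (parts[3] if len(parts) > 3 else "repetitive")
                mask.add(parts[0], int(parts[1]), int(parts[2]), name)
        return mask


@dataclass
class ScreenDecision:
    """Audit-trail outcome of the cascade for one candidate record."""

    key: VariantKey
    failed_filters: list[str] = field(default_factory=list)
    trio_id: str = ""
    proband_vaf: float = float("nan")
    record: Optional[TrioSiteCall] = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_filters


def is_apparent_denovo(trio: TrioSiteCall) -> tuple[bool, Optional[str]]:
    """Whether the proband call looks de novo against hom-ref parents.

    Returns ``(flag, qc_flag)``; a missing parental genotype yields
    ``(False, "incomplete_trio")`` — never a pass.
    """
    if (
        trio.mother.genotype is Genotype.MISSING
        or trio.father.genotype is Genotype.MISSING
        or trio.proband.genotype is Genotype.MISSING
    ):
        return False, FILTER_INCOMPLETE_TRIO
    proband_ok = trio.proband.genotype in (Genotype.HET, Genotype.HEMI)
    parents_ref = (
        trio.mother.genotype is Genotype.REF_HOM
        and trio.father.genotype is Genotype.REF_HOM
    )
    return proband_ok and parents_ref, None


def passes_het_window(vaf: float, cfg: ScreenConfig, hemizygous: bool = False) -> bool:
    """Credible-genotype VAF window: inclusive 30–70% for het calls;
    hemizygous calls instead require VAF >= ``hemi_vaf_min``.

    An undefined VAF (zero depth) fails.
    """
    if is_undefined(vaf):
        return False
    if hemizygous:
        return vaf >= cfg.hemi_vaf_min
    return cfg.het_vaf_low <= vaf <= cfg.het_vaf_high


def passes_depth(depth: int, cfg: ScreenConfig) -> bool:
    """Minimum exome coverage: depth >= 20x passes (20 itself is kept)."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return depth >= cfg.min_depth


def passes_popfreq(freqs: PopulationFrequencies, cfg: ScreenConfig) -> tuple[bool, bool]:
    """Rarity filters, strict: GnomAD AF < 0.01% and internal AF < 0.015%.

    Absent frequencies are treated as 0 (unobserved alleles pass). Returns
    ``(gnomad_ok, internal_ok)`` so failures are attributable.
    """
    g = freqs.gnomad_af if freqs.gnomad_af is not None else 0.0
    i = freqs.internal_af if freqs.internal_af is not None else 0.0
    return g < cfg.max_gnomad_af, i < cfg.max_internal_af


def passes_region_mask(key: VariantKey, mask: Optional[RegionMask]) -> bool:
    """True iff the position overlaps no repetitive/pseudogene interval."""
    if mask is None or len(mask) == 0:
        return True
    return not mask.contains(key.chrom, key.pos)


FreqLookup = Callable[[VariantKey], PopulationFrequencies]


def _as_lookup(
    freqs: Mapping[VariantKey, PopulationFrequencies] | FreqLookup | None,
) -> FreqLookup:
    if freqs is None:
        return lambda key: PopulationFrequencies()
    if callable(freqs):
        return freqs
    return lambda key: freqs.get(key, PopulationFrequencies())


def screen_trio(
    trio: TrioSiteCall,
    freqs: PopulationFrequencies,
    mask: Optional[RegionMask],
    cfg: ScreenConfig,
) -> ScreenDecision:
    """Apply all cascade predicates to a single trio record."""
    decision = ScreenDecision(
        key=trio.key,
        trio_id=trio.trio_id,
        proband_vaf=trio.proband_vaf,
        record=trio,
    )
    denovo, qc = is_apparent_denovo(trio)
    if qc is not None:
        decision.qc_flags.append(qc)
    if not denovo:
        decision.failed_filters.append(FILTER_DENOVO)

    hemi = trio.proband.genotype is Genotype.HEMI
    pvaf = trio.proband_vaf
    if is_undefined(pvaf):
        decision.qc_flags.append("undefined_vaf")
    if not passes_het_window(pvaf, cfg, hemizygous=hemi):
        decision.failed_filters.append(FILTER_HET_WINDOW)

    # coverage must be adequate in every trio member: the proband call and
    # both parental re-genotyping samples all rely on it
    min_member_depth = min(
        trio.proband.depth, trio.mother.depth, trio.father.depth
    )
    if not passes_depth(min_member_depth, cfg):
        decision.failed_filters.append(FILTER_DEPTH)

    gnomad_ok, internal_ok = passes_popfreq(freqs, cfg)
    if not gnomad_ok:
        decision.failed_filters.append(FILTER_GNOMAD)
    if not internal_ok:
        decision.failed_filters.append(FILTER_INTERNAL_AF)

    if not passes_region_mask(trio.key, mask):
        decision.failed_filters.append(FILTER_REGION_MASK)
    return decision


def screen_trios(
    records: Iterable[TrioSiteCall],
    freqs: Mapping[VariantKey, PopulationFrequencies] | FreqLookup | None = None,
    mask: Optional[RegionMask] = None,
    cfg: Optional[ScreenConfig] = None,
) -> list[ScreenDecision]:
    """Run the full cascade over a stream of trio records.

    Emits one decision per input record; malformed records yield a failing
    decision with a QC flag and processing continues.
    """
    cfg = cfg or ScreenConfig()
    lookup = _as_lookup(freqs)
    decisions: list[ScreenDecision] = []
    for trio in records:
        try:
            decisions.append(screen_trio(trio, lookup(trio.key), mask, cfg))
        except (ValueError, TypeError) as exc:  # malformed record: keep going
            log.warning("malformed record %s: %s", getattr(trio, "key", "?"), exc)
            d = ScreenDecision(key=trio.key, trio_id=getattr(trio, "trio_id", ""))
            d.failed_filters.append("malformed_record")
            d.qc_flags.append(str(exc))
            decisions.append(d)
    return decisions


# ---------------------------------------------------------------------------
# I/O: trio VCF, allele-frequency TSV, candidates TSV
# ---------------------------------------------------------------------------

_PLOIDY1 = {(0,): Genotype.REF_HOM, (1,): Genotype.HEMI}


def _genotype_for_alt(alleles: tuple[int, ...], alt_index: int) -> Genotype:
    """Map a VCF genotype tuple to a call with respect to one alt allele.

    ``alt_index`` is the 1-based ALT allele number. Hemizygous = single-allele
    genotype carrying the alt. Genotypes involving other alt alleles count as
    non-ref but not het for this alt.
    """
    if any(a is None or a < 0 for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        return Genotype.HEMI if n_alt == 1 else (
            Genotype.REF_HOM if alleles[0] == 0 else Genotype.MISSING
        )
    if n_alt == len(alleles):
        return Genotype.ALT_HOM
    if n_alt > 0:
        return Genotype.HET
    if all(a == 0 for a in alleles):
        return Genotype.REF_HOM
    # carries a different alt allele: not ref-hom for de novo purposes
    return Genotype.HET


def read_trio_vcf(
    path: str | Path,
    proband: str,
    mother: str,
    father: str,
    trio_id: str = "",
) -> Iterator[TrioSiteCall]:
    """Stream TrioSiteCall records from a multi-sample VCF.

    Multi-allelic records are decomposed: each ALT allele becomes its own
    biallelic candidate with allele depths taken from the AD field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = {name: samples.index(name) for name in (proband, mother, father)}
    except ValueError as exc:
        raise ValueError(f"sample not found in VCF {path}: {exc}") from exc

    for variant in vcf:
        ad = variant.format("AD")  # (n_samples, n_alleles) or None
        dp = variant.format("DP")
        for alt_i, alt in enumerate(variant.ALT, start=1):
            if alt in (".", "*", "<NON_REF>"):
                continue
            key = VariantKey(variant.CHROM, variant.POS, variant.REF, alt)
            calls = {}
            for role, name in (
                ("proband", proband),
                ("mother", mother),
                ("father", father),
            ):
                i = idx[name]
                gt_alleles = tuple(
                    a for a in variant.genotypes[i][:-1]  # last entry is phasing
                )
                genotype = _genotype_for_alt(gt_alleles, alt_i)
                alt_depth = 0
                depth = 0
                if ad is not None and ad.shape[1] > alt_i:
                    alt_depth = max(int(ad[i][alt_i]), 0)
                    depth = sum(max(int(x), 0) for x in ad[i])
                if dp is not None:
                    depth = max(depth, int(dp[i][0]))
                calls[role] = SampleCall(genotype, depth, min(alt_depth, depth))
            yield TrioSiteCall(key=key, trio_id=trio_id or Path(path).stem, **calls)


def read_freq_table(path: str | Path) -> dict[VariantKey, PopulationFrequencies]:
    """Read a tab-delimited allele-frequency lookup.

    Columns: chrom, pos, ref, alt, gnomad_af, internal_af. Empty or ``.``
    frequency fields mean the allele is absent from the resource.
    """
    out: dict[VariantKey, PopulationFrequencies] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])

            def _af(v: str) -> Optional[float]:
                v = (v or "").strip()
                return None if v in ("", ".", "NA") else float(v)

            out[key] = PopulationFrequencies(
                gnomad_af=_af(row.get("gnomad_af", "")),
                internal_af=_af(row.get("internal_af", "")),
            )
    return out


_CANDIDATE_COLS = [
    "trio_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "proband_gt",
    "proband_dp",
    "proband_ad",
    "mother_gt",
    "mother_dp",
    "mother_ad",
    "father_gt",
    "father_dp",
    "father_ad",
    "proband_vaf",
    "passed",
    "failed_filters",
    "qc_flags",
]


def write_candidates_tsv(
    decisions: Iterable[ScreenDecision], path: str | Path, version: str = ""
) -> None:
    """Write one row per decision; ``failed_filters`` semicolon-joined."""
    with open(path, "w", newline="") as fh:
        if version:
            fh.write(f"# mosaicscreen {version}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CANDIDATE_COLS)
        for d in decisions:
            rec = d.record
            member_cols: list = []
            for role in ("proband", "mother", "father"):
                if rec is None:
                    member_cols += ["", "", ""]
                else:
                    c = rec.members()[role]
                    member_cols += [c.genotype.value, c.depth, c.alt_depth]
            w.writerow(
                [
                    d.trio_id,
                    d.key.chrom,
                    d.key.pos,
                    d.key.ref,
                    d.key.alt,
                    *member_cols,
                    f"{d.proband_vaf:.6g}",
                    int(d.passed),
                    ";".join(d.failed_filters),
                    ";".join(d.qc_flags),
                ]
            )


def read_candidates_tsv(path: str | Path) -> list[ScreenDecision]:
    """Read a candidates TSV written by :func:`write_candidates_tsv`."""
    decisions = []
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        record = None
        if row.get("proband_gt"):
            calls = {}
            for role in ("proband", "mother", "father"):
                calls[role] = SampleCall(
                    Genotype(row[f"{role}_gt"]),
                    int(row[f"{role}_dp"]),
                    int(row[f"{role}_ad"]),
                )
            record = TrioSiteCall(key=key, trio_id=row["trio_id"], **calls)
        d = ScreenDecision(
            key=key,
            trio_id=row["trio_id"],
            proband_vaf=float(row["proband_vaf"]),
            record=record,
            failed_filters=[f for f in row["failed_filters"].split(";") if f],
            qc_flags=[f for f in row["qc_flags"].split(";") if f],
        )
        decisions.append(d)
    return decisions
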