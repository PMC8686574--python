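"""Cross-tissue and cross-method summaries of validated mosaic parents.

Bundled fixtures transcribe the study's three result tables — 21 validated
parents (blood exome / amplicon NGS / ddPCR VAFs), 10 enrolled parents, and
5 parents measured across six tissues by two methods — verbatim, including
their internal inconsistencies (see ``data/errata.md``). Coded measurement
states (``ND`` not detected, ``NT`` not tested, ``NA`` not accountable,
``DEG`` degraded DNA) are first-class values and never contribute to a
numeric statistic.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
import statistics
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VafValue",
    "ValidatedParentRecord",
    "TissuePanel",
    "CODED_STATES",
    "load_fixtures",
    "load_cohort_counts",
    "load_germ_layers",
    "summarize_method",
    "parent_of_origin_counts",
    "inheritance_breakdown",
    "cross_method_concordance",
    "tissue_variance",
    "germ_layer_summary",
    "cohort_rates",
    "FixtureIntegrityError",
]

CODED_STATES = ("ND", "NT", "NA", "DEG")


class FixtureIntegrityError(RuntimeError):
    """Raised when a bundled fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class VafValue:
    """A VAF percentage or a coded measurement state.

    ``numeric`` is None for coded states; ``tag`` carries a method
    annotation (e.g. ``HC`` for a haplotype-caller-derived indel value).
    """

    numeric: Optional[float] = None
    code: Optional[str] = None
    tag: str = ""

    def __post_init__(self) -> None:
        if (self.numeric is None) == (self.code is None):
            raise ValueError("exactly one of numeric/code must be set")
        if self.code is not None and self.code not in CODED_STATES:
            raise ValueError(f"unknown coded state {self.code!r}")
        if self.numeric is not None and self.numeric < 0:
            raise ValueError("VAF percentage must be >= 0")

    @property
    def is_numeric(self) -> bool:
        return self.numeric is not None

    @classmethod
    def parse(cls, text: str, tag: str = "") -> "VafValue":
        text = text.strip()
        if text in CODED_STATES:
            return cls(code=text, tag=tag)
        if text.endswith("%"):
            text = text[:-1]
        return cls(numeric=float(text), tag=tag)

    def __str__(self) -> str:
        if self.code is not None:
            return self.code
        s = f"{self.numeric:g}"
        return f"{s} ({self.tag})" if self.tag else s


@dataclass(frozen=True)
class ValidatedParentRecord:
    """One validated mosaic parent: blood VAFs by three methods."""

    gene: str
    variant: str
    acmg_class: str
    phenotype: str
    inheritance_mode: str  # AD | AR | AD/AR | XL | XLR
    parent_of_origin: str  # maternal | paternal
    es: VafValue
    ngs: VafValue
    ddpcr: VafValue

    def value(self, method: str) -> VafValue:
        return {"es": self.es, "amplicon_ngs": self.ngs, "ddpcr": self.ddpcr}[method]


@dataclass
class TissuePanel:
    """Per-parent measurements across tissues and methods.

    ``measurements[(tissue, method)]`` maps to a :class:`VafValue`; method is
    one of ``es`` (blood only), ``amplicon_ngs``, ``ddpcr``.
    """

    parent: str
    gene: str
    variant: str
    measurements: dict[tuple[str, str], VafValue] = field(default_factory=dict)

    def values(self, method: str) -> dict[str, VafValue]:
        return {
            tissue: v
            for (tissue, m), v in self.measurements.items()
            if m == method
        }

    def numeric_values(self, method: str) -> dict[str, float]:
        return {
            t: v.numeric
            for t, v in self.values(method).items()
            if v.is_numeric
        }


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

_DATA = resources.files("mosaicscreen") / "data"


def _read_verified(name: str) -> str:
    """Read a bundled fixture and verify it against the checksum manifest."""
    raw = (_DATA / name).read_bytes()
    manifest = (_DATA / "MANIFEST.sha256").read_text()
    expected = {
        line.split()[1]: line.split()[0]
        for line in manifest.strip().splitlines()
    }
    digest = hashlib.sha256(raw).hexdigest()
    if expected.get(name) != digest:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {expected.get(name)}"
        )
    return raw.decode()


def load_fixtures() -> tuple[list[ValidatedParentRecord], list[dict], list[TissuePanel]]:
    """Load the bundled validated-parent, enrollment and tissue-panel tables.

    Returns ``(table1_records, table2_records, table3_panels)`` with 21, 10
    and 5 entries respectively; a checksum mismatch raises
    :class:`FixtureIntegrityError`.
    """
    t1_rows = list(
        csv.DictReader(_read_verified("table1_validated_parents.tsv").splitlines(), delimiter="\t")
    )
    records = [
        ValidatedParentRecord(
            gene=r["gene"],
            variant=r["variant"],
            acmg_class=r["acmg_class"],
            phenotype=r["phenotype"],
            inheritance_mode=r["inheritance_mode"],
            parent_of_origin=r["parent_of_origin"],
            es=VafValue.parse(r["es_vaf_pct"]),
            ngs=VafValue.parse(r["ngs_vaf_pct"], tag=r.get("ngs_method", "") or ""),
            ddpcr=VafValue.parse(r["ddpcr_vaf_pct"]),
        )
        for r in t1_rows
    ]

    t2 = list(
        csv.DictReader(_read_verified("table2_enrolled_parents.tsv").splitlines(), delimiter="\t")
    )

    panels: dict[str, TissuePanel] = {}
    for r in csv.DictReader(
        _read_verified("table3_tissue_panels.tsv").splitlines(), delimiter="\t"
    ):
        panel = panels.setdefault(
            r["parent"], TissuePanel(r["parent"], r["gene"], r["variant"])
        )
        panel.measurements[(r["tissue"], r["method"])] = VafValue.parse(
            r["value"], tag=(r.get("tag") or "").strip()
        )
    return records, t2, list(panels.values())


def load_cohort_counts() -> dict[str, int]:
    """Cohort bookkeeping counts (trios queried, flagged, validated...)."""
    return json.loads(_read_verified("cohort_counts.json"))


def load_germ_layers() -> dict[str, str]:
    """Default tissue → embryonic germ-layer mapping."""
    rows = csv.DictReader(_read_verified("germ_layers.tsv").splitlines(), delimiter="\t")
    return {r["tissue"]: r["germ_layer"] for r in rows}


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

_STATS = {"min": min, "max": max, "median": statistics.median}


def _numeric(values: Iterable[VafValue]) -> list[float]:
    return [v.numeric for v in values if v.is_numeric]


def summarize_method(
    records: Sequence[ValidatedParentRecord], method: str, statistic: str
) -> float:
    """Min/max/median of the numeric VAF percentages for one method.

    Coded states are excluded; a method with no numeric value yields NaN.
    The median of an even count is the midpoint mean.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    vals = _numeric(r.value(method) for r in records)
    if not vals:
        return math.nan
    return float(_STATS[statistic](vals))


def parent_of_origin_counts(
    records: Sequence[ValidatedParentRecord],
) -> tuple[int, int]:
    """``(n_paternal, n_maternal)``; the two counts partition the records."""
    n_pat = sum(1 for r in records if r.parent_of_origin == "paternal")
    n_mat = sum(1 for r in records if r.parent_of_origin == "maternal")
    return n_pat, n_mat


def inheritance_breakdown(
    records: Sequence[ValidatedParentRecord], group_x_linked: bool = False
) -> dict[str, int]:
    """Counts per inheritance mode (partitioning the records).

    With ``group_x_linked`` the XL and XLR modes are pooled under ``XL``.
    """
    counts = Counter(r.inheritance_mode for r in records)
    if group_x_linked and "XLR" in counts:
        counts["XL"] = counts.get("XL", 0) + counts.pop("XLR")
    return dict(counts)


def cross_method_concordance(
    pairs: Iterable[tuple[str, VafValue, VafValue]],
    ngs_nd_threshold_pct: float = 2.0,
) -> list[dict]:
    """Amplicon-NGS vs ddPCR agreement per variant.

    ``pairs`` yields ``(label, ngs_value, ddpcr_value)``. A pair is
    concordant if both are numeric (the absolute difference is reported), or
    if the NGS blood VAF is strictly below ``ngs_nd_threshold_pct`` (default
    2.0%) and ddPCR reports ND — the study's empirical rule that mosaicism
    under ~2% by deep amplicon sequencing falls below what the droplet assay
    resolves. NT/DEG states are excluded and tallied.
    """
    out = []
    for label, ngs, dd in pairs:
        row: dict = {"label": label, "ngs": ngs, "ddpcr": dd}
        if (ngs.code in ("NT", "DEG", "NA")) or (dd.code in ("NT", "DEG", "NA")):
            row["status"] = "excluded"
        elif ngs.is_numeric and dd.is_numeric:
            row["status"] = "concordant"
            row["difference_pct"] = abs(ngs.numeric - dd.numeric)
        elif ngs.is_numeric and dd.code == "ND":
            row["status"] = (
                "concordant"
                if ngs.numeric < ngs_nd_threshold_pct
                else "discordant"
            )
        else:
            # e.g. NGS ND but ddPCR numeric: methods disagree outright
            row["status"] = "discordant"
        out.append(row)
    return out


def concordance_pairs_from_records(
    records: Sequence[ValidatedParentRecord],
) -> list[tuple[str, VafValue, VafValue]]:
    """(label, NGS, ddPCR) blood pairs for records where both were attempted."""
    return [
        (f"{r.gene} {r.variant}", r.ngs, r.ddpcr)
        for r in records
        if r.ddpcr.code != "NA"
    ]


def concordance_pairs_from_panels(
    panels: Sequence[TissuePanel], tissue: str = "blood"
) -> list[tuple[str, VafValue, VafValue]]:
    out = []
    for p in panels:
        ngs = p.measurements.get((tissue, "amplicon_ngs"))
        dd = p.measurements.get((tissue, "ddpcr"))
        if ngs is not None and dd is not None:
            out.append((f"{p.parent} {p.gene} {p.variant}", ngs, dd))
    return out


def tissue_variance(panel: TissuePanel, method: str) -> float:
    """Sample variance (n−1 denominator) of numeric VAF percentages across
    tissues for one method; NaN with fewer than two numeric values."""
    vals = list(panel.numeric_values(method).values())
    if len(vals) < 2:
        return math.nan
    return statistics.variance(vals)


def germ_layer_summary(
    panel: TissuePanel,
    method: str,
    mapping: Optional[Mapping[str, str]] = None,
) -> dict[str, dict[str, float]]:
    """Per-germ-layer (max, min, mean) of numeric VAFs for one method.

    Layers with no numeric measurement are omitted; an unmapped tissue is a
    configuration error.
    """
    mapping = dict(mapping) if mapping is not None else load_germ_layers()
    by_layer: dict[str, list[float]] = {}
    for tissue, value in panel.numeric_values(method).items():
        if tissue not in mapping:
            raise ValueError(f"tissue {tissue!r} has no germ-layer mapping")
        by_layer.setdefault(mapping[tissue], []).append(value)
    return {
        layer: {"max": max(v), "min": min(v), "mean": sum(v) / len(v)}
        for layer, v in by_layer.items()
    }


def cohort_rates(counts: Optional[Mapping[str, int]] = None) -> dict[str, float]:
    """Cohort screening/validation rates (percent, 1 decimal place).

    * flagged_rate: trios flagged by the computational screen / trios queried
    * validated_rate_cohort: amplicon-validated parents / trios queried
    * validated_rate_flagged: amplicon-validated parents / flagged trios
    """
    c = dict(counts) if counts is not None else load_cohort_counts()
    return {
        "flagged_rate_pct": round(100 * c["n_flagged"] / c["n_trios_queried"], 1),
        "validated_rate_cohort_pct": round(
            100 * c["n_amplicon_validated"] / c["n_trios_queried"], 1
        ),
        "validated_rate_flagged_pct": round(
            100 * c["n_amplicon_validated"] / c["n_flagged"], 1
        ),
    }
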