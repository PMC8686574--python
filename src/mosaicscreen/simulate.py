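"""Synthetic-data generators for every pipeline stage.

Statistical structure emulated (all generators are pure functions of their
parameters and seed):

* trio exome counts at a candidate site — heterozygous proband alt reads
  ~ Binomial(depth, 0.5); a mosaic parent ~ Binomial(depth, p_eff) with
  p_eff = vaf·(1−e) + (1−vaf)·e (symmetric sequencing error e); the other
  parent ~ Binomial(depth, e);
* deep amplicon counts — alt ~ Binomial(depth, vaf + e·(1−vaf)) at depths of
  10^5–10^6;
* ddPCR droplets — mutant and wildtype copies per droplet are independent
  Poisson(λ·vaf) and Poisson(λ·(1−vaf)); a droplet is positive in a channel
  iff it holds ≥ 1 copy of that template, giving the four-way droplet
  classification counted by the instrument.

Defaults mirror the study conditions: cohorts of trios at exome depth
100–300x, ~10% of trios carrying one mosaic parent with VAF uniform in
1–9%, sequencing error 0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Genotype, PileupCounts, SampleCall, TrioSiteCall, VariantKey
from .quantify import DropletCounts

__all__ = [
    "SimTruth",
    "SimulatedSite",
    "simulate_trio_site",
    "simulate_cohort",
    "simulate_amplicon",
    "simulate_droplets",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated trio site."""

    mosaic_vaf: float  # 0.0 = no mosaicism
    parent_of_origin: str  # "mother" | "father"
    proband_genotype: Genotype = Genotype.HET
    seq_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mosaic_vaf < 0.5:
            raise ValueError("mosaic_vaf must be in [0, 0.5)")
        if self.parent_of_origin not in ("mother", "father"):
            raise ValueError("parent_of_origin must be 'mother' or 'father'")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")


@dataclass
class SimulatedSite:
    """A simulated trio record with the parental pileups and its truth."""

    trio: TrioSiteCall
    mother_pileup: PileupCounts
    father_pileup: PileupCounts
    truth: SimTruth


def _binom_pileup(rng: np.random.Generator, depth: int, p: float) -> PileupCounts:
    """Binomial alt sampling split uniformly across strands."""
    alt = int(rng.binomial(depth, p))
    ref = depth - alt
    alt_fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    ref_fwd = int(rng.binomial(ref, 0.5)) if ref else 0
    return PileupCounts(
        ref_fwd=ref_fwd,
        ref_rev=ref - ref_fwd,
        alt_fwd=alt_fwd,
        alt_rev=alt - alt_fwd,
    )


def _effective_p(vaf: float, e: float) -> float:
    # sequencing error flips ref->alt and alt->ref symmetrically
    return vaf * (1.0 - e) + (1.0 - vaf) * e


def simulate_trio_site(
    depths: tuple[int, int, int],
    truth: SimTruth,
    seed: Optional[int] = None,
    key: Optional[VariantKey] = None,
    trio_id: str = "",
) -> SimulatedSite:
    """Simulate read counts for (proband, mother, father) at one site.

    The proband is sampled under its true genotype (het: p = 0.5, hemi:
    p = 1−e); the mosaic parent under its true VAF plus error; the other
    parent under error alone. Reproducible for a fixed seed.
    """
    d_pro, d_mo, d_fa = depths
    if min(depths) <= 0:
        raise ValueError("depths must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    e = truth.seq_error_rate
    key = key or VariantKey("chr1", 1_000_000, "A", "G")

    p_pro = {
        Genotype.HET: 0.5,
        Genotype.HEMI: 1.0 - e,
    }.get(truth.proband_genotype, _effective_p(0.0, e))
    pro_alt = int(rng.binomial(d_pro, p_pro))

    p_mosaic = _effective_p(truth.mosaic_vaf, e)
    p_clean = _effective_p(0.0, e)
    mo_p = p_mosaic if truth.parent_of_origin == "mother" else p_clean
    fa_p = p_mosaic if truth.parent_of_origin == "father" else p_clean
    mo_pile = _binom_pileup(rng, d_mo, mo_p)
    fa_pile = _binom_pileup(rng, d_fa, fa_p)

    trio = TrioSiteCall(
        key=key,
        trio_id=trio_id,
        proband=SampleCall(truth.proband_genotype, d_pro, pro_alt),
        mother=SampleCall(Genotype.REF_HOM, d_mo, mo_pile.alt_count()),
        father=SampleCall(Genotype.REF_HOM, d_fa, fa_pile.alt_count()),
    )
    return SimulatedSite(trio, mo_pile, fa_pile, truth)


def simulate_cohort(
    n_trios: int,
    mosaic_fraction: float = 0.10,
    vaf_range: tuple[float, float] = (0.01, 0.09),
    depth_range: tuple[int, int] = (100, 300),
    seq_error_rate: float = 0.005,
    seed: int = 0,
) -> list[SimulatedSite]:
    """Simulate a trio cohort with a fraction of mosaic parents.

    Each trio contributes one candidate site. A ``mosaic_fraction`` of trios
    has one parent (mother or father, equiprobable) truly mosaic with VAF
    uniform over ``vaf_range``; the rest have VAF 0. Depths are uniform
    integers over ``depth_range`` independently per member.
    """
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    if not 0.0 <= mosaic_fraction <= 1.0:
        raise ValueError("mosaic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites: list[SimulatedSite] = []
    for i in range(n_trios):
        is_mosaic = rng.random() < mosaic_fraction
        vaf_true = float(rng.uniform(*vaf_range)) if is_mosaic else 0.0
        parent = "mother" if rng.random() < 0.5 else "father"
        depths = tuple(int(rng.integers(depth_range[0], depth_range[1] + 1)) for _ in range(3))
        truth = SimTruth(
            mosaic_vaf=vaf_true,
            parent_of_origin=parent,
            seq_error_rate=seq_error_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        key = VariantKey("chr1", 1_000_000 + i, "A", "G")
        sites.append(
            simulate_trio_site(depths, truth, key=key, trio_id=f"trio{i:04d}")
        )
    return sites


def simulate_amplicon(
    depth: int,
    vaf_true: float,
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[int, int]:
    """Simulate deep-amplicon allele counts: ``(alt_count, depth)``.

    alt ~ Binomial(depth, vaf_true + e·(1−vaf_true)): error can only inflate
    the alternate count at the low fractions of interest.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= vaf_true <= 1.0:
        raise ValueError("vaf_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = vaf_true + seq_error_rate * (1.0 - vaf_true)
    return int(rng.binomial(depth, p)), depth


def simulate_droplets(
    n_droplets: int,
    mean_copies_per_droplet: float,
    vaf_true: float,
    seed: int = 0,
) -> DropletCounts:
    """Simulate ddPCR droplet partitioning.

    Mutant and wildtype template copies per droplet are independent
    Poisson(λ·vaf) and Poisson(λ·(1−vaf)); a droplet is channel-positive iff
    it received ≥ 1 copy of that template. Droplets are classified into the
    four (mut±, wt±) classes by a single multinomial draw with the implied
    class probabilities, which is distributionally identical to per-droplet
    sampling.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    if mean_copies_per_droplet < 0:
        raise ValueError("mean_copies_per_droplet must be >= 0")
    if not 0.0 <= vaf_true <= 1.0:
        raise ValueError("vaf_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lam = mean_copies_per_droplet
    p_mut = 1.0 - math.exp(-lam * vaf_true)
    p_wt = 1.0 - math.exp(-lam * (1.0 - vaf_true))
    probs = [
        p_mut * (1 - p_wt),  # mutant-only
        p_wt * (1 - p_mut),  # wildtype-only
        p_mut * p_wt,  # double positive
        (1 - p_mut) * (1 - p_wt),  # negative
    ]
    n_mut, n_wt, n_double, n_neg = (int(x) for x in rng.multinomial(n_droplets, probs))
    return DropletCounts(
        n_mut_only=n_mut, n_wt_only=n_wt, n_double_pos=n_double, n_neg=n_neg
    )
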