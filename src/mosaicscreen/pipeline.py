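"""Run configuration and end-to-end orchestration.

``run_pipeline`` chains the screen → re-genotype → report stages over file
inputs, writing diff-friendly TSV outputs, a per-filter attrition log
(n_in = n_passed + n_failed for every filter) and a copy of the effective
configuration into the output directory for provenance. Outputs are
deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .core import ScreenConfig
from .regenotype import (
    classify_parent,
    cohort_flag_rate,
    read_pileup_tsv,
    write_classifications_tsv,
)
from .screen import (
    RegionMask,
    read_freq_table,
    read_trio_vcf,
    screen_trios,
    write_candidates_tsv,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_pedigree"]

_ALL_FILTERS = [
    "denovo",
    "het_window",
    "depth",
    "gnomad",
    "internal_af",
    "region_mask",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end run."""

    vcf: Optional[str] = None
    pedigree: Optional[str] = None
    freq: Optional[str] = None
    mask: Optional[str] = None
    pileup: Optional[str] = None
    out_dir: str = "mosaicscreen_out"
    seed: int = 0
    lod: float = 0.005
    droplet_volume_nl: float = 0.85
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def validate(self, require_inputs: bool = True) -> None:
        if require_inputs:
            for name in ("vcf", "pedigree"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError(f"config is missing required input: {name}")
                if not Path(p).exists():
                    raise PipelineError(f"{name} file not found: {p}")
            for name in ("freq", "mask", "pileup"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"{name} file not found: {p}")
        if self.seed < 0:
            raise PipelineError("seed must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screen"] = self.screen.to_dict()
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("version", None)
        screen = d.pop("screen", {})
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.screen = ScreenConfig.from_dict(screen)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def read_pedigree(path: str | Path) -> list[dict]:
    """Read trio role assignments: trio_id, proband, mother, father (TSV)."""
    import csv

    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    trios = list(csv.DictReader(rows, delimiter="\t"))
    for t in trios:
        for col in ("trio_id", "proband", "mother", "father"):
            if not t.get(col):
                raise PipelineError(f"pedigree missing column {col}: {t}")
    return trios


def _attrition(decisions) -> dict:
    n_in = len(decisions)
    filters = {}
    for f in _ALL_FILTERS:
        n_failed = sum(1 for d in decisions if f in d.failed_filters)
        filters[f] = {"n_in": n_in, "n_failed": n_failed, "n_passed": n_in - n_failed}
    return {
        "n_in": n_in,
        "n_passed": sum(1 for d in decisions if d.passed),
        "filters": filters,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute screen → re-genotype over the configured inputs.

    Returns the output directory. Any stage failure leaves partial outputs in
    place together with a ``FAILED`` marker file and raises
    :class:`PipelineError`.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    try:
        # ---- screen stage -------------------------------------------------
        freqs = read_freq_table(config.freq) if config.freq else None
        mask = RegionMask.from_bed(config.mask) if config.mask else None
        decisions = []
        for trio in read_pedigree(config.pedigree):
            records = read_trio_vcf(
                config.vcf,
                proband=trio["proband"],
                mother=trio["mother"],
                father=trio["father"],
                trio_id=trio["trio_id"],
            )
            decisions.extend(screen_trios(records, freqs, mask, config.screen))
        write_candidates_tsv(decisions, out / "candidates.tsv", version=__version__)
        stage_log = {"screen": _attrition(decisions)}

        # ---- re-genotype stage -------------------------------------------
        classifications = []
        if config.pileup:
            pileups = read_pileup_tsv(config.pileup)
            passed_keys = {(d.trio_id, d.key) for d in decisions if d.passed}
            for (trio_id, parent, key), counts in sorted(
                pileups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            ):
                if (trio_id, key) not in passed_keys:
                    continue
                classifications.append(
                    classify_parent(
                        counts, config.screen, key=key, parent=parent, trio_id=trio_id
                    )
                )
            n_trios = len({d.trio_id for d in decisions})
            write_classifications_tsv(
                classifications,
                out / "classifications.tsv",
                summary_path=out / "summary.json",
                n_trios=n_trios,
            )
            n_flagged, rate = cohort_flag_rate(classifications, n_trios)
            stage_log["regenotype"] = {
                "n_candidates": len(classifications),
                "n_trios": n_trios,
                "n_flagged": n_flagged,
                "flag_rate": rate,
            }

        with open(out / "pipeline_log.json", "w") as fh:
            json.dump(stage_log, fh, indent=2)
            fh.write("\n")
    except PipelineError:
        marker.touch()
        raise
    except Exception as exc:
        marker.touch()
        raise PipelineError(f"pipeline stage failed: {exc}") from exc
    return out
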