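"""Whole-exome somatic-variant filtering cascade for cell-line experiments.

The cascade retains variants that (1) have at least 5 reads supporting the
mutant allele and total coverage of at least 30, (2) are not known germline
polymorphisms — dbSNP members are removed unless also catalogued in COSMIC,
(3) are single-nucleotide variants, and (4) are not present in the matched
earliest-timepoint sample of the same lineage at a mutant-allele fraction of
1 (a fixation pattern indicating a pre-existing, i.e. germinal, variant
rather than one acquired during the experiment).

Every stage's input/removed/output counts are recorded in an auditable
:class:`FilterReport` whose counts telescope exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ithkit.variant_io import SampleVariantSet, SomaticVariant

DEFAULT_MIN_ALT = 5
DEFAULT_MIN_DEPTH = 30
DEFAULT_BASELINE_MAF = 1.0
_MAF_TOL = 1e-9


def filter_support(
    variants: Iterable[SomaticVariant],
    min_alt: int = DEFAULT_MIN_ALT,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[SomaticVariant]:
    """Keep variants with alt_count ≥ min_alt and depth ≥ min_depth.

    Both bounds are inclusive. Variants with undefined counts fail the
    predicate (they cannot demonstrate support) and are removed here.
    """
    return [
        v for v in variants
        if v.depth is not None and v.alt_count >= min_alt and v.depth >= min_depth
    ]


def filter_known_germline(variants: Iterable[SomaticVariant]) -> list[SomaticVariant]:
    """Remove known polymorphisms: dbSNP members not also present in COSMIC."""
    return [v for v in variants if not (v.in_dbsnp and not v.in_cosmic)]


def keep_snvs(variants: Iterable[SomaticVariant]) -> list[SomaticVariant]:
    """Retain single-nucleotide variants only."""
    return [v for v in variants if v.variant_class == "SNV"]


def remove_baseline_germline(
    target: Iterable[SomaticVariant],
    baseline: SampleVariantSet | Sequence[SomaticVariant] | None,
    maf_threshold: float = DEFAULT_BASELINE_MAF,
) -> list[SomaticVariant]:
    """Remove target variants fixed in the matched earliest-timepoint sample.

    A target variant is removed when its (chrom, pos, ref, alt) occurs in
    the baseline with a baseline mutant-allele fraction ≥ ``maf_threshold``
    (default 1, i.e. fixed; compared with a 1e-9 numerical tolerance). A
    lower threshold, e.g. 0.95, accommodates sequencing noise around
    fixation.
    """
    target = list(target)
    baseline_vars = list(baseline) if baseline is not None else []
    if not baseline_vars:
        warnings.warn("empty baseline: no germline variants removed", stacklevel=2)
        return target
    fixed = {
        v.key for v in baseline_vars
        if v.maf is not None and v.maf >= maf_threshold - _MAF_TOL
    }
    return [v for v in target if v.key not in fixed]


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int
    n_out: int
    params: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the cascade; counts telescope."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, **params) -> None:
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError("stage input does not equal previous stage output")
        self.stages.append(FilterStage(name, n_in, n_in - n_out, n_out, params))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"stage": s.name, "input": s.n_in, "removed": s.n_removed,
             "output": s.n_out,
             "parameters": ";".join(f"{k}={v}" for k, v in s.params.items())}
            for s in self.stages
        ])

    def __str__(self) -> str:
        lines = ["stage                    in  removed  out"]
        for s in self.stages:
            lines.append(f"{s.name:<22} {s.n_in:>5} {s.n_removed:>8} {s.n_out:>4}")
        return "\n".join(lines)


@dataclass
class FilterConfig:
    """Cascade thresholds; set a stage's switch to False to pass it through."""

    min_alt: int = DEFAULT_MIN_ALT
    min_depth: int = DEFAULT_MIN_DEPTH
    baseline_maf: float = DEFAULT_BASELINE_MAF
    support_enabled: bool = True
    germline_db_enabled: bool = True
    snv_only: bool = True
    baseline_enabled: bool = True


def run_filter_cascade(
    target: SampleVariantSet,
    baseline: SampleVariantSet | None = None,
    config: FilterConfig | None = None,
) -> tuple[SampleVariantSet, FilterReport]:
    """Apply the four filters in canonical order with a full audit trail.

    Order: read support → known germline (dbSNP/COSMIC) → SNV-only →
    baseline-fixed germline. Variants with undefined depth are removed in a
    dedicated stage before the support filter so their tally is visible.
    """
    cfg = config or FilterConfig()
    report = FilterReport()
    current = list(target.variants)

    if cfg.support_enabled:
        n_in = len(current)
        defined = [v for v in current if v.depth is not None]
        report.add("undefined_depth", n_in, len(defined))
        current = defined
        n_in = len(current)
        current = filter_support(current, cfg.min_alt, cfg.min_depth)
        report.add("read_support", n_in, len(current),
                   min_alt=cfg.min_alt, min_depth=cfg.min_depth)
    else:
        report.add("read_support", len(current), len(current), disabled=True)

    n_in = len(current)
    if cfg.germline_db_enabled:
        current = filter_known_germline(current)
    report.add("known_germline", n_in, len(current),
               rule="dbSNP unless COSMIC" if cfg.germline_db_enabled else "disabled")

    n_in = len(current)
    if cfg.snv_only:
        current = keep_snvs(current)
    report.add("snv_only", n_in, len(current), enabled=cfg.snv_only)

    n_in = len(current)
    if cfg.baseline_enabled and baseline is not None and len(baseline) > 0:
        current = remove_baseline_germline(current, baseline, cfg.baseline_maf)
        report.add("baseline_germline", n_in, len(current),
                   maf_threshold=cfg.baseline_maf, baseline=baseline.sample_id)
    else:
        report.add("baseline_germline", n_in, len(current), skipped=True)

    out = SampleVariantSet(sample_id=target.sample_id,
                           cancer_type=target.cancer_type, variants=current)
    return out, report
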