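"""Seeded generators emulating the statistical structure of the real inputs.

Every pipeline stage can be exercised without external data:

* :func:`simulate_tumor` — a tumor as a mixture of clones with given
  cancer-cell fractions (CCF) under a diploid, copy-neutral, heterozygous
  model: a mutation private to a clone with fraction *f* in a tumor of
  purity *ρ* has expected mutant-allele fraction ρ·f/2; reads are drawn as
  depth ~ Poisson(mean_depth) (floored at 1) and alt ~ Binomial(depth, ρf/2).
* :func:`simulate_cohort` — binary gene-mutation indicators with configured
  prevalences and additive per-gene effects on a heterogeneity score, for
  driver-recovery tests.
* :func:`simulate_timecourse` — knockout-vs-control style serial samples
  (e.g. 1/3/6 months) whose clonal architecture gains subclones each step,
  plus fixed (allele fraction 1) germline variants shared by all timepoints
  for baseline-removal tests.
* :func:`simulate_ocr_trace` — an OCR time course whose phase means invert
  exactly through the respirometry parameter formulas at zero noise.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ithkit.cohort_association import MutationMatrix
from ithkit.respirometry import OCRTrace, RespirationParams
from ithkit.variant_io import SampleVariantSet, SomaticVariant

_BASES = np.array(list("ACGT"))


@dataclass
class CloneArchitecture:
    """Subclonal composition of a simulated tumor.

    ``clones`` is a list of (cancer-cell fraction, mutation count); the
    first clone must be truncal (fraction 1) and fractions must be
    non-increasing. Ploidy is fixed at 2 with heterozygous mutations, so
    expected allele fraction = purity × CCF / 2.
    """

    purity: float
    clones: list[tuple[float, int]]

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not self.clones:
            raise ValueError("need at least one clone")
        fracs = [f for f, _ in self.clones]
        if fracs[0] != 1.0:
            raise ValueError("first clone must be truncal (fraction 1)")
        if any(b > a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("clone fractions must be non-increasing")
        if any(not 0 < f <= 1 for f in fracs):
            raise ValueError("clone fractions must be in (0, 1]")
        if any(n < 0 for _, n in self.clones):
            raise ValueError("mutation counts must be >= 0")


def _substitution_at(pos: int) -> tuple[str, str]:
    """Deterministic ref/alt pair per coordinate, so the same locus carries
    the same alleles in every sample it appears in."""
    ref = pos % 4
    alt = (ref + 1 + (pos // 4) % 3) % 4
    return str(_BASES[ref]), str(_BASES[alt])


def _emit_variants(
    rng: np.random.Generator,
    fractions: Sequence[float],
    positions: Sequence[int],
    mean_depth: int,
    sample_id: str,
    gene_of=None,
) -> list[SomaticVariant]:
    out = []
    for frac, pos in zip(fractions, positions):
        depth = max(1, int(rng.poisson(mean_depth)))
        alt_count = int(rng.binomial(depth, frac))
        ref, alt = _substitution_at(pos)
        out.append(SomaticVariant(
            sample_id=sample_id, chrom="1", pos=int(pos),
            ref_allele=ref, alt_allele=alt, variant_class="SNV",
            gene=gene_of(pos) if gene_of else "",
            ref_count=depth - alt_count, alt_count=alt_count,
        ))
    return out


def simulate_tumor(
    arch: CloneArchitecture,
    mean_depth: int = 100,
    seed: int = 0,
    sample_id: str = "SIM",
    cancer_type: str = "SYN",
    start_pos: int = 1_000,
) -> SampleVariantSet:
    """Sample one tumor's variant calls from a clonal architecture.

    Coordinates are unique consecutive positions on a synthetic chromosome;
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    fractions, positions = [], []
    pos = start_pos
    for ccf, n_mut in arch.clones:
        f = arch.purity * ccf / 2.0
        for _ in range(n_mut):
            fractions.append(f)
            positions.append(pos)
            pos += 1
    variants = _emit_variants(rng, fractions, positions, mean_depth, sample_id)
    return SampleVariantSet(sample_id=sample_id, cancer_type=cancer_type,
                            variants=variants)


@dataclass
class CohortSpec:
    """Generator settings for a cohort with injected heterogeneity drivers."""

    n_samples: int
    genes: list[str]
    prevalence: dict[str, float]       # per-gene mutation probability
    effects: dict[str, float]          # additive shift in ITH units
    baseline_mean: float = 30.0
    baseline_sd: float = 10.0
    cancer_type: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {g} outside [0, 1]")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[MutationMatrix, pd.Series, pd.DataFrame]:
    """Draw mutation indicators and a driver-shifted heterogeneity score.

    ITH(sample) = baseline + Σ_g effect(g)·mutated(sample, g) + N(0, sd).
    Returns (matrix, true ITH vector, true effect table).
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    cols = {}
    for g in spec.genes:
        p = spec.prevalence.get(g, 0.0)
        cols[g] = rng.binomial(1, p, size=spec.n_samples)
    data = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"),
                        dtype=np.int8)
    ith = np.full(spec.n_samples, spec.baseline_mean, dtype=float)
    for g in spec.genes:
        eff = spec.effects.get(g, 0.0)
        if eff:
            ith += eff * data[g].to_numpy()
    ith += rng.normal(0.0, spec.baseline_sd, size=spec.n_samples)
    matrix = MutationMatrix(
        data, pd.Series(spec.cancer_type, index=data.index, name="cancer_type")
    )
    effects = pd.DataFrame({
        "gene": spec.genes,
        "prevalence": [spec.prevalence.get(g, 0.0) for g in spec.genes],
        "effect": [spec.effects.get(g, 0.0) for g in spec.genes],
    })
    return matrix, pd.Series(ith, index=data.index, name="ith"), effects


def simulate_timecourse(
    base_arch: CloneArchitecture,
    subclone_gain_per_step: int = 2,
    steps: int = 3,
    seed: int = 0,
    mean_depth: int = 100,
    lineage: str = "KO",
    n_germline: int = 20,
    subclone_ccf: tuple[float, float] = (0.2, 0.4),
    muts_per_subclone: int = 30,
) -> list[SampleVariantSet]:
    """Serial samples of one lineage with diverging clonal structure.

    Step 1 carries the base architecture; each later step adds
    ``subclone_gain_per_step`` new subclones (fresh private mutations at new
    coordinates, CCF drawn uniformly from ``subclone_ccf``) before reads are
    resampled. ``n_germline`` extra variants at allele fraction exactly 1
    are shared by every timepoint, emulating pre-existing (germinal)
    variants that the baseline-removal filter should eliminate.
    """
    rng = np.random.default_rng(seed)
    germline_pos = list(range(100, 100 + n_germline))
    somatic_start = 10_000
    # (fraction, position) of every somatic mutation, grown step by step
    somatic: list[tuple[float, int]] = []
    pos = somatic_start
    for ccf, n_mut in base_arch.clones:
        for _ in range(n_mut):
            somatic.append((base_arch.purity * ccf / 2.0, pos))
            pos += 1
    out = []
    for step in range(1, steps + 1):
        if step > 1:
            for _ in range(subclone_gain_per_step):
                ccf = rng.uniform(*subclone_ccf)
                for _ in range(muts_per_subclone):
                    somatic.append((base_arch.purity * ccf / 2.0, pos))
                    pos += 1
        sid = f"{lineage}_t{step}"
        fracs = [1.0] * n_germline + [f for f, _ in somatic]
        positions = germline_pos + [p for _, p in somatic]
        variants = _emit_variants(rng, fracs, positions, mean_depth, sid)
        out.append(SampleVariantSet(sample_id=sid, cancer_type="SYN",
                                    variants=variants))
    return out


def simulate_ocr_trace(
    true_params: RespirationParams,
    oligo_level: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    well: str = "W1",
    group: str = "control",
    n_baseline: int = 3,
    n_per_phase: int = 3,
    protein: float | None = None,
) -> OCRTrace:
    """Generate an OCR trace whose phase means invert the parameter formulas.

    Baseline points sit at basal + non_mito (so the 3rd baseline point
    recovers basal), FCCP points at maximal + non_mito, rotenone/antimycin
    points at non_mito, oligomycin points at ``oligo_level``; independent
    Normal(0, noise_sd) noise is added per point. With noise_sd = 0,
    :func:`ithkit.respirometry.derive_params` returns ``true_params``
    exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    levels = (
        [true_params.basal + true_params.non_mito] * n_baseline
        + [oligo_level] * n_per_phase
        + [true_params.maximal + true_params.non_mito] * n_per_phase
        + [true_params.non_mito] * n_per_phase
    )
    phases = (
        ["baseline"] * n_baseline + ["oligomycin"] * n_per_phase
        + ["fccp"] * n_per_phase + ["rot_anti"] * n_per_phase
    )
    ocr = np.asarray(levels, dtype=float)
    if noise_sd > 0:
        ocr = ocr + rng.normal(0.0, noise_sd, size=len(ocr))
    times = np.arange(len(ocr), dtype=float) * 6.5  # ~6.5 min per cycle
    return OCRTrace(well=well, group=group, times=times, ocr=ocr,
                    phases=phases, protein=protein)
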