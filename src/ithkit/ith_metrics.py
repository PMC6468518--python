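"""Per-sample genomic instability and MATH intratumor-heterogeneity scores.

Genomic instability is the absolute count of somatic point mutations plus
small insertions/deletions (1–100 bp) called in a tumor exome. Intratumor
heterogeneity is quantified with MATH (mutant-allele tumor heterogeneity):

    MATH = 100 × MAD / median

over the sample's mutant-allele fractions, where MAD is the median absolute
deviation scaled by 1.4826 so that it estimates the standard deviation for
normally distributed data. A homogeneous tumor (one clone, all fractions near
purity/2) gives a narrow fraction distribution and a low MATH; subclonal
structure widens the distribution and raises MATH.

The instability–ITH relationship per cancer type is summarized by the Pearson
correlation between log10(instability) and MATH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ithkit.variant_io import SampleVariantSet

#: MAD→SD consistency scale for normal data, as conventionally printed.
#: Equals 1/Φ⁻¹(3/4) to 4 decimal places; see
#: :func:`normal_consistency_constant` for the computed value.
MAD_SCALE = 1.4826

DEFAULT_MIN_LOCI = 5
DEFAULT_MAX_INDEL_LEN = 100


def normal_consistency_constant() -> float:
    """The exact MAD-to-SD consistency factor, 1/Φ⁻¹(3/4) ≈ 1.4826.

    For X ~ Normal(μ, σ), median(|X − μ|) = σ·Φ⁻¹(3/4); dividing by the
    upper-quartile of the standard normal therefore rescales the MAD to an
    unbiased SD estimate in the normal limit.
    """
    return 1.0 / stats.norm.ppf(0.75)


def scaled_mad(values: Sequence[float], scale: float = MAD_SCALE) -> float:
    """Median absolute deviation scaled by the normal consistency constant.

    Returns ``scale × median(|x − median(x)|)``. Raises on empty input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("scaled_mad is undefined for an empty vector")
    med = np.median(arr)
    return float(scale * np.median(np.abs(arr - med)))


def math_score(
    mafs: Sequence[float],
    min_loci: int = DEFAULT_MIN_LOCI,
) -> float | None:
    """MATH = 100 × scaled MAD / median of the mutant-allele fractions.

    Returns ``None`` (undefined, never 0) when fewer than ``min_loci``
    fractions are available or the median is 0. Raises ``ValueError`` if any
    fraction lies outside [0, 1].
    """
    arr = np.asarray(mafs, dtype=float)
    if arr.size and ((arr < 0).any() or (arr > 1).any()):
        bad = arr[(arr < 0) | (arr > 1)][0]
        raise ValueError(f"mutant-allele fraction {bad} outside [0, 1]")
    if arr.size < min_loci:
        return None
    med = float(np.median(arr))
    if med == 0:
        return None
    return 100.0 * scaled_mad(arr) / med


def genomic_instability(
    sample: SampleVariantSet | Iterable,
    max_indel_len: int = DEFAULT_MAX_INDEL_LEN,
) -> int:
    """Count of SNVs plus indels of 1–``max_indel_len`` bp in a sample.

    Indels longer than the bound are excluded (the bound is inclusive);
    SNVs always count.
    """
    n = 0
    for v in sample:
        if v.variant_class == "SNV":
            n += 1
        elif 1 <= v.indel_length <= max_indel_len:
            n += 1
    return n


@dataclass
class ITHRecord:
    """Per-sample instability count and MATH score with its ingredients."""

    sample_id: str
    cancer_type: str
    instability: int
    math: float | None
    n_loci: int
    median_maf: float | None
    scaled_mad: float | None


ITH_COLUMNS = ["sample_id", "cancer_type", "instability", "math",
               "n_loci", "median_maf", "scaled_mad"]


def profile_cohort(
    sets: Iterable[SampleVariantSet],
    min_loci: int = DEFAULT_MIN_LOCI,
    max_indel_len: int = DEFAULT_MAX_INDEL_LEN,
) -> pd.DataFrame:
    """One ITH record per sample, as a DataFrame.

    The mutant-allele-fraction vector is built from exactly the variants
    counted for instability (SNVs and in-bound indels), restricted to those
    with defined, nonzero depth. Variants without counts contribute to
    instability but not to MATH.
    """
    rows = []
    for s in sets:
        counted = [
            v for v in s
            if v.variant_class == "SNV" or 1 <= v.indel_length <= max_indel_len
        ]
        mafs = [v.maf for v in counted if v.maf is not None]
        med = float(np.median(mafs)) if mafs else None
        smad = scaled_mad(mafs) if mafs else None
        rows.append(ITHRecord(
            sample_id=s.sample_id,
            cancer_type=s.cancer_type,
            instability=len(counted),
            math=math_score(mafs, min_loci=min_loci),
            n_loci=len(mafs),
            median_maf=med,
            scaled_mad=smad,
        ))
    return pd.DataFrame(
        [[r.sample_id, r.cancer_type, r.instability, r.math, r.n_loci,
          r.median_maf, r.scaled_mad] for r in rows],
        columns=ITH_COLUMNS,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation of log10(instability) vs MATH for one cancer type."""

    cancer_type: str
    r: float | None
    p_value: float | None
    n: int
    n_excluded: int = 0
    flag: str = ""

    @property
    def defined(self) -> bool:
        return self.r is not None


def correlate_instability_ith(
    records: pd.DataFrame,
    cancer_type: str | None = None,
) -> CorrelationResult:
    """Pearson r between log10(genomic instability) and MATH.

    Samples with undefined MATH or zero instability are excluded (log10(0)
    is undefined and such samples carry no fraction distribution either);
    the number excluded is reported. Fewer than 3 usable samples yields an
    undefined result with an explanatory flag rather than an error.
    """
    df = records
    label = cancer_type if cancer_type is not None else "all"
    if cancer_type is not None:
        df = df[df["cancer_type"] == cancer_type]
    total = len(df)
    usable = df[(df["math"].notna()) & (df["instability"] >= 1)]
    n = len(usable)
    if n < 3:
        return CorrelationResult(
            cancer_type=label, r=None, p_value=None, n=n,
            n_excluded=total - n,
            flag=f"only {n} usable sample(s); need >= 3",
        )
    x = np.log10(usable["instability"].to_numpy(dtype=float))
    y = usable["math"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(
            cancer_type=label, r=None, p_value=None, n=n,
            n_excluded=total - n, flag="zero variance in one variable",
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(cancer_type=label, r=float(r), p_value=float(p),
                             n=n, n_excluded=total - n)


def correlate_all_types(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cancer-type correlation table (one row per type)."""
    rows = []
    for ct in sorted(records["cancer_type"].unique()):
        res = correlate_instability_ith(records, ct)
        rows.append([res.cancer_type, res.r, res.p_value, res.n,
                     res.n_excluded, res.flag])
    return pd.DataFrame(
        rows, columns=["cancer_type", "r", "p_value", "n", "n_excluded", "flag"]
    )
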