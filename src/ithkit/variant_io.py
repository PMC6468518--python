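"""Read and write somatic variant calls with per-allele read counts.

Two standard input formats are supported — the TCGA Mutation Annotation
Format (a tab-separated table, one row per called variant) and VCF — and both
are mapped onto a single internal representation, :class:`SomaticVariant`,
which carries the reference/alternate read counts from which mutant-allele
fractions are computed downstream.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (the MAF and VCF convention).
* Chromosome labels are normalized by stripping a leading ``chr``.
* Indels are normalized to VCF anchored-base style: the MAF ``-`` allele
  dialect (e.g. ref ``ACG`` / alt ``-`` for a deletion) is converted on read
  to an anchored pair with a placeholder ``N`` anchor base, so that one
  canonical representation serves deduplication and class derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

VARIANT_CLASSES = ("SNV", "INS", "DEL")

#: Default MAF-dialect column names; override any entry via ``column_map``.
MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_type": "Variant_Type",
    "ref_count": "t_ref_count",
    "alt_count": "t_alt_count",
    "gene": "Hugo_Symbol",
    "cancer_type": "cancer_type",
    "in_dbsnp": "in_dbsnp",
    "in_cosmic": "in_cosmic",
}

_MANDATORY = ("sample", "chrom", "pos", "ref", "alt")

#: Fixed column order of the round-trippable TSV written by
#: :func:`write_variants_table`.
TABLE_COLUMNS = [
    "sample_id", "cancer_type", "chrom", "pos", "ref", "alt",
    "class", "gene", "ref_count", "alt_count", "in_dbsnp", "in_cosmic",
]


@dataclass(frozen=True)
class SomaticVariant:
    """One called somatic variant with per-allele read counts.

    ``ref_count``/``alt_count`` are ``None`` when the source row carried no
    parseable counts; such variants have undefined depth and undefined
    mutant-allele fraction, never a silent zero.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    gene: str = ""
    ref_count: int | None = None
    alt_count: int | None = None
    in_dbsnp: bool = False
    in_cosmic: bool = False

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        for name in ("ref_count", "alt_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def depth(self) -> int | None:
        """Total read depth, or ``None`` when counts are undefined."""
        if self.ref_count is None or self.alt_count is None:
            return None
        return self.ref_count + self.alt_count

    @property
    def maf(self) -> float | None:
        """Mutant-allele fraction ``alt/(ref+alt)``; ``None`` if depth is 0
        or undefined."""
        d = self.depth
        if d is None or d == 0:
            return None
        return self.alt_count / d

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def indel_length(self) -> int:
        """Inserted/deleted length; 0 for SNVs."""
        return abs(len(self.ref_allele) - len(self.alt_allele))


@dataclass
class SampleVariantSet:
    """All somatic variants called in one tumor sample."""

    sample_id: str
    cancer_type: str = ""
    variants: list[SomaticVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [v.sample_id for v in self.variants if v.sample_id != self.sample_id]
        if bad:
            raise ValueError(
                f"variant sample_id {bad[0]!r} does not match set {self.sample_id!r}"
            )
        self.variants = _dedupe(self.variants, self.sample_id)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def _dedupe(variants: Sequence[SomaticVariant], sample_id: str) -> list[SomaticVariant]:
    seen: set[tuple] = set()
    out = []
    dropped = 0
    for v in variants:
        if v.key in seen:
            dropped += 1
            continue
        seen.add(v.key)
        out.append(v)
    if dropped:
        warnings.warn(
            f"sample {sample_id}: dropped {dropped} duplicate (chrom,pos,ref,alt) "
            "variant(s)",
            stacklevel=3,
        )
    return out


def classify_alleles(ref: str, alt: str) -> str:
    """Derive the variant class from anchored allele lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    # equal-length multi-nucleotide substitution: treat as SNV-like point event
    return "SNV"


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Convert the MAF ``-`` allele dialect to VCF anchored-base style.

    A deletion ``(pos, ACG, -)`` becomes ``(pos-1, NACG, N)``; an insertion
    ``(pos, -, AC)`` becomes ``(pos, N, NAC)``. ``N`` is a placeholder anchor
    (the true reference base is unknown without the genome). Alleles without
    ``-`` are returned unchanged.
    """
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    if ref in ("-", ""):
        return pos, "N", "N" + alt
    if alt in ("-", ""):
        return pos - 1, "N" + ref, "N"
    return pos, ref, alt


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


_CLASS_ALIASES = {
    "SNP": "SNV", "SNV": "SNV", "DNP": "SNV", "TNP": "SNV", "ONP": "SNV",
    "INS": "INS", "DEL": "DEL", "INSERTION": "INS", "DELETION": "DEL",
}


def _parse_count(value) -> int | None:
    try:
        if pd.isna(value):
            return None
        n = int(float(value))
    except (TypeError, ValueError):
        return None
    return n if n >= 0 else None


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "t")
    try:
        return bool(value) and not pd.isna(value)
    except (TypeError, ValueError):
        return False


def read_mutation_annotation(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[SampleVariantSet]:
    """Read a Mutation Annotation Format table into per-sample variant sets.

    Parameters
    ----------
    path
        Tab-separated file with a header row; ``#``-prefixed lines are
        skipped (MAF version pragma).
    column_map
        Overrides for the default MAF column names (keys of
        :data:`MAF_COLUMNS`), accommodating dialect differences in e.g. the
        tumor read-count columns.

    Returns
    -------
    One :class:`SampleVariantSet` per distinct sample barcode, in first-seen
    order. Rows with unparseable counts are retained with undefined depth.
    Duplicate (chrom, pos, ref, alt) rows within a sample are dropped with a
    warning.
    """
    cols = dict(MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty mutation annotation file")
        return []
    # tolerate the common Start_position capitalization dialect
    if cols["pos"] not in df.columns and cols["pos"] == "Start_Position" \
            and "Start_position" in df.columns:
        cols["pos"] = "Start_position"
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise ValueError(
                f"{path}: mandatory column {cols[key]!r} (for {key!r}) is missing"
            )
    if df.empty:
        warnings.warn(f"{path}: no data rows")
        return []

    has = {k: cols[k] in df.columns for k in cols}
    sets: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        sid = str(row[cols["sample"]]).strip()
        pos, ref, alt = normalize_alleles(
            int(float(row[cols["pos"]])), row[cols["ref"]], row[cols["alt"]]
        )
        vclass = None
        if has["variant_type"]:
            vclass = _CLASS_ALIASES.get(str(row[cols["variant_type"]]).strip().upper())
        if vclass is None:
            vclass = classify_alleles(ref, alt)
        variant = SomaticVariant(
            sample_id=sid,
            chrom=normalize_chrom(row[cols["chrom"]]),
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            variant_class=vclass,
            gene=str(row[cols["gene"]]).strip() if has["gene"] else "",
            ref_count=_parse_count(row[cols["ref_count"]]) if has["ref_count"] else None,
            alt_count=_parse_count(row[cols["alt_count"]]) if has["alt_count"] else None,
            in_dbsnp=_parse_bool(row[cols["in_dbsnp"]]) if has["in_dbsnp"] else False,
            in_cosmic=_parse_bool(row[cols["in_cosmic"]]) if has["in_cosmic"] else False,
        )
        entry = sets.setdefault(
            sid,
            {"cancer_type": str(row[cols["cancer_type"]]).strip()
             if has["cancer_type"] else "", "variants": []},
        )
        entry["variants"].append(variant)
    return [
        SampleVariantSet(sample_id=sid, cancer_type=e["cancer_type"],
                         variants=e["variants"])
        for sid, e in sets.items()
    ]


def read_vcf(
    path,
    sample_id: str,
    cancer_type: str = "",
    cosmic_ids: Iterable[str] | None = None,
    dbsnp_ids: Iterable[str] | None = None,
) -> SampleVariantSet:
    """Read one sample's variants from a VCF (plain or bgzipped).

    Allele depths are taken from the per-sample ``AD`` genotype field when
    present, falling back to the ``DP4`` INFO counts. Multi-allelic records
    are split into one variant per alternate allele, with the reference count
    shared. dbSNP membership is set from the ID column being non-missing
    (supplemented by ``dbsnp_ids`` if given); COSMIC membership from the ID
    being in ``cosmic_ids``. Records lacking depth information are kept with
    undefined depth and reported in a warning summary.
    """
    from cyvcf2 import VCF

    cosmic = set(cosmic_ids) if cosmic_ids else set()
    dbsnp_extra = set(dbsnp_ids) if dbsnp_ids else set()
    variants: list[SomaticVariant] = []
    n_nodepth = 0
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            rid = rec.ID if rec.ID not in (None, ".") else None
            ids = set(rid.split(";")) if rid else set()
            in_dbsnp = bool(ids) or bool(ids & dbsnp_extra)
            in_cosmic = bool(ids & cosmic)
            ref_count, alt_counts = _vcf_counts(rec, len(rec.ALT))
            if ref_count is None:
                n_nodepth += 1
            for alt, alt_count in zip(rec.ALT, alt_counts):
                variants.append(
                    SomaticVariant(
                        sample_id=sample_id,
                        chrom=normalize_chrom(rec.CHROM),
                        pos=rec.POS,
                        ref_allele=rec.REF,
                        alt_allele=alt,
                        variant_class=classify_alleles(rec.REF, alt),
                        gene="",
                        ref_count=ref_count,
                        alt_count=alt_count,
                        in_dbsnp=in_dbsnp,
                        in_cosmic=in_cosmic,
                    )
                )
    finally:
        vcf.close()
    if n_nodepth:
        warnings.warn(
            f"{path}: {n_nodepth} record(s) without allele-depth information; "
            "kept with undefined depth"
        )
    return SampleVariantSet(sample_id=sample_id, cancer_type=cancer_type,
                            variants=variants)


def _vcf_counts(rec, n_alt: int):
    """Extract (ref_count, [alt_count per ALT]) from AD or DP4."""
    try:
        ad = rec.format("AD")
    except KeyError:
        ad = None
    if ad is not None and ad.shape[-1] >= n_alt + 1:
        row = [int(x) for x in ad[0]]
        if all(x >= 0 for x in row[: n_alt + 1]):
            return row[0], row[1 : n_alt + 1]
    dp4 = rec.INFO.get("DP4")
    if dp4 is not None and len(dp4) == 4 and n_alt == 1:
        return int(dp4[0]) + int(dp4[1]), [int(dp4[2]) + int(dp4[3])]
    return None, [None] * n_alt


def write_variants_table(sets: Iterable[SampleVariantSet], path) -> None:
    """Write variant sets as a fixed-column TSV that round-trips through
    :func:`read_variants_table`."""
    rows = []
    for s in sets:
        for v in s:
            rows.append({
                "sample_id": v.sample_id,
                "cancer_type": s.cancer_type,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "class": v.variant_class,
                "gene": v.gene,
                "ref_count": "" if v.ref_count is None else v.ref_count,
                "alt_count": "" if v.alt_count is None else v.alt_count,
                "in_dbsnp": v.in_dbsnp,
                "in_cosmic": v.in_cosmic,
            })
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


#: column_map that makes :func:`read_mutation_annotation` parse our own TSV.
TABLE_COLUMN_MAP = {
    "sample": "sample_id", "chrom": "chrom", "pos": "pos", "ref": "ref",
    "alt": "alt", "variant_type": "class", "ref_count": "ref_count",
    "alt_count": "alt_count", "gene": "gene", "cancer_type": "cancer_type",
    "in_dbsnp": "in_dbsnp", "in_cosmic": "in_cosmic",
}


def read_variants_table(path) -> list[SampleVariantSet]:
    """Read a TSV written by :func:`write_variants_table`."""
    return read_mutation_annotation(path, column_map=TABLE_COLUMN_MAP)
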