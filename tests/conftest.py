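import numpy as np
import pytest

from ithkit.variant_io import SampleVariantSet, SomaticVariant


@pytest.fixture
def make_variant():
    """Factory for SomaticVariant with sensible defaults."""

    def _make(pos=1, sample_id="S1", chrom="1", ref="A", alt="C",
              variant_class="SNV", gene="", ref_count=30, alt_count=10,
              in_dbsnp=False, in_cosmic=False):
        return SomaticVariant(
            sample_id=sample_id, chrom=chrom, pos=pos, ref_allele=ref,
            alt_allele=alt, variant_class=variant_class, gene=gene,
            ref_count=ref_count, alt_count=alt_count,
            in_dbsnp=in_dbsnp, in_cosmic=in_cosmic,
        )

    return _make


@pytest.fixture
def random_variant_set(make_variant):
    """Seeded random variant-set generator for oracle comparisons."""

    def _gen(seed, n=50, sample_id="S1", cancer_type="SYN"):
        rng = np.random.default_rng(seed)
        variants = []
        for i in range(n):
            cls = rng.choice(["SNV", "INS", "DEL"], p=[0.7, 0.15, 0.15])
            if cls == "SNV":
                ref, alt = "A", "C"
            elif cls == "INS":
                ref, alt = "A", "A" + "T" * int(rng.integers(1, 5))
            else:
                ref, alt = "A" + "T" * int(rng.integers(1, 5)), "A"
            if rng.random() < 0.1:
                rc, ac = None, None
            else:
                depth = int(rng.integers(0, 200))
                ac = int(rng.integers(0, depth + 1)) if depth else 0
                rc = depth - ac
            variants.append(make_variant(
                pos=i + 1, sample_id=sample_id, ref=ref, alt=alt,
                variant_class=cls, gene=f"G{int(rng.integers(0, 8)):02d}",
                ref_count=rc, alt_count=ac,
                in_dbsnp=bool(rng.random() < 0.3),
                in_cosmic=bool(rng.random() < 0.2),
            ))
        return SampleVariantSet(sample_id=sample_id, cancer_type=cancer_type,
                                variants=variants)

    return _gen


@pytest.fixture
def maf_file(tmp_path):
    """Write a minimal Mutation Annotation Format file from row dicts."""

    def _write(rows, name="test.maf"):
        cols = ["Hugo_Symbol", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type",
                "Tumor_Sample_Barcode", "t_ref_count", "t_alt_count"]
        path = tmp_path / name
        lines = ["\t".join(cols)]
        for r in rows:
            lines.append("\t".join(str(r.get(c, "")) for c in cols))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def vcf_file(tmp_path):
    """Write a small VCF v4.2 with per-sample AD from record tuples
    (chrom, pos, vid, ref, alts, ad)."""

    def _write(records, name="test.vcf"):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
        )
        lines = []
        for chrom, pos, vid, ref, alts, ad in records:
            gt = "0/1:" + ",".join(str(x) for x in ad)
            lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{','.join(alts)}"
                         f"\t.\tPASS\t.\tGT:AD\t{gt}")
        path = tmp_path / name
        path.write_text(header + "\n".join(lines) + "\n")
        return path

    return _write
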