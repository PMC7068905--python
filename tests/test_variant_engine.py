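"""VCF filtering, mORF-start screening, pseudo-cDNA construction."""

import pytest

from conftest import make_spliced
from uorfkit.variant_engine import (
    FilteredVariant,
    VariantCall,
    accession_variant_set,
    build_pseudo_cdna,
    causal_variants,
    filter_variants,
    screen_morf_start,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FILTER=<ID=LowQual,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestFilterVariants:
    def test_failing_filter_is_dropped(self, tmp_path):
        vcf = _write_vcf(
            tmp_path,
            "chr1\t10\tv1\tC\tA\t50\tLowQual\t.\tGT:AD\t1/1:0,20\t1/1:0,20\n"
            "chr1\t20\tv2\tC\tA\t50\tPASS\t.\tGT:AD\t1/1:0,20\t0/0:20,0\n",
        )
        calls, samples = filter_variants(vcf)
        assert samples == ["sampleA", "sampleB"]
        assert [c.variant.variant_id for c in calls] == ["v2"]

    def test_heterozygous_and_missing_are_not_carriers(self, tmp_path):
        vcf = _write_vcf(
            tmp_path,
            "chr1\t10\tv1\tC\tA\t50\tPASS\t.\tGT:AD\t0/1:10,10\t./.:0,0\n",
        )
        (call,), _ = filter_variants(vcf)
        assert call.hom_alt_accessions == frozenset()

    def test_allele_depth_threshold(self, tmp_path):
        vcf = _write_vcf(
            tmp_path,
            "chr1\t10\tv1\tC\tA\t50\tPASS\t.\tGT:AD\t1/1:0,20\t1/1:10,10\n",
        )
        (call,), _ = filter_variants(vcf, af_threshold=0.90)
        assert call.hom_alt_accessions == frozenset({"sampleA"})
        (call,), _ = filter_variants(vcf, af_threshold=0.40)
        assert call.hom_alt_accessions == frozenset({"sampleA", "sampleB"})

    def test_multiallelic_records_are_split(self, tmp_path):
        vcf = _write_vcf(
            tmp_path,
            "chr1\t10\t.\tC\tA,T\t50\tPASS\t.\tGT:AD\t1/1:0,20,0\t2/2:0,0,20\n",
        )
        calls, _ = filter_variants(vcf)
        assert [(c.variant.alt, sorted(c.hom_alt_accessions)) for c in calls] == [
            ("A", ["sampleA"]),
            ("T", ["sampleB"]),
        ]

    def test_variant_classes(self):
        assert FilteredVariant("v", "c", 0, "C", "A").vclass == "SNP"
        assert FilteredVariant("v", "c", 0, "CAA", "C").vclass == "deletion"
        assert FilteredVariant("v", "c", 0, "C", "CTT").vclass == "insertion"
        assert FilteredVariant("v", "c", 0, "CA", "TG").vclass == "MNP"
        with pytest.raises(ValueError):
            FilteredVariant("v", "c", 0, "C", "C")


def _calls(*variants):
    return [VariantCall(v, frozenset({"acc1"})) for v in variants]


# toy: 22-nt single-exon transcript at genomic 100, leader 13, CDS 9
TOY = "CCATGAAATGAGGATGTTTTAG"


def toy_spliced(strand="+"):
    return make_spliced(TOY, morf_start=13, morf_end=22, offset=100, strand=strand)


class TestScreenMorfStart:
    # the mORF start codon occupies genomic 113..115 on the plus strand
    @pytest.mark.parametrize(
        "variant,keep",
        [
            (FilteredVariant("v", "chr1", 114, "T", "C"), False),  # 2nd codon base
            (FilteredVariant("v", "chr1", 112, "GAT", "G"), False),  # del clips base 1
            (FilteredVariant("v", "chr1", 105, "A", "C"), True),  # 8 nt upstream
        ],
    )
    def test_intersection_rule(self, variant, keep):
        sp = toy_spliced()
        varset = accession_variant_set(sp, "acc1", _calls(variant))
        assert screen_morf_start(sp, varset) is keep


class TestBuildPseudoCDNA:
    def test_single_snp_changes_one_base(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v", "chr1", 105, "A", "C"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        assert len(pseudo.seq) == len(TOY)
        diffs = [i for i, (a, b) in enumerate(zip(TOY, pseudo.seq)) if a != b]
        assert diffs == [5]
        assert pseudo.morf_start == 13

    def test_leader_deletion_shifts_morf_start(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v", "chr1", 105, "AAA", "A"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        assert len(pseudo.seq) == len(TOY) - 2
        assert pseudo.morf_start == 11
        assert pseudo.seq[11:14] == "ATG"

    def test_zero_variants_is_identity(self):
        sp = toy_spliced()
        pseudo = build_pseudo_cdna(sp, accession_variant_set(sp, "acc1", []))
        assert pseudo.seq == TOY
        assert pseudo.anchors == list(range(100, 122))
        assert not any(pseudo.inserted)

    def test_insertion_bases_anchor_to_insertion_point(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v", "chr1", 105, "A", "ACC"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        assert len(pseudo.seq) == len(TOY) + 2
        assert pseudo.anchors[5:9] == [105, 105, 105, 106]
        assert pseudo.inserted[6:8] == [True, True]
        assert pseudo.morf_start == 15

    def test_minus_strand_edit_applied_in_transcript_sense(self):
        # same transcript on the minus strand: genomic base pairs reversed
        sp = toy_spliced(strand="-")
        # transcript offset 5 ('A') sits at genomic 116 and pairs with 'T'
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v", "chr1", 116, "T", "G"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        diffs = [i for i, (a, b) in enumerate(zip(TOY, pseudo.seq)) if a != b]
        assert diffs == [5]
        assert pseudo.seq[5] == "C"

    def test_overlapping_variants_keep_five_prime_most(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp,
            "acc1",
            _calls(
                FilteredVariant("v1", "chr1", 105, "AAA", "A"),
                FilteredVariant("v2", "chr1", 106, "A", "C"),
            ),
        )
        assert [e.variant.variant_id for e in varset.edits] == ["v1"]
        assert [v.variant_id for v, _ in varset.skipped] == ["v2"]

    def test_determinism_across_input_orderings(self):
        sp = toy_spliced()
        variants = [
            FilteredVariant("v1", "chr1", 105, "A", "C"),
            FilteredVariant("v2", "chr1", 108, "T", "G"),
        ]
        a = build_pseudo_cdna(sp, accession_variant_set(sp, "acc1", _calls(*variants)))
        b = build_pseudo_cdna(
            sp, accession_variant_set(sp, "acc1", _calls(*variants[::-1]))
        )
        assert a.seq == b.seq and a.anchors == b.anchors


def _invert(pseudo, reference):
    """Replay the applied edits backwards; must restore the reference.

    Reverting in ascending order keeps every prefix fully restored, so each
    edit's alternate allele sits exactly at its reference transcript offset.
    """
    seq = pseudo.seq
    for edit in sorted(pseudo.applied, key=lambda e: e.tstart):
        start = edit.tstart
        assert seq[start : start + len(edit.tx_alt)] == edit.tx_alt
        seq = seq[:start] + edit.tx_ref + seq[start + len(edit.tx_alt) :]
    return seq


class TestBookkeeping:
    def test_reversibility_and_length_delta(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp,
            "acc1",
            _calls(
                FilteredVariant("v1", "chr1", 105, "AAA", "A"),
                FilteredVariant("v2", "chr1", 109, "G", "GTTTT"),
                FilteredVariant("v3", "chr1", 116, "T", "A"),
            ),
        )
        pseudo = build_pseudo_cdna(sp, varset)
        expected_delta = sum(e.variant.length_delta for e in pseudo.applied)
        assert len(pseudo.seq) - len(TOY) == expected_delta == 2
        assert _invert(pseudo, TOY) == TOY


class TestCausalVariants:
    def test_interior_snp(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v1", "chr1", 105, "A", "C"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        # reference uORF at tx 2..11 -> genomic 102..111
        ids, n_snps, n_indels = causal_variants(pseudo, 102, 111)
        assert (ids, n_snps, n_indels) == (["v1"], 1, 0)

    def test_unrelated_variant_is_not_causal(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp, "acc1", _calls(FilteredVariant("v1", "chr1", 118, "T", "C"))
        )
        pseudo = build_pseudo_cdna(sp, varset)
        ids, n_snps, n_indels = causal_variants(pseudo, 102, 111)
        assert (ids, n_snps, n_indels) == ([], 0, 0)

    def test_stop_destroying_plus_interior_snp_counts_two(self):
        sp = toy_spliced()
        varset = accession_variant_set(
            sp,
            "acc1",
            _calls(
                FilteredVariant("v1", "chr1", 105, "A", "C"),
                FilteredVariant("v2", "chr1", 109, "G", "C"),
            ),
        )
        pseudo = build_pseudo_cdna(sp, varset)
        ids, n_snps, n_indels = causal_variants(pseudo, 102, 111)
        assert (sorted(ids), n_snps, n_indels) == (["v1", "v2"], 2, 0)
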