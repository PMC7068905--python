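"""Gene-model loading, representative selection and coordinate maps."""

import pytest

from uorfkit.genome_annotation import (
    AnnotationError,
    GenomeSequence,
    TranscriptModel,
    load_annotation,
    map_coordinate,
    revcomp,
    select_representative,
    spliced_cdna,
)
from uorfkit.pipeline import scan_reference


def _write_two_exon_gene(tmp_path, strand):
    """A 2-exon gene with a 60-nt leader; the minus-strand version mirrors
    the plus-strand coordinates on the same contig."""
    # exon1: 40nt leader; exon2: 20nt leader + 30nt CDS + 10nt trailer
    leader = "C" * 60
    cds = "ATG" + "GGC" * 8 + "TGA"
    trailer = "G" * 10
    cdna = leader + cds + trailer
    exon1_tx, exon2_tx = cdna[:40], cdna[40:]
    intron = "GTAAGT" + "A" * 20 + "CAG"
    if strand == "+":
        contig = "T" * 10 + exon1_tx + intron + exon2_tx + "T" * 10
        e1 = (10, 50)
        e2 = (50 + len(intron), 50 + len(intron) + len(exon2_tx))
        cds_iv = (e2[0] + 20, e2[0] + 20 + 30)
        utr = [(10, 50), (e2[0], e2[0] + 20)]
    else:
        contig = "T" * 10 + revcomp(exon2_tx) + intron + revcomp(exon1_tx) + "T" * 10
        e2 = (10, 10 + len(exon2_tx))
        e1 = (e2[1] + len(intron), e2[1] + len(intron) + 40)
        cds_iv = (e2[1] - 50, e2[1] - 20)
        utr = [(e2[1] - 20, e2[1]), e1]
    lines = ["##gff-version 3"]

    def feat(ftype, s, e, attrs, phase="."):
        lines.append(
            f"chr1\ttest\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t{attrs}"
        )

    lo = min(e1[0], e2[0])
    hi = max(e1[1], e2[1])
    feat("gene", lo, hi, "ID=G1")
    feat("mRNA", lo, hi, "ID=G1.1;Parent=G1")
    for s, e in sorted([e1, e2]):
        feat("exon", s, e, "Parent=G1.1")
    for s, e in sorted(utr):
        feat("five_prime_UTR", s, e, "Parent=G1.1")
    feat("CDS", cds_iv[0], cds_iv[1], "Parent=G1.1", phase="0")
    fasta = tmp_path / f"g_{'p' if strand == '+' else 'm'}.fa"
    gff = tmp_path / f"g_{'p' if strand == '+' else 'm'}.gff3"
    fasta.write_text(f">chr1\n{contig}\n")
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff, cdna


@pytest.mark.parametrize("strand", ["+", "-"])
def test_two_exon_gene_leader_is_strand_symmetric(tmp_path, strand):
    fasta, gff, cdna = _write_two_exon_gene(tmp_path, strand)
    genome = GenomeSequence.from_fasta(fasta)
    models, excluded = load_annotation(gff, genome)
    assert not excluded
    (model,) = models
    assert model.leader_length == 60
    assert model.cds_length == 30
    spliced = spliced_cdna(model, genome)
    assert spliced.seq == cdna
    assert spliced.morf_start == 60
    assert spliced.seq[60:63] == "ATG"


def test_cds_not_multiple_of_three_is_excluded(tmp_path):
    contig = "A" * 10 + "C" * 20 + "ATG" + "G" * 97 + "C" * 10
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">chr1\n{contig}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tt\tgene\t1\t140\t.\t+\t.\tID=G1\n"
        "chr1\tt\tmRNA\t1\t140\t.\t+\t.\tID=G1.1;Parent=G1\n"
        "chr1\tt\texon\t1\t140\t.\t+\t.\tParent=G1.1\n"
        "chr1\tt\tCDS\t31\t130\t.\t+\t0\tParent=G1.1\n"
    )
    models, excluded = load_annotation(gff, GenomeSequence.from_fasta(fasta))
    assert models == []
    assert excluded == {"G1.1": "CDS not multiple of 3"}


def test_cds_outside_exons_is_rejected(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">chr1\n{'ACGT' * 50}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tt\tgene\t1\t100\t.\t+\t.\tID=G1\n"
        "chr1\tt\tmRNA\t1\t100\t.\t+\t.\tID=G1.1;Parent=G1\n"
        "chr1\tt\texon\t1\t50\t.\t+\t.\tParent=G1.1\n"
        "chr1\tt\tCDS\t40\t99\t.\t+\t0\tParent=G1.1\n"
    )
    with pytest.raises(AnnotationError):
        load_annotation(gff, GenomeSequence.from_fasta(fasta))


def _toy_model(tid, gene="G"):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid,
        contig="chr1",
        strand="+",
        exons=((0, 30),),
        cds=((9, 27),),
    )


def test_representative_selection_rules():
    models = [_toy_model(t) for t in ("G.2", "G.1", "G.3")]
    chosen, _ = select_representative(models)
    assert chosen["G"].transcript_id == "G.1"

    chosen, _ = select_representative([_toy_model("G.2")])
    assert chosen["G"].transcript_id == "G.2"

    chosen, _ = select_representative(models, override={"G": "G.2"})
    assert chosen["G"].transcript_id == "G.2"

    # dotted sub-model ids sort numerically: 0.1 before 0.2 before 1
    models = [_toy_model(t) for t in ("G.0.2", "G.0.1")]
    chosen, _ = select_representative(models)
    assert chosen["G"].transcript_id == "G.0.1"

    _, excluded = select_representative([_toy_model("Gnosuffix")])
    assert "G" in excluded


def test_map_coordinate_anchor_cases():
    genome = GenomeSequence({"chr1": "T" * 100 + "ATGCATGCTTGATTGAGGGCCC" + "T" * 50})
    plus = TranscriptModel("G", "G.1", "chr1", "+", ((100, 122),), ((105, 117),))
    sp = spliced_cdna(plus, genome)
    assert map_coordinate(sp, 0, "to_genome") == 100
    assert map_coordinate(sp, 100, "to_transcript") == 0
    assert map_coordinate(sp, 50, "to_transcript") is None  # intergenic
    minus = TranscriptModel("H", "H.1", "chr1", "-", ((100, 122),), ((105, 117),))
    sm = spliced_cdna(minus, genome)
    assert map_coordinate(sm, 0, "to_genome") == 121
    with pytest.raises(IndexError):
        map_coordinate(sp, 22, "to_genome")


def test_round_trip_identity_on_every_exonic_base(universe):
    scan = scan_reference(universe["genome"], universe["models"])
    for tid, (spliced, _r, _a, _t) in scan.items():
        n = len(spliced.seq)
        assert n == sum(1 for _ in spliced.genome_map)
        for i in range(n):
            g = map_coordinate(spliced, i, "to_genome")
            assert map_coordinate(spliced, g, "to_transcript") == i, tid


def test_length_conservation(universe):
    for model in universe["models"]:
        spliced = spliced_cdna(model, universe["genome"])
        assert len(spliced.seq) == model.exonic_length
        assert (
            model.leader_length + model.cds_length + model.trailer_length
            == model.exonic_length
        )


def test_strand_mirror_leaves_cdna_unchanged(tmp_path):
    """Reverse-complementing the contig and mirroring all coordinates must
    reproduce the identical cDNA."""
    fasta, gff, cdna = _write_two_exon_gene(tmp_path, "+")
    genome = GenomeSequence.from_fasta(fasta)
    (model,) = load_annotation(gff, genome)[0]
    n = len(genome["chr1"])
    mirrored_genome = GenomeSequence({"chr1": revcomp(genome["chr1"])})
    mirror = lambda s, e: (n - e, n - s)
    mirrored = TranscriptModel(
        model.gene_id,
        model.transcript_id,
        "chr1",
        "-",
        tuple(sorted(mirror(s, e) for s, e in model.exons)),
        tuple(sorted(mirror(s, e) for s, e in model.cds)),
    )
    assert spliced_cdna(mirrored, mirrored_genome).seq == cdna
    assert mirrored.leader_length == model.leader_length
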