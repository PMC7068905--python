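"""Anchoring, Level1.Level2 identifier assignment and event calls."""

import random

import pytest

from conftest import make_spliced
from oracles import brute_force_identifiers
from uorfkit.pipeline import analyze_gene
from uorfkit.uorf_finder import find_uorfs
from uorfkit.uorf_indexer import (
    UORFForm,
    UORFIdentifier,
    anchor_uorf,
    assign_identifiers,
    classify_event,
    form_from_record,
    reference_form,
)
from uorfkit.variant_engine import (
    FilteredVariant,
    VariantCall,
    accession_variant_set,
    build_pseudo_cdna,
)

TOY = "CCATGAAATGAGGATGTTTTAG"  # leader 13, uORFs at 2 (Type1) and 7 (Type3)


def toy_spliced():
    return make_spliced(TOY, morf_start=13, morf_end=22, offset=100)


def _pseudo(*variants):
    sp = toy_spliced()
    calls = [VariantCall(v, frozenset({"acc1"})) for v in variants]
    return sp, build_pseudo_cdna(sp, accession_variant_set(sp, "acc1", calls))


class TestAnchoring:
    def test_reference_offset_arithmetic(self):
        sp, pseudo = _pseudo()
        (rec, _t3) = find_uorfs(pseudo)[:2]
        assert anchor_uorf(rec, pseudo) == (102, False)

    def test_anchor_survives_upstream_deletion(self):
        # remove the two leading C's: the uORF shifts to pseudo offset 0 but
        # keeps its reference anchor
        sp, pseudo = _pseudo(FilteredVariant("v", "chr1", 99, "TCC", "T"))
        # deletion anchor base sits outside the transcript: only offsets
        # 100..101 are exonic, so the edit is skipped -- use an exonic one
        sp, pseudo = _pseudo(FilteredVariant("v", "chr1", 100, "CC", "C"))
        rec = find_uorfs(pseudo)[0]
        assert rec.start == 1
        assert anchor_uorf(rec, pseudo) == (102, False)

    def test_start_codon_inside_insertion_flags_origin(self):
        # plant ATGTAA wholly inside an insertion after genomic 110
        sp, pseudo = _pseudo(FilteredVariant("v", "chr1", 110, "A", "AATGTAAC"))
        created = [r for r in find_uorfs(pseudo) if r.start == 11]
        (rec,) = created
        assert anchor_uorf(rec, pseudo) == (110, True)
        form = form_from_record(rec, pseudo)
        assert form.origin == "insertion-bearing"


def _form(anchor, length, seq, origin="snp-only", n_snps=0, n_indels=0, positions=()):
    return UORFForm(
        anchor=anchor,
        length=length,
        sequence=seq,
        origin=origin,
        n_snps=n_snps,
        n_indels=n_indels,
        variant_positions=tuple(positions),
    )


class TestAssignIdentifiers:
    def test_single_invariant_reference_form(self):
        ref = _form(102, 9, "ATGAAATAA", origin="reference")
        ident = assign_identifiers([ref] * 5)
        assert ident[ref.key] == UORFIdentifier(1, 1)

    def test_reference_and_substitution_share_level1(self):
        ref = _form(102, 9, "ATGAAATAA", origin="reference")
        sub = _form(102, 9, "ATGACATAA", n_snps=1, positions=(104,))
        ident = assign_identifiers([ref, sub])
        assert str(ident[ref.key]) == "1.1"
        assert str(ident[sub.key]) == "1.2"

    def test_created_upstream_anchor_takes_level1_one(self):
        ref = _form(102, 9, "ATGAAATAA", origin="reference")
        created = _form(95, 6, "ATGTAA", n_snps=1, positions=(96,))
        ident = assign_identifiers([ref, created])
        assert str(ident[created.key]) == "1.1"
        assert str(ident[ref.key]) == "2.1"

    def test_length_then_origin_class_orders_level1(self):
        ref = _form(102, 9, "ATGAAATAA", origin="reference")
        shorter_del = _form(
            102, 6, "ATGTAA", origin="deletion-bearing", n_indels=1, positions=(104,)
        )
        longer_snp = _form(102, 15, "ATGAAATCACCCTAA", n_snps=1, positions=(109,))
        ins = _form(
            102, 12, "ATGACCCAATAA", origin="insertion-bearing", n_indels=1,
            positions=(105,),
        )
        ident = {
            f.sequence: str(i)
            for f, i in (
                (f, assign_identifiers([ref, shorter_del, longer_snp, ins])[f.key])
                for f in (ref, shorter_del, longer_snp, ins)
            )
        }
        assert ident == {
            "ATGTAA": "1.1",
            "ATGAAATAA": "2.1",
            "ATGACCCAATAA": "3.1",
            "ATGAAATCACCCTAA": "4.1",
        }

    def test_equal_length_deletion_before_insertion(self):
        dele = _form(
            102, 6, "ATGTAA", origin="deletion-bearing", n_indels=1, positions=(103,)
        )
        ins = _form(
            102, 6, "ATGTAA"[:3] + "TGA", origin="insertion-bearing", n_indels=1,
            positions=(104,),
        )
        ident = assign_identifiers([ins, dele])
        assert str(ident[dele.key]) == "1.1"
        assert str(ident[ins.key]) == "2.1"

    def test_permutation_invariance_and_continuity(self):
        rng = random.Random(7)
        forms = [
            _form(102, 9, "ATGAAATAA", origin="reference"),
            _form(102, 9, "ATGACATAA", n_snps=1, positions=(104,)),
            _form(102, 9, "ATGACCTAA", n_snps=2, positions=(104, 105)),
            _form(95, 6, "ATGTAA", n_snps=1, positions=(96,)),
            _form(
                102, 6, "ATGTAA", origin="deletion-bearing", n_indels=1,
                positions=(103,),
            ),
        ]
        baseline = assign_identifiers(forms)
        for _ in range(10):
            shuffled = forms[:]
            rng.shuffle(shuffled)
            assert assign_identifiers(shuffled) == baseline
        level1 = sorted({i.level1 for i in baseline.values()})
        assert level1 == list(range(1, len(level1) + 1))
        for l1 in level1:
            l2s = sorted(i.level2 for i in baseline.values() if i.level1 == l1)
            assert l2s == list(range(1, len(l2s) + 1))

    def test_agrees_with_composite_key_oracle(self):
        forms = [
            _form(102, 9, "ATGAAATAA", origin="reference"),
            _form(102, 9, "ATGACATAA", n_snps=1, positions=(104,)),
            _form(102, 15, "ATGAAATCACCCTAA", n_snps=1, positions=(109,)),
            _form(95, 6, "ATGTAA", n_snps=1, positions=(96,)),
            _form(
                102, 12, "ATGACCCAATAA", origin="insertion-bearing", n_indels=1,
                positions=(105,),
            ),
            _form(
                102, 6, "ATGTAA", origin="deletion-bearing", n_indels=1,
                positions=(103,),
            ),
        ]
        got = {k: str(v) for k, v in assign_identifiers(forms).items()}
        assert got == brute_force_identifiers(forms)


class TestClassifyEvent:
    def test_loss_of_only_uorf(self):
        ref = [_form(102, 9, "ATGAAATAA", origin="reference")]
        events = classify_event(ref, [], "acc1")
        assert [(e.kind, e.anchor) for e in events] == [("loss", 102)]

    def test_stop_snp_is_length_change_plus_type_switch(self):
        ref = [
            UORFForm(102, 6, "ATGTAA", "reference", uorf_type="Type1"),
        ]
        acc = [
            UORFForm(
                102, 12, "ATGTCACCATGA", "snp-only", n_snps=1,
                variant_positions=(106,), uorf_type="Type2",
            ),
        ]
        events = classify_event(ref, acc, "acc1")
        kinds = [(e.kind, e.old_type, e.new_type) for e in events]
        assert ("length_change", None, None) in kinds
        assert ("type_switch", "Type1", "Type2") in kinds

    def test_identical_forms_are_unchanged_with_equal_identifier(self):
        ref = [_form(102, 9, "ATGAAATAA", origin="reference")]
        events = classify_event(ref, ref, "acc1")
        assert [e.kind for e in events] == ["unchanged"]
        ident = assign_identifiers(ref + ref)
        assert len(ident) == 1

    def test_creation(self):
        acc = [_form(95, 6, "ATGTAA", n_snps=1, positions=(96,))]
        events = classify_event([], acc, "acc1")
        assert [(e.kind, e.anchor) for e in events] == [("creation", 95)]

    def test_substitution(self):
        ref = [_form(102, 9, "ATGAAATAA", origin="reference")]
        acc = [_form(102, 9, "ATGACATAA", n_snps=1, positions=(104,))]
        events = classify_event(ref, acc, "acc1")
        assert [e.kind for e in events] == ["substitution"]


class TestFixtureOracleAgreement:
    def test_identifiers_match_oracle_on_every_fixture_gene(self, universe):
        from uorfkit.genome_annotation import spliced_cdna

        for gene_id, model in sorted(universe["representative"].items()):
            spliced = spliced_cdna(model, universe["genome"])
            analysis = analyze_gene(
                gene_id, spliced, universe["calls"], universe["samples"]
            )
            forms = list(analysis.ref_forms)
            for fs in analysis.accession_forms.values():
                forms.extend(fs)
            want = brute_force_identifiers(forms)
            got = {k: str(v) for k, v in analysis.identifiers.items()}
            assert got == want, gene_id
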