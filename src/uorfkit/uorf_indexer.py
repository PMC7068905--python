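"""Reference anchoring and two-level Level1.Level2 uORF-variant identifiers.

Every uORF observed on any accession's pseudo-cDNA is anchored at the
reference genomic coordinate of the first base of its start codon, then
collapsed into "forms": two uORFs with the same anchor and the same
nucleotide sequence are the same form.  Identifiers are assigned per gene:

* Level1 groups forms by (anchor, length, origin class) — i.e. major
  differences: creation, loss or length change through SNPs or INDELs.
  Groups are numbered 1..n by anchor (ascending reference coordinate),
  then length (shorter first), then origin class (reference/SNP-only,
  then deletion-bearing, then insertion-bearing), then the sorted causal
  variant positions.
* Level2 numbers the forms inside one group 1..m by causal SNP count
  (fewer first), then sorted variant positions, then sequence — minor
  differences: nucleotide/amino-acid substitutions through SNPs.

Numbering starts at 1.1 and is gap-free; it is a pure function of the
observed form set, so accession input order never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .uorf_finder import UORFRecord
from .variant_engine import PseudoCDNA, causal_variants

ORIGIN_REFERENCE = "reference"
ORIGIN_SNP_ONLY = "snp-only"
ORIGIN_DELETION = "deletion-bearing"
ORIGIN_INSERTION = "insertion-bearing"

# reference-identical and SNP-only forms share Level1 rank 0: a SNP never
# changes length, so they can only differ from the reference at Level2.
_ORIGIN_RANK = {
    ORIGIN_REFERENCE: 0,
    ORIGIN_SNP_ONLY: 0,
    ORIGIN_DELETION: 1,
    ORIGIN_INSERTION: 2,
}


def origin_class(n_snps: int, n_deletions: int, n_insertions: int) -> str:
    if n_insertions:
        return ORIGIN_INSERTION
    if n_deletions:
        return ORIGIN_DELETION
    if n_snps:
        return ORIGIN_SNP_ONLY
    return ORIGIN_REFERENCE


@dataclass(frozen=True)
class UORFForm:
    """One distinct uORF form: (anchor, sequence) is its identity."""

    anchor: int
    length: int
    sequence: str
    origin: str
    n_snps: int = 0
    n_indels: int = 0
    variant_positions: tuple[int, ...] = ()
    causal_ids: tuple[str, ...] = ()
    uorf_type: str = ""
    insertion_origin: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.anchor, self.sequence)

    @property
    def n_causal(self) -> int:
        return self.n_snps + self.n_indels


@dataclass(frozen=True, order=True)
class UORFIdentifier:
    level1: int
    level2: int

    def __str__(self) -> str:
        return f"{self.level1}.{self.level2}"


def anchor_uorf(
    record: UORFRecord, pseudo: PseudoCDNA
) -> tuple[int, bool]:
    """Reference genomic anchor of a uORF's start codon on a pseudo-cDNA.

    Returns (anchor, insertion_origin).  Start codons created wholly inside
    an insertion anchor to the reference base 5' of the insertion point and
    carry the insertion-origin flag.
    """
    return pseudo.anchor_of(record.start), bool(pseudo.inserted[record.start])


def form_from_record(
    record: UORFRecord,
    pseudo: PseudoCDNA,
) -> UORFForm:
    """Build the anchored form of a terminated uORF on a pseudo-cDNA,
    attaching the causal variants intersecting its reference footprint."""
    if record.stop_end is None:
        raise ValueError("unterminated uORFs are excluded from indexing")
    anchor, ins_origin = anchor_uorf(record, pseudo)
    footprint = [pseudo.anchor_of(o) for o in range(record.start, record.stop_end)]
    lo, hi = min(footprint), max(footprint) + 1
    ids, n_snps, n_indels = causal_variants(pseudo, lo, hi)
    n_del = n_ins = 0
    positions = []
    for edit in pseudo.applied:
        if edit.variant.variant_id in ids:
            positions.append(edit.variant.pos)
            if edit.variant.is_indel:
                if edit.variant.length_delta < 0:
                    n_del += 1
                else:
                    n_ins += 1
    origin = origin_class(n_snps, n_del, n_ins)
    if ins_origin:
        origin = ORIGIN_INSERTION
    return UORFForm(
        anchor=anchor,
        length=record.stop_end - record.start,
        sequence=pseudo.seq[record.start : record.stop_end],
        origin=origin,
        n_snps=n_snps,
        n_indels=n_indels,
        variant_positions=tuple(sorted(positions)),
        causal_ids=tuple(ids),
        uorf_type=record.uorf_type,
        insertion_origin=ins_origin,
    )


def reference_form(record: UORFRecord, spliced) -> UORFForm:
    """Anchored form of a uORF on the reference spliced cDNA (no variants)."""
    if record.stop_end is None:
        raise ValueError("unterminated uORFs are excluded from indexing")
    return UORFForm(
        anchor=spliced.anchor_of(record.start),
        length=record.stop_end - record.start,
        sequence=spliced.seq[record.start : record.stop_end],
        origin=ORIGIN_REFERENCE,
        uorf_type=record.uorf_type,
    )


def assign_identifiers(
    forms: Iterable[UORFForm],
) -> dict[tuple[int, str], UORFIdentifier]:
    """Assign Level1.Level2 identifiers to the full form set of one gene.

    Pure function of the set: duplicates (same anchor and sequence) collapse
    first, so input order and multiplicity are irrelevant.  Indices are
    gap-free starting at 1.1.
    """
    unique: dict[tuple[int, str], UORFForm] = {}
    for form in forms:
        unique.setdefault(form.key, form)
    groups: dict[tuple[int, int, int], list[UORFForm]] = {}
    for form in unique.values():
        gkey = (form.anchor, form.length, _ORIGIN_RANK[form.origin])
        groups.setdefault(gkey, []).append(form)

    def group_sort_key(item):
        (anchor, length, rank), members = item
        tiebreak = min(m.variant_positions for m in members)
        return (anchor, length, rank, tiebreak)

    assignment: dict[tuple[int, str], UORFIdentifier] = {}
    for l1, (gkey, members) in enumerate(
        sorted(groups.items(), key=group_sort_key), start=1
    ):
        members.sort(key=lambda m: (m.n_snps, m.variant_positions, m.sequence))
        for l2, form in enumerate(members, start=1):
            assignment[form.key] = UORFIdentifier(l1, l2)
    return assignment


CREATION = "creation"
LOSS = "loss"
LENGTH_CHANGE = "length_change"
SUBSTITUTION = "substitution"
TYPE_SWITCH = "type_switch"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class VariantEvent:
    """How one accession's uORF complement differs from the reference at one
    reference-anchored locus."""

    kind: str
    accession: str
    anchor: int
    old_type: str | None = None
    new_type: str | None = None


def classify_event(
    reference_forms: Sequence[UORFForm],
    accession_forms: Sequence[UORFForm],
    accession: str,
) -> list[VariantEvent]:
    """Compare an accession's anchored uORF forms against the reference.

    Per locus anchor: present only in the accession -> creation; only in the
    reference -> loss; same anchor but different length -> length_change;
    same anchor and length but different sequence -> substitution; identical
    -> unchanged.  Whenever the uORF type at a shared locus differs an
    additional type_switch event is emitted, annotated with old and new type.
    """
    ref_by_anchor: dict[int, UORFForm] = {f.anchor: f for f in reference_forms}
    acc_by_anchor: dict[int, UORFForm] = {f.anchor: f for f in accession_forms}
    events: list[VariantEvent] = []
    for anchor in sorted(set(ref_by_anchor) | set(acc_by_anchor)):
        ref = ref_by_anchor.get(anchor)
        acc = acc_by_anchor.get(anchor)
        if ref is None and acc is not None:
            events.append(VariantEvent(CREATION, accession, anchor))
            continue
        if ref is not None and acc is None:
            events.append(VariantEvent(LOSS, accession, anchor))
            continue
        assert ref is not None and acc is not None
        if ref.length != acc.length:
            events.append(VariantEvent(LENGTH_CHANGE, accession, anchor))
        elif ref.sequence != acc.sequence:
            events.append(VariantEvent(SUBSTITUTION, accession, anchor))
        else:
            events.append(VariantEvent(UNCHANGED, accession, anchor))
        if ref.uorf_type and acc.uorf_type and ref.uorf_type != acc.uorf_type:
            events.append(
                VariantEvent(
                    TYPE_SWITCH,
                    accession,
                    anchor,
                    old_type=ref.uorf_type,
                    new_type=acc.uorf_type,
                )
            )
    return events
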