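"""VCF filtering, mORF-start screening and per-accession pseudo-cDNAs.

Only homozygous-alternate calls contribute edits: heterozygous and missing
genotypes leave the reference allele in place for that accession.  When
per-sample allele depths (AD) are present, a call additionally needs a
supporting-read fraction of at least ``af_threshold`` (default 0.90); without
AD the threshold is a no-op.  Multi-allelic records are split per alternate
allele.  Records failing FILTER (anything other than PASS/'.') are dropped.

Variant positions are taken as written in the VCF (left-aligned anchor-base
style is assumed); no re-normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .genome_annotation import SplicedCDNA, revcomp

logger = logging.getLogger(__name__)

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
MNP = "MNP"


@dataclass(frozen=True)
class FilteredVariant:
    """One quality-filtered alternate allele, 0-based genomic position."""

    variant_id: str
    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNP
        if len(self.ref) > len(self.alt):
            return DELETION
        if len(self.ref) < len(self.alt):
            return INSERTION
        return MNP

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval replaced by the alternate allele (half-open)."""
        return (self.pos, self.pos + len(self.ref))

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class VariantCall:
    """A filtered variant plus the accessions carrying it homozygously."""

    variant: FilteredVariant
    hom_alt_accessions: frozenset[str]


def filter_variants(
    vcf_path: str,
    af_threshold: float = 0.90,
    accessions: list[str] | None = None,
) -> tuple[list[VariantCall], list[str]]:
    """Read a VCF and return per-allele calls with their homozygous carriers.

    Returns (calls, samples).  ``accessions`` restricts the sample set;
    unknown ids raise.  FILTER failures are dropped; multi-allelic records
    split; per-sample AD fractions below ``af_threshold`` drop that sample's
    call only.
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    if accessions is not None:
        unknown = set(accessions) - set(samples)
        if unknown:
            raise ValueError(f"accessions not in VCF: {sorted(unknown)}")
        wanted = set(accessions)
    else:
        wanted = set(samples)
    calls: list[VariantCall] = []
    for rec in vcf:
        if rec.FILTER is not None:  # None means PASS/'.' in cyvcf2
            continue
        genotypes = rec.genotypes  # [allele1, allele2, phased] per sample
        try:
            ad = rec.format("AD")
        except Exception:
            ad = None
        for allele_idx, alt in enumerate(rec.ALT, start=1):
            if alt is None or alt.startswith("<"):
                continue
            carriers = set()
            for s_idx, sample in enumerate(samples):
                if sample not in wanted:
                    continue
                gt = genotypes[s_idx]
                if len(gt) < 3 or gt[0] != allele_idx or gt[1] != allele_idx:
                    continue
                if ad is not None:
                    depths = np.asarray(ad[s_idx], dtype=float)
                    depths[depths < 0] = 0.0  # missing AD encoded as negatives
                    total = depths.sum()
                    if total > 0 and allele_idx < len(depths):
                        if depths[allele_idx] / total < af_threshold:
                            continue
                carriers.add(sample)
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}:{allele_idx}" if rec.ID else vid
            calls.append(
                VariantCall(
                    FilteredVariant(vid, rec.CHROM, rec.POS - 1, rec.REF, alt),
                    frozenset(carriers),
                )
            )
    return calls, samples


@dataclass(frozen=True)
class TranscriptEdit:
    """A variant expressed in transcript space: replace
    ``seq[tstart:tstart+len(tx_ref)]`` by ``tx_alt`` (both 5'->3' mRNA)."""

    variant: FilteredVariant
    tstart: int
    tx_ref: str
    tx_alt: str

    @property
    def tend(self) -> int:
        return self.tstart + len(self.tx_ref)


@dataclass
class AccessionVariantSet:
    """Filtered homozygous variants of one accession on one transcript,
    projected into transcript space and restricted to the exonic
    leader+CDS span.  Overlapping edits keep the 5'-most; variants crossing
    a splice junction or only partly exonic are skipped with a warning."""

    accession: str
    transcript_id: str
    edits: list[TranscriptEdit] = field(default_factory=list)
    skipped: list[tuple[FilteredVariant, str]] = field(default_factory=list)


def _project_variant(
    spliced: SplicedCDNA, variant: FilteredVariant
) -> TranscriptEdit | None:
    """Express a genomic variant as a transcript-space edit, or None when its
    reference span is not fully and contiguously exonic."""
    lo, hi = variant.span
    offsets = [spliced.offset_of(g) for g in range(lo, hi)]
    if any(o is None for o in offsets):
        return None
    offs = sorted(offsets)  # type: ignore[arg-type]
    if offs[-1] - offs[0] != len(offs) - 1:
        return None  # spans a splice junction
    if spliced.strand == "+":
        tx_ref, tx_alt = variant.ref, variant.alt
    else:
        tx_ref, tx_alt = revcomp(variant.ref), revcomp(variant.alt)
    tstart = offs[0]
    if spliced.seq[tstart : tstart + len(tx_ref)] != tx_ref:
        return None  # reference mismatch
    return TranscriptEdit(variant, tstart, tx_ref, tx_alt)


def accession_variant_set(
    spliced: SplicedCDNA,
    accession: str,
    calls: list[VariantCall],
) -> AccessionVariantSet:
    """Select this accession's homozygous variants touching the transcript's
    exonic leader+CDS span, sorted 5'->3', overlap conflicts resolved in
    favour of the 5'-most edit."""
    varset = AccessionVariantSet(accession, spliced.transcript_id)
    candidates: list[TranscriptEdit] = []
    for call in calls:
        v = call.variant
        if v.contig != spliced.contig or accession not in call.hom_alt_accessions:
            continue
        lo, hi = v.span
        touched = [spliced.offset_of(g) for g in range(lo, hi)]
        exonic = [o for o in touched if o is not None]
        if not exonic:
            continue
        edit = _project_variant(spliced, v)
        if edit is None:
            varset.skipped.append((v, "splice-junction or partly exonic span"))
            logger.warning(
                "%s/%s: variant %s skipped (splice junction or partly exonic)",
                accession,
                spliced.transcript_id,
                v.variant_id,
            )
            continue
        if edit.tstart >= spliced.morf_end:
            continue  # 3' of the mORF stop: cannot affect uORFs
        candidates.append(edit)
    candidates.sort(key=lambda e: (e.tstart, e.tend))
    last_end = -1
    for edit in candidates:
        if edit.tstart < last_end:
            varset.skipped.append((edit.variant, "overlaps a 5' variant"))
            logger.warning(
                "%s/%s: variant %s skipped (overlaps a 5' variant)",
                accession,
                spliced.transcript_id,
                edit.variant.variant_id,
            )
            continue
        varset.edits.append(edit)
        last_end = edit.tend
    return varset


def screen_morf_start(
    spliced: SplicedCDNA, varset: AccessionVariantSet
) -> bool:
    """True (keep) unless any variant's reference span touches one of the
    three genomic bases of the mORF start codon (splice-aware).  The mORF
    start codon is the fixed coordinate that anchors every uORF, so
    accessions in which it is altered are excluded from analysis."""
    codon_bases = {
        spliced.anchor_of(spliced.morf_start + k) for k in range(3)
    }
    for edit in varset.edits:
        lo, hi = edit.variant.span
        if any(lo <= b < hi for b in codon_bases):
            return False
    for variant, _reason in varset.skipped:
        lo, hi = variant.span
        if any(lo <= b < hi for b in codon_bases):
            return False
    return True


@dataclass
class PseudoCDNA:
    """An accession's transcript rebuilt from its filtered variants.

    ``anchors[i]`` is the reference genomic anchor of pseudo base ``i``;
    bases created by insertions anchor to the reference base 5' of the
    insertion point and are flagged in ``inserted``.
    """

    accession: str
    transcript_id: str
    contig: str
    strand: str
    seq: str
    morf_start: int
    morf_end: int
    anchors: list[int]
    inserted: list[bool]
    applied: list[TranscriptEdit]

    def __len__(self) -> int:
        return len(self.seq)

    def anchor_of(self, offset: int) -> int:
        return self.anchors[offset]

    @property
    def applied_variant_ids(self) -> list[str]:
        return [e.variant.variant_id for e in self.applied]


class MorfStartError(ValueError):
    """A variant destroys the mORF initiation codon."""


def _rescan_morf_end(seq: str, morf_start: int, fallback: int) -> int:
    """First in-frame stop downstream of the (pseudo) mORF start; falls back
    to the bookkeeping estimate when a variant removed the mORF stop."""
    for p in range(morf_start, len(seq) - 2, 3):
        if seq[p : p + 3] in ("TAA", "TAG", "TGA"):
            return p + 3
    logger.warning("no in-frame mORF stop found after editing; using shifted estimate")
    return fallback


def build_pseudo_cdna(
    spliced: SplicedCDNA, varset: AccessionVariantSet
) -> PseudoCDNA:
    """Apply an accession's edits to the reference spliced cDNA.

    Edits are applied in descending transcript-offset order so earlier
    offsets stay valid.  The pseudo mORF start is the reference start shifted
    by the summed indel deltas 5' of it; the mORF end is re-derived by an
    in-frame stop scan (variants destroying the mORF stop are logged).
    """
    if not screen_morf_start(spliced, varset):
        raise MorfStartError(
            f"{varset.accession}/{spliced.transcript_id}: variant hits mORF start codon"
        )
    seq = spliced.seq
    anchors = [int(g) for g in spliced.genome_map]
    inserted = [False] * len(seq)
    morf_start = spliced.morf_start
    morf_end_est = spliced.morf_end
    for edit in sorted(varset.edits, key=lambda e: -e.tstart):
        L, M = len(edit.tx_ref), len(edit.tx_alt)
        assert seq[edit.tstart : edit.tend] == edit.tx_ref
        seq = seq[: edit.tstart] + edit.tx_alt + seq[edit.tend :]
        old_anchors = anchors[edit.tstart : edit.tend]
        keep = min(L, M)
        new_anchors = old_anchors[:keep] + [old_anchors[keep - 1]] * (M - keep)
        new_inserted = [False] * keep + [True] * (M - keep)
        anchors[edit.tstart : edit.tend] = new_anchors
        inserted[edit.tstart : edit.tend] = new_inserted
        if edit.tend <= morf_start:
            morf_start += M - L
        if edit.tend <= morf_end_est:
            morf_end_est += M - L
    morf_end = _rescan_morf_end(seq, morf_start, morf_end_est)
    return PseudoCDNA(
        accession=varset.accession,
        transcript_id=spliced.transcript_id,
        contig=spliced.contig,
        strand=spliced.strand,
        seq=seq,
        morf_start=morf_start,
        morf_end=morf_end,
        anchors=anchors,
        inserted=inserted,
        applied=list(varset.edits),
    )


def causal_variants(
    pseudo: PseudoCDNA,
    anchor_lo: int,
    anchor_hi: int,
) -> tuple[list[str], int, int]:
    """Applied variants whose reference spans intersect a reference-anchored
    genomic interval [anchor_lo, anchor_hi), with counts split by class.

    The interval is typically a uORF's footprint (start codon through stop
    codon) in reference coordinates; for creations and losses it covers the
    bases forming or destroying the start/stop.
    """
    ids: list[str] = []
    n_snps = n_indels = 0
    for edit in pseudo.applied:
        lo, hi = edit.variant.span
        if lo < anchor_hi and hi > anchor_lo:
            ids.append(edit.variant.variant_id)
            if edit.variant.is_indel:
                n_indels += 1
            else:
                n_snps += 1
    return ids, n_snps, n_indels
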