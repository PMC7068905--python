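"""uORF scanning, Type1/2/3 classification, initiation-codon context.

A uORF is any open reading frame whose start codon lies in the 5' leader
(start offset strictly upstream of the mORF start codon).  Translation runs
codon by codon from the start until the first in-frame stop (TAA/TAG/TGA)
anywhere in the transcript; uORFs with no stop before the transcript end are
recorded as "unterminated" and excluded from type statistics.

Type classification by the stop-codon position relative to the mORF:

* Type1 — stop codon still in the leader (reinitiation possible);
* Type2 — stop inside the mORF region, out of frame (reinitiation impossible);
* Type3 — in frame with the mORF and sharing its stop codon (N-extension).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genome_annotation import SplicedCDNA, VALID_ALPHABET

import numpy as np

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG",)

TYPE1 = "Type1"
TYPE2 = "Type2"
TYPE3 = "Type3"
UNTERMINATED = "unterminated"


@dataclass(frozen=True)
class UORFRecord:
    """One uORF on one (pseudo-)cDNA, transcript coordinates.

    ``stop_end`` is exclusive (last base of the stop codon + 1) and None for
    unterminated uORFs.  ``length_nt`` includes the stop codon, so the minimal
    uORF (a start codon directly followed by a stop) has length 6.  ``space3``
    is signed: negative values mean the uORF overlaps the mORF (Type2/3).
    """

    transcript_id: str
    start: int
    stop_end: int | None
    uorf_type: str
    length_nt: int | None
    peptide: str
    icc: str
    kozak: bool
    space5: int
    space3: int | None
    start_codon: str

    @property
    def terminated(self) -> bool:
        return self.stop_end is not None


def classify_type(start: int, stop_end: int | None, morf_start: int, morf_end: int) -> str:
    """Type of a uORF given its start and (exclusive) stop end.

    In-frame uORFs either terminate in the leader (Type1) or run into the
    mORF reading frame, where the first stop they can meet is the mORF's own
    stop codon (Type3).  Out-of-frame uORFs terminating anywhere past the
    mORF start are Type2.
    """
    if stop_end is None:
        return UNTERMINATED
    if stop_end <= morf_start:
        return TYPE1
    if (morf_start - start) % 3 == 0 and stop_end == morf_end:
        return TYPE3
    return TYPE2


def extract_icc(seq: str, start: int) -> str:
    """7-mer initiation-codon context, positions -3..+4 around a start codon
    (A of ATG = +1), 'N'-padded where the window leaves the transcript."""
    if not 0 <= start < len(seq) - 2:
        raise ValueError(f"start offset {start} leaves no room for a codon")
    lo, hi = start - 3, start + 4
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    return "N" * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + "N" * right_pad


def is_kozak(icc: str) -> bool:
    """True iff the context matches the Kozak consensus (A/G)CCxxxG: -3 is a
    purine, -2 and -1 are C, +4 is G.  Padded ('N') positions never match."""
    if len(icc) != 7:
        raise ValueError("ICC must be exactly 7 nucleotides")
    return icc[0] in "AG" and icc[1] == "C" and icc[2] == "C" and icc[6] == "G"


def _translate(seq: str) -> str:
    """Amino-acid string of complete codons, standard code, stop excluded."""
    usable = seq[: len(seq) - len(seq) % 3]
    if not usable:
        return ""
    return str(Seq(usable).translate(table=1))


def _frame_stop_index(seq: str) -> list[list[int]]:
    """Per-frame sorted positions p (p % 3 == frame) where seq[p:p+3] is a stop."""
    frames: list[list[int]] = [[], [], []]
    for p in range(len(seq) - 2):
        if seq[p : p + 3] in STOP_CODONS:
            frames[p % 3].append(p)
    return frames


def find_uorfs(
    spliced: SplicedCDNA,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[UORFRecord]:
    """Scan the 5' leader of a spliced (pseudo-)cDNA for uORFs.

    Every occurrence of a configured start codon at an offset strictly less
    than the mORF start yields one record; overlapping and nested uORFs are
    all reported, sorted by start offset.  A zero-length leader yields an
    empty list.  Non-A/C/G/T/N characters in the sequence are an error.
    """
    starts = {c.upper() for c in start_codons}
    if not starts:
        raise ValueError("start-codon set must be non-empty")
    seq = spliced.seq
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"cDNA contains invalid characters: {sorted(bad)}")
    morf_start, morf_end = spliced.morf_start, spliced.morf_end
    if morf_start == 0:
        return []
    stop_index = _frame_stop_index(seq)
    records: list[UORFRecord] = []
    for i in range(morf_start):
        codon = seq[i : i + 3]
        if codon not in starts:
            continue
        frame = stop_index[i % 3]
        # first stop at or after the codon following the start
        j = bisect_left(frame, i + 3)
        stop_end: int | None = frame[j] + 3 if j < len(frame) else None
        utype = classify_type(i, stop_end, morf_start, morf_end)
        if stop_end is not None:
            length = stop_end - i
            peptide = _translate(seq[i : stop_end - 3])
            space3 = morf_start - stop_end
        else:
            length = None
            peptide = _translate(seq[i:])
            space3 = None
        icc = extract_icc(seq, i)
        records.append(
            UORFRecord(
                transcript_id=spliced.transcript_id,
                start=i,
                stop_end=stop_end,
                uorf_type=utype,
                length_nt=length,
                peptide=peptide,
                icc=icc,
                kozak=is_kozak(icc),
                space5=i,
                space3=space3,
                start_codon=codon,
            )
        )
    return records


UORF_FREE = "uORF-free"
TYPE1_ONLY = "Type1-only"
TYPE2_CLASS = "Type2"


def gene_type_attribute(records: Sequence[UORFRecord]) -> tuple[str, bool]:
    """Three-way gene attribute plus a separate has-Type3 flag.

    Only terminated, ATG-initiated uORFs count.  A model with at least one
    Type2 uORF is "Type2" (even if Type1 uORFs co-occur); one with Type1 but
    no Type2 is "Type1-only"; otherwise "uORF-free".  Type3 never changes the
    three-way class and is reported separately.
    """
    counted = [
        r for r in records if r.terminated and r.start_codon == "ATG"
    ]
    has_t1 = any(r.uorf_type == TYPE1 for r in counted)
    has_t2 = any(r.uorf_type == TYPE2 for r in counted)
    has_t3 = any(r.uorf_type == TYPE3 for r in counted)
    if has_t2:
        return TYPE2_CLASS, has_t3
    if has_t1:
        return TYPE1_ONLY, has_t3
    return UORF_FREE, has_t3


class CDSPlacementError(ValueError):
    """The CDS sequence does not occur exactly once in the cDNA."""


def scan_cdna_with_cds(
    cdna: str,
    cds: str,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    transcript_id: str = "query",
) -> list[UORFRecord]:
    """Single-sequence mode: locate the CDS in the cDNA by exact substring
    match and scan the implied leader for uORFs.

    Zero or multiple CDS matches raise :class:`CDSPlacementError`.
    """
    cdna = cdna.upper().replace("U", "T")
    cds = cds.upper().replace("U", "T")
    hits = []
    pos = cdna.find(cds)
    while pos != -1:
        hits.append(pos)
        pos = cdna.find(cds, pos + 1)
    if not hits:
        raise CDSPlacementError("CDS sequence not found in cDNA")
    if len(hits) > 1:
        raise CDSPlacementError(
            f"ambiguous CDS placement: {len(hits)} matches in cDNA"
        )
    morf_start = hits[0]
    spliced = SplicedCDNA(
        transcript_id=transcript_id,
        contig=transcript_id,
        strand="+",
        seq=cdna,
        morf_start=morf_start,
        morf_end=morf_start + len(cds),
        genome_map=np.arange(len(cdna), dtype=np.int64),
    )
    return find_uorfs(spliced, start_codons)
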