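"""Gene models, spliced cDNAs and transcript/genome coordinate maps.

All coordinates inside the package are 0-based, half-open on the forward
genomic strand; GFF3 (1-based, inclusive) and VCF (1-based) are converted at
the I/O boundary.  The genomic "anchor" of any mRNA base is always the
forward-strand reference coordinate of the paired base, so anchors from
minus-strand transcripts are directly comparable with VCF positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for structurally invalid gene annotation records."""


class GenomeSequence:
    """Mapping of contig id to an upper-case nucleotide string.

    Thin container so tests can build genomes from dicts while production
    code loads FASTA through :func:`GenomeSequence.from_fasta` (pyfaidx).
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise AnnotationError("genome has no contigs")
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise AnnotationError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains characters outside A/C/G/T/N: {sorted(bad)}"
                )
            self._contigs[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def __getitem__(self, contig: str) -> str:
        return self._contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def keys(self):
        return self._contigs.keys()

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand slice, 0-based half-open, bounds-checked."""
        seq = self._contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise AnnotationError(
                f"interval [{start},{end}) outside contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """One splicing model: exon structure plus the CDS span, genomic coordinates.

    ``exons`` and ``cds`` are tuples of (start, end) half-open intervals on the
    forward strand, sorted by genomic coordinate regardless of strand.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{start},{end})")
            if start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        for cstart, cend in self.cds:
            if not any(s <= cstart and cend <= e for s, e in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{cstart},{cend}) not contained in an exon"
                )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))

    @property
    def leader_length(self) -> int:
        """Exonic bases 5' of the CDS start, in transcript orientation."""
        lo, hi = self.cds_span
        if self.strand == "+":
            return sum(min(e, lo) - s for s, e in self.exons if s < lo)
        return sum(e - max(s, hi) for s, e in self.exons if e > hi)

    @property
    def trailer_length(self) -> int:
        return self.exonic_length - self.leader_length - self.cds_length


@dataclass
class SplicedCDNA:
    """Spliced mRNA sequence with a per-base map back to genomic coordinates.

    ``genome_map[i]`` is the forward-strand genomic coordinate of cDNA base
    ``i``; it is strictly increasing for plus-strand transcripts and strictly
    decreasing for minus-strand ones.
    """

    transcript_id: str
    contig: str
    strand: str
    seq: str
    morf_start: int
    morf_end: int
    genome_map: np.ndarray
    _tx_of_genomic: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._tx_of_genomic:
            self._tx_of_genomic = {int(g): i for i, g in enumerate(self.genome_map)}

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def leader_length(self) -> int:
        return self.morf_start

    def anchor_of(self, offset: int) -> int:
        """Genomic anchor of a transcript offset (forward-strand coordinate)."""
        if not 0 <= offset < len(self.seq):
            raise IndexError(f"transcript offset {offset} outside [0,{len(self.seq)})")
        return int(self.genome_map[offset])

    def offset_of(self, genomic: int) -> int | None:
        """Transcript offset of a genomic coordinate, or None if not exonic."""
        return self._tx_of_genomic.get(genomic)


def load_annotation(
    gff3_path: str | Path,
    genome: GenomeSequence,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Parse a GFF3 file into transcript models.

    Returns (models, excluded) where ``excluded`` maps transcript id to the
    reason it was dropped from uORF analysis (CDS length not a multiple of 3,
    CDS shorter than two codons, or non-zero phase on the first CDS segment).
    Transcripts with a zero-length leader are retained but flagged
    ``no_annotated_leader``; downstream scanning skips them.

    A CDS segment falling outside the exon union is a structural error and
    raises :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    excluded: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_feats = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        if not exons or not cds_feats:
            excluded[tid] = "missing exon or CDS features"
            logger.warning("%s: %s", tid, excluded[tid])
            continue
        cds = tuple((f.start - 1, f.end) for f in cds_feats)
        if mrna.seqid not in genome:
            raise AnnotationError(f"{tid}: contig {mrna.seqid!r} not in genome")
        model = TranscriptModel(
            gene_id=gene_id,
            transcript_id=tid,
            contig=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            cds=cds,
        )
        first_cds = cds_feats[0] if mrna.strand == "+" else cds_feats[-1]
        phase = first_cds.frame
        if phase not in (".", "0", None):
            excluded[tid] = f"first CDS segment has phase {phase}"
            logger.warning("%s excluded: %s", tid, excluded[tid])
            continue
        if model.cds_length % 3 != 0:
            excluded[tid] = "CDS not multiple of 3"
            logger.warning("%s excluded: %s", tid, excluded[tid])
            continue
        if model.cds_length < 6:
            excluded[tid] = "CDS shorter than two codons"
            logger.warning("%s excluded: %s", tid, excluded[tid])
            continue
        flags = []
        if model.leader_length == 0:
            flags.append("no_annotated_leader")
        if flags:
            model = TranscriptModel(
                model.gene_id,
                model.transcript_id,
                model.contig,
                model.strand,
                model.exons,
                model.cds,
                tuple(flags),
            )
        models.append(model)
    return models, excluded


_DEFAULT_SUFFIX_RE = re.compile(r"\.((?:\d+\.)*\d+)$")


def model_suffix_key(
    transcript_id: str, pattern: re.Pattern = _DEFAULT_SUFFIX_RE
) -> tuple[int, ...] | None:
    """Numeric sort key of a splicing-model suffix, e.g. 'g1.2' -> (2,),
    'g1.0.1' -> (0, 1).  None when the id carries no parsable suffix."""
    m = pattern.search(transcript_id)
    if not m:
        return None
    return tuple(int(p) for p in m.group(1).split("."))


def select_representative(
    models: Iterable[TranscriptModel],
    override: Mapping[str, str] | None = None,
    pattern: re.Pattern = _DEFAULT_SUFFIX_RE,
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Pick one representative splicing model per gene.

    The model with the numerically smallest dotted suffix wins (".1" before
    ".2"; "0.1" before "0.2"), unless ``override`` maps the gene id to an
    explicit transcript id.  Genes whose models have no parsable suffix and no
    override are excluded with a logged reason.
    """
    override = override or {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    chosen: dict[str, TranscriptModel] = {}
    excluded: dict[str, str] = {}
    for gene_id, cands in by_gene.items():
        if gene_id in override:
            wanted = override[gene_id]
            match = [m for m in cands if m.transcript_id == wanted]
            if not match:
                excluded[gene_id] = f"override model {wanted!r} not found"
                logger.warning("%s excluded: %s", gene_id, excluded[gene_id])
                continue
            chosen[gene_id] = match[0]
            continue
        keyed = [(model_suffix_key(m.transcript_id, pattern), m) for m in cands]
        keyed = [(k, m) for k, m in keyed if k is not None]
        if not keyed:
            excluded[gene_id] = "no parsable model suffix and no override"
            logger.warning("%s excluded: %s", gene_id, excluded[gene_id])
            continue
        chosen[gene_id] = min(keyed, key=lambda km: km[0])[1]
    return chosen, excluded


def spliced_cdna(transcript: TranscriptModel, genome: GenomeSequence) -> SplicedCDNA:
    """Concatenate exon sequences in transcription order (minus strand
    reverse-complemented) and build the per-base genome map."""
    pieces: list[str] = []
    coords: list[np.ndarray] = []
    exons = transcript.exons if transcript.strand == "+" else transcript.exons[::-1]
    for start, end in exons:
        block = genome.fetch(transcript.contig, start, end)
        positions = np.arange(start, end, dtype=np.int64)
        if transcript.strand == "-":
            block = revcomp(block)
            positions = positions[::-1]
        pieces.append(block)
        coords.append(positions)
    seq = "".join(pieces)
    genome_map = np.concatenate(coords)
    leader = transcript.leader_length
    morf_end = leader + transcript.cds_length
    cdna = SplicedCDNA(
        transcript_id=transcript.transcript_id,
        contig=transcript.contig,
        strand=transcript.strand,
        seq=seq,
        morf_start=leader,
        morf_end=morf_end,
        genome_map=genome_map,
    )
    start_codon = seq[leader : leader + 3]
    if start_codon != "ATG":
        logger.warning(
            "%s: mORF start codon is %s, not ATG", transcript.transcript_id, start_codon
        )
    return cdna


def map_coordinate(
    spliced: SplicedCDNA, position: int, direction: str
) -> int | None:
    """Convert between transcript offsets and genomic coordinates.

    ``direction`` is ``"to_genome"`` (raises on out-of-range offsets) or
    ``"to_transcript"`` (returns None for intronic/intergenic coordinates).
    Round-tripping is the identity on every exonic base.
    """
    if direction == "to_genome":
        return spliced.anchor_of(position)
    if direction == "to_transcript":
        return spliced.offset_of(position)
    raise ValueError(f"unknown direction {direction!r}")
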