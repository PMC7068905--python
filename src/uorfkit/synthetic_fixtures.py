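"""Self-contained synthetic test universes with planted uORFs and variants.

The generator emits a genome FASTA, a GFF3 annotation, a multi-sample VCF,
an accession-metadata table and a machine-readable truth table that are
mutually consistent by construction.  Genes are built from hand-verified
sequence templates (one per archetype) embedded in inert padding:

* padding inside transcripts uses only C/G, so it can never contain or help
  form a start codon (needs A and T) or a stop codon (needs A) — every ATG
  and stop in a leader is planted deliberately;
* each archetype plants uORFs of a known type and carries "dormant" sites
  where a single SNP or INDEL realizes one population event (creation, loss,
  length change, substitution, type switch, or a mORF-start hit that gets
  the accession screened out).

All randomness is integer-only (``random.Random.randrange``/``sample``), so
a seed fully determines the output bytes on any platform.  An internal naive
re-scan (independent of the scanning module under test) verifies every
planted uORF and every event outcome before files are written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from random import Random
from typing import Sequence

from .genome_annotation import revcomp

STOPS = ("TAA", "TAG", "TGA")


class FixtureError(RuntimeError):
    """An infeasible configuration or a failed internal consistency check."""


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of one synthetic universe.  Rates are per accession x gene and
    at most one event is planted per pair; the seed fixes output bytes."""

    n_genes: int = 10
    n_accessions: int = 20
    exon_range: tuple[int, int] = (1, 3)
    strand_mix: bool = True
    pad5_range: tuple[int, int] = (8, 30)
    event_rates: dict = field(
        default_factory=lambda: {
            "morf_hit": 0.05,
            "creation": 0.30,
            "loss": 0.25,
            "length_change": 0.30,
            "substitution": 0.30,
            "type_switch": 0.30,
        }
    )
    distractor_rate: float = 0.5
    seed: int = 0
    contig: str = "chr1"
    archetypes: tuple[str, ...] | None = None

    def __post_init__(self):
        for kind, rate in self.event_rates.items():
            if not 0 <= rate <= 1:
                raise FixtureError(f"event rate {kind}={rate} outside [0,1]")
        if self.exon_range[0] < 1 or self.exon_range[1] > 3:
            raise FixtureError("exons per gene must lie in 1..3")
        if self.pad5_range[0] < 4:
            raise FixtureError("leader padding must be at least 4 nt")


@dataclass
class Realization:
    """One concrete way an event kind plays out on one gene: the transcript-
    space edits plus the expected uORF form they produce (None for loss and
    mORF-start hits)."""

    name: str
    kind: str
    edits: tuple[tuple[int, str, str], ...]  # (tx offset, ref, alt), mRNA sense
    locus_tx: int | None
    form: dict | None  # {"tx_start","type","length","sequence"}
    origin_rank: int = 0  # 0 SNP-only, 1 deletion-bearing, 2 insertion-bearing


@dataclass
class GeneFixture:
    gene_id: str
    archetype: str
    strand: str
    cdna: str
    core: int
    morf_start: int
    morf_end: int
    tx_exons: list[tuple[int, int]]
    tx2g: list[int]
    gene_start: int
    gene_end: int
    trim_tx: int | None
    ref_uorfs: list[dict]  # {"tx_start","type","length","sequence"}
    events: dict[str, list[Realization]]


# ---------------------------------------------------------------------------
# archetype templates (each hand-verified; see the naive re-scan below)

_INERT = "CG"
_CDS_CODONS = ("GGC", "GCC", "CTC", "GTC", "TCC", "CGG")


def _pad(rng: Random, n: int) -> str:
    return "".join(_INERT[rng.randrange(2)] for _ in range(n))


def _rand_seq(rng: Random, n: int) -> str:
    return "".join("ACGT"[rng.randrange(4)] for _ in range(n))


def _generic_cds(rng: Random) -> str:
    n = rng.randrange(2, 6)
    body = "".join(_CDS_CODONS[rng.randrange(len(_CDS_CODONS))] for _ in range(n))
    return "ATG" + body + "TGA"


def _uorf(tx_start: int, utype: str, length: int, sequence: str) -> dict:
    return {
        "tx_start": tx_start,
        "type": utype,
        "length": length,
        "sequence": sequence,
    }


def _arch_type1_events() -> dict:
    tpl = "ATGAAATAACCCTAA"
    return {
        "leader_tpl": tpl,
        "cds": None,
        "ref_uorfs": [_uorf(0, "Type1", 9, "ATGAAATAA")],
        "trim_rel": len(tpl) + 3,  # model .2 starts inside the mid padding
        "events": {
            "loss": [Realization("loss", "loss", ((1, "T", "C"),), 0, None)],
            "substitution": [
                Realization(
                    "sub1",
                    "substitution",
                    ((4, "A", "C"),),
                    0,
                    _uorf(0, "Type1", 9, "ATGACATAA"),
                ),
                Realization(
                    "sub2",
                    "substitution",
                    ((4, "A", "C"), (5, "A", "C")),
                    0,
                    _uorf(0, "Type1", 9, "ATGACCTAA"),
                ),
            ],
            "length_change": [
                Realization(
                    "len_snp",
                    "length_change",
                    ((7, "A", "C"),),
                    0,
                    _uorf(0, "Type1", 15, "ATGAAATCACCCTAA"),
                ),
                Realization(
                    "len_del",
                    "length_change",
                    ((2, "GAAA", "G"),),
                    0,
                    _uorf(0, "Type1", 6, "ATGTAA"),
                    origin_rank=1,
                ),
                Realization(
                    "len_ins",
                    "length_change",
                    ((3, "A", "ACCC"),),
                    0,
                    _uorf(0, "Type1", 12, "ATGACCCAATAA"),
                    origin_rank=2,
                ),
            ],
        },
    }


def _arch_type2() -> dict:
    # leader tail "AATGC" runs straight into the CDS; the uORF at +1 stops
    # out of frame inside the mORF (Type2).
    return {
        "leader_tpl": "AATGC",
        "cds": "ATGCTTGATTGA",
        "ref_uorfs": [_uorf(1, "Type2", 12, "ATGCATGCTTGA")],
        "trim_rel": 4,  # model .2 leader is the single base "C": uORF-free
        "events": {
            "loss": [Realization("loss", "loss", ((2, "T", "C"),), 1, None)],
            "substitution": [
                Realization(
                    "sub",
                    "substitution",
                    ((4, "C", "G"),),
                    1,
                    _uorf(1, "Type2", 12, "ATGGATGCTTGA"),
                )
            ],
            "morf_hit": [
                Realization("morf_hit", "morf_hit", ((6, "T", "C"),), None, None)
            ],
        },
    }


def _arch_type3() -> dict:
    # in-frame uORF sharing the mORF stop (N-extension).
    return {
        "leader_tpl": "ATGAGG",
        "cds": "ATGTTTTAG",
        "ref_uorfs": [_uorf(0, "Type3", 15, "ATGAGGATGTTTTAG")],
        "trim_rel": None,
        "events": {
            "loss": [Realization("loss", "loss", ((1, "T", "C"),), 0, None)],
        },
    }


def _arch_minimal() -> dict:
    return {
        "leader_tpl": "ATGTAA",
        "cds": None,
        "ref_uorfs": [_uorf(0, "Type1", 6, "ATGTAA")],
        "trim_rel": None,
        "events": {
            "loss": [Realization("loss", "loss", ((1, "T", "C"),), 0, None)],
        },
    }


def _arch_free_creation() -> dict:
    # dormant motif: one SNP away from the minimal uORF.
    return {
        "leader_tpl": "ACGTAA",
        "cds": None,
        "ref_uorfs": [],
        "trim_rel": None,
        "events": {
            "creation": [
                Realization(
                    "creation",
                    "creation",
                    ((1, "C", "T"),),
                    0,
                    _uorf(0, "Type1", 6, "ATGTAA"),
                )
            ],
        },
    }


def _arch_typeswitch() -> dict:
    # destroying the Type1 stop extends the uORF out of frame into the mORF.
    return {
        "leader_tpl": "ATGTAACC",
        "cds": "ATGATGAGGTAA",
        "ref_uorfs": [_uorf(0, "Type1", 6, "ATGTAA")],
        "trim_rel": None,
        "events": {
            "type_switch": [
                Realization(
                    "ts",
                    "type_switch",
                    ((4, "A", "C"),),
                    0,
                    _uorf(0, "Type2", 12, "ATGTCACCATGA"),
                )
            ],
        },
    }


def _arch_t1t2_models() -> dict:
    # model .1 carries a long Type2 uORF plus a nested Type1; model .2 trims
    # the leader past the Type2 start codon and becomes Type1-only.
    return {
        "leader_tpl": "ATGGATGTAACCC",
        "cds": "ATGCTTGATTGA",
        "ref_uorfs": [
            _uorf(0, "Type2", 21, "ATGGATGTAACCCATGCTTGA"),
            _uorf(4, "Type1", 6, "ATGTAA"),
        ],
        "trim_rel": 4,
        "events": {},
    }


ARCHETYPES = {
    "type1_events": _arch_type1_events,
    "type2": _arch_type2,
    "type3": _arch_type3,
    "minimal": _arch_minimal,
    "free_creation": _arch_free_creation,
    "typeswitch": _arch_typeswitch,
    "t1t2_models": _arch_t1t2_models,
}

_ARCH_CYCLE = (
    "type1_events",
    "type2",
    "type3",
    "minimal",
    "free_creation",
    "typeswitch",
    "t1t2_models",
)


# ---------------------------------------------------------------------------
# independent naive re-scan used to verify every planted construction

def _naive_scan(cdna: str, morf_start: int, morf_end: int) -> list[dict]:
    """Position-by-position leader walk, codon-wise translation to the first
    stop.  Deliberately naive; exists only to certify the planted truth."""
    found = []
    for i in range(morf_start):
        if cdna[i : i + 3] != "ATG":
            continue
        j = i + 3
        stop_end = None
        while j + 3 <= len(cdna):
            if cdna[j : j + 3] in STOPS:
                stop_end = j + 3
                break
            j += 3
        if stop_end is None:
            found.append({"tx_start": i, "type": "unterminated", "length": None})
            continue
        if stop_end <= morf_start:
            utype = "Type1"
        elif (morf_start - i) % 3 == 0 and stop_end == morf_end:
            utype = "Type3"
        else:
            utype = "Type2"
        found.append(
            {
                "tx_start": i,
                "type": utype,
                "length": stop_end - i,
                "sequence": cdna[i:stop_end],
            }
        )
    return found


def _apply_edits(cdna: str, morf_start: int, edits: Sequence[tuple[int, str, str]]):
    seq = cdna
    shift_5prime = 0
    for off, ref, alt in sorted(edits, key=lambda e: -e[0]):
        if seq[off : off + len(ref)] != ref:
            raise FixtureError(f"edit reference mismatch at transcript offset {off}")
        seq = seq[:off] + alt + seq[off + len(ref) :]
        if off + len(ref) <= morf_start:
            shift_5prime += len(alt) - len(ref)
    return seq, morf_start + shift_5prime


def _verify_gene(gene: GeneFixture) -> None:
    def check_model(cdna, morf_start, morf_end, expected, label):
        got = [u for u in _naive_scan(cdna, morf_start, morf_end) if u["length"]]
        want = sorted(expected, key=lambda u: u["tx_start"])
        got_key = [(u["tx_start"], u["type"], u["length"], u["sequence"]) for u in got]
        want_key = [
            (u["tx_start"], u["type"], u["length"], u["sequence"]) for u in want
        ]
        if got_key != want_key:
            raise FixtureError(
                f"{gene.gene_id} ({label}): planted uORFs {want_key} != scanned {got_key}"
            )

    check_model(gene.cdna, gene.morf_start, gene.morf_end, gene.ref_uorfs, "model .1")
    if gene.trim_tx is not None:
        trimmed = gene.cdna[gene.trim_tx :]
        shifted = [
            {**u, "tx_start": u["tx_start"] - gene.trim_tx}
            for u in _model2_uorfs(gene)
        ]
        check_model(
            trimmed,
            gene.morf_start - gene.trim_tx,
            gene.morf_end - gene.trim_tx,
            shifted,
            "model .2",
        )
    for reals in gene.events.values():
        for real in reals:
            if real.kind == "morf_hit":
                continue
            edits = tuple((off, ref, alt) for off, ref, alt in real.edits)
            seq, new_morf = _apply_edits(gene.cdna, gene.morf_start, edits)
            morf_end = _morf_end_of(seq, new_morf)
            scanned = {
                u["tx_start"]: u
                for u in _naive_scan(seq, new_morf, morf_end)
                if u["length"]
            }
            if real.form is None:
                if real.locus_tx in scanned:
                    raise FixtureError(
                        f"{gene.gene_id}/{real.name}: lost uORF still detected"
                    )
                continue
            got = scanned.get(real.form["tx_start"])
            want = real.form
            if (
                got is None
                or got["type"] != want["type"]
                or got["length"] != want["length"]
                or got["sequence"] != want["sequence"]
            ):
                raise FixtureError(
                    f"{gene.gene_id}/{real.name}: event outcome {got} != planted {want}"
                )


def _morf_end_of(seq: str, morf_start: int) -> int:
    for p in range(morf_start, len(seq) - 2, 3):
        if seq[p : p + 3] in STOPS:
            return p + 3
    raise FixtureError("mORF has no stop codon")


def _model2_uorfs(gene: GeneFixture) -> list[dict]:
    assert gene.trim_tx is not None
    kept = []
    for u in gene.ref_uorfs:
        if u["tx_start"] >= gene.trim_tx:
            kept.append(dict(u))
    return kept


# ---------------------------------------------------------------------------
# reference build


@dataclass
class ReferenceFixture:
    config: FixtureConfig
    contig: str
    contig_seq: str
    genes: list[GeneFixture]

    def truth_reference(self) -> dict:
        out = {}
        for g in self.genes:
            models = {
                f"{g.gene_id}.1": _model_truth(g, trim=0, uorfs=g.ref_uorfs),
            }
            if g.trim_tx is not None:
                models[f"{g.gene_id}.2"] = _model_truth(
                    g, trim=g.trim_tx, uorfs=_model2_uorfs(g)
                )
            out[g.gene_id] = {
                "archetype": g.archetype,
                "strand": g.strand,
                "models": models,
            }
        return out


def _attribute_of(uorfs: Sequence[dict]) -> tuple[str, bool]:
    has_t1 = any(u["type"] == "Type1" for u in uorfs)
    has_t2 = any(u["type"] == "Type2" for u in uorfs)
    has_t3 = any(u["type"] == "Type3" for u in uorfs)
    if has_t2:
        return "Type2", has_t3
    if has_t1:
        return "Type1-only", has_t3
    return "uORF-free", has_t3


def _model_truth(gene: GeneFixture, trim: int, uorfs: Sequence[dict]) -> dict:
    attr, has_t3 = _attribute_of(uorfs)
    return {
        "leader_length": gene.morf_start - trim,
        "attribute": attr,
        "has_type3": has_t3,
        "uorfs": [
            {
                "tx_start": u["tx_start"] - trim,
                "anchor": gene.tx2g[u["tx_start"]],
                "type": u["type"],
                "length": u["length"],
                "sequence": u["sequence"],
            }
            for u in uorfs
        ],
    }


def _build_gene_cdna(rng: Random, config: FixtureConfig, arch_name: str) -> dict:
    arch = ARCHETYPES[arch_name]()
    pad5 = _pad(rng, rng.randrange(config.pad5_range[0], config.pad5_range[1] + 1))
    core = len(pad5)
    tpl = arch["leader_tpl"]
    if arch["cds"] is None:
        padmid = _pad(rng, rng.randrange(8, 16))
        leader = pad5 + tpl + padmid
        cds = _generic_cds(rng)
        cut_zones = (
            list(range(1, len(pad5)))
            + list(range(core + len(tpl) + 1, len(leader)))
        )
    else:
        leader = pad5 + tpl
        cds = arch["cds"]
        cut_zones = list(range(1, len(pad5)))
    pad3 = _pad(rng, rng.randrange(6, 20))
    cdna = leader + cds + pad3
    morf_start = len(leader)
    morf_end = morf_start + len(cds)
    cut_zones += list(range(morf_end + 1, len(cdna)))
    trim_tx = None if arch["trim_rel"] is None else core + arch["trim_rel"]
    ref_uorfs = [
        {**u, "tx_start": u["tx_start"] + core} for u in arch["ref_uorfs"]
    ]
    events: dict[str, list[Realization]] = {}
    for kind, reals in arch["events"].items():
        events[kind] = [
            Realization(
                name=r.name,
                kind=r.kind,
                edits=tuple((off + core, ref, alt) for off, ref, alt in r.edits),
                locus_tx=None if r.locus_tx is None else r.locus_tx + core,
                form=None
                if r.form is None
                else {**r.form, "tx_start": r.form["tx_start"] + core},
                origin_rank=r.origin_rank,
            )
            for r in reals
        ]
    return {
        "cdna": cdna,
        "core": core,
        "morf_start": morf_start,
        "morf_end": morf_end,
        "cut_zones": cut_zones,
        "trim_tx": trim_tx,
        "ref_uorfs": ref_uorfs,
        "events": events,
        "pad5_len": len(pad5),
    }


def _place_gene(
    rng: Random,
    config: FixtureConfig,
    build: dict,
    gene_id: str,
    strand: str,
    g_cursor: int,
) -> GeneFixture:
    cdna = build["cdna"]
    n_exons = rng.randrange(config.exon_range[0], config.exon_range[1] + 1)
    n_cuts = min(n_exons - 1, len(build["cut_zones"]))
    cuts = sorted(rng.sample(sorted(build["cut_zones"]), n_cuts)) if n_cuts else []
    bounds = [0] + cuts + [len(cdna)]
    tx_exons = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    tx2g = [0] * len(cdna)
    parts: list[str] = []
    cursor = g_cursor
    genomic_order = tx_exons if strand == "+" else list(reversed(tx_exons))
    for idx, (s, e) in enumerate(genomic_order):
        block = cdna[s:e] if strand == "+" else revcomp(cdna[s:e])
        for k in range(e - s):
            if strand == "+":
                tx2g[s + k] = cursor + k
            else:
                tx2g[e - 1 - k] = cursor + k
        parts.append(block)
        cursor += e - s
        if idx < len(genomic_order) - 1:
            intron = _rand_seq(rng, rng.randrange(20, 51))
            parts.append(intron)
            cursor += len(intron)
    return GeneFixture(
        gene_id=gene_id,
        archetype=build["arch_name"],
        strand=strand,
        cdna=cdna,
        core=build["core"],
        morf_start=build["morf_start"],
        morf_end=build["morf_end"],
        tx_exons=tx_exons,
        tx2g=tx2g,
        gene_start=g_cursor,
        gene_end=cursor,
        trim_tx=build["trim_tx"],
        ref_uorfs=build["ref_uorfs"],
        events=build["events"],
    ), "".join(parts)


def generate_reference(config: FixtureConfig) -> ReferenceFixture:
    """Build the reference slice: one contig carrying ``n_genes`` genes drawn
    cyclically from the archetype list, on mixed strands, 1-3 exons each.
    Deterministic in ``config.seed``; every planted uORF is re-verified by an
    independent naive scan before the fixture is returned."""
    rng = Random(f"{config.seed}-reference")
    cycle = config.archetypes or _ARCH_CYCLE
    for name in cycle:
        if name not in ARCHETYPES:
            raise FixtureError(f"unknown archetype {name!r}")
    genes: list[GeneFixture] = []
    chunks: list[str] = []
    cursor = 0
    for i in range(config.n_genes):
        arch_name = cycle[i % len(cycle)]
        build = _build_gene_cdna(rng, config, arch_name)
        build["arch_name"] = arch_name
        gap = _rand_seq(rng, rng.randrange(30, 81))
        chunks.append(gap)
        cursor += len(gap)
        if config.strand_mix:
            strand = "+" if rng.randrange(2) == 0 else "-"
        else:
            strand = "+"
        gene, gene_seq = _place_gene(
            rng, config, build, f"g{i + 1:03d}", strand, cursor
        )
        chunks.append(gene_seq)
        cursor = gene.gene_end
        genes.append(gene)
    chunks.append(_rand_seq(rng, 40))
    fixture = ReferenceFixture(config, config.contig, "".join(chunks), genes)
    for gene in genes:
        _verify_gene(gene)
        # the spliced map must reproduce the cDNA exactly
        rebuilt = "".join(
            fixture.contig_seq[gene.tx2g[i]]
            if gene.strand == "+"
            else revcomp(fixture.contig_seq[gene.tx2g[i]])
            for i in range(len(gene.cdna))
        )
        if rebuilt != gene.cdna:
            raise FixtureError(f"{gene.gene_id}: genome/cDNA map inconsistent")
    return fixture


# ---------------------------------------------------------------------------
# population build


@dataclass
class VcfEntry:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    filter: str = "PASS"
    hom: set = field(default_factory=set)
    het: set = field(default_factory=set)
    ad_low: set = field(default_factory=set)
    vid: str = ""


@dataclass
class PopulationFixture:
    reference: ReferenceFixture
    accessions: list[str]
    latitudes: dict[str, int]
    entries: list[VcfEntry]
    assignments: dict[str, dict[str, dict]]  # gene -> accession -> record
    truth: dict


def _to_genomic(gene: GeneFixture, off: int, ref_tx: str, alt_tx: str):
    if gene.strand == "+":
        return gene.tx2g[off], ref_tx, alt_tx
    return gene.tx2g[off + len(ref_tx) - 1], revcomp(ref_tx), revcomp(alt_tx)


def _expected_identifiers(forms: list[dict]) -> dict[tuple[int, str], str]:
    """Composite-key ordering of realized forms into Level1.Level2 labels.

    Level1 groups are (anchor, length, origin rank) sorted by anchor, then
    length, then rank (reference/SNP-only < deletion < insertion), then the
    group's smallest sorted variant-position tuple; Level2 sorts members by
    SNP count, variant positions, then sequence.
    """
    unique: dict[tuple[int, str], dict] = {}
    for f in forms:
        unique.setdefault((f["anchor"], f["sequence"]), f)
    groups: dict[tuple, list] = {}
    for key, f in unique.items():
        gkey = (f["anchor"], f["length"], f["origin_rank"])
        groups.setdefault(gkey, []).append((key, f))
    ordered = sorted(
        groups.items(),
        key=lambda item: (
            item[0][0],
            item[0][1],
            item[0][2],
            min(tuple(f["positions"]) for _, f in item[1]),
        ),
    )
    out: dict[tuple[int, str], str] = {}
    for l1, (_gkey, members) in enumerate(ordered, start=1):
        members.sort(
            key=lambda kf: (kf[1]["n_snps"], tuple(kf[1]["positions"]), kf[0][1])
        )
        for l2, (key, _f) in enumerate(members, start=1):
            out[key] = f"{l1}.{l2}"
    return out


_EVENT_ORDER = (
    "morf_hit",
    "creation",
    "loss",
    "length_change",
    "substitution",
    "type_switch",
)


def generate_population(
    reference: ReferenceFixture, config: FixtureConfig | None = None
) -> PopulationFixture:
    """Plant population events on a reference fixture.

    For each accession x gene at most one event is drawn from the gene's
    archetype repertoire; the minimal variant realizing it is emitted as a
    homozygous PASS call.  Distractor variants (heterozygous, failing
    FILTER, or with a sub-threshold supporting-read fraction) are added at
    ``distractor_rate`` and must be invisible to the pipeline.
    """
    config = config or reference.config
    rng = Random(f"{config.seed}-population")
    accessions = [f"acc{i + 1:03d}" for i in range(config.n_accessions)]
    latitudes = {a: rng.randrange(-60, 75) for a in accessions}
    registry: dict[tuple, VcfEntry] = {}

    def entry(gene, off, ref_tx, alt_tx, **kw) -> VcfEntry:
        pos, ref, alt = _to_genomic(gene, off, ref_tx, alt_tx)
        key = (pos, ref, alt)
        if key not in registry:
            registry[key] = VcfEntry(reference.contig, pos, ref, alt, **kw)
        return registry[key]

    assignments: dict[str, dict[str, dict]] = {}
    for gene in reference.genes:
        per_acc: dict[str, dict] = {}
        for acc in accessions:
            chosen: tuple[str, Realization] | None = None
            for kind in _EVENT_ORDER:
                if kind not in gene.events:
                    continue
                rate = config.event_rates.get(kind, 0.0)
                if rng.randrange(1000) < int(round(rate * 1000)):
                    reals = gene.events[kind]
                    real = reals[rng.randrange(len(reals))] if len(reals) > 1 else reals[0]
                    chosen = (kind, real)
                    break
            if chosen is None:
                per_acc[acc] = {"event": None, "realization": None, "entries": []}
                continue
            kind, real = chosen
            ents = []
            for off, ref_tx, alt_tx in real.edits:
                e = entry(gene, off, ref_tx, alt_tx)
                e.hom.add(acc)
                ents.append(e)
            per_acc[acc] = {"event": kind, "realization": real, "entries": ents}
        assignments[gene.gene_id] = per_acc
        # distractors live in the 5' padding (inert C/G alphabet)
        pad_offsets = [o for o in range(1, gene.core - 1)]
        used: set[int] = set()
        for flavour in ("het", "lowqual", "adlow"):
            if not pad_offsets:
                break
            if rng.randrange(1000) >= int(round(config.distractor_rate * 1000)):
                continue
            free = [o for o in pad_offsets if o not in used]
            if not free:
                continue
            off = free[rng.randrange(len(free))]
            used.add(off)
            base = gene.cdna[off]
            alt = "G" if base == "C" else "C"
            acc = accessions[rng.randrange(len(accessions))]
            if flavour == "het":
                entry(gene, off, base, alt).het.add(acc)
            elif flavour == "lowqual":
                e = entry(gene, off, base, alt)
                e.filter = "LowQual"
                e.hom.add(acc)
            else:
                entry(gene, off, base, alt).ad_low.add(acc)

    entries = sorted(registry.values(), key=lambda e: (e.pos, e.ref, e.alt))
    for i, e in enumerate(entries, start=1):
        e.vid = f"v{i:04d}"
    truth = _population_truth(reference, config, accessions, latitudes, assignments)
    return PopulationFixture(
        reference=reference,
        accessions=accessions,
        latitudes=latitudes,
        entries=entries,
        assignments=assignments,
        truth=truth,
    )


def _population_truth(reference, config, accessions, latitudes, assignments) -> dict:
    genes_truth: dict[str, dict] = {}
    cohort_forms: dict[tuple, dict] = {}
    transition_counts: dict[str, dict[str, int]] = {}
    for gene in reference.genes:
        per_acc = assignments[gene.gene_id]
        ref_forms = [
            {
                "anchor": gene.tx2g[u["tx_start"]],
                "length": u["length"],
                "sequence": u["sequence"],
                "type": u["type"],
                "origin_rank": 0,
                "n_snps": 0,
                "n_indels": 0,
                "positions": [],
                "variant_ids": [],
            }
            for u in gene.ref_uorfs
        ]
        realized = [dict(f) for f in ref_forms]
        acc_truth: dict[str, dict] = {}
        screened: list[str] = []
        ref_attr, _ = _attribute_of(gene.ref_uorfs)
        counts = {
            "Type1-only<->Type2": 0,
            "uORF-free<->Type1-only": 0,
            "uORF-free<->Type2": 0,
        }
        for acc in accessions:
            rec = per_acc[acc]
            if rec["event"] == "morf_hit":
                screened.append(acc)
                acc_truth[acc] = {
                    "event": "morf_hit",
                    "screened": True,
                    "variant_ids": sorted(e.vid for e in rec["entries"]),
                }
                continue
            forms_here: dict[int, dict] = {
                f["anchor"]: dict(f) for f in ref_forms
            }
            expected_events: list[dict] = []
            if rec["event"] is not None:
                real: Realization = rec["realization"]
                vids = sorted(e.vid for e in rec["entries"])
                positions = sorted(e.pos for e in rec["entries"])
                n_indels = sum(
                    1 for e in rec["entries"] if len(e.ref) != len(e.alt)
                )
                n_snps = len(rec["entries"]) - n_indels
                locus_anchor = gene.tx2g[
                    real.locus_tx if real.locus_tx is not None else 0
                ]
                if real.form is None:  # loss
                    del forms_here[locus_anchor]
                    expected_events.append({"kind": "loss", "anchor": locus_anchor})
                else:
                    new_form = {
                        "anchor": gene.tx2g[real.form["tx_start"]],
                        "length": real.form["length"],
                        "sequence": real.form["sequence"],
                        "type": real.form["type"],
                        "origin_rank": real.origin_rank,
                        "n_snps": n_snps,
                        "n_indels": n_indels,
                        "positions": positions,
                        "variant_ids": vids,
                    }
                    forms_here[new_form["anchor"]] = new_form
                    realized.append(new_form)
                    cohort_forms.setdefault(
                        (gene.gene_id, new_form["anchor"], new_form["sequence"]),
                        new_form,
                    )
                    if rec["event"] == "creation":
                        expected_events.append(
                            {"kind": "creation", "anchor": new_form["anchor"]}
                        )
                    else:
                        ref_at = next(
                            (f for f in ref_forms if f["anchor"] == new_form["anchor"]),
                            None,
                        )
                        assert ref_at is not None
                        if ref_at["length"] != new_form["length"]:
                            expected_events.append(
                                {"kind": "length_change", "anchor": new_form["anchor"]}
                            )
                        elif ref_at["sequence"] != new_form["sequence"]:
                            expected_events.append(
                                {"kind": "substitution", "anchor": new_form["anchor"]}
                            )
                        if ref_at["type"] != new_form["type"]:
                            expected_events.append(
                                {
                                    "kind": "type_switch",
                                    "anchor": new_form["anchor"],
                                    "old_type": ref_at["type"],
                                    "new_type": new_form["type"],
                                }
                            )
                acc_truth[acc] = {
                    "event": rec["event"],
                    "realization": real.name,
                    "screened": False,
                    "variant_ids": vids,
                    "expected_events": expected_events,
                    "forms": {
                        str(a): {
                            k: f[k]
                            for k in (
                                "length",
                                "sequence",
                                "type",
                                "n_snps",
                                "n_indels",
                            )
                        }
                        for a, f in forms_here.items()
                    },
                }
            else:
                acc_truth[acc] = {
                    "event": None,
                    "realization": None,
                    "screened": False,
                    "variant_ids": [],
                    "expected_events": [],
                    "forms": {
                        str(a): {
                            k: f[k]
                            for k in (
                                "length",
                                "sequence",
                                "type",
                                "n_snps",
                                "n_indels",
                            )
                        }
                        for a, f in forms_here.items()
                    },
                }
            attr, _ = _attribute_of(list(forms_here.values()))
            acc_truth[acc]["attribute"] = attr
            if attr != ref_attr:
                pair = frozenset({attr, ref_attr})
                if pair == frozenset({"Type1-only", "Type2"}):
                    counts["Type1-only<->Type2"] += 1
                elif pair == frozenset({"uORF-free", "Type1-only"}):
                    counts["uORF-free<->Type1-only"] += 1
                elif pair == frozenset({"uORF-free", "Type2"}):
                    counts["uORF-free<->Type2"] += 1
        ident_table = _expected_identifiers(realized)
        loci = sorted({a for a, _s in ident_table})
        per_acc_idents: dict[str, dict[str, str]] = {}
        for acc in accessions:
            if acc in screened:
                continue
            forms = acc_truth[acc]["forms"]
            per_acc_idents[acc] = {
                str(a): (
                    ident_table[(a, forms[str(a)]["sequence"])]
                    if str(a) in forms
                    else "absent"
                )
                for a in loci
            }
        genes_truth[gene.gene_id] = {
            "reference_attribute": ref_attr,
            "loci": loci,
            "screened_accessions": sorted(screened),
            "identifier_table": {
                f"{a}|{s}": ident for (a, s), ident in sorted(ident_table.items())
            },
            "accessions": acc_truth,
            "identifiers": per_acc_idents,
            "transition_counts": counts,
        }
        transition_counts[gene.gene_id] = counts
    nonref = [f for f in cohort_forms.values()]
    n_multi = sum(1 for f in nonref if f["n_snps"] + f["n_indels"] >= 2)
    mvf = (n_multi / len(nonref)) if nonref else None
    return {
        "seed": config.seed,
        "accessions": accessions,
        "latitudes": latitudes,
        "genes": genes_truth,
        "cohort": {
            "n_nonreference_forms": len(nonref),
            "n_multi_variant_forms": n_multi,
            "multi_variant_fraction": mvf,
            "transition_counts": transition_counts,
        },
    }


# ---------------------------------------------------------------------------
# writers (plain-text FASTA / GFF3 / VCF / TSV / JSON)


def _tx_to_genomic_intervals(gene: GeneFixture, lo: int, hi: int):
    """Genomic intervals (ascending) covered by transcript range [lo, hi)."""
    coords = sorted(gene.tx2g[i] for i in range(lo, hi))
    runs = []
    for c in coords:
        if runs and c == runs[-1][1]:
            runs[-1][1] = c + 1
        else:
            runs.append([c, c + 1])
    return [(s, e) for s, e in runs]


def _gff3_lines(fixture: ReferenceFixture) -> list[str]:
    lines = ["##gff-version 3"]
    for gene in fixture.genes:
        gid = gene.gene_id
        lines.append(
            "\t".join(
                [
                    fixture.contig,
                    "uorfkit_fixture",
                    "gene",
                    str(gene.gene_start + 1),
                    str(gene.gene_end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gid}",
                ]
            )
        )
        model_trims = [(f"{gid}.1", 0)]
        if gene.trim_tx is not None:
            model_trims.append((f"{gid}.2", gene.trim_tx))
        for tid, trim in model_trims:
            exon_iv = _tx_to_genomic_intervals(gene, trim, len(gene.cdna))
            utr_iv = (
                _tx_to_genomic_intervals(gene, trim, gene.morf_start)
                if gene.morf_start > trim
                else []
            )
            cds_iv = _tx_to_genomic_intervals(gene, gene.morf_start, gene.morf_end)
            mstart = min(s for s, _ in exon_iv)
            mend = max(e for _, e in exon_iv)
            lines.append(
                "\t".join(
                    [
                        fixture.contig,
                        "uorfkit_fixture",
                        "mRNA",
                        str(mstart + 1),
                        str(mend),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={tid};Parent={gid}",
                    ]
                )
            )
            for ftype, ivs in (
                ("exon", exon_iv),
                ("five_prime_UTR", utr_iv),
                ("CDS", cds_iv),
            ):
                cum = 0
                ordered = ivs if gene.strand == "+" else list(reversed(ivs))
                for s, e in ordered:
                    phase = "."
                    if ftype == "CDS":
                        phase = str((3 - cum % 3) % 3)
                        cum += e - s
                    lines.append(
                        "\t".join(
                            [
                                fixture.contig,
                                "uorfkit_fixture",
                                ftype,
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                phase,
                                f"Parent={tid}",
                            ]
                        )
                    )
    return lines


def _vcf_lines(pop: PopulationFixture) -> list[str]:
    ref = pop.reference
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.contig},length={len(ref.contig_seq)}>",
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(pop.accessions),
    ]
    for e in pop.entries:
        cells = []
        for acc in pop.accessions:
            if acc in e.hom:
                cells.append("1/1:0,20")
            elif acc in e.ad_low:
                cells.append("1/1:10,10")
            elif acc in e.het:
                cells.append("0/1:10,10")
            else:
                cells.append("0/0:20,0")
        lines.append(
            "\t".join(
                [
                    pop.reference.contig,
                    str(e.pos + 1),
                    e.vid,
                    e.ref,
                    e.alt,
                    "50",
                    e.filter,
                    ".",
                    "GT:AD",
                ]
                + cells
            )
        )
    return lines


def write_reference(fixture: ReferenceFixture, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    seq = fixture.contig_seq
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    fasta.write_text(f">{fixture.contig}\n{wrapped}\n")
    gff = outdir / "annotation.gff3"
    gff.write_text("\n".join(_gff3_lines(fixture)) + "\n")
    truth = outdir / "truth_reference.json"
    truth.write_text(
        json.dumps(fixture.truth_reference(), indent=2, sort_keys=True) + "\n"
    )
    return {"fasta": fasta, "gff3": gff, "truth": truth}


def write_population(pop: PopulationFixture, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf = outdir / "variants.vcf"
    vcf.write_text("\n".join(_vcf_lines(pop)) + "\n")
    meta = outdir / "metadata.tsv"
    rows = ["accession_id\tlatitude"] + [
        f"{a}\t{pop.latitudes[a]}" for a in pop.accessions
    ]
    meta.write_text("\n".join(rows) + "\n")
    truth = outdir / "truth_population.json"
    truth.write_text(json.dumps(pop.truth, indent=2, sort_keys=True) + "\n")
    return {"vcf": vcf, "metadata": meta, "truth": truth}


def generate_fixture(
    config: FixtureConfig, outdir: str | Path | None = None
) -> PopulationFixture:
    """Reference plus population in one call; writes all files when given an
    output directory."""
    ref = generate_reference(config)
    pop = generate_population(ref, config)
    if outdir is not None:
        paths = write_reference(ref, outdir)
        paths.update(write_population(pop, outdir))
    return pop
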