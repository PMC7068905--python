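"""End-to-end orchestration: reference scan, per-accession pseudo-cDNAs,
identifier assignment, events and population statistics for whole cohorts.

This is the glue the command-line layer and the test-suite drive; all
science lives in the per-step modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_annotation import GenomeSequence, SplicedCDNA, TranscriptModel, spliced_cdna
from .population_analysis import (
    compute_frequencies,
    multi_variant_fraction,
    population_transitions,
    splicing_model_transitions,
)
from .uorf_finder import DEFAULT_START_CODONS, UORFRecord, find_uorfs, gene_type_attribute
from .uorf_indexer import (
    UORFForm,
    UORFIdentifier,
    assign_identifiers,
    classify_event,
    form_from_record,
    reference_form,
    VariantEvent,
)
from .variant_engine import (
    VariantCall,
    accession_variant_set,
    build_pseudo_cdna,
    screen_morf_start,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneAnalysis:
    """Everything the pipeline derives for one gene on one splicing model."""

    gene_id: str
    transcript_id: str
    spliced: SplicedCDNA
    ref_records: list[UORFRecord]
    ref_forms: list[UORFForm]
    ref_attribute: str
    has_type3: bool
    accession_forms: dict[str, list[UORFForm]] = field(default_factory=dict)
    accession_attributes: dict[str, str] = field(default_factory=dict)
    accession_records: dict[str, list[UORFRecord]] = field(default_factory=dict)
    screened: list[str] = field(default_factory=list)
    events: dict[str, list[VariantEvent]] = field(default_factory=dict)
    identifiers: dict[tuple[int, str], UORFIdentifier] = field(default_factory=dict)
    assignments: dict[str, dict[int, str]] = field(default_factory=dict)
    loci: list[int] = field(default_factory=list)


def scan_reference(
    genome: GenomeSequence,
    models: Iterable[TranscriptModel],
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> dict[str, tuple[SplicedCDNA, list[UORFRecord], str, bool]]:
    """uORF scan of every splicing model on the reference genome.

    Returns transcript id -> (spliced cDNA, records, attribute, has_type3).
    Models flagged as lacking an annotated leader are scanned trivially
    (empty record list) so they still appear in outputs.
    """
    out = {}
    for model in models:
        spliced = spliced_cdna(model, genome)
        records = find_uorfs(spliced, start_codons)
        attr, has_t3 = gene_type_attribute(records)
        out[model.transcript_id] = (spliced, records, attr, has_t3)
    return out


def analyze_gene(
    gene_id: str,
    spliced: SplicedCDNA,
    calls: list[VariantCall],
    accessions: Sequence[str],
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> GeneAnalysis:
    """Full per-gene population analysis on one (representative) model.

    Builds every accession's pseudo-cDNA, rescans, anchors forms, assigns
    Level1.Level2 identifiers over the whole observed form set and classifies
    each accession's events against the reference.  Accessions with a variant
    in the mORF start codon are screened out and reported in ``screened``.
    """
    ref_records = find_uorfs(spliced, start_codons)
    ref_forms = [reference_form(r, spliced) for r in ref_records if r.terminated]
    ref_attr, has_t3 = gene_type_attribute(ref_records)
    analysis = GeneAnalysis(
        gene_id=gene_id,
        transcript_id=spliced.transcript_id,
        spliced=spliced,
        ref_records=ref_records,
        ref_forms=ref_forms,
        ref_attribute=ref_attr,
        has_type3=has_t3,
    )
    all_forms: list[UORFForm] = list(ref_forms)
    for acc in accessions:
        varset = accession_variant_set(spliced, acc, calls)
        if not screen_morf_start(spliced, varset):
            analysis.screened.append(acc)
            continue
        pseudo = build_pseudo_cdna(spliced, varset)
        records = find_uorfs(pseudo, start_codons)
        forms = [form_from_record(r, pseudo) for r in records if r.terminated]
        analysis.accession_records[acc] = records
        analysis.accession_forms[acc] = forms
        analysis.accession_attributes[acc] = gene_type_attribute(records)[0]
        analysis.events[acc] = classify_event(ref_forms, forms, acc)
        all_forms.extend(forms)
    analysis.identifiers = assign_identifiers(all_forms)
    analysis.loci = sorted({anchor for anchor, _seq in analysis.identifiers})
    for acc, forms in analysis.accession_forms.items():
        by_anchor = {f.anchor: f for f in forms}
        analysis.assignments[acc] = {
            anchor: (
                str(analysis.identifiers[by_anchor[anchor].key])
                if anchor in by_anchor
                else "absent"
            )
            for anchor in analysis.loci
        }
    return analysis


@dataclass
class PopulationResult:
    genes: dict[str, GeneAnalysis]
    frequencies: dict[str, pd.DataFrame]
    transition_counts: dict[str, dict[str, int]]
    multi_variant_fraction: float | None


def run_population(
    genome: GenomeSequence,
    representative: Mapping[str, TranscriptModel],
    calls: list[VariantCall],
    accessions: Sequence[str],
    groups: Mapping[str, Sequence[str]] | None = None,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> PopulationResult:
    """Population pipeline over the representative model of every gene."""
    genes: dict[str, GeneAnalysis] = {}
    frequencies: dict[str, pd.DataFrame] = {}
    transition_counts: dict[str, dict[str, int]] = {}
    cohort_forms: list[UORFForm] = []
    for gene_id in sorted(representative):
        model = representative[gene_id]
        if "no_annotated_leader" in model.flags:
            logger.info("%s skipped: no annotated leader", gene_id)
            continue
        spliced = spliced_cdna(model, genome)
        analysis = analyze_gene(gene_id, spliced, calls, accessions, start_codons)
        genes[gene_id] = analysis
        if analysis.loci and analysis.assignments:
            frequencies[gene_id] = compute_frequencies(
                analysis.assignments, groups or {}, analysis.screened
            )
        _calls, counts = population_transitions(
            gene_id, analysis.ref_attribute, analysis.accession_attributes
        )
        transition_counts[gene_id] = counts
        for forms in analysis.accession_forms.values():
            cohort_forms.extend(forms)
    return PopulationResult(
        genes=genes,
        frequencies=frequencies,
        transition_counts=transition_counts,
        multi_variant_fraction=multi_variant_fraction(cohort_forms),
    )


def splicing_transitions_table(
    scan: Mapping[str, tuple[SplicedCDNA, list[UORFRecord], str, bool]],
    gene_of: Mapping[str, str],
) -> pd.DataFrame:
    """Attribute transitions among the splicing models of each gene, from a
    :func:`scan_reference` result.  ``gene_of`` maps transcript -> gene."""
    per_gene: dict[str, dict[str, str]] = {}
    for tid, (_spliced, _records, attr, _t3) in scan.items():
        per_gene.setdefault(gene_of[tid], {})[tid] = attr
    rows = []
    for gene_id, attrs in sorted(per_gene.items()):
        if len(attrs) < 2:
            continue
        for call in splicing_model_transitions(gene_id, attrs):
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "context": call.context,
                    "attr_a": call.attr_a,
                    "attr_b": call.attr_b,
                    "transition": call.transition,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "context", "attr_a", "attr_b", "transition"]
    )


def records_table(records_by_tid: Mapping[str, list[UORFRecord]]) -> pd.DataFrame:
    """Flatten uORF records into the standard TSV layout."""
    rows = []
    for tid in sorted(records_by_tid):
        for r in records_by_tid[tid]:
            rows.append(
                {
                    "transcript_id": tid,
                    "uorf_start_tx": r.start,
                    "uorf_end_tx": r.stop_end if r.stop_end is not None else ".",
                    "type": r.uorf_type,
                    "length_nt": r.length_nt if r.length_nt is not None else ".",
                    "peptide": r.peptide,
                    "icc_u": r.icc,
                    "kozak_u": int(r.kozak),
                    "space5": r.space5,
                    "space3": r.space3 if r.space3 is not None else ".",
                    "start_codon": r.start_codon,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "uorf_start_tx",
            "uorf_end_tx",
            "type",
            "length_nt",
            "peptide",
            "icc_u",
            "kozak_u",
            "space5",
            "space3",
            "start_codon",
        ],
    )


def identifier_table(genes: Mapping[str, GeneAnalysis]) -> pd.DataFrame:
    """Per-form identifier table across all analyzed genes."""
    rows = []
    for gene_id in sorted(genes):
        analysis = genes[gene_id]
        forms: dict[tuple[int, str], UORFForm] = {}
        for f in analysis.ref_forms:
            forms.setdefault(f.key, f)
        for acc_forms in analysis.accession_forms.values():
            for f in acc_forms:
                forms.setdefault(f.key, f)
        carrier_counts: dict[tuple[int, str], int] = {k: 0 for k in forms}
        for acc_forms in analysis.accession_forms.values():
            for f in acc_forms:
                carrier_counts[f.key] += 1
        for key, form in sorted(forms.items()):
            rows.append(
                {
                    "gene_id": gene_id,
                    "locus_anchor": form.anchor,
                    "identifier": str(analysis.identifiers[key]),
                    "type": form.uorf_type,
                    "length_nt": form.length,
                    "n_snps": form.n_snps,
                    "n_indels": form.n_indels,
                    "causal_variant_ids": ",".join(form.causal_ids) or ".",
                    "accession_count": carrier_counts[key],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "locus_anchor",
            "identifier",
            "type",
            "length_nt",
            "n_snps",
            "n_indels",
            "causal_variant_ids",
            "accession_count",
        ],
    )
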