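# Methods

## uORF model

A uORF is defined by the presence of a start codon in the annotated 5′
leader of a spliced transcript: every occurrence at an offset strictly
smaller than the mORF start yields one record, including overlapping and
nested uORFs. The default start-codon set is {ATG}; any set of 3-mers may
be supplied for non-AUG scans. Translation is simulated codon by codon from
the start until the first in-frame stop (TAA/TAG/TGA, standard code; the
genetic-code table is not configurable) anywhere in the transcript. uORFs
with no stop before the transcript end are recorded as *unterminated* and
excluded from type statistics, identifier assignment and gene attributes.

Classification by the stop position relative to the mORF:

| type | rule |
|------|------|
| Type1 | stop end ≤ mORF start |
| Type3 | in frame with the mORF and stop end = mORF end |
| Type2 | every other terminated uORF (stop past the mORF start, out of frame) |

The Type2 rule is deliberately total: in the rare case of an out-of-frame
uORF whose first stop falls 3′ of the mORF stop (in the trailer), the uORF
is still reported Type2 even though its stop is not inside the coding
region proper. In-frame uORFs cannot present this case (the mORF frame is
free of internal stops), so the three classes partition all terminated
uORFs.

uORF length includes the stop codon: the minimal uORF, a start codon
directly followed by a stop, has length 6 nt. The 3′ space
(mORF start − stop end) is signed; negative values mean overlap. The
initiation-codon context (ICC) is the 7-mer at −3..+4 around the start
codon (A = +1), N-padded at transcript edges; the Kozak flag requires a
purine at −3, C at −2 and −1 and G at +4, and padded positions never match.

Gene type attributes collapse a model's terminated AUG-initiated uORFs to
one of *uORF-free*, *Type1-only*, or *Type2* (any Type2 uORF dominates, even
when Type1 uORFs co-occur). Type3 never changes the three-way class; a
Type3-only model is reported uORF-free with a separate has-Type3 flag,
since a definitive convention for counting N-extensions as "uORF-containing"
does not exist.

## Coordinates and splicing

Internally all coordinates are 0-based, half-open, on the forward genomic
strand; GFF3 and VCF conventions are converted at the I/O boundary. Spliced
cDNAs carry a per-base map to genomic coordinates (strictly increasing on
plus-strand, strictly decreasing on minus-strand transcripts), so the
genomic anchor of any mRNA base is always a forward-strand reference
coordinate and directly comparable with VCF positions. Leader length is
derived from exonic bases 5′ of the CDS start; transcripts without an
annotated leader are kept but skipped by the scanner. Transcripts whose CDS
length is not a multiple of 3, is shorter than two codons, or whose first
CDS segment carries a non-zero phase are excluded with a logged reason — the
annotation gives no reliable reading frame for them. A CDS outside the exon
union is a structural error. Per gene, the representative model is the one
with the numerically smallest dotted suffix (".1" before ".2"; "0.1" before
"0.2"), overridable by an explicit table.

## Variants and pseudo-cDNAs

Records failing FILTER are dropped and multi-allelic records split. Only
homozygous-alternate genotypes contribute edits — heterozygous or missing
calls leave the reference allele for that accession. When per-sample AD is
present, a call additionally needs a supporting-read fraction ≥ 0.90
(configurable; a no-op without AD). This reading of the upstream filter
("alleles with frequency over 90%") is deliberately per-sample and
configurable, since the originating pipelines do not publish a formula.

Edits are projected into transcript space (minus-strand alleles
reverse-complemented), restricted to the exonic leader+CDS span; variants
crossing a splice junction or only partly exonic are skipped with a
warning, as are variants 3′ of the mORF stop (they cannot affect uORFs).
Overlapping edits keep the 5′-most. Any accession with a variant touching
one of the three genomic bases of the mORF start codon is screened out for
that gene — the mORF start is the fixed coordinate that anchors all uORFs —
and reported separately; the gene is dropped only for affected accessions,
not cohort-wide. Edits are applied in descending transcript offset so
earlier offsets stay valid; the pseudo mORF start is shifted by the summed
upstream indel deltas, and the pseudo mORF end is re-derived by an in-frame
stop scan (a variant destroying the mORF stop is logged and the shifted
estimate used). Every pseudo base carries a reference anchor; bases created
by insertions anchor to the reference base 5′ of the insertion point and
are flagged. VCF positions are used as written (left-aligned anchor-base
style assumed); no re-normalization is performed.

## Identifiers

uORF forms are identified by (reference anchor of the start codon's first
base, nucleotide sequence). The causal variants of a form are the applied
variants whose reference spans intersect the uORF's reference-anchored
footprint. Level1 groups forms by (anchor, length, origin class) with
origin classes reference/SNP-only < deletion-bearing < insertion-bearing —
keying the group by origin class is the only reading under which a
deletion-priority and an insertion-priority can order Level1 at all, since
equal-length forms at one anchor are otherwise indistinguishable. Groups
are numbered ascending by (anchor, length, origin class, smallest sorted
variant-position tuple); within a group, forms are numbered by SNP count,
then variant positions, then sequence (the final lexicographic tie-break is
documented and stable). Numbering starts at 1.1 and is gap-free; assignment
is a pure function of the observed form set, so accession order never
matters. Created loci are sorted together with reference loci on the same
ascending forward-strand anchor axis — note this means Level1 order on
minus-strand genes follows genomic, not transcript, orientation. Loss is an
event, not a form: absent states appear as an explicit "absent" category in
frequency tables rather than receiving an identifier.

Event calls compare an accession's forms with the reference per locus:
creation (accession only), loss (reference only), length change (same
anchor, different length), substitution (same anchor and length, different
sequence), unchanged (identical); a type switch is additionally emitted
whenever the type at a shared locus differs.

## Population statistics

Frequencies are occurrence fractions of each identifier (or "absent") per
locus, in the total population and per group; every column sums to 1 over
the informative accessions — accessions screened at the mORF start leave
the denominator and are counted separately. Grouping is by explicit label
or by collection latitude in closed-left/open-right 15-degree bins over
[−90, 90); accessions without latitude form an "unassigned" group that is
reported but not binned. Transitions are restricted to the three-way
attribute classes (Type1-only↔Type2, uORF-free↔Type1-only,
uORF-free↔Type2), compared pairwise among splicing models of the reference
or between each accession and the reference; Type3 changes are kept out of
the three-way calls and visible through the has-Type3 flag. The
multi-variant fraction is the share of distinct non-reference forms with at
least two causal SNPs/INDELs; with no non-reference forms it is reported as
not applicable rather than 0.

## Synthetic data

The fixture generator emits a genome FASTA, GFF3, multi-sample VCF v4.2,
metadata table and truth tables that are consistent by construction. Genes
are built from hand-verified templates — a Type1 uORF with substitution/
length-change sites, a boundary-overlapping Type2, a Type3 N-extension, the
minimal 6-nt uORF, a dormant creation motif one SNP away from an AUG, a
Type1 whose stop-codon SNP extends it out of frame into the mORF (type
switch + length change), and a two-model gene whose trimmed leader flips
Type2 to Type1-only. Transcript padding uses only C/G, which cannot form or
complete a start or stop codon, so every AUG and stop in a leader is
planted; intron and intergenic sequence is unconstrained. Genes get 1–3
exons (junctions only inside padding), mixed strands, and a second splicing
model with a trimmed leader where the archetype defines one.

Population events are drawn per accession × gene (at most one each) with
default rates of 0.25–0.30 per kind and 0.05 for mORF-start hits, sizes
that give a 10-gene × 20-accession universe several instances of every
event class without saturating any locus. Distractor variants —
heterozygous, FILTER-failing, and below the allele-fraction threshold — are
planted at rate 0.5 and must be invisible to the pipeline. All randomness
is integer-only so a seed fixes the output bytes across platforms. Before
any file is written, an internal naive re-scan (independent of the scanner
module) verifies every planted uORF and every event outcome; expected
identifiers are derived by a separate straightforward implementation of the
published ordering rule.

What the generator does *not* emulate: realistic leader-length, uORF-length
or allele-frequency distributions, linkage between variants, sequencing
error, or annotation noise. Passing the closed-loop tests therefore shows
the machinery is exact on well-formed inputs, not that real-genome
annotations are clean; on real data the logged exclusions (non-multiple-of-3
CDS, junction-crossing variants, screened accessions) do the corresponding
work.

## Problem sizes and numerics

The test suite runs a 10-gene × 20-accession universe (seeded), 1,000
random cDNAs of length ≤ 500 against the brute-force oracle, exhaustive
4⁴ Kozak-context enumeration, and coordinate round-trips over every exonic
base; the acceptance script uses a 30-gene × 40-accession cohort — sizes
chosen so each archetype and event class is exercised many times over.
Frequency columns are exact rational counts; the only tolerance in the
package is the 1e-9 normalization check in tests. Degenerate inputs are
defined rather than special-cased: zero-length leaders scan to an empty
list, empty variant sets reproduce the reference exactly, and an empty
accession group is an error.

## Known limitations

* No translation-efficiency prediction, ribosome-profiling integration, or
  conserved-peptide curation; the toolkit stops at sequence-level variant
  classification and emits causal variant IDs for external lookup.
* No alternative TSS inference: leaders are as annotated, and genes without
  an annotated leader are excluded from scanning.
* Structural variants, phasing and imputation are out of scope; variants
  destroying the mORF stop codon are logged but their downstream effects are
  not modelled.
* Identifiers are gene-local; there is no cross-gene or cross-species
  coordination.
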