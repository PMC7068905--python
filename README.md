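# uorfkit

Discovery and population-scale classification of upstream open reading
frames (uORFs) in annotated 5′ leaders.

uORFs are short ORFs whose start codon lies 5′ of a transcript's main ORF
(mORF). Because a scanning ribosome meets them first, they throttle mORF
translation, and a single SNP or INDEL that creates, destroys or reshapes a
uORF can change protein output without touching the protein sequence.
`uorfkit` finds these elements in reference annotations, rebuilds each
population accession's transcript from its variant calls, and describes how
every accession's uORF complement differs from the reference.

## What it computes

For each transcript the leader is scanned for start codons (default AUG;
configurable for non-AUG studies). Translation proceeds codon by codon to
the first stop, and each uORF is classified by where that stop falls:

* **Type1** — stop still in the 5′ leader (reinitiation of the mORF remains
  possible);
* **Type2** — stop inside the mORF region, out of frame (reinitiation is
  impossible; only leaky scanning rescues the mORF);
* **Type3** — in frame with the mORF, sharing its stop codon (an N-terminal
  extension).

Each record carries the uORF length (start through stop codon, so the
minimal AUG+stop uORF is 6 nt), the encoded peptide, the 5′/3′ spaces
(cap→uAUG and uORF stop→mAUG distances; the 3′ space is signed and negative
when the uORF overlaps the mORF), and the initiation-codon context (ICC) —
the 7-mer from −3 to +4 around the AUG (A = +1) — with a flag for the Kozak
consensus (A/G)CCAUGG.

At the population level, filtered homozygous SNPs/INDELs of each accession
are applied to the reference spliced cDNA to build a *pseudo-cDNA*, the
leader is rescanned, and every observed uORF is anchored back to reference
genome coordinates. Distinct forms get two-level identifiers **Level1.Level2**:
Level1 separates major changes (creation, loss, length change via SNP or
INDEL), Level2 separates substitutions via SNPs. Numbering starts at 1.1,
ordered by genomic anchor, then length (shorter first), then
deletion-before-insertion origin, then SNP count. The toolkit then reports
per-locus occurrence frequencies stratified by accession group (latitude
bins or labels), per-accession variant events (creation / loss /
length change / substitution / type switch), the three headline
type-attribute transitions (Type1-only↔Type2, uORF-free↔Type1-only,
uORF-free↔Type2) among splicing models and among accessions, and the
fraction of variant forms driven by at least two variants.

## Worked example

Single-sequence mode takes a cDNA and its CDS separately:

```python
from uorfkit import scan_cdna_with_cds

records = scan_cdna_with_cds(
    "CCATGAAATGAGGATGTTTTAG",   # cDNA
    "ATGTTTTAG",                # CDS
)
for r in records:
    print(f"start={r.start} type={r.uorf_type} length={r.length_nt} "
          f"peptide={r.peptide!r} icc={r.icc} kozak={r.kozak} "
          f"space5={r.space5} space3={r.space3}")
```

prints

```
start=2 type=Type1 length=9 peptide='MK' icc=NCCATGA kozak=False space5=2 space3=2
start=7 type=Type3 length=15 peptide='MRMF' icc=GAAATGA kozak=False space5=7 space3=-9
```

The 22-nt toy transcript has its mORF at offset 13. The AUG at offset 2
terminates at a leader stop after two codons (Type1, 9 nt, peptide MK, two
bases of 5′ and 3′ space); the AUG at offset 7 is in frame with the mORF and
runs through to the mORF's own stop (Type3, an N-extension), so its 3′
space is negative.

The same analysis runs from the shell over whole genomes:

```
uorfkit simulate --genes 10 --accessions 20 --seed 11 --out-dir fixture/
uorfkit scan       --fasta fixture/genome.fa --gff fixture/annotation.gff3 --out-dir scan_out/
uorfkit population --fasta fixture/genome.fa --gff fixture/annotation.gff3 \
                   --vcf fixture/variants.vcf --metadata fixture/metadata.tsv --out-dir pop_out/
uorfkit transitions --fasta fixture/genome.fa --gff fixture/annotation.gff3 --out-dir tr_out/
```

`simulate` writes a fully synthetic universe (genome, annotation, VCF,
metadata) together with machine-readable truth tables; `population` emits
per-form identifiers (`identifiers.tsv`), stratified frequencies
(`frequencies.tsv`, every column summing to 1 per locus), per-accession
events (`events.tsv`), screened accessions and a JSON summary. Every run
writes a `manifest.json` with the configuration and input checksums.

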