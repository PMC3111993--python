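# prokannot

A toolkit for automated structural curation and functional annotation of
bacterial and archaeal genomes.  It implements the computational core of a
classic evidence-hierarchy annotation workflow: a frameshift-tolerant
translated aligner for extended gene regions, evidence-directed curation
of gene models (start-site voting, overlap resolution, interevidence
regions), a hierarchical rule engine that turns heterogeneous evidence
into exactly one functional call per polypeptide, and deterministic
emission of GFF3/FASTA/TSV output.  It is aimed at people building or
studying prokaryotic annotation pipelines who want the decision rules as
inspectable, testable code rather than buried in a workflow engine.

## The rule system

**Extended alignment (BER-style).**  Each predicted gene's nucleotide
region, padded by 300 nt on both sides, is aligned against a subject
protein with a modified Smith–Waterman over (query nucleotide × subject
residue).  Besides codon matches and affine gaps, the dynamic program
allows frame-slip transitions consuming 1, 2, 4 or 5 nt per residue
(penalty −15) and can carry an alignment across a stop codon (score −10);
every slip or crossed stop is reported as a disruption event, giving a
per-gene frameshift/in-frame-stop report for manual review.  Matching
beyond the annotated boundaries exposes mis-called start sites.

**Structural curation.**  Start sites are chosen by voting: each of the
top alignments whose subject's first residue maps onto a candidate start
codon (ATG/GTG/TTG) casts a vote, a Shine–Dalgarno consensus match
(≥4/6 to AGGAGG, 4–14 nt upstream) casts one more, and ties fall to the
best supporting p-value, then to the annotated start.  Where two features
overlap by more than 60 bp, an evidence-free gene overlapping an
evidenced gene or an RNA is removed as a likely false positive; all other
such overlaps are flagged.  Maximal spans containing no evidenced gene
("interevidence regions") are emitted as FASTA for external re-search.

**Functional annotation (pFunc-style).**  Alignment matches below 40%
identity are discarded; 80% coverage separates Full from Partial on the
query and match axes; trusted matches are those with experimental
characterization (curated list or GO evidence codes EXP/IDA/IPI/IMP/
IGI/IEP).  Vague non-trusted names (putative, probable, …) become
"conserved hypothetical protein".  Each evidence type is reduced to its
best candidate via its own table (trusted/coverage classes for alignment
evidence; equivalog → … → Pfam isologies for HMMs; ≥5 predicted membrane
spans for topology; an SpII lipoprotein signal), then a single 17-rank
hierarchy picks the winner; with no evidence at all the product is
"hypothetical protein" with the three GO root terms.  Post-processing
repairs stuttered suffixes, relocates embedded EC numbers and gene
symbols, and backfills coarse functional roles from name keywords.

## Worked example

The package ships a deterministic generator that fabricates a two-contig
toy genome with planted scenarios (a clean gene, an upstream true start,
an engineered frameshift, an overlapping decoy ORF, lipoprotein-only and
membrane-only genes, an evidence-free gene) plus all matching evidence
files:

```sh
prokannot fixtures make --seed 1 --out fx
prokannot annotate \
    --genome fx/genome.fna --genes fx/genes.gff3 \
    --ber fx/ber_evidence.tsv \
    --hmm fx/hmm_evidence.tsv --hmm-metadata fx/hmm_metadata.tsv \
    --lipop fx/lipop.txt --tmhmm fx/tmhmm.txt \
    --gaf fx/goa.gaf --characterized fx/characterized.txt \
    --locus-prefix TOY --out out
```

which prints

```
annotated 9 genes (1 hypothetical), removed 1
```

and writes `out/annotation.tsv` beginning

```
locus_tag  gene_id  common_name                                gene_symbol  ...  final_rank  source_evidence
TOY_0001   gA01     DNA-directed RNA polymerase, beta subunit  rpoB         ...  1           HMM:TIGR00001
TOY_0002   gA02     possible alcohol dehydrogenase                          ...  14          BER:UP_ADH1
TOY_0003   gA03     possible beta-galactosidase                             ...  14          BER:UP_LACZ
```

Reading the run: the clean gene's above-cutoff equivalog HMM outranks
even its trusted full/full alignment match (rank 1 beats rank 2), so the
HMM's name and identifiers transfer.  `gA02`'s start was moved 30 nt
upstream (3 alignment votes plus a ribosome-binding-site vote, logged in
`out/start_report.tsv`); the evidence-free decoy ORF overlapping an
evidenced gene by 90 bp was removed (`out/curation_report.tsv`); the
engineered frameshift appears in `out/disruption_report.tsv` with its
nucleotide position and frame change; genes with only a lipoprotein
signal or only membrane spans receive their fallback names at ranks 12
and 11; the gene with no evidence at all is `hypothetical protein`.
Locus tags number features sequentially starting from the first gene of
the longest contig.

Every stage is also runnable standalone (`prokannot ber-align`,
`curate-starts`, `curate-overlaps`, `pfunc`) on the same file formats,
and the whole pipeline is byte-reproducible: identical inputs give
byte-identical outputs.

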