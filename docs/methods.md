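# Methods

This note documents the models, conventions and design choices behind
prokannot, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, translation and domain model

Internal coordinates are 0-based half-open on the forward strand; strand
is carried separately and GFF3 I/O (1-based inclusive) converts at the
boundary.  This makes overlap arithmetic (`min(ends) − max(starts)`)
exact and removes off-by-one ambiguity.  Translation uses NCBI genetic
code table 11 with ATG/GTG/TTG accepted as initiators; the first codon
of a complete CDS is rendered M whatever the initiator, internal and
terminal stops render as `*`.  A complete CDS must have length divisible
by three and translate without internal stops; the synthetic generator
asserts this for every model it plants.

All numeric operating points live in one registry
(`PipelineThresholds`): identity floor 40%, Full/Partial coverage cutoff
80% (inclusive: exactly 80% classifies Full), overlap action threshold
60 bp (strictly greater triggers), extension 300 nt per side, membrane
annotation at ≥5 predicted spans, up to 150 alignments per gene, seeding
e-value 1e-5.  All are validated (positive; percentages in (0,100]) and
overridable.

## Frameshift-tolerant extended alignment

The aligner is a local dynamic program over states (query nucleotide
position × subject residue × {aligned, gap-in-query, gap-in-subject}).
Moves into an aligned column consume k ∈ {1,2,3,4,5} query nucleotides
for one subject residue.  k = 3 is an ordinary codon column scored by
the substitution matrix; k ≠ 3 is a frame slip charged the frameshift
penalty (for k ∈ {4,5} the trailing three nucleotides form the scored
codon; for k ∈ {1,2} no full codon exists and only the penalty is
charged).  A codon column whose codon is a stop scores the stop penalty
instead of a matrix lookup.  Gaps are affine with the convention that
the first gap column costs `gap_open` and each further column
`gap_extend`.  Traceback is deterministic: at equal score an in-frame
diagonal beats a slip, smaller slips beat larger, a query-consuming gap
beats a subject-consuming one, and a shorter alignment beats a longer
one.  Every slip emits a `frameshift` disruption event recording the
frame transition, every crossed stop an `in_frame_stop` event; the
per-gene disruption report simply lists all events in retained matches.

Scoring defaults are BLOSUM62 with gap open −11 / extend −1, mirroring
the settings of the seeding translated search, with frameshift −15 and
stop −10.  The slip penalty is deliberately stiffer than a gap open so
disruptions are invoked only when the flanking similarity pays for them;
with both penalties sent to −∞ the aligner provably (and, in the tests,
empirically) degenerates to the best of three single-frame
Smith–Waterman runs.  Optimality is checked against an exhaustive
memoized-recursion oracle on hundreds of random instances (queries
≤24 nt, subjects ≤8 aa).

Extension pads the gene region by exactly 300 nt per side, clipped at
contig edges, once and never iterated; minus-strand genes are reverse
complemented first.  Query coverage is measured against the *unextended*
gene — only codon columns starting inside the annotated coding span
(stop codon excluded) count, over the gene's protein length — so an
alignment continuing upstream never inflates coverage.  Match coverage
is the fraction of subject residues aligned.  Where the seeding search
provides no p-value, a monotone score-ordered surrogate (2^−score) is
used; it is only ever used for ranking, never interpreted as a
probability.  Where subject residue 1 is not itself aligned, its query
position is extrapolated back along the first segment's frame so that
start-site voting can still use the match.

## Structural curation

Start candidates are all in-frame ATG/GTG/TTG codons between the nearest
upstream in-frame stop (within the 300 nt window) and a minimum-product
bound (default 30 aa), with no stop between candidate and the gene's
stop; the annotated start is always a candidate.  The top 10 alignments
by p-value vote for the candidate where subject residue 1 maps (exact
codon by default; a tolerance in codons is configurable), the
ribosome-binding-site consensus adds one vote per candidate (AGGAGG,
≥4/6 match, 3' end 4–14 nt upstream — canonical Shine–Dalgarno
defaults, all configurable), and ties break by smallest supporting
p-value, then to the annotated start.  One curation pass only: starts
are voted first, overlaps resolved second, and neither step is iterated.

Overlap resolution freezes evidence state at input (a gene "has
evidence" iff it has an alignment match at ≥40% identity or an HMM hit
at or above its trusted cutoff), so removals cannot cascade within a
pass and the outcome is independent of input order — both properties are
tested over randomized gene sets.  Pairs where both genes lack evidence
are flagged, not removed: the removal rules require an evidenced
partner.  RNA features count as evidence for their own span, both as
overlap partners and when interevidence regions are computed; a
predicted rRNA/tRNA is its own justification, and re-searching its span
with a translated search would be noise.  Interevidence regions shorter
than 90 nt are suppressed (configurable); the re-search itself is out of
scope — regions are emitted as FASTA.

## The annotation hierarchy

Per-type reduction first, then a single final hierarchy.

Alignment matches: after the identity filter, non-trusted names
containing an ambiguous term (default list: putative, probable,
possible, potential, predicted, uncharacterized, unknown, hypothetical,
homolog, like, related; word-boundary, case-insensitive, configurable)
are sanitized to "conserved hypothetical protein" with GO roots and the
conserved-hypothetical role.  The remaining matches map by (trusted,
query class, match class) to within-type ranks 1–5 and final ranks
{2, 4, 10, 14, 15, 16, 17}.  Two rows share within-type rank 2 but
transfer annotations differently — trusted partial-query/full-match
copies GO/roles from the subject while trusted full-query/partial-match
assigns GO roots and the unknown-function role — and this asymmetry is
implemented exactly as published.  A match partial on both axes fits no
row and yields no candidate.  Gene symbols and EC numbers transfer only
on full/full rows whose name is not rewritten into a domain-protein
form; rows that assign GO roots transfer neither.  A match must carry a
trusted flag derived from a curated characterized list, a database
experimental-evidence set, or experimental GO codes; the derivation is
monotone (more evidence never revokes trust).

HMM hits below their per-model trusted cutoff are never considered.
Isology maps to within-type rank (equivalog 1 … Pfam/hypothetical-
equivalog 7) and name suffix (none / " family protein" / " domain
protein"); GO terms and roles always transfer from the HMM metadata,
symbols and ECs only when the name is unmodified.  The within-type tie
between Pfam and hypothetical-equivalog breaks toward Pfam, whose final
rank is better.  Coverage is ignored for HMM candidates: the final
hierarchy's coverage columns are meaningful only for alignment evidence.

Final ranks: HMM equivalog 1; trusted full/full alignment 2; equivalog-
domain 3; trusted partial/full 4; subfamily 5; superfamily 6; subfamily-
domain 7; domain 8; Pfam 9; trusted full/partial 10; membrane topology
(≥5 spans, "putative integral membrane protein") 11; lipoprotein signal
(SpII, "putative lipoprotein") 12 — both with GO:0016020 and role 88;
hypothetical-equivalog 13; non-trusted full/full 14, partial/full 15,
full/partial 16; sanitized ambiguous 17.  The membrane-span criterion is
implemented as ≥5, the threshold the prose rule states.  No-evidence
polypeptides take a distinct HYPOTHETICAL sentinel — deliberately not a
numeric rank 18 — with name "hypothetical protein", the three GO roots
(GO:0008150, GO:0003674, GO:0005575) and the hypothetical-protein role.
The engine is total (exactly one call per polypeptide), permutation
invariant, and dominant (adding a worse candidate never changes the
winner); all three are property-tested.

Role-category ids other than 88 (cell envelope: other) are package
defaults — 156 conserved hypothetical, 157 hypothetical, 185 unknown
function — shipped in an editable table, as is the keyword→role
vocabulary used for backfilling; both are fixtures standing in for
site-specific curation vocabularies, not reconstructions of any
particular one.

## Post-processing

Name repair is an ordered, editable rule table (doubled-suffix rules
before stutter rules, so "x family protein family protein" collapses to
"x family protein"), iterated to a fixed point in ≤3 passes.  EC tokens
(d.d.d.d with '-' components allowed) are moved verbatim — partial EC
numbers remain valid annotations and no token is ever rewritten.  Gene
symbol extraction is deliberately conservative: only trailing
parenthesized letter-initial tokens of ≤6 characters, stripped to a
fixed point, keeping the first as the symbol.  Keyword-based role
assignment applies only when the role list is empty or holds only
placeholder roles, trying keywords longest-first.  The whole stage is
idempotent (property-tested over randomized compositions).

## Output conventions

Locus tags form one shared series over coding and RNA genes:
contigs ordered by length descending (ties by id), features by start
coordinate (ties: longer first, then id), `PREFIX_0001` onward.  GFF3
output emits gene + child feature pairs with product, locus_tag and
Dbxref (GO/EC/role) attributes and round-trips through the package's
reader exactly; FASTA and TSV emitters share the same global ordering,
and all emission is deterministic — identical inputs give byte-identical
files.  GFF3+FASTA+TSV replace the legacy XML/relational-database/
GenBank output path: they are the modern interoperable equivalents, and
database loading/visualization are services, not algorithms.

## The synthetic generator

The generator emulates the *decision surface* of the workflow, not the
statistics of real genomes: planted genes are random proteins
back-translated with uniform codon choice (no codon-usage or GC model),
intergenic sequence is A/C-biased to keep spurious starts and
RBS-lookalikes rare, and evidence rows carry hand-set identities,
coverages and p-values chosen to land on specific hierarchy rows.  Two
constructions are exact by design: the frameshift gene encodes an intact
60-residue homolog with one inserted nucleotide whose immediate in-frame
stop truncates the annotated model while the +1 frame carries the rest
of the protein (its evidence row is produced by actually running the
aligner, so the reported disruption is genuine); and the decoy ORF is
engineered on the antisense strand of an evidenced gene's tail — codons
whose reverse complements are stops are avoided globally so the decoy
reads through cleanly — overlapping it by exactly 90 bp.  The evidence
row for the frameshift scenario therefore also demonstrates what the
aligner reports on real data; everything else (identities of 95%, 88%,
72–68%, 81%, 55%; p-values 1e-120 … 1e-25; an HMM at 250 vs cutoff 100)
is a designed operating point, one per hierarchy behaviour.  A single
integer seed drives one `random.Random` stream; the same seed yields
byte-identical files.  Passing tests on this fixture show the rule
system fires exactly as specified; they do not show robustness to the
noise, contamination or compositional bias of real assemblies.

## Problem sizes and known limitations

The test suite and acceptance script run at desk scale: a ~3.8 kb
two-contig toy assembly, alignment-oracle instances of ≤24 nt × ≤8 aa
(500 random instances), 1000 randomized hierarchy bundles, 100 randomized
overlap and voting scenarios.  These sizes were chosen because every
rule in the system is exact — boundary behaviour, not asymptotics, is
what needs testing.  The aligner is pure Python with O(n·m) states and a
constant factor of ~7 transitions; it is comfortable for gene-scale
queries (≤ a few kb) against single subjects but is not a drop-in
replacement for a vectorized search tool over whole databases.  Known
functional limitations, intentionally out of scope: bifunctional
proteins receive a single call; duplicate gene symbols across a genome
are not arbitrated; similarity extending beyond the 300 nt pads needs
manual assessment; interevidence regions are emitted but not re-searched;
and gene/RNA prediction itself (the upstream model-training steps) is
not performed — the package curates and annotates an existing prediction
set.
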