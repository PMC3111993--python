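"""Shared domain model for prokaryotic annotation.

Coordinates are 0-based half-open on the forward strand throughout the
package; strand is stored separately and GFF3 I/O converts at the boundary.
Translation uses NCBI genetic code table 11 (bacterial/archaeal) with the
standard initiator convention: the first codon of a complete CDS is rendered
as methionine even for GTG/TTG starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

__all__ = [
    "InvalidAlphabetError",
    "FrameError",
    "CoordinateError",
    "Contig",
    "GeneModel",
    "Polypeptide",
    "PipelineThresholds",
    "FunctionalAnnotation",
    "EvidenceBundle",
    "HYPOTHETICAL",
    "GO_ROOT_TERMS",
    "ROLE_CELL_ENVELOPE_OTHER",
    "ROLE_CONSERVED_HYPOTHETICAL",
    "ROLE_HYPOTHETICAL",
    "ROLE_UNKNOWN_FUNCTION",
    "DNA_ALPHABET",
    "START_CODONS",
    "STOP_CODONS",
    "translate",
    "reverse_complement",
    "gff_to_internal",
    "internal_to_gff",
    "extract_cds",
    "polypeptide_for",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Initiator codons accepted for bacterial CDS models (Glimmer3 defaults).
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_FORWARD = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    _FORWARD[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Sentinel final rank for polypeptides with no usable evidence; deliberately
#: distinct from the numeric hierarchy so "no evidence" is never confused
#: with a real rank.
HYPOTHETICAL = "HYPOTHETICAL"

#: The three GO ontology roots (biological_process, molecular_function,
#: cellular_component), assigned whenever no informative terms transfer.
GO_ROOT_TERMS = (
    ("GO:0008150", "P"),
    ("GO:0003674", "F"),
    ("GO:0005575", "C"),
)

# Functional role-category ids.  88 (cell envelope: other) is the standard
# id used for membrane/lipoprotein fallback annotations; the remaining ids
# are package defaults and may be overridden via the role table.
ROLE_CELL_ENVELOPE_OTHER = 88
ROLE_CONSERVED_HYPOTHETICAL = 156
ROLE_HYPOTHETICAL = 157
ROLE_UNKNOWN_FUNCTION = 185


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class FrameError(ValueError):
    """A complete CDS whose length is not a multiple of three."""


class CoordinateError(ValueError):
    """Feature coordinates fall outside the containing sequence."""


def _validate_dna(nt: str) -> str:
    nt = nt.upper()
    bad = set(nt) - DNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"non-DNA characters {sorted(bad)} in sequence"
        )
    return nt


def reverse_complement(nt: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    nt = _validate_dna(nt)
    return nt.translate(_COMPLEMENT)[::-1]


def codon_to_aa(codon: str) -> str:
    """Translate one codon under table 11; '*' for stops, 'X' if ambiguous."""
    return _FORWARD.get(codon, "X")


def translate(nt: str, partial5: bool = False) -> str:
    """Translate a strand-oriented coding sequence under code table 11.

    Internal and terminal stops are rendered ``*``.  For a complete CDS
    (``partial5=False``) the initiator codon is rendered ``M`` when it is one
    of ATG/GTG/TTG, and the length must be a multiple of three.  For a
    5'-partial CDS any trailing incomplete codon is dropped and no initiator
    rule applies.
    """
    nt = _validate_dna(nt)
    if not partial5 and len(nt) % 3 != 0:
        raise FrameError(
            f"complete CDS length {len(nt)} is not a multiple of 3"
        )
    usable = len(nt) - len(nt) % 3
    aa = "".join(codon_to_aa(nt[i : i + 3]) for i in range(0, usable, 3))
    if not partial5 and aa and nt[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


@dataclass
class Contig:
    """One input nucleotide sequence (chromosome, plasmid or draft contig)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.sequence = _validate_dna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A predicted feature (CDS, rRNA or tRNA) on a contig.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    regardless of ``strand``.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    locus_tag: Optional[str] = None
    partial5: bool = False
    partial3: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.feature_type not in ("CDS", "rRNA", "tRNA"):
            raise ValueError(f"unsupported feature type {self.feature_type!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.id}: invalid span [{self.start}, {self.end})"
            )
        if (
            self.feature_type == "CDS"
            and not (self.partial5 or self.partial3)
            and (self.end - self.start) % 3 != 0
        ):
            raise FrameError(
                f"{self.id}: complete CDS length not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_on(self, contig: Contig) -> None:
        if self.contig_id != contig.id or self.end > contig.length:
            raise CoordinateError(
                f"{self.id} does not lie on contig {contig.id}"
            )


@dataclass
class Polypeptide:
    """Translated product of a CDS gene model (no terminal stop symbol)."""

    gene_id: str
    aa_sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


def extract_cds(contig: Contig, gene: GeneModel) -> str:
    """Strand-oriented (5'->3') nucleotide sequence of a gene model."""
    gene.validate_on(contig)
    span = contig.sequence[gene.start : gene.end]
    return reverse_complement(span) if gene.strand == "-" else span


def polypeptide_for(contig: Contig, gene: GeneModel) -> Polypeptide:
    """Translate a CDS model; the terminal stop is stripped when present."""
    aa = translate(extract_cds(contig, gene), partial5=gene.partial5)
    if aa.endswith("*"):
        aa = aa[:-1]
    return Polypeptide(gene_id=gene.id, aa_sequence=aa)


@dataclass
class PipelineThresholds:
    """Every numeric knob of the annotation rule system, in one place.

    Defaults are the published operating points of the rule system:
    matches below 40% identity are dropped, 80% coverage separates full
    from partial alignments, overlaps must exceed 60 bp to act on, genes
    are extended 300 nt per side before alignment, membrane annotation
    requires >=5 predicted spans, and the seeding search keeps up to 150
    alignments at e-value 1e-5.
    """

    ber_min_identity_pct: float = 40.0
    full_coverage_cutoff_pct: float = 80.0
    overlap_threshold_bp: int = 60
    extension_nt: int = 300
    tmhmm_min_spans: int = 5
    max_alignments: int = 150
    blast_evalue: float = 1e-5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "ber_min_identity_pct",
            "full_coverage_cutoff_pct",
            "overlap_threshold_bp",
            "extension_nt",
            "tmhmm_min_spans",
            "max_alignments",
            "blast_evalue",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("ber_min_identity_pct", "full_coverage_cutoff_pct"):
            if not 0 < getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in (0, 100]")


@dataclass
class FunctionalAnnotation:
    """The single functional call made for one polypeptide."""

    gene_id: str
    common_name: str
    gene_symbol: Optional[str] = None
    ec_numbers: list[str] = field(default_factory=list)
    go_terms: list[tuple[str, str]] = field(default_factory=list)
    tigr_roles: list[int] = field(default_factory=list)
    source_evidence: Optional[str] = None
    final_rank: object = HYPOTHETICAL

    def __post_init__(self) -> None:
        if not self.common_name:
            raise ValueError(f"{self.gene_id}: common name must be non-empty")

    def replace(self, **kwargs) -> "FunctionalAnnotation":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EvidenceBundle:
    """All evidence collected for one polypeptide."""

    gene_id: str
    ber_matches: list = field(default_factory=list)
    hmm_hits: list = field(default_factory=list)
    lipop: Optional[object] = None
    tmhmm: Optional[object] = None
    attachments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in list(self.ber_matches) + list(self.hmm_hits):
            if ev.gene_id != self.gene_id:
                raise ValueError(
                    f"evidence for {ev.gene_id} in bundle for {self.gene_id}"
                )
        for ev in (self.lipop, self.tmhmm):
            if ev is not None and ev.gene_id != self.gene_id:
                raise ValueError(
                    f"evidence for {ev.gene_id} in bundle for {self.gene_id}"
                )
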