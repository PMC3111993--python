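"""Evidence-directed structural curation of gene models.

Three operations refine a raw gene set: start-site selection by voting
(extended-alignment subject starts plus a ribosome-binding-site consensus
match each contribute one vote), removal of evidence-free genes that
overlap an evidenced gene or an RNA by more than 60 bp, and emission of
"interevidence" regions — maximal spans of intergenic sequence plus
evidence-free genes — for external re-searching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .ber import extend_query
from .core import (
    Contig,
    EvidenceBundle,
    GeneModel,
    PipelineThresholds,
    START_CODONS,
    STOP_CODONS,
)
from .evidence import BerMatch

__all__ = [
    "StartCandidate",
    "OverlapDecision",
    "InterevidenceRegion",
    "RbsConfig",
    "enumerate_start_candidates",
    "rbs_vote",
    "vote_start_sites",
    "apply_start",
    "has_evidence",
    "curate_overlaps",
    "find_interevidence_regions",
]


@dataclass
class StartCandidate:
    """A potential start codon for a gene.

    ``nt_position`` is strand-oriented and relative to the annotated start
    codon (0 = annotated start, negative = upstream, always a multiple of
    three).
    """

    nt_position: int
    codon: str
    ber_votes: int = 0
    rbs_vote: int = 0
    best_supporting_p_value: Optional[float] = None

    @property
    def total_votes(self) -> int:
        return self.ber_votes + self.rbs_vote


@dataclass
class RbsConfig:
    """Shine-Dalgarno consensus matching parameters."""

    consensus: str = "AGGAGG"
    min_matches: int = 4
    spacer_min: int = 4
    spacer_max: int = 14


@dataclass
class OverlapDecision:
    feature_a: str
    feature_b: str
    overlap_bp: int
    action: str  # remove_a | remove_b | flag | none
    rationale: str

    def __post_init__(self) -> None:
        if self.action not in ("remove_a", "remove_b", "flag", "none"):
            raise ValueError(f"unknown action {self.action!r}")


@dataclass
class InterevidenceRegion:
    contig_id: str
    start: int
    end: int
    member_gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_start_candidates(
    contig: Contig,
    gene: GeneModel,
    thresholds: Optional[PipelineThresholds] = None,
    min_product_aa: int = 30,
) -> list[StartCandidate]:
    """All viable in-frame start codons for a complete CDS, 5'->3'.

    Candidates are ATG/GTG/TTG codons in frame with the gene's stop,
    bounded upstream by the nearest in-frame stop within the extension
    window and downstream by the minimum product length.  The annotated
    start is always included, whatever its codon.  No candidate has an
    in-frame stop between itself and the gene's stop codon.
    """
    thresholds = thresholds or PipelineThresholds()
    eq = extend_query(contig, gene, thresholds)
    seq = eq.nt_sequence
    off = eq.original_start_offset
    gene_nt = eq.gene_nt_length

    r_min = -(off - off % 3)
    r_max = gene_nt - 3 * max(min_product_aa, 1) - 3  # leave room + stop
    candidates: list[StartCandidate] = []
    upstream_stop_bound = r_min
    # find the in-frame stop nearest to the annotated start
    for r in range(r_min, 0, 3):
        codon = seq[off + r : off + r + 3]
        if codon in STOP_CODONS:
            upstream_stop_bound = r + 3
    for r in range(upstream_stop_bound, max(r_max, 0) + 1, 3):
        codon = seq[off + r : off + r + 3]
        if len(codon) < 3:
            continue
        if r == 0 or codon in START_CODONS:
            # reject candidates with an in-frame stop before the gene stop
            blocked = any(
                seq[off + p : off + p + 3] in STOP_CODONS
                for p in range(r, gene_nt - 3, 3)
            )
            if not blocked or r == 0:
                candidates.append(StartCandidate(nt_position=r, codon=codon))
    if not any(c.nt_position == 0 for c in candidates):
        candidates.append(
            StartCandidate(nt_position=0, codon=seq[off : off + 3])
        )
    candidates.sort(key=lambda c: c.nt_position)
    return candidates


def rbs_vote(
    contig: Contig,
    gene: GeneModel,
    candidate: StartCandidate,
    config: Optional[RbsConfig] = None,
    thresholds: Optional[PipelineThresholds] = None,
) -> int:
    """1 iff a consensus ribosome-binding site sits upstream of a candidate.

    The hexamer consensus (default AGGAGG) may sit with its 3' end 4-14 nt
    upstream of the candidate start; a placement matching at >=4 of 6
    positions counts.
    """
    config = config or RbsConfig()
    thresholds = thresholds or PipelineThresholds()
    eq = extend_query(contig, gene, thresholds)
    seq = eq.nt_sequence
    cand = eq.original_start_offset + candidate.nt_position
    w = len(config.consensus)
    for spacer in range(config.spacer_min, config.spacer_max + 1):
        start = cand - spacer - w
        if start < 0:
            continue
        window = seq[start : start + w]
        matches = sum(a == b for a, b in zip(window, config.consensus))
        if matches >= config.min_matches:
            return 1
    return 0


def vote_start_sites(
    candidates: Sequence[StartCandidate],
    ber_matches: Sequence[BerMatch],
    rbs_votes: Optional[Mapping[int, int]] = None,
    top_n: int = 10,
    tolerance_codons: int = 0,
) -> tuple[StartCandidate, list[StartCandidate]]:
    """Pick the start with the most votes; return (winner, tally table).

    The top ``top_n`` alignments by p-value each contribute one vote to the
    candidate where subject residue 1 aligns (exact codon by default).  An
    upstream consensus match adds one vote per candidate.  Ties are broken
    by the smallest supporting p-value; a persisting tie keeps the
    annotated start.
    """
    if not candidates:
        raise ValueError("need at least one start candidate")
    tally = [
        StartCandidate(
            nt_position=c.nt_position,
            codon=c.codon,
            rbs_vote=(rbs_votes or {}).get(c.nt_position, 0),
        )
        for c in candidates
    ]
    by_pos = {c.nt_position: c for c in tally}
    top = sorted(
        (m for m in ber_matches if m.subject_start_query_nt is not None),
        key=lambda m: (m.p_value, m.subject_id),
    )[:top_n]
    tol_nt = 3 * tolerance_codons
    for match in top:
        for cand in tally:
            if abs(match.subject_start_query_nt - cand.nt_position) <= tol_nt:
                cand.ber_votes += 1
                if (
                    cand.best_supporting_p_value is None
                    or match.p_value < cand.best_supporting_p_value
                ):
                    cand.best_supporting_p_value = match.p_value
    def sort_key(c: StartCandidate):
        return (
            -c.total_votes,
            c.best_supporting_p_value
            if c.best_supporting_p_value is not None
            else float("inf"),
            c.nt_position != 0,  # annotated start wins remaining ties
            abs(c.nt_position),
            c.nt_position,
        )

    winner = min(tally, key=sort_key)
    if winner.total_votes == 0:
        winner = by_pos[0] if 0 in by_pos else winner
    return winner, tally


def apply_start(gene: GeneModel, chosen: StartCandidate) -> GeneModel:
    """Return a gene model with its start moved to the chosen candidate."""
    rel = chosen.nt_position
    if rel == 0:
        return gene
    if gene.strand == "+":
        return GeneModel(
            id=gene.id,
            contig_id=gene.contig_id,
            start=gene.start + rel,
            end=gene.end,
            strand=gene.strand,
            feature_type=gene.feature_type,
            locus_tag=gene.locus_tag,
            partial5=gene.partial5,
            partial3=gene.partial3,
        )
    return GeneModel(
        id=gene.id,
        contig_id=gene.contig_id,
        start=gene.start,
        end=gene.end - rel,
        strand=gene.strand,
        feature_type=gene.feature_type,
        locus_tag=gene.locus_tag,
        partial5=gene.partial5,
        partial3=gene.partial3,
    )


def has_evidence(
    bundle: Optional[EvidenceBundle],
    thresholds: Optional[PipelineThresholds] = None,
) -> bool:
    """Whether a gene has similarity evidence usable for curation.

    True iff it has an extended-alignment match at or above the identity
    floor, or a profile-HMM hit passing its trusted cutoff.
    """
    if bundle is None:
        return False
    thresholds = thresholds or PipelineThresholds()
    if any(
        m.percent_identity >= thresholds.ber_min_identity_pct
        for m in bundle.ber_matches
    ):
        return True
    return any(h.passes_trusted for h in bundle.hmm_hits)


def _overlap_bp(a: GeneModel, b: GeneModel) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def curate_overlaps(
    features: Sequence[GeneModel],
    evidence: Mapping[str, EvidenceBundle],
    thresholds: Optional[PipelineThresholds] = None,
) -> tuple[list[GeneModel], list[GeneModel], list[OverlapDecision]]:
    """Resolve overlapping features; returns (kept, removed, decisions).

    For every pair overlapping by more than the threshold (60 bp): an
    evidence-free protein-coding gene overlapping an evidenced gene or an
    RNA is removed as a likely false positive; every other such pair is
    flagged for manual review.  Smaller overlaps are untouched.  Evidence
    state is frozen at input, so removals never cascade within a pass, and
    the outcome is independent of input order.
    """
    thresholds = thresholds or PipelineThresholds()
    ordered = sorted(
        features, key=lambda f: (f.contig_id, f.start, f.end, f.id)
    )
    ev = {
        f.id: (
            f.feature_type != "CDS"
            or has_evidence(evidence.get(f.id), thresholds)
        )
        for f in ordered
    }
    removed_ids: set[str] = set()
    decisions: list[OverlapDecision] = []
    for idx, a in enumerate(ordered):
        for b in ordered[idx + 1 :]:
            if b.contig_id != a.contig_id or b.start >= a.end:
                break
            ov = _overlap_bp(a, b)
            if ov <= thresholds.overlap_threshold_bp:
                continue
            a_cds_free = a.feature_type == "CDS" and not ev[a.id]
            b_cds_free = b.feature_type == "CDS" and not ev[b.id]
            if a_cds_free and ev[b.id]:
                action, rationale = "remove_a", (
                    "evidence-free gene overlaps "
                    + ("RNA" if b.feature_type != "CDS" else "evidenced gene")
                )
                removed_ids.add(a.id)
            elif b_cds_free and ev[a.id]:
                action, rationale = "remove_b", (
                    "evidence-free gene overlaps "
                    + ("RNA" if a.feature_type != "CDS" else "evidenced gene")
                )
                removed_ids.add(b.id)
            else:
                action, rationale = "flag", "overlap needs manual review"
            decisions.append(
                OverlapDecision(
                    feature_a=a.id,
                    feature_b=b.id,
                    overlap_bp=ov,
                    action=action,
                    rationale=rationale,
                )
            )
    kept = [f for f in ordered if f.id not in removed_ids]
    removed = [f for f in ordered if f.id in removed_ids]
    return kept, removed, decisions


def find_interevidence_regions(
    contig: Contig,
    features: Sequence[GeneModel],
    evidence: Mapping[str, EvidenceBundle],
    thresholds: Optional[PipelineThresholds] = None,
    min_length: int = 90,
) -> list[InterevidenceRegion]:
    """Maximal spans of intergenic sequence plus evidence-free genes.

    Spans are bounded by evidenced genes (RNA features count as evidenced
    for their own span) or contig ends; spans shorter than ``min_length``
    are suppressed.  ``member_gene_ids`` lists the evidence-free genes
    wholly inside each region.
    """
    thresholds = thresholds or PipelineThresholds()
    on_contig = [f for f in features if f.contig_id == contig.id]
    evidenced = [
        f
        for f in on_contig
        if f.feature_type != "CDS"
        or has_evidence(evidence.get(f.id), thresholds)
    ]
    # merge evidenced intervals
    merged: list[list[int]] = []
    for f in sorted(evidenced, key=lambda f: (f.start, f.end)):
        if merged and f.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], f.end)
        else:
            merged.append([f.start, f.end])
    regions: list[InterevidenceRegion] = []
    cursor = 0
    bounds = merged + [[contig.length, contig.length]]
    free_genes = [f for f in on_contig if f not in evidenced]
    for start, end in bounds:
        if start - cursor >= min_length:
            members = sorted(
                f.id
                for f in free_genes
                if cursor <= f.start and f.end <= start
            )
            regions.append(
                InterevidenceRegion(
                    contig_id=contig.id,
                    start=cursor,
                    end=start,
                    member_gene_ids=members,
                )
            )
        cursor = max(cursor, end)
    return regions
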