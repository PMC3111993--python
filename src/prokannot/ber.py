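"""Frameshift-tolerant translated alignment of extended gene regions.

The aligner takes the nucleotide region of a predicted gene, padded by up
to 300 nt on each side, and aligns its translation against a subject
protein with a modified Smith-Waterman.  The dynamic program runs over
(query nucleotide position x subject residue) and, in addition to the
usual codon match and affine gap moves, allows "frame slip" columns that
consume 1, 2, 4 or 5 query nucleotides for one subject residue.  Each slip
is charged a frameshift penalty and reported as a disruption event, as is
every stop codon the alignment is carried across.  Because the query is
padded, a strong alignment can continue past the annotated gene
boundaries, exposing mis-called starts, frameshifts and in-frame stops.

Gap convention: the first column of a gap run costs ``gap_open``, each
further column ``gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from .core import (
    Contig,
    GeneModel,
    PipelineThresholds,
    codon_to_aa,
    reverse_complement,
)
from .evidence import BerMatch, DisruptionEvent

__all__ = [
    "ExtendedQuery",
    "ScoringScheme",
    "AlignmentColumn",
    "FrameshiftAlignment",
    "extend_query",
    "align_frameshift",
    "alignment_metrics",
    "ber_match_from_alignment",
    "align_gene_to_subject",
    "disruption_report",
    "DisruptionReportRow",
]

NEG_INF = float("-inf")

# Query-nt advances for one aligned subject residue; 3 is an in-frame codon,
# the rest are frame slips.  Listed in deterministic tie-break preference:
# in-frame first, then the smallest slip, lower frame first.
_K_ORDER = (3, 2, 4, 1, 5)

# Traceback state codes.
_M, _IX, _IY, _START = 0, 1, 2, 3


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


@dataclass
class ScoringScheme:
    """Scoring parameters for the frameshift-tolerant aligner.

    The substitution matrix and gap parameters mirror the settings of the
    seeding translated search (BLOSUM62, 11/1).  The frameshift penalty is
    deliberately stiffer than a gap open so that slips are only taken when
    strongly supported by downstream similarity; carrying the alignment
    across a stop codon costs ``stop_codon_score`` instead of a matrix
    lookup.
    """

    matrix: object = None
    gap_open: float = -11.0
    gap_extend: float = -1.0
    frameshift_penalty: float = -15.0
    stop_codon_score: float = -10.0

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = _blosum62()
        for name in (
            "gap_open",
            "gap_extend",
            "frameshift_penalty",
            "stop_codon_score",
        ):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative")

    def substitution(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[a, b])
        except (KeyError, IndexError):
            return 0.0


@dataclass
class ExtendedQuery:
    """A gene's nucleotide region padded for alignment, read 5'->3'.

    ``nt_sequence`` is strand-oriented (minus-strand genes are reverse
    complemented), so the annotated start codon begins at
    ``original_start_offset`` (== ``upstream_pad``).
    """

    gene_id: str
    nt_sequence: str
    upstream_pad: int
    downstream_pad: int

    def __post_init__(self) -> None:
        if not 0 <= self.upstream_pad or not 0 <= self.downstream_pad:
            raise ValueError("pads must be non-negative")

    @property
    def original_start_offset(self) -> int:
        return self.upstream_pad

    @property
    def gene_nt_length(self) -> int:
        return len(self.nt_sequence) - self.upstream_pad - self.downstream_pad


def extend_query(
    contig: Contig,
    gene: GeneModel,
    thresholds: Optional[PipelineThresholds] = None,
) -> ExtendedQuery:
    """Pad a gene's region by up to ``extension_nt`` per side (300 default).

    Pads are clipped at contig edges; minus-strand genes are returned
    reverse complemented so the gene reads 5'->3'.  Extension is applied
    exactly once, never iterated.
    """
    thresholds = thresholds or PipelineThresholds()
    gene.validate_on(contig)
    ext = thresholds.extension_nt
    w_start = max(0, gene.start - ext)
    w_end = min(contig.length, gene.end + ext)
    window = contig.sequence[w_start:w_end]
    if gene.strand == "-":
        window = reverse_complement(window)
        upstream = w_end - gene.end
        downstream = gene.start - w_start
    else:
        upstream = gene.start - w_start
        downstream = w_end - gene.end
    return ExtendedQuery(
        gene_id=gene.id,
        nt_sequence=window,
        upstream_pad=upstream,
        downstream_pad=downstream,
    )


@dataclass
class AlignmentColumn:
    """One traceback column.

    ``kind`` is ``aligned`` (consumes ``k`` query nt and one subject
    residue), ``gap_subject`` (one query codon, no subject residue) or
    ``gap_query`` (one subject residue, no query nt).
    """

    kind: str
    query_start: Optional[int]  # start nt of consumed query span
    query_len: int
    subject_index: Optional[int]
    query_aa: Optional[str] = None
    subject_aa: Optional[str] = None

    @property
    def frame(self) -> Optional[int]:
        if self.query_start is None:
            return None
        return self.query_start % 3


@dataclass
class FrameshiftAlignment:
    """Result of one extended-query vs protein alignment."""

    score: float
    columns: list[AlignmentColumn]
    disruptions: list[DisruptionEvent]
    percent_identity: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    coordinate_map: list[tuple[int, int]]  # (query nt, subject residue idx)
    query: Optional[ExtendedQuery] = None
    subject_aa: str = ""
    query_coverage_pct: Optional[float] = None
    subject_coverage_pct: Optional[float] = None

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """(frame, first query nt, last query nt end) per constant-frame run."""
        segs: list[tuple[int, int, int]] = []
        for col in self.columns:
            if col.query_start is None:
                continue
            frame = col.frame
            end = col.query_start + col.query_len
            if segs and segs[-1][0] == frame and segs[-1][2] == col.query_start:
                segs[-1] = (frame, segs[-1][1], end)
            else:
                segs.append((frame, col.query_start, end))
        return segs

    def subject_start_query_nt(self) -> Optional[int]:
        """Query nt where subject residue 1 aligns (extrapolated if unaligned)."""
        if not self.coordinate_map:
            return None
        q0, j0 = self.coordinate_map[0]
        return q0 - 3 * j0


def align_frameshift(
    query: ExtendedQuery,
    subject_aa: str,
    scoring: Optional[ScoringScheme] = None,
) -> FrameshiftAlignment:
    """Optimal local frameshift-tolerant alignment (deterministic traceback).

    Tie order: in-frame diagonal before frame slips, query-consuming gap
    ("up") before subject-consuming gap ("left"), lower frame first.
    """
    if not subject_aa:
        raise ValueError("subject protein must be non-empty")
    if len(query.nt_sequence) < 3:
        raise ValueError("query must be at least one codon long")
    scoring = scoring or ScoringScheme()
    q = query.nt_sequence
    n, m = len(q), len(subject_aa)

    # codon ending at nt i (i >= 3)
    aa_at = [None] * (n + 1)
    stop_at = [False] * (n + 1)
    for i in range(3, n + 1):
        aa = codon_to_aa(q[i - 3 : i])
        aa_at[i] = aa
        stop_at[i] = aa == "*"

    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptrM: list[list[Optional[tuple[int, int]]]] = [
        [None] * (m + 1) for _ in range(n + 1)
    ]
    ptrIx = [[0] * (m + 1) for _ in range(n + 1)]
    ptrIy = [[0] * (m + 1) for _ in range(n + 1)]

    best = (0.0, 0, 0)  # empty alignment fallback
    for i in range(0, n + 1):
        Mi, Ixi, Iyi = M[i], Ix[i], Iy[i]
        for j in range(1, m + 1):
            s_aa = subject_aa[j - 1]
            # aligned column
            best_val = NEG_INF
            best_ptr: Optional[tuple[int, int]] = None
            for k in _K_ORDER:
                pi = i - k
                if pi < 0:
                    continue
                if k >= 3:
                    col = (
                        scoring.stop_codon_score
                        if stop_at[i]
                        else scoring.substitution(aa_at[i], s_aa)
                    )
                else:
                    col = 0.0
                if k != 3:
                    col += scoring.frameshift_penalty
                # predecessor preference: fresh start, then M > Iy > Ix
                for state, prev in (
                    (_START, 0.0),
                    (_M, M[pi][j - 1]),
                    (_IY, Iy[pi][j - 1]),
                    (_IX, Ix[pi][j - 1]),
                ):
                    if prev == NEG_INF:
                        continue
                    if state == _START:
                        val = col
                    else:
                        val = prev + col
                    if val > best_val:
                        best_val = val
                        best_ptr = (k, state)
            Mi[j] = best_val
            ptrM[i][j] = best_ptr
            # gap in query (consume subject residue): from column j-1, row i
            open_ = Mi[j - 1] + scoring.gap_open
            ext_ = Ixi[j - 1] + scoring.gap_extend
            if open_ >= ext_:
                Ixi[j] = open_
                ptrIx[i][j] = _M
            else:
                Ixi[j] = ext_
                ptrIx[i][j] = _IX
            # gap in subject (consume one query codon)
            if i >= 3:
                open_ = M[i - 3][j] + scoring.gap_open
                ext_ = Iy[i - 3][j] + scoring.gap_extend
                if open_ >= ext_:
                    Iyi[j] = open_
                    ptrIy[i][j] = _M
                else:
                    Iyi[j] = ext_
                    ptrIy[i][j] = _IY
            if Mi[j] > best[0]:
                best = (Mi[j], i, j)

    score, bi, bj = best
    columns: list[AlignmentColumn] = []
    if score > 0:
        i, j, state = bi, bj, _M
        while True:
            if state == _M:
                k, prev_state = ptrM[i][j]
                q_start = i - k
                codon_aa = aa_at[i] if k >= 3 else "X"
                columns.append(
                    AlignmentColumn(
                        kind="aligned",
                        query_start=q_start,
                        query_len=k,
                        subject_index=j - 1,
                        query_aa=codon_aa,
                        subject_aa=subject_aa[j - 1],
                    )
                )
                i, j = i - k, j - 1
                if prev_state == _START:
                    break
                state = prev_state
            elif state == _IX:
                prev = ptrIx[i][j]
                columns.append(
                    AlignmentColumn(
                        kind="gap_query",
                        query_start=None,
                        query_len=0,
                        subject_index=j - 1,
                        subject_aa=subject_aa[j - 1],
                    )
                )
                j -= 1
                state = prev
            else:  # _IY
                prev = ptrIy[i][j]
                columns.append(
                    AlignmentColumn(
                        kind="gap_subject",
                        query_start=i - 3,
                        query_len=3,
                        subject_index=None,
                        query_aa=aa_at[i],
                    )
                )
                i -= 3
                state = prev
        columns.reverse()

    disruptions: list[DisruptionEvent] = []
    prev_frame: Optional[int] = None
    identical = 0
    coord_map: list[tuple[int, int]] = []
    for col in columns:
        if col.query_start is not None:
            frame = col.frame
            if col.kind == "aligned" and col.query_len != 3:
                # frame before the slip vs frame the alignment continues in
                disruptions.append(
                    DisruptionEvent(
                        kind="frameshift",
                        query_nt_position=col.query_start,
                        frames_involved=(
                            frame,
                            (col.query_start + col.query_len) % 3,
                        ),
                    )
                )
            if (
                col.kind == "aligned"
                and col.query_len >= 3
                and col.query_aa == "*"
            ):
                disruptions.append(
                    DisruptionEvent(
                        kind="in_frame_stop",
                        query_nt_position=col.query_start,
                        frames_involved=(frame, frame),
                    )
                )
            prev_frame = frame
        if col.kind == "aligned":
            coord_map.append((col.query_start, col.subject_index))
            if (
                col.query_len >= 3
                and col.query_aa == col.subject_aa
                and col.query_aa != "*"
            ):
                identical += 1

    n_cols = len(columns)
    identity = 100.0 * identical / n_cols if n_cols else 0.0
    q_positions = [c.query_start for c in columns if c.query_start is not None]
    s_positions = [
        c.subject_index for c in columns if c.subject_index is not None
    ]
    return FrameshiftAlignment(
        score=score,
        columns=columns,
        disruptions=disruptions,
        percent_identity=identity,
        query_start=min(q_positions) if q_positions else 0,
        query_end=max(
            c.query_start + c.query_len
            for c in columns
            if c.query_start is not None
        )
        if q_positions
        else 0,
        subject_start=min(s_positions) if s_positions else 0,
        subject_end=max(s_positions) + 1 if s_positions else 0,
        coordinate_map=coord_map,
        query=query,
        subject_aa=subject_aa,
    )


def alignment_metrics(
    aln: FrameshiftAlignment,
    gene: GeneModel,
    subject_aa: str,
    thresholds: Optional[PipelineThresholds] = None,
) -> tuple[float, float, float]:
    """(identity, query coverage %, subject coverage %) for an alignment.

    Query coverage is measured against the *unextended* gene: only aligned
    codon columns whose start falls inside the annotated coding span
    (excluding the stop codon) count, divided by the gene's protein length.
    Subject coverage is the fraction of subject residues aligned.
    """
    if aln.query is None:
        raise ValueError("alignment carries no extended query")
    offset = aln.query.original_start_offset
    gene_nt = gene.length
    protein_len = gene_nt // 3 - 1
    if protein_len <= 0:
        raise ValueError(f"{gene.id}: gene too short for a protein product")
    in_gene = {
        c.query_start
        for c in aln.columns
        if c.kind == "aligned"
        and c.query_start is not None
        and offset <= c.query_start < offset + gene_nt - 3
    }
    query_cov = min(100.0, 100.0 * len(in_gene) / protein_len)
    subject_res = {
        c.subject_index for c in aln.columns if c.subject_index is not None
    }
    subject_cov = 100.0 * len(subject_res) / len(subject_aa)
    aln.query_coverage_pct = query_cov
    aln.subject_coverage_pct = subject_cov
    return aln.percent_identity, query_cov, subject_cov


def align_gene_to_subject(
    contig: Contig,
    gene: GeneModel,
    subject_aa: str,
    scoring: Optional[ScoringScheme] = None,
    thresholds: Optional[PipelineThresholds] = None,
) -> FrameshiftAlignment:
    """Extend, align and attach coverage metrics in one call."""
    eq = extend_query(contig, gene, thresholds)
    aln = align_frameshift(eq, subject_aa, scoring)
    alignment_metrics(aln, gene, subject_aa, thresholds)
    return aln


def ber_match_from_alignment(
    aln: FrameshiftAlignment,
    gene: GeneModel,
    subject_id: str,
    subject_name: str,
    p_value: Optional[float] = None,
    **subject_fields,
) -> BerMatch:
    """Convert an alignment into the canonical evidence record.

    When the seeding search supplies no p-value, a score-ordered surrogate
    is used (monotone decreasing in score) so that ranking by p-value
    reproduces ranking by score.
    """
    if aln.query_coverage_pct is None:
        raise ValueError("run alignment_metrics before building a match")
    if p_value is None:
        p_value = 2.0 ** (-max(aln.score, 0.0))
        p_value = max(p_value, 1e-300)
    offset = aln.query.original_start_offset
    ssq = aln.subject_start_query_nt()
    return BerMatch(
        gene_id=gene.id,
        subject_id=subject_id,
        subject_name=subject_name,
        percent_identity=aln.percent_identity,
        query_coverage_pct=aln.query_coverage_pct,
        subject_coverage_pct=aln.subject_coverage_pct,
        p_value=p_value,
        score=aln.score,
        disruptions=list(aln.disruptions),
        subject_start_query_nt=None if ssq is None else ssq - offset,
        subject_length=len(aln.subject_aa),
        **subject_fields,
    )


@dataclass
class DisruptionReportRow:
    gene_id: str
    subject_id: str
    kind: str
    query_nt_position: int
    frames_involved: tuple[int, int]


def disruption_report(
    matches_by_gene: dict[str, Sequence[BerMatch]]
) -> list[DisruptionReportRow]:
    """Genes whose retained alignments contain frameshifts / in-frame stops.

    One row per disruption event, for manual review.  Genes with no
    disruptions in any retained alignment are absent from the report.
    """
    rows: list[DisruptionReportRow] = []
    for gene_id in sorted(matches_by_gene):
        for match in matches_by_gene[gene_id]:
            for ev in match.disruptions:
                rows.append(
                    DisruptionReportRow(
                        gene_id=gene_id,
                        subject_id=match.subject_id,
                        kind=ev.kind,
                        query_nt_position=ev.query_nt_position,
                        frames_involved=ev.frames_involved,
                    )
                )
    return rows
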