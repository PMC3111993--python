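"""Hierarchical functional annotation (the pFunc rule system).

Each evidence type is first reduced to its best candidate annotation
using a per-type hierarchy (extended-alignment matches by trusted status
and query/match coverage class; HMM hits by family-specificity class),
then a single cross-evidence hierarchy of 17 numbered ranks picks the
winning candidate.  Polypeptides with no usable evidence fall back to
"hypothetical protein" with the three GO root terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    EvidenceBundle,
    FunctionalAnnotation,
    GO_ROOT_TERMS,
    HYPOTHETICAL,
    PipelineThresholds,
    ROLE_CELL_ENVELOPE_OTHER,
    ROLE_CONSERVED_HYPOTHETICAL,
    ROLE_HYPOTHETICAL,
    ROLE_UNKNOWN_FUNCTION,
)
from .evidence import (
    BerMatch,
    HmmHit,
    LipopPrediction,
    TmhmmPrediction,
)

__all__ = [
    "CandidateAnnotation",
    "DEFAULT_AMBIGUOUS_TERMS",
    "coverage_class",
    "filter_ber",
    "sanitize_ambiguous",
    "rank_ber",
    "best_ber",
    "filter_and_rank_hmm",
    "annotate_lipop",
    "annotate_tmhmm",
    "pfunc_final",
]

#: Name tokens that make a non-trusted transferred name too vague to keep.
DEFAULT_AMBIGUOUS_TERMS = (
    "putative",
    "probable",
    "possible",
    "potential",
    "predicted",
    "uncharacterized",
    "unknown",
    "hypothetical",
    "homolog",
    "like",
    "related",
)

_GO_MEMBRANE = ("GO:0016020", "C")

# Evidence-type precedence for (theoretical) equal final ranks, following
# the order types appear in the final hierarchy.
_TYPE_ORDER = {"HMM": 0, "BER": 1, "TMHMM": 2, "LipoP": 3}

# isology -> (within-type rank, name suffix, final rank)
_HMM_TABLE = {
    "equivalog": (1, None, 1),
    "equivalog_domain": (2, None, 3),
    "subfamily": (3, " family protein", 5),
    "superfamily": (4, " family protein", 6),
    "subfamily_domain": (5, " domain protein", 7),
    "domain": (6, " domain protein", 8),
    "pfam": (7, " family protein", 9),
    "hypothetical_equivalog": (7, None, 13),
}

# (trusted, query class, match class) -> (within rank, final rank,
#   prefix, suffix, copy annotations from match?)
_BER_TABLE = {
    (True, "Full", "Full"): (1, 2, "", "", True),
    (True, "Full", "Partial"): (2, 10, "", " domain protein", False),
    (True, "Partial", "Full"): (2, 4, "", " domain protein", True),
    (False, "Full", "Full"): (3, 14, "possible ", "", True),
    (False, "Partial", "Full"): (4, 15, "possible ", " domain protein", False),
    (False, "Full", "Partial"): (4, 16, "possible ", " domain protein", False),
}


@dataclass
class CandidateAnnotation:
    """Best annotation offered by one evidence type."""

    evidence_type: str  # BER | HMM | TMHMM | LipoP
    within_type_rank: int
    final_rank: int
    common_name: str
    gene_symbol: Optional[str] = None
    ec_numbers: list[str] = field(default_factory=list)
    go_terms: list[tuple[str, str]] = field(default_factory=list)
    tigr_roles: list[int] = field(default_factory=list)
    provenance: str = ""
    tie_break_key: float = 0.0


def coverage_class(
    coverage_pct: float, thresholds: Optional[PipelineThresholds] = None
) -> str:
    """"Full" at or above the coverage cutoff (80% default), else "Partial"."""
    thresholds = thresholds or PipelineThresholds()
    return (
        "Full"
        if coverage_pct >= thresholds.full_coverage_cutoff_pct
        else "Partial"
    )


def filter_ber(
    matches: Iterable[BerMatch],
    thresholds: Optional[PipelineThresholds] = None,
) -> list[BerMatch]:
    """Drop matches below the identity floor (40%); idempotent."""
    thresholds = thresholds or PipelineThresholds()
    return [
        m
        for m in matches
        if m.percent_identity >= thresholds.ber_min_identity_pct
    ]


def _ambiguous_pattern(terms: Sequence[str]) -> re.Pattern:
    alts = "|".join(re.escape(t) for t in terms)
    return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


def sanitize_ambiguous(
    match: BerMatch,
    ambiguous_terms: Sequence[str] = DEFAULT_AMBIGUOUS_TERMS,
) -> BerMatch:
    """Replace vague non-trusted transferred names.

    A non-trusted match whose name contains an ambiguous term (word-boundary,
    case-insensitive) becomes "conserved hypothetical protein" carrying the
    GO root terms and the conserved-hypothetical role; trusted matches are
    never modified.
    """
    if match.trusted or match.sanitized:
        return match
    if not _ambiguous_pattern(ambiguous_terms).search(match.subject_name):
        return match
    return match.replace(
        subject_name="conserved hypothetical protein",
        subject_symbol=None,
        subject_ecs=[],
        subject_go=list(GO_ROOT_TERMS),
        subject_tigr_roles=[ROLE_CONSERVED_HYPOTHETICAL],
        sanitized=True,
    )


def rank_ber(
    match: BerMatch, thresholds: Optional[PipelineThresholds] = None
) -> Optional[CandidateAnnotation]:
    """Map a filtered match to its per-type and final hierarchy position.

    Sanitized matches take the bottom row (within-type 5, final 17).  A
    match that is partial on both axes fits no hierarchy row and yields no
    candidate.  Rows whose annotation column reads "copied from match"
    transfer GO terms and roles from the subject; the others assign the GO
    roots and the unknown-function role.  Gene symbols and EC numbers
    transfer only on unmodified-or-"possible" full/full rows.
    """
    thresholds = thresholds or PipelineThresholds()
    if match.sanitized:
        return CandidateAnnotation(
            evidence_type="BER",
            within_type_rank=5,
            final_rank=17,
            common_name="conserved hypothetical protein",
            go_terms=list(GO_ROOT_TERMS),
            tigr_roles=[ROLE_CONSERVED_HYPOTHETICAL],
            provenance=match.subject_id,
            tie_break_key=match.p_value,
        )
    q_cls = coverage_class(match.query_coverage_pct, thresholds)
    m_cls = coverage_class(match.subject_coverage_pct, thresholds)
    row = _BER_TABLE.get((match.trusted, q_cls, m_cls))
    if row is None:
        return None
    within, final, prefix, suffix, copy = row
    name = f"{prefix}{match.subject_name}{suffix}"
    if copy:
        go = [(g, "") for g, _ in match.subject_go] or list(GO_ROOT_TERMS)
        roles = list(match.subject_tigr_roles) or [ROLE_UNKNOWN_FUNCTION]
    else:
        go = list(GO_ROOT_TERMS)
        roles = [ROLE_UNKNOWN_FUNCTION]
    transfer_ids = copy and not suffix
    return CandidateAnnotation(
        evidence_type="BER",
        within_type_rank=within,
        final_rank=final,
        common_name=name,
        gene_symbol=match.subject_symbol if transfer_ids else None,
        ec_numbers=list(match.subject_ecs) if transfer_ids else [],
        go_terms=go,
        tigr_roles=roles,
        provenance=match.subject_id,
        tie_break_key=match.p_value,
    )


def best_ber(
    matches: Iterable[BerMatch],
    thresholds: Optional[PipelineThresholds] = None,
    ambiguous_terms: Sequence[str] = DEFAULT_AMBIGUOUS_TERMS,
) -> Optional[CandidateAnnotation]:
    """Filter, sanitize and rank matches; return the best candidate.

    Best = smallest within-type rank, then smallest p-value, then subject
    id (lexicographic) for determinism.
    """
    thresholds = thresholds or PipelineThresholds()
    ranked: list[tuple[int, float, str, CandidateAnnotation]] = []
    for match in filter_ber(matches, thresholds):
        cand = rank_ber(
            sanitize_ambiguous(match, ambiguous_terms), thresholds
        )
        if cand is not None:
            ranked.append(
                (
                    cand.within_type_rank,
                    match.p_value,
                    match.subject_id,
                    cand,
                )
            )
    if not ranked:
        return None
    return min(ranked, key=lambda r: r[:3])[3]


def filter_and_rank_hmm(
    hits: Iterable[HmmHit],
) -> Optional[CandidateAnnotation]:
    """Best HMM candidate: below-cutoff hits are never considered.

    Family-specificity class maps to the per-type hierarchy; the two
    classes sharing within-type rank 7 break toward the general-family
    class (whose final rank is better), then ties go to the hit farthest
    above its cutoff, then accession.
    """
    scored = []
    for hit in hits:
        if hit.isology not in _HMM_TABLE:
            raise ValueError(f"unknown isology {hit.isology!r}")
        if not hit.passes_trusted:
            continue
        within, suffix, final = _HMM_TABLE[hit.isology]
        margin = hit.total_score - hit.trusted_cutoff
        scored.append(((within, final, -margin, hit.accession), hit))
    if not scored:
        return None
    key, hit = min(scored, key=lambda s: s[0])
    within, suffix, final = _HMM_TABLE[hit.isology]
    name = hit.hmm_name + (suffix or "")
    plain_name = suffix is None
    return CandidateAnnotation(
        evidence_type="HMM",
        within_type_rank=within,
        final_rank=final,
        common_name=name,
        gene_symbol=hit.hmm_symbol if plain_name else None,
        ec_numbers=list(hit.ecs) if plain_name else [],
        go_terms=[(g, "") for g in hit.go] or list(GO_ROOT_TERMS),
        tigr_roles=list(hit.tigr_roles) or [ROLE_UNKNOWN_FUNCTION],
        provenance=hit.accession,
        tie_break_key=-(hit.total_score - hit.trusted_cutoff),
    )


def annotate_lipop(
    pred: Optional[LipopPrediction],
) -> Optional[CandidateAnnotation]:
    """Fallback lipoprotein call from a signal-peptidase-II prediction."""
    if pred is None or not pred.predicted_lipoprotein:
        return None
    return CandidateAnnotation(
        evidence_type="LipoP",
        within_type_rank=1,
        final_rank=12,
        common_name="putative lipoprotein",
        go_terms=[_GO_MEMBRANE],
        tigr_roles=[ROLE_CELL_ENVELOPE_OTHER],
        provenance="LipoP",
        tie_break_key=-pred.score,
    )


def annotate_tmhmm(
    pred: Optional[TmhmmPrediction],
    thresholds: Optional[PipelineThresholds] = None,
) -> Optional[CandidateAnnotation]:
    """Membrane-protein call when enough spans are predicted (>=5)."""
    thresholds = thresholds or PipelineThresholds()
    if pred is None or pred.predicted_helices < thresholds.tmhmm_min_spans:
        return None
    return CandidateAnnotation(
        evidence_type="TMHMM",
        within_type_rank=1,
        final_rank=11,
        common_name="putative integral membrane protein",
        go_terms=[_GO_MEMBRANE],
        tigr_roles=[ROLE_CELL_ENVELOPE_OTHER],
        provenance="TMHMM",
        tie_break_key=-pred.predicted_helices,
    )


def pfunc_final(
    bundle: EvidenceBundle,
    thresholds: Optional[PipelineThresholds] = None,
    ambiguous_terms: Sequence[str] = DEFAULT_AMBIGUOUS_TERMS,
) -> FunctionalAnnotation:
    """Apply the final cross-evidence hierarchy; always returns one call.

    The smallest final rank wins (ties: evidence-type order as listed in
    the hierarchy, then the per-type tie-break key).  With no candidate at
    all the polypeptide is called "hypothetical protein" with the GO root
    terms and the hypothetical-protein role.
    """
    thresholds = thresholds or PipelineThresholds()
    candidates = [
        c
        for c in (
            best_ber(bundle.ber_matches, thresholds, ambiguous_terms),
            filter_and_rank_hmm(bundle.hmm_hits),
            annotate_tmhmm(bundle.tmhmm, thresholds),
            annotate_lipop(bundle.lipop),
        )
        if c is not None
    ]
    if not candidates:
        return FunctionalAnnotation(
            gene_id=bundle.gene_id,
            common_name="hypothetical protein",
            go_terms=list(GO_ROOT_TERMS),
            tigr_roles=[ROLE_HYPOTHETICAL],
            final_rank=HYPOTHETICAL,
        )
    winner = min(
        candidates,
        key=lambda c: (
            c.final_rank,
            _TYPE_ORDER[c.evidence_type],
            c.tie_break_key,
        ),
    )
    return FunctionalAnnotation(
        gene_id=bundle.gene_id,
        common_name=winner.common_name,
        gene_symbol=winner.gene_symbol,
        ec_numbers=list(winner.ec_numbers),
        go_terms=list(winner.go_terms),
        tigr_roles=list(winner.tigr_roles),
        source_evidence=f"{winner.evidence_type}:{winner.provenance}",
        final_rank=winner.final_rank,
    )
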