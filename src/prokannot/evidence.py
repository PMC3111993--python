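"""Evidence model and parsers.

External search results enter the package in two ways: native report
formats (BLAST 12-column tabular, GAF 2.x GO associations, LipoP and TMHMM
"short" reports) and canonical tab-separated evidence tables
(``ber_evidence.tsv``, ``hmm_evidence.tsv`` with ``hmm_metadata.tsv``)
which are the package's exchange format between pipeline stages.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

__all__ = [
    "ParseError",
    "BerMatch",
    "HmmHit",
    "HmmMetadata",
    "LipopPrediction",
    "TmhmmPrediction",
    "DisruptionEvent",
    "BlastTabHit",
    "EXPERIMENTAL_GO_CODES",
    "ISOLOGIES",
    "determine_trusted",
    "parse_blast_tabular",
    "parse_gaf",
    "parse_lipop_short",
    "parse_tmhmm_short",
    "load_hmm_metadata",
    "parse_hmm_hits",
    "read_ber_tsv",
    "write_ber_tsv",
    "read_hmm_tsv",
    "write_hmm_tsv",
]

#: GAF evidence codes counted as experimental support.
EXPERIMENTAL_GO_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

#: Family-specificity classes, most to least specific, that govern how
#: confidently an HMM's name transfers to a hit.
ISOLOGIES = (
    "equivalog",
    "equivalog_domain",
    "subfamily",
    "superfamily",
    "subfamily_domain",
    "domain",
    "pfam",
    "hypothetical_equivalog",
)


class ParseError(ValueError):
    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class DisruptionEvent:
    """A frameshift or in-frame stop observed inside an alignment."""

    kind: str  # "frameshift" | "in_frame_stop"
    query_nt_position: int
    frames_involved: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("frameshift", "in_frame_stop"):
            raise ValueError(f"unknown disruption kind {self.kind!r}")


@dataclass
class BerMatch:
    """One extended-alignment protein match for a gene.

    ``subject_start_query_nt`` is the strand-oriented nucleotide offset,
    relative to the annotated start codon (0 = annotated start, negative =
    upstream), at which subject residue 1 aligns; it drives start-site
    voting.
    """

    gene_id: str
    subject_id: str
    subject_name: str
    percent_identity: float
    query_coverage_pct: float
    subject_coverage_pct: float
    p_value: float
    subject_symbol: Optional[str] = None
    subject_ecs: list[str] = field(default_factory=list)
    subject_go: list[tuple[str, str]] = field(default_factory=list)
    subject_tigr_roles: list[int] = field(default_factory=list)
    trusted: bool = False
    score: Optional[float] = None
    disruptions: list[DisruptionEvent] = field(default_factory=list)
    subject_start_query_nt: Optional[int] = None
    subject_length: Optional[int] = None
    sanitized: bool = False

    def __post_init__(self) -> None:
        for name in (
            "percent_identity",
            "query_coverage_pct",
            "subject_coverage_pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.p_value <= 0:
            raise ValueError("p_value must be > 0")

    def replace(self, **kwargs) -> "BerMatch":
        return dataclasses.replace(self, **kwargs)


@dataclass
class HmmMetadata:
    accession: str
    name: str
    isology: str
    trusted_cutoff: float
    symbol: Optional[str] = None
    ecs: list[str] = field(default_factory=list)
    go: list[str] = field(default_factory=list)
    tigr_roles: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.isology not in ISOLOGIES:
            raise ValueError(
                f"{self.accession}: unknown isology {self.isology!r}"
            )


@dataclass
class HmmHit:
    """A profile-HMM hit joined to its library metadata."""

    gene_id: str
    accession: str
    total_score: float
    trusted_cutoff: float
    isology: str
    hmm_name: str
    hmm_symbol: Optional[str] = None
    ecs: list[str] = field(default_factory=list)
    go: list[str] = field(default_factory=list)
    tigr_roles: list[int] = field(default_factory=list)

    @property
    def passes_trusted(self) -> bool:
        return self.total_score >= self.trusted_cutoff


@dataclass
class LipopPrediction:
    gene_id: str
    best_class: str
    score: float

    @property
    def predicted_lipoprotein(self) -> bool:
        # SpII = lipoprotein signal peptidase class; SpI/TMH/CYT do not count.
        return self.best_class == "SpII"


@dataclass
class TmhmmPrediction:
    gene_id: str
    predicted_helices: int
    topology: str = ""

    def __post_init__(self) -> None:
        if self.predicted_helices < 0:
            raise ValueError("predicted_helices must be >= 0")
        if self.topology:
            n = len(re.findall(r"\d+-\d+", self.topology))
            if n != self.predicted_helices:
                warnings.warn(
                    f"{self.gene_id}: topology lists {n} segments but "
                    f"PredHel={self.predicted_helices}",
                    stacklevel=2,
                )


def determine_trusted(
    subject_go: Iterable[tuple[str, str]],
    characterized: set[str],
    uniprot_experimental: set[str],
    subject_id: str,
) -> bool:
    """Whether a subject protein counts as experimentally characterized.

    True iff the subject appears in the literature-characterized list, is
    flagged as having experimental support in the sequence database, or
    carries at least one GO association with an experimental evidence code.
    Monotone: adding evidence can only flip False -> True.
    """
    if subject_id in characterized or subject_id in uniprot_experimental:
        return True
    return any(code in EXPERIMENTAL_GO_CODES for _, code in subject_go)


# ---------------------------------------------------------------------------
# Native report formats


@dataclass
class BlastTabHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int  # 0-based half-open, normalized start < end
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    query_minus: bool = False
    subject_minus: bool = False


def parse_blast_tabular(stream: TextIO) -> list[BlastTabHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6`` dialect).

    Coordinates are normalized to 0-based half-open with start < end; a
    reversed coordinate pair (minus-frame hit) is recorded on the
    ``*_minus`` flags.
    """
    hits: list[BlastTabHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ParseError(
                f"expected 12 tab-separated columns, got {len(cols)}", lineno
            )
        try:
            qs, qe = int(cols[6]), int(cols[7])
            ss, se = int(cols[8]), int(cols[9])
            q_minus = qs > qe
            s_minus = ss > se
            if q_minus:
                qs, qe = qe, qs
            if s_minus:
                ss, se = se, ss
            hits.append(
                BlastTabHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=qs - 1,
                    q_end=qe,
                    s_start=ss - 1,
                    s_end=se,
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    query_minus=q_minus,
                    subject_minus=s_minus,
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
    return hits


def parse_gaf(stream: TextIO) -> dict[str, list[tuple[str, str, str]]]:
    """Parse GAF 2.x into object id -> [(GO id, evidence code, aspect)]."""
    out: dict[str, list[tuple[str, str, str]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(
                f"GAF row has {len(cols)} columns, need >= 15", lineno
            )
        obj_id, go_id, code, aspect = cols[1], cols[4], cols[6], cols[8]
        out.setdefault(obj_id, []).append((go_id, code, aspect))
    return out


_LIPOP_CLASS = re.compile(r"\b(SpII|SpI|TMH|CYT)\b")
_LIPOP_SCORE = re.compile(r"score=(-?[\d.]+)")


def parse_lipop_short(stream: TextIO) -> dict[str, LipopPrediction]:
    """Tolerant reader for LipoP ``-short`` report lines.

    Expected shape: ``# <seq id> <class> score=<x> ...``.  Lines that do not
    look like predictions produce a warning, never an error.
    """
    out: dict[str, LipopPrediction] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        body = line.lstrip("#").strip()
        fields = body.split()
        cls = _LIPOP_CLASS.search(body)
        if not fields or cls is None:
            warnings.warn(
                f"lipop line {lineno} not understood: {line!r}", stacklevel=2
            )
            continue
        score_m = _LIPOP_SCORE.search(body)
        score = float(score_m.group(1)) if score_m else 0.0
        out[fields[0]] = LipopPrediction(
            gene_id=fields[0], best_class=cls.group(1), score=score
        )
    return out


def parse_tmhmm_short(stream: TextIO) -> dict[str, TmhmmPrediction]:
    """Tolerant reader for TMHMM one-line-per-protein short output."""
    out: dict[str, TmhmmPrediction] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        pred = re.search(r"PredHel=(\d+)", line)
        if not fields or pred is None:
            warnings.warn(
                f"tmhmm line {lineno} not understood: {line!r}", stacklevel=2
            )
            continue
        topo = re.search(r"Topology=(\S+)", line)
        out[fields[0]] = TmhmmPrediction(
            gene_id=fields[0],
            predicted_helices=int(pred.group(1)),
            topology=topo.group(1) if topo else "",
        )
    return out


# ---------------------------------------------------------------------------
# Canonical evidence TSVs


def _join(values: Iterable[str]) -> str:
    return ",".join(values)


def _split(text: str) -> list[str]:
    return [t for t in text.split(",") if t]


def load_hmm_metadata(stream: TextIO) -> dict[str, HmmMetadata]:
    """Load the HMM library metadata table (one row per accession)."""
    header = stream.readline().rstrip("\n").split("\t")
    expected = [
        "accession",
        "name",
        "isology",
        "trusted_cutoff",
        "symbol",
        "ec",
        "go",
        "tigr_roles",
    ]
    if header != expected:
        raise ParseError(f"bad metadata header {header}", 1)
    out: dict[str, HmmMetadata] = {}
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != len(expected):
            raise ParseError(
                f"expected {len(expected)} columns, got {len(cols)}", lineno
            )
        out[cols[0]] = HmmMetadata(
            accession=cols[0],
            name=cols[1],
            isology=cols[2],
            trusted_cutoff=float(cols[3]),
            symbol=cols[4] or None,
            ecs=_split(cols[5]),
            go=_split(cols[6]),
            tigr_roles=[int(r) for r in _split(cols[7])],
        )
    return out


_HMM_HEADER = ["gene_id", "accession", "total_score"]


def parse_hmm_hits(
    stream: TextIO, metadata: dict[str, HmmMetadata]
) -> list[HmmHit]:
    """Join raw HMM hits (gene, accession, score) to library metadata.

    A hit whose accession is absent from the metadata table is an error:
    ranking is impossible without an isology and trusted cutoff.
    """
    header = stream.readline().rstrip("\n").split("\t")
    if header != _HMM_HEADER:
        raise ParseError(f"bad hmm evidence header {header}", 1)
    hits: list[HmmHit] = []
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(f"expected 3 columns, got {len(cols)}", lineno)
        gene_id, accession, score = cols[0], cols[1], float(cols[2])
        meta = metadata.get(accession)
        if meta is None:
            raise ParseError(
                f"accession {accession!r} missing from metadata table", lineno
            )
        hits.append(
            HmmHit(
                gene_id=gene_id,
                accession=accession,
                total_score=score,
                trusted_cutoff=meta.trusted_cutoff,
                isology=meta.isology,
                hmm_name=meta.name,
                hmm_symbol=meta.symbol,
                ecs=list(meta.ecs),
                go=list(meta.go),
                tigr_roles=list(meta.tigr_roles),
            )
        )
    return hits


read_hmm_tsv = parse_hmm_hits


def write_hmm_tsv(stream: TextIO, hits: Iterable[HmmHit]) -> None:
    stream.write("\t".join(_HMM_HEADER) + "\n")
    for h in hits:
        stream.write(f"{h.gene_id}\t{h.accession}\t{h.total_score:g}\n")


BER_TSV_COLUMNS = [
    "gene_id",
    "subject_id",
    "subject_name",
    "subject_symbol",
    "subject_ecs",
    "subject_go",
    "subject_tigr_roles",
    "percent_identity",
    "query_coverage_pct",
    "subject_coverage_pct",
    "p_value",
    "score",
    "trusted",
    "disruptions",
    "subject_start_query_nt",
    "subject_length",
]


def _format_disruptions(events: Iterable[DisruptionEvent]) -> str:
    return ";".join(
        f"{e.kind}:{e.query_nt_position}:{e.frames_involved[0]}-"
        f"{e.frames_involved[1]}"
        for e in events
    )


def _parse_disruptions(text: str) -> list[DisruptionEvent]:
    events = []
    for tok in text.split(";"):
        if not tok:
            continue
        kind, pos, frames = tok.split(":")
        f0, f1 = frames.split("-")
        events.append(
            DisruptionEvent(
                kind=kind,
                query_nt_position=int(pos),
                frames_involved=(int(f0), int(f1)),
            )
        )
    return events


def write_ber_tsv(stream: TextIO, matches: Iterable[BerMatch]) -> None:
    stream.write("\t".join(BER_TSV_COLUMNS) + "\n")
    for m in matches:
        row = [
            m.gene_id,
            m.subject_id,
            m.subject_name,
            m.subject_symbol or "",
            _join(m.subject_ecs),
            _join(f"{g}|{c}" for g, c in m.subject_go),
            _join(str(r) for r in m.subject_tigr_roles),
            repr(m.percent_identity),
            repr(m.query_coverage_pct),
            repr(m.subject_coverage_pct),
            repr(m.p_value),
            "" if m.score is None else repr(m.score),
            "1" if m.trusted else "0",
            _format_disruptions(m.disruptions),
            ""
            if m.subject_start_query_nt is None
            else str(m.subject_start_query_nt),
            "" if m.subject_length is None else str(m.subject_length),
        ]
        stream.write("\t".join(row) + "\n")


def read_ber_tsv(stream: TextIO) -> list[BerMatch]:
    header = stream.readline().rstrip("\n").split("\t")
    if header != BER_TSV_COLUMNS:
        raise ParseError(f"bad ber evidence header {header}", 1)
    matches: list[BerMatch] = []
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != len(BER_TSV_COLUMNS):
            raise ParseError(
                f"expected {len(BER_TSV_COLUMNS)} columns, got {len(cols)}",
                lineno,
            )
        go_pairs = []
        for tok in _split(cols[5]):
            go_id, _, code = tok.partition("|")
            go_pairs.append((go_id, code))
        matches.append(
            BerMatch(
                gene_id=cols[0],
                subject_id=cols[1],
                subject_name=cols[2],
                subject_symbol=cols[3] or None,
                subject_ecs=_split(cols[4]),
                subject_go=go_pairs,
                subject_tigr_roles=[int(r) for r in _split(cols[6])],
                percent_identity=float(cols[7]),
                query_coverage_pct=float(cols[8]),
                subject_coverage_pct=float(cols[9]),
                p_value=float(cols[10]),
                score=float(cols[11]) if cols[11] else None,
                trusted=cols[12] == "1",
                disruptions=_parse_disruptions(cols[13]),
                subject_start_query_nt=int(cols[14]) if cols[14] else None,
                subject_length=int(cols[15]) if cols[15] else None,
            )
        )
    return matches
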