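"""Locus-tag assignment and standard-format emission (GFF3/FASTA/TSV).

All emitters are deterministic: identical inputs produce byte-identical
files.  GFF3 output uses 1-based inclusive coordinates with gene/child
feature pairs; re-parsing reproduces internal coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import gffutils
from Bio import SeqIO

from .core import (
    Contig,
    FunctionalAnnotation,
    GeneModel,
    HYPOTHETICAL,
    extract_cds,
    gff_to_internal,
    internal_to_gff,
    polypeptide_for,
)

__all__ = [
    "LocusTagPolicy",
    "read_genome_fasta",
    "read_features_gff3",
    "assign_locus_tags",
    "write_gff3",
    "write_cds_fasta",
    "write_polypeptide_fasta",
    "write_annotation_tsv",
    "write_regions_fasta",
]


@dataclass
class LocusTagPolicy:
    """How locus tags are generated: PREFIX_NNNN by default."""

    prefix: str
    separator: str = "_"
    pad_width: int = 4
    step: int = 1

    def tag(self, ordinal: int) -> str:
        number = ordinal * self.step
        return f"{self.prefix}{self.separator}{number:0{self.pad_width}d}"


def read_genome_fasta(path: str) -> dict[str, Contig]:
    """Load contigs from a (multi-)FASTA file, in file order."""
    contigs: dict[str, Contig] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig id {record.id!r}")
        contigs[record.id] = Contig(id=record.id, sequence=str(record.seq))
    return contigs


_FEATURE_TYPES = ("CDS", "rRNA", "tRNA")


def read_features_gff3(path: str) -> list[GeneModel]:
    """Parse CDS/rRNA/tRNA features from GFF3 into gene models."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    from urllib.parse import unquote

    models: list[GeneModel] = []
    for ftype in _FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            fid = unquote(parents[0] if parents else feat.id)
            start, end = gff_to_internal(feat.start, feat.end)
            models.append(
                GeneModel(
                    id=fid,
                    contig_id=feat.seqid,
                    start=start,
                    end=end,
                    strand=feat.strand,
                    feature_type=ftype,
                    locus_tag=feat.attributes.get("locus_tag", [None])[0],
                    partial5=feat.attributes.get("partial5", ["false"])[0]
                    == "true",
                    partial3=feat.attributes.get("partial3", ["false"])[0]
                    == "true",
                )
            )
    models.sort(key=lambda g: (g.contig_id, g.start, g.end, g.id))
    return models


def assign_locus_tags(
    contigs: Mapping[str, Contig],
    features: Sequence[GeneModel],
    policy: LocusTagPolicy,
) -> dict[str, str]:
    """Sequential locus tags over one shared series for all feature types.

    Numbering starts with the first feature of the longest contig (length
    ties broken by contig id); within a contig, features are ordered by
    start coordinate (ties: longer feature first, then id).
    """
    seen: set[str] = set()
    for f in features:
        if f.id in seen:
            raise ValueError(f"duplicate feature id {f.id!r}")
        seen.add(f.id)
        if f.contig_id not in contigs:
            raise ValueError(f"{f.id}: unknown contig {f.contig_id!r}")
    contig_order = sorted(
        contigs.values(), key=lambda c: (-c.length, c.id)
    )
    rank = {c.id: i for i, c in enumerate(contig_order)}
    ordered = sorted(
        features,
        key=lambda f: (rank[f.contig_id], f.start, -(f.end - f.start), f.id),
    )
    return {
        f.id: policy.tag(i) for i, f in enumerate(ordered, start=1)
    }


def _attr_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def _dbxrefs(ann: FunctionalAnnotation) -> str:
    parts = [f"GO:{go.split(':')[-1]}" for go, _ in ann.go_terms]
    parts += [f"EC:{ec}" for ec in ann.ec_numbers]
    parts += [f"TIGR_role:{r}" for r in ann.tigr_roles]
    return ",".join(parts)


def _sorted_features(
    contigs: Mapping[str, Contig], features: Sequence[GeneModel]
) -> list[GeneModel]:
    contig_order = sorted(contigs.values(), key=lambda c: (-c.length, c.id))
    rank = {c.id: i for i, c in enumerate(contig_order)}
    return sorted(
        features,
        key=lambda f: (rank[f.contig_id], f.start, -(f.end - f.start), f.id),
    )


def write_gff3(
    stream: TextIO,
    contigs: Mapping[str, Contig],
    features: Sequence[GeneModel],
    annotations: Optional[Mapping[str, FunctionalAnnotation]] = None,
    locus_tags: Optional[Mapping[str, str]] = None,
) -> None:
    """Emit gene + child (CDS/rRNA/tRNA) feature pairs as GFF3."""
    locus_tags = locus_tags or {}
    stream.write("##gff-version 3\n")
    for contig in sorted(contigs.values(), key=lambda c: (-c.length, c.id)):
        stream.write(f"##sequence-region {contig.id} 1 {contig.length}\n")
    for feat in _sorted_features(contigs, features):
        start, end = internal_to_gff(feat.start, feat.end)
        tag = locus_tags.get(feat.id) or feat.locus_tag
        gene_attrs = [f"ID={_attr_escape(feat.id)}"]
        if tag:
            gene_attrs.append(f"locus_tag={_attr_escape(tag)}")
        stream.write(
            "\t".join(
                [
                    feat.contig_id,
                    "prokannot",
                    "gene",
                    str(start),
                    str(end),
                    ".",
                    feat.strand,
                    ".",
                    ";".join(gene_attrs),
                ]
            )
            + "\n"
        )
        child_attrs = [
            f"ID={_attr_escape(feat.id)}.{feat.feature_type.lower()}",
            f"Parent={_attr_escape(feat.id)}",
        ]
        if tag:
            child_attrs.append(f"locus_tag={_attr_escape(tag)}")
        ann = (annotations or {}).get(feat.id)
        if ann is not None:
            child_attrs.append(f"product={_attr_escape(ann.common_name)}")
            if ann.gene_symbol:
                child_attrs.append(f"gene={_attr_escape(ann.gene_symbol)}")
            xref = _dbxrefs(ann)
            if xref:
                child_attrs.append(f"Dbxref={xref}")
        if feat.partial5:
            child_attrs.append("partial5=true")
        if feat.partial3:
            child_attrs.append("partial3=true")
        phase = "0" if feat.feature_type == "CDS" else "."
        stream.write(
            "\t".join(
                [
                    feat.contig_id,
                    "prokannot",
                    feat.feature_type,
                    str(start),
                    str(end),
                    ".",
                    feat.strand,
                    phase,
                    ";".join(child_attrs),
                ]
            )
            + "\n"
        )


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _require_annotation(
    feat: GeneModel,
    annotations: Optional[Mapping[str, FunctionalAnnotation]],
) -> Optional[FunctionalAnnotation]:
    if annotations is None:
        return None
    ann = annotations.get(feat.id)
    if ann is None and feat.feature_type == "CDS":
        raise KeyError(f"no annotation for CDS gene {feat.id}")
    return ann


def write_cds_fasta(
    stream: TextIO,
    contigs: Mapping[str, Contig],
    features: Sequence[GeneModel],
    annotations: Optional[Mapping[str, FunctionalAnnotation]] = None,
    locus_tags: Optional[Mapping[str, str]] = None,
) -> None:
    """Strand-oriented nucleotide sequences of CDS features."""
    locus_tags = locus_tags or {}
    for feat in _sorted_features(contigs, features):
        if feat.feature_type != "CDS":
            continue
        ann = _require_annotation(feat, annotations)
        header = locus_tags.get(feat.id) or feat.locus_tag or feat.id
        if ann is not None:
            header += f" {ann.common_name}"
        nt = extract_cds(contigs[feat.contig_id], feat)
        stream.write(f">{header}\n{_wrap(nt)}\n")


def write_polypeptide_fasta(
    stream: TextIO,
    contigs: Mapping[str, Contig],
    features: Sequence[GeneModel],
    annotations: Optional[Mapping[str, FunctionalAnnotation]] = None,
    locus_tags: Optional[Mapping[str, str]] = None,
) -> None:
    """Translated products of CDS features (terminal stop stripped)."""
    locus_tags = locus_tags or {}
    for feat in _sorted_features(contigs, features):
        if feat.feature_type != "CDS":
            continue
        ann = _require_annotation(feat, annotations)
        header = locus_tags.get(feat.id) or feat.locus_tag or feat.id
        if ann is not None:
            header += f" {ann.common_name}"
        aa = polypeptide_for(contigs[feat.contig_id], feat).aa_sequence
        stream.write(f">{header}\n{_wrap(aa)}\n")


ANNOTATION_TSV_COLUMNS = [
    "locus_tag",
    "gene_id",
    "common_name",
    "gene_symbol",
    "ec_numbers",
    "go_terms",
    "tigr_roles",
    "final_rank",
    "source_evidence",
]


def write_annotation_tsv(
    stream: TextIO,
    contigs: Mapping[str, Contig],
    features: Sequence[GeneModel],
    annotations: Mapping[str, FunctionalAnnotation],
    locus_tags: Optional[Mapping[str, str]] = None,
) -> None:
    """The final annotation table, one row per CDS, in locus-tag order."""
    locus_tags = locus_tags or {}
    stream.write("\t".join(ANNOTATION_TSV_COLUMNS) + "\n")
    for feat in _sorted_features(contigs, features):
        if feat.feature_type != "CDS":
            continue
        ann = annotations.get(feat.id)
        if ann is None:
            raise KeyError(f"no annotation for CDS gene {feat.id}")
        rank = (
            "hypothetical"
            if ann.final_rank == HYPOTHETICAL
            else str(ann.final_rank)
        )
        stream.write(
            "\t".join(
                [
                    locus_tags.get(feat.id) or feat.locus_tag or "",
                    feat.id,
                    ann.common_name,
                    ann.gene_symbol or "",
                    ",".join(ann.ec_numbers),
                    ",".join(go for go, _ in ann.go_terms),
                    ",".join(str(r) for r in ann.tigr_roles),
                    rank,
                    ann.source_evidence or "",
                ]
            )
            + "\n"
        )


def write_regions_fasta(
    stream: TextIO,
    contigs: Mapping[str, Contig],
    regions: Iterable,
) -> None:
    """Emit interevidence regions as FASTA for external re-searching."""
    for region in regions:
        contig = contigs[region.contig_id]
        seq = contig.sequence[region.start : region.end]
        members = (
            ";".join(region.member_gene_ids)
            if region.member_gene_ids
            else "-"
        )
        stream.write(
            f">{contig.id}:{region.start}-{region.end} members={members}\n"
            f"{_wrap(seq)}\n"
        )
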