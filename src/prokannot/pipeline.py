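"""End-to-end orchestration: evidence -> start curation -> overlap
curation -> interevidence regions -> hierarchical annotation ->
post-processing -> standard-format output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annot_io, curation, pfunc, postprocess
from .ber import disruption_report
from .core import EvidenceBundle, GeneModel, PipelineThresholds
from .curation import RbsConfig
from .evidence import (
    BerMatch,
    determine_trusted,
    load_hmm_metadata,
    parse_gaf,
    parse_hmm_hits,
    parse_lipop_short,
    parse_tmhmm_short,
    read_ber_tsv,
)

__all__ = ["RunConfig", "run_annotate", "build_bundles"]


@dataclass
class RunConfig:
    """Inputs, knobs and output location for one annotation run."""

    genome: str
    genes: str
    out_dir: str
    locus_prefix: str = "PKA"
    ber: Optional[str] = None
    hmm: Optional[str] = None
    hmm_metadata: Optional[str] = None
    lipop: Optional[str] = None
    tmhmm: Optional[str] = None
    gaf: Optional[str] = None
    characterized: Optional[str] = None
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    rbs: RbsConfig = field(default_factory=RbsConfig)
    min_interevidence_nt: int = 90

    def validate(self) -> None:
        self.thresholds.validate()
        for name in ("genome", "genes"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"--{name}: {path} does not exist")
        for name in (
            "ber",
            "hmm",
            "hmm_metadata",
            "lipop",
            "tmhmm",
            "gaf",
            "characterized",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"--{name}: {path} does not exist")
        if self.hmm is not None and self.hmm_metadata is None:
            raise ValueError("--hmm requires --hmm-metadata")


def _load_evidence(config: RunConfig):
    ber_matches: list[BerMatch] = []
    if config.ber:
        with open(config.ber) as fh:
            ber_matches = read_ber_tsv(fh)
    hmm_hits = []
    if config.hmm:
        with open(config.hmm_metadata) as fh:
            metadata = load_hmm_metadata(fh)
        with open(config.hmm) as fh:
            hmm_hits = parse_hmm_hits(fh, metadata)
    lipop = {}
    if config.lipop:
        with open(config.lipop) as fh:
            lipop = parse_lipop_short(fh)
    tmhmm = {}
    if config.tmhmm:
        with open(config.tmhmm) as fh:
            tmhmm = parse_tmhmm_short(fh)
    gaf = {}
    if config.gaf:
        with open(config.gaf) as fh:
            gaf = parse_gaf(fh)
    characterized: set[str] = set()
    if config.characterized:
        with open(config.characterized) as fh:
            characterized = {
                line.strip() for line in fh if line.strip()
            }
    # re-derive trusted status from the association data where available;
    # codes embedded in the evidence table also count
    refreshed = []
    for m in ber_matches:
        go_pairs = list(m.subject_go) + [
            (go, code) for go, code, _ in gaf.get(m.subject_id, [])
        ]
        trusted = m.trusted or determine_trusted(
            go_pairs, characterized, set(), m.subject_id
        )
        refreshed.append(m.replace(trusted=trusted))
    return refreshed, hmm_hits, lipop, tmhmm


def build_bundles(
    gene_ids, ber_matches, hmm_hits, lipop, tmhmm
) -> dict[str, EvidenceBundle]:
    by_gene: dict[str, EvidenceBundle] = {}
    for gid in gene_ids:
        by_gene[gid] = EvidenceBundle(
            gene_id=gid,
            ber_matches=[m for m in ber_matches if m.gene_id == gid],
            hmm_hits=[h for h in hmm_hits if h.gene_id == gid],
            lipop=lipop.get(gid),
            tmhmm=tmhmm.get(gid),
        )
    return by_gene


def run_annotate(config: RunConfig) -> dict:
    """Run the full pipeline; returns the machine-readable run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds

    contigs = annot_io.read_genome_fasta(config.genome)
    features = annot_io.read_features_gff3(config.genes)
    for feat in features:
        feat.validate_on(contigs[feat.contig_id])
    genes = [f for f in features if f.feature_type == "CDS"]
    rnas = [f for f in features if f.feature_type != "CDS"]

    ber_matches, hmm_hits, lipop, tmhmm = _load_evidence(config)
    bundles = build_bundles(
        [g.id for g in genes], ber_matches, hmm_hits, lipop, tmhmm
    )

    # --- start-site curation -------------------------------------------
    start_rows = []
    curated_genes: list[GeneModel] = []
    for gene in genes:
        bundle = bundles[gene.id]
        votable = [
            m
            for m in pfunc.filter_ber(bundle.ber_matches, thresholds)
            if m.subject_start_query_nt is not None
        ]
        if gene.partial5 or not votable:
            curated_genes.append(gene)
            continue
        contig = contigs[gene.contig_id]
        candidates = curation.enumerate_start_candidates(
            contig, gene, thresholds
        )
        rbs = {
            c.nt_position: curation.rbs_vote(
                contig, gene, c, config.rbs, thresholds
            )
            for c in candidates
        }
        chosen, tally = curation.vote_start_sites(candidates, votable, rbs)
        curated_genes.append(curation.apply_start(gene, chosen))
        if chosen.nt_position != 0:
            start_rows.append(
                {
                    "gene_id": gene.id,
                    "moved_nt": chosen.nt_position,
                    "codon": chosen.codon,
                    "votes": chosen.total_votes,
                }
            )
    genes = curated_genes

    # --- overlap curation ----------------------------------------------
    kept, removed, decisions = curation.curate_overlaps(
        genes + rnas, bundles, thresholds
    )
    kept_genes = [f for f in kept if f.feature_type == "CDS"]
    kept_rnas = [f for f in kept if f.feature_type != "CDS"]

    # --- interevidence regions -----------------------------------------
    regions = []
    for contig in contigs.values():
        regions.extend(
            curation.find_interevidence_regions(
                contig,
                kept,
                bundles,
                thresholds,
                min_length=config.min_interevidence_nt,
            )
        )

    # --- functional annotation + post-processing -----------------------
    annotations = {}
    for gene in kept_genes:
        ann = pfunc.pfunc_final(bundles[gene.id], thresholds)
        annotations[gene.id] = postprocess.post_process_annotation(ann)

    # --- disruption report ---------------------------------------------
    retained = {
        g.id: pfunc.filter_ber(bundles[g.id].ber_matches, thresholds)
        for g in kept_genes
    }
    disruptions = disruption_report(retained)

    # --- output ---------------------------------------------------------
    policy = annot_io.LocusTagPolicy(prefix=config.locus_prefix)
    tags = annot_io.assign_locus_tags(contigs, kept, policy)

    with open(out / "curated.gff3", "w") as fh:
        annot_io.write_gff3(fh, contigs, kept, annotations, tags)
    with open(out / "cds.fna", "w") as fh:
        annot_io.write_cds_fasta(fh, contigs, kept_genes, annotations, tags)
    with open(out / "polypeptides.faa", "w") as fh:
        annot_io.write_polypeptide_fasta(
            fh, contigs, kept_genes, annotations, tags
        )
    with open(out / "annotation.tsv", "w") as fh:
        annot_io.write_annotation_tsv(
            fh, contigs, kept_genes, annotations, tags
        )
    with open(out / "interevidence.fna", "w") as fh:
        annot_io.write_regions_fasta(fh, contigs, regions)
    with open(out / "curation_report.tsv", "w") as fh:
        fh.write("feature_a\tfeature_b\toverlap_bp\taction\trationale\n")
        for d in decisions:
            fh.write(
                f"{d.feature_a}\t{d.feature_b}\t{d.overlap_bp}\t{d.action}\t"
                f"{d.rationale}\n"
            )
    with open(out / "start_report.tsv", "w") as fh:
        fh.write("gene_id\tmoved_nt\tcodon\tvotes\n")
        for row in start_rows:
            fh.write(
                f"{row['gene_id']}\t{row['moved_nt']}\t{row['codon']}\t"
                f"{row['votes']}\n"
            )
    with open(out / "disruption_report.tsv", "w") as fh:
        fh.write(
            "gene_id\tsubject_id\tkind\tquery_nt_position\tframes\n"
        )
        for row in disruptions:
            fh.write(
                f"{row.gene_id}\t{row.subject_id}\t{row.kind}\t"
                f"{row.query_nt_position}\t"
                f"{row.frames_involved[0]}>{row.frames_involved[1]}\n"
            )

    summary = {
        "contigs": len(contigs),
        "genes_in": len(genes),
        "genes_kept": len(kept_genes),
        "rnas": len(kept_rnas),
        "genes_removed": [g.id for g in removed],
        "starts_moved": start_rows,
        "overlap_decisions": len(decisions),
        "interevidence_regions": len(regions),
        "disruption_rows": len(disruptions),
        "hypothetical": sum(
            1
            for a in annotations.values()
            if a.common_name == "hypothetical protein"
        ),
    }
    with open(out / "run.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
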