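"""Deterministic synthetic assembly + evidence generator.

Every pipeline stage is testable offline: this module fabricates a small
two-contig assembly with planted curation scenarios and the matching
evidence files (extended-alignment evidence TSV, HMM evidence + metadata,
lipoprotein/membrane reports, a GO association file and a characterized-
protein list).  A single integer seed drives one pseudo-random stream;
the same seed always yields byte-identical outputs.

Planted scenarios
-----------------
clean_gene              trusted full/full alignment + equivalog HMM
upstream_start_variant  true start 30 nt upstream of the annotated one,
                        supported by three alignments and a consensus RBS
frameshifted_gene       single inserted nucleotide; the evidence row is
                        produced by actually running the frameshift-
                        tolerant aligner against the intact homolog
overlapping_pair        evidenced gene + evidence-free decoy ORF on the
                        opposite strand overlapping it by 90 bp
lipoprotein_only        signal-peptidase-II prediction, nothing else
membrane_only           7 predicted membrane spans, nothing else
no_evidence             nothing at all
ambiguous_name          non-trusted match named with a vague term
trusted_partial         trusted match, full query / partial match coverage

The generator makes no attempt at realistic codon usage or GC content.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Data import CodonTable

from . import ber
from .core import Contig, GeneModel, PipelineThresholds, translate
from .evidence import BerMatch, HmmHit, HmmMetadata, write_ber_tsv

__all__ = ["FixtureSpec", "ToyAssembly", "ToyEvidence", "make_toy_assembly",
           "make_evidence", "write_fixture"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Codons per amino acid under table 11, excluding TTA/CTA/TCA whose reverse
# complements are stop codons — keeps engineered antisense ORFs stop-free.
_T11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_T11.forward_table.items()):
    if _codon in ("TTA", "CTA", "TCA"):
        continue
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class FixtureSpec:
    seed: int = 1
    intergenic_min: int = 120
    intergenic_max: int = 200


@dataclass
class ToyAssembly:
    contigs: dict[str, Contig]
    genes: list[GeneModel]
    rnas: list[GeneModel]
    scenarios: dict[str, str]  # scenario name -> gene id
    proteins: dict[str, str] = field(default_factory=dict)  # true homologs

    @property
    def features(self) -> list[GeneModel]:
        return self.genes + self.rnas


@dataclass
class ToyEvidence:
    ber_matches: list[BerMatch]
    hmm_hits: list[HmmHit]
    hmm_metadata: dict[str, HmmMetadata]
    lipop_lines: list[str]
    tmhmm_lines: list[str]
    gaf_rows: list[tuple[str, str, str, str]]  # (subject, go, code, aspect)
    characterized: set[str]
    subjects: dict[str, str]  # subject id -> protein sequence


def _random_protein(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(_AA20) for _ in range(length - 1))


def _back_translate(rng: random.Random, protein: str) -> str:
    """CDS nucleotides: forced ATG start, TAA stop, no TTA/CTA/TCA codons."""
    body = "".join(rng.choice(_CODONS[aa]) for aa in protein[1:])
    return "ATG" + body + "TAA"


def _random_intergenic(rng: random.Random, length: int) -> str:
    # A/C-biased so spurious start codons and RBS-like hexamers stay rare
    return "".join(rng.choice("ACACGT") for _ in range(length))


def _neutral_codons(n: int) -> str:
    # no starts, no stops, A/C only (cannot resemble the AGGAGG consensus
    # at >= 4 of 6 positions)
    return "".join("CAC" if i % 2 == 0 else "CAA" for i in range(n))


def make_toy_assembly(spec: Optional[FixtureSpec] = None) -> ToyAssembly:
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    proteins: dict[str, str] = {}
    scenarios: dict[str, str] = {}
    genes: list[GeneModel] = []
    rnas: list[GeneModel] = []

    # ---- contig A (the long one): all structural scenarios -------------
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    def spacer() -> None:
        emit(
            _random_intergenic(
                rng, rng.randint(spec.intergenic_min, spec.intergenic_max)
            )
        )

    def add_gene(
        gene_id: str, scenario: str, protein: str, strand: str = "+"
    ) -> GeneModel:
        nt = _back_translate(rng, protein)
        if strand == "-":
            from .core import reverse_complement

            start = emit(reverse_complement(nt))
        else:
            start = emit(nt)
        gene = GeneModel(
            id=gene_id,
            contig_id="contig_A",
            start=start,
            end=start + len(nt),
            strand=strand,
        )
        genes.append(gene)
        scenarios[scenario] = gene_id
        proteins[gene_id] = protein
        return gene

    spacer()
    add_gene("gA01", "clean_gene", _random_protein(rng, 80))
    spacer()

    # upstream start variant: [TAA][CC][AGGAGG][CCACCAC][ATG + 9 neutral
    # codons][GTG gene body ...]; annotated start is the GTG, true start
    # the ATG 30 nt upstream with the consensus RBS at spacer 7.
    sv_protein = _random_protein(rng, 60)
    sv_body = "GTG" + "".join(
        rng.choice(_CODONS[aa]) for aa in sv_protein[1:]
    ) + "TAA"
    upstream_block = "TAA" + "CC" + "AGGAGG" + "CCACCAC"
    hidden_start = "ATG" + _neutral_codons(9)
    emit(upstream_block)
    sv_start = emit(hidden_start + sv_body) + len(hidden_start)
    sv_gene = GeneModel(
        id="gA02",
        contig_id="contig_A",
        start=sv_start,
        end=sv_start + len(sv_body),
        strand="+",
    )
    genes.append(sv_gene)
    scenarios["upstream_start_variant"] = "gA02"
    proteins["gA02"] = sv_protein
    spacer()

    # frameshifted gene: intact 60-aa homolog, one inserted T after codon
    # 30; residue 31 is fixed to K (codon AAA) so the insertion creates an
    # immediate in-frame TAA stop and the annotated model ends there, while
    # the +1 frame carries the rest of the homolog.
    fs_protein = (
        _random_protein(rng, 30) + "K" + _random_protein(rng, 30)[1:]
    )
    head = "".join(
        rng.choice(_CODONS[aa]) for aa in fs_protein[1:30]
    )
    tail = "AAA" + "".join(
        rng.choice(_CODONS[aa]) for aa in fs_protein[31:]
    )
    fs_nt = "ATG" + head + "T" + tail + "TAA"
    fs_start = emit(fs_nt)
    fs_gene = GeneModel(
        id="gA03",
        contig_id="contig_A",
        start=fs_start,
        end=fs_start + 93,  # up to and including the created TAA
        strand="+",
    )
    genes.append(fs_gene)
    scenarios["frameshifted_gene"] = "gA03"
    proteins["gA03"] = fs_protein
    spacer()

    # overlapping pair: evidenced gene gA04 (60 aa) whose residue 31 is
    # fixed to L (codon TTA allowed here on purpose: its reverse
    # complement TAA is the decoy's stop), plus a 210 nt decoy ORF on the
    # minus strand overlapping the last 90 bp of gA04.
    ov_protein = (
        _random_protein(rng, 60)[:31] + "L" + _random_protein(rng, 60)[32:]
    )
    ov_codons = ["ATG"] + [rng.choice(_CODONS[aa]) for aa in ov_protein[1:]]
    ov_codons[31] = "TTA"
    ov_nt = "".join(ov_codons) + "TAA"
    ov_start = emit(ov_nt)
    ov_gene = GeneModel(
        id="gA04",
        contig_id="contig_A",
        start=ov_start,
        end=ov_start + len(ov_nt),
        strand="+",
    )
    genes.append(ov_gene)
    scenarios["overlapping_pair"] = "gA04"
    proteins["gA04"] = ov_protein
    # decoy 5' half lives in the 120 nt after gA04
    from .core import reverse_complement

    decoy_protein = _random_protein(rng, 40)
    decoy_5p = "ATG" + "".join(
        rng.choice(_CODONS[aa]) for aa in decoy_protein[1:]
    )
    assert len(decoy_5p) == 120
    emit(reverse_complement(decoy_5p))
    decoy_start = ov_gene.end - 90
    decoy_gene = GeneModel(
        id="gA05",
        contig_id="contig_A",
        start=decoy_start,
        end=decoy_start + 210,
        strand="-",
    )
    genes.append(decoy_gene)
    scenarios["decoy_orf"] = "gA05"
    spacer()

    add_gene("gA06", "lipoprotein_only", _random_protein(rng, 50))
    spacer()
    add_gene("gA07", "membrane_only", _random_protein(rng, 60))
    spacer()
    add_gene("gA08", "no_evidence", _random_protein(rng, 40))
    spacer()

    # one tRNA feature for locus-tag / overlap bookkeeping
    trna_start = emit(_random_intergenic(rng, 75))
    rnas.append(
        GeneModel(
            id="rA01",
            contig_id="contig_A",
            start=trna_start,
            end=trna_start + 75,
            strand="+",
            feature_type="tRNA",
        )
    )
    spacer()
    contig_a = Contig(id="contig_A", sequence="".join(parts))

    # ---- contig B (shorter): functional-annotation-only scenarios ------
    parts_b: list[str] = []
    pos_b = 0

    def emit_b(seq: str) -> int:
        nonlocal pos_b
        parts_b.append(seq)
        start = pos_b
        pos_b += len(seq)
        return start

    def add_gene_b(gene_id: str, scenario: str, length: int) -> None:
        protein = _random_protein(rng, length)
        nt = _back_translate(rng, protein)
        start = emit_b(nt)
        genes.append(
            GeneModel(
                id=gene_id,
                contig_id="contig_B",
                start=start,
                end=start + len(nt),
                strand="+",
            )
        )
        scenarios[scenario] = gene_id
        proteins[gene_id] = protein

    emit_b(_random_intergenic(rng, 150))
    add_gene_b("gB01", "trusted_partial", 70)
    emit_b(_random_intergenic(rng, 150))
    add_gene_b("gB02", "ambiguous_name", 55)
    emit_b(_random_intergenic(rng, 150))
    contig_b = Contig(id="contig_B", sequence="".join(parts_b))

    assembly = ToyAssembly(
        contigs={"contig_A": contig_a, "contig_B": contig_b},
        genes=genes,
        rnas=rnas,
        scenarios=scenarios,
        proteins=proteins,
    )
    _check(assembly)
    return assembly


def _check(assembly: ToyAssembly) -> None:
    """Construction invariants: every planted model is a valid CDS/RNA."""
    for gene in assembly.features:
        contig = assembly.contigs[gene.contig_id]
        gene.validate_on(contig)
        if gene.feature_type != "CDS":
            continue
        from .core import extract_cds

        nt = extract_cds(contig, gene)
        aa = translate(nt)
        if not aa.endswith("*") or "*" in aa[:-1]:
            raise AssertionError(f"{gene.id}: planted CDS is not clean")


def make_evidence(
    assembly: ToyAssembly, spec: Optional[FixtureSpec] = None
) -> ToyEvidence:
    spec = spec or FixtureSpec()
    s = assembly.scenarios
    thresholds = PipelineThresholds()
    matches: list[BerMatch] = []
    subjects: dict[str, str] = {}

    def protein(gene_key: str) -> str:
        return assembly.proteins[s[gene_key]]

    # clean gene: trusted full/full match + equivalog HMM
    subjects["UP_CLEAN"] = protein("clean_gene")
    matches.append(
        BerMatch(
            gene_id=s["clean_gene"],
            subject_id="UP_CLEAN",
            subject_name="DNA-directed RNA polymerase subunit beta",
            subject_symbol="rpoB",
            subject_ecs=["2.7.7.6"],
            subject_go=[("GO:0003899", "IDA")],
            subject_tigr_roles=[129],
            percent_identity=95.0,
            query_coverage_pct=95.0,
            subject_coverage_pct=95.0,
            p_value=1e-120,
            trusted=True,
            subject_start_query_nt=0,
            subject_length=len(subjects["UP_CLEAN"]),
        )
    )

    # start variant: three concordant non-trusted matches voting for the
    # upstream ATG at -30
    subjects["UP_ADH1"] = "M" + protein("upstream_start_variant")
    for idx, (ident, p) in enumerate(
        [(72.0, 1e-40), (70.0, 1e-35), (68.0, 1e-30)], start=1
    ):
        matches.append(
            BerMatch(
                gene_id=s["upstream_start_variant"],
                subject_id=f"UP_ADH{idx}",
                subject_name="alcohol dehydrogenase",
                percent_identity=ident,
                query_coverage_pct=96.0,
                subject_coverage_pct=92.0,
                p_value=p,
                trusted=False,
                subject_start_query_nt=-30,
                subject_length=len(subjects["UP_ADH1"]),
            )
        )

    # frameshifted gene: evidence row computed by the real aligner against
    # the intact homolog, so the disruption events are genuine
    fs_gene = next(g for g in assembly.genes if g.id == s["frameshifted_gene"])
    fs_subject = assembly.proteins[fs_gene.id]
    subjects["UP_LACZ"] = fs_subject
    aln = ber.align_gene_to_subject(
        assembly.contigs[fs_gene.contig_id], fs_gene, fs_subject,
        thresholds=thresholds,
    )
    matches.append(
        ber.ber_match_from_alignment(
            aln,
            fs_gene,
            subject_id="UP_LACZ",
            subject_name="beta-galactosidase",
            p_value=1e-50,
        )
    )

    # overlap pair: the plus-strand gene gets evidence, the decoy none
    subjects["UP_ABC"] = protein("overlapping_pair")
    matches.append(
        BerMatch(
            gene_id=s["overlapping_pair"],
            subject_id="UP_ABC",
            subject_name="ABC transporter ATP-binding protein",
            percent_identity=88.0,
            query_coverage_pct=97.0,
            subject_coverage_pct=95.0,
            p_value=1e-60,
            trusted=False,
            subject_start_query_nt=0,
            subject_length=len(subjects["UP_ABC"]),
        )
    )

    # trusted full-query/partial-match: name gains the domain suffix
    subjects["UP_B1"] = protein("trusted_partial") + 40 * "G"
    matches.append(
        BerMatch(
            gene_id=s["trusted_partial"],
            subject_id="UP_B1",
            subject_name="chaperone ClpB",
            subject_symbol="clpB",
            subject_go=[("GO:0016887", "IDA")],
            subject_tigr_roles=[94],
            percent_identity=81.0,
            query_coverage_pct=92.0,
            subject_coverage_pct=62.0,
            p_value=1e-45,
            trusted=True,
            subject_start_query_nt=0,
            subject_length=len(subjects["UP_B1"]),
        )
    )

    # ambiguous non-trusted name -> sanitized downstream
    subjects["UP_B2"] = protein("ambiguous_name")
    matches.append(
        BerMatch(
            gene_id=s["ambiguous_name"],
            subject_id="UP_B2",
            subject_name="putative oxidoreductase",
            percent_identity=55.0,
            query_coverage_pct=90.0,
            subject_coverage_pct=88.0,
            p_value=1e-25,
            trusted=False,
            subject_start_query_nt=0,
            subject_length=len(subjects["UP_B2"]),
        )
    )

    hmm_metadata = {
        "TIGR00001": HmmMetadata(
            accession="TIGR00001",
            name="DNA-directed RNA polymerase, beta subunit",
            isology="equivalog",
            trusted_cutoff=100.0,
            symbol="rpoB",
            ecs=["2.7.7.6"],
            go=["GO:0003899"],
            tigr_roles=[129],
        ),
        "PF00005": HmmMetadata(
            accession="PF00005",
            name="ABC transporter",
            isology="pfam",
            trusted_cutoff=25.0,
        ),
    }
    hmm_hits = [
        HmmHit(
            gene_id=s["clean_gene"],
            accession="TIGR00001",
            total_score=250.0,
            trusted_cutoff=100.0,
            isology="equivalog",
            hmm_name=hmm_metadata["TIGR00001"].name,
            hmm_symbol="rpoB",
            ecs=["2.7.7.6"],
            go=["GO:0003899"],
            tigr_roles=[129],
        ),
        # below-cutoff hit: must never be considered for annotation
        HmmHit(
            gene_id=s["overlapping_pair"],
            accession="PF00005",
            total_score=18.0,
            trusted_cutoff=25.0,
            isology="pfam",
            hmm_name="ABC transporter",
        ),
    ]

    lipop_lines = []
    tmhmm_lines = []
    for gene in assembly.genes:
        aa_len = (gene.end - gene.start) // 3 - 1
        if gene.id == s["lipoprotein_only"]:
            lipop_lines.append(f"# {gene.id} SpII score=21.35 margin=9.40")
        else:
            lipop_lines.append(f"# {gene.id} CYT score=-0.20")
        if gene.id == s["membrane_only"]:
            topo = "i" + "o".join(
                f"{10 + 30 * k}-{28 + 30 * k}" for k in range(7)
            ) + "o"
            tmhmm_lines.append(
                f"{gene.id}\tlen={aa_len}\tExpAA=150.2\tFirst60=28.1\t"
                f"PredHel=7\tTopology={topo}"
            )
        else:
            tmhmm_lines.append(
                f"{gene.id}\tlen={aa_len}\tExpAA=0.1\tFirst60=0.0\t"
                f"PredHel=0\tTopology=o"
            )

    gaf_rows = [
        ("UP_CLEAN", "GO:0003899", "IDA", "F"),
        ("UP_LACZ", "GO:0004565", "IEA", "F"),
        ("UP_B1", "GO:0016887", "IDA", "F"),
    ]
    characterized = {"UP_B1"}

    return ToyEvidence(
        ber_matches=matches,
        hmm_hits=hmm_hits,
        hmm_metadata=hmm_metadata,
        lipop_lines=lipop_lines,
        tmhmm_lines=tmhmm_lines,
        gaf_rows=gaf_rows,
        characterized=characterized,
        subjects=subjects,
    )


def write_fixture(
    out_dir: str | Path,
    spec: Optional[FixtureSpec] = None,
) -> tuple[ToyAssembly, ToyEvidence]:
    """Generate and write the complete fixture file set; returns the data."""
    spec = spec or FixtureSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assembly = make_toy_assembly(spec)
    evidence = make_evidence(assembly, spec)

    with open(out / "genome.fna", "w") as fh:
        # shorter contig first on purpose: locus tags must still start on
        # the longest contig
        for cid in sorted(
            assembly.contigs, key=lambda c: assembly.contigs[c].length
        ):
            seq = assembly.contigs[cid].sequence
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    from .annot_io import write_gff3

    with open(out / "genes.gff3", "w") as fh:
        write_gff3(fh, assembly.contigs, assembly.features)

    with open(out / "ber_evidence.tsv", "w") as fh:
        write_ber_tsv(fh, evidence.ber_matches)

    with open(out / "hmm_evidence.tsv", "w") as fh:
        fh.write("gene_id\taccession\ttotal_score\n")
        for hit in evidence.hmm_hits:
            fh.write(f"{hit.gene_id}\t{hit.accession}\t{hit.total_score:g}\n")

    with open(out / "hmm_metadata.tsv", "w") as fh:
        fh.write(
            "accession\tname\tisology\ttrusted_cutoff\tsymbol\tec\tgo\t"
            "tigr_roles\n"
        )
        for meta in evidence.hmm_metadata.values():
            fh.write(
                "\t".join(
                    [
                        meta.accession,
                        meta.name,
                        meta.isology,
                        f"{meta.trusted_cutoff:g}",
                        meta.symbol or "",
                        ",".join(meta.ecs),
                        ",".join(meta.go),
                        ",".join(str(r) for r in meta.tigr_roles),
                    ]
                )
                + "\n"
            )

    with open(out / "lipop.txt", "w") as fh:
        fh.write("\n".join(evidence.lipop_lines) + "\n")
    with open(out / "tmhmm.txt", "w") as fh:
        fh.write("\n".join(evidence.tmhmm_lines) + "\n")

    with open(out / "goa.gaf", "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for obj, go, code, aspect in evidence.gaf_rows:
            cols = ["UniRef"] + [""] * 16
            cols[1] = obj
            cols[2] = obj
            cols[4] = go
            cols[6] = code
            cols[8] = aspect
            fh.write("\t".join(cols[:17]) + "\n")

    with open(out / "characterized.txt", "w") as fh:
        for sid in sorted(evidence.characterized):
            fh.write(sid + "\n")

    with open(out / "subjects.faa", "w") as fh:
        for sid in sorted(evidence.subjects):
            fh.write(f">{sid}\n{evidence.subjects[sid]}\n")

    return assembly, evidence
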