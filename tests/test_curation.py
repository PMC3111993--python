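import random

import pytest

from prokannot.core import Contig, EvidenceBundle, GeneModel, translate
from prokannot.curation import (
    RbsConfig,
    StartCandidate,
    apply_start,
    curate_overlaps,
    enumerate_start_candidates,
    find_interevidence_regions,
    has_evidence,
    rbs_vote,
    vote_start_sites,
)
from prokannot.evidence import BerMatch, HmmHit


def ber(gene_id="g", identity=90.0, p=1e-20, ssq=None, subject="S"):
    return BerMatch(
        gene_id=gene_id,
        subject_id=subject,
        subject_name="protein",
        percent_identity=identity,
        query_coverage_pct=90,
        subject_coverage_pct=90,
        p_value=p,
        subject_start_query_nt=ssq,
    )


def hmm(gene_id="g", score=150.0, cutoff=100.0):
    return HmmHit(
        gene_id=gene_id,
        accession="TIGR1",
        total_score=score,
        trusted_cutoff=cutoff,
        isology="equivalog",
        hmm_name="x",
    )


NEUTRAL = "CACCAACACCAACACCAACACCAACACCAA"  # ten stop/start-free codons


def simple_gene(upstream: str, body_codons: str = NEUTRAL):
    """contig = upstream + ATG + neutral body + TAA; gene over the ORF."""
    nt = "ATG" + body_codons + "TAA"
    contig = Contig(id="c", sequence=upstream + nt + "CACCAA")
    gene = GeneModel(
        id="g",
        contig_id="c",
        start=len(upstream),
        end=len(upstream) + len(nt),
        strand="+",
    )
    return contig, gene


class TestStartCandidates:
    def test_single_start_behind_upstream_stop(self):
        contig, gene = simple_gene("TAA")
        cands = enumerate_start_candidates(contig, gene, min_product_aa=5)
        assert [c.nt_position for c in cands] == [0]
        assert cands[0].codon == "ATG"

    def test_planted_upstream_variant_has_both_candidates(self, assembly):
        gene = next(
            g
            for g in assembly.genes
            if g.id == assembly.scenarios["upstream_start_variant"]
        )
        cands = enumerate_start_candidates(
            assembly.contigs["contig_A"], gene
        )
        positions = {c.nt_position: c.codon for c in cands}
        assert positions[-30] == "ATG"
        assert positions[0] == "GTG"

    def test_candidate_list_never_empty_and_contains_annotated(self):
        contig, gene = simple_gene("ACGCGA")  # no upstream stop planted
        cands = enumerate_start_candidates(contig, gene, min_product_aa=5)
        assert any(c.nt_position == 0 for c in cands)

    def test_no_candidate_beyond_upstream_in_frame_stop(self):
        # an upstream ATG exists but sits behind an in-frame stop
        contig, gene = simple_gene("ATGCACTAA")
        cands = enumerate_start_candidates(contig, gene, min_product_aa=5)
        assert min(c.nt_position for c in cands) == 0


class TestRbsVote:
    def make(self, hexamer, spacer):
        pad = "C" * spacer
        upstream = "CC" + hexamer + pad
        return simple_gene(upstream)

    def test_exact_consensus_at_spacer_7(self):
        contig, gene = self.make("AGGAGG", 7)
        assert rbs_vote(contig, gene, StartCandidate(0, "ATG")) == 1

    def test_all_t_upstream(self):
        contig, gene = simple_gene("T" * 30)
        assert rbs_vote(contig, gene, StartCandidate(0, "ATG")) == 0

    def test_four_of_six_core_at_spacer_6(self):
        contig, gene = self.make("AGGATT", 6)
        assert rbs_vote(contig, gene, StartCandidate(0, "ATG")) == 1

    def test_three_of_six_insufficient(self):
        contig, gene = self.make("AGGTTT", 6)
        assert rbs_vote(contig, gene, StartCandidate(0, "ATG")) == 0

    def test_spacer_outside_window_ignored(self):
        contig, gene = self.make("AGGAGG", 20)
        assert rbs_vote(contig, gene, StartCandidate(0, "ATG")) == 0


class TestVoting:
    CANDS = [StartCandidate(-30, "ATG"), StartCandidate(0, "GTG")]

    def test_three_concordant_votes_win(self):
        matches = [ber(ssq=-30, p=p, subject=f"S{i}")
                   for i, p in enumerate([1e-40, 1e-30, 1e-20])]
        chosen, tally = vote_start_sites(self.CANDS, matches)
        assert chosen.nt_position == -30 and chosen.ber_votes == 3

    def test_no_evidence_keeps_annotated_start(self):
        chosen, _ = vote_start_sites(self.CANDS, [])
        assert chosen.nt_position == 0

    def test_tie_broken_by_best_p_value(self):
        matches = [
            ber(ssq=-30, p=1e-50, subject="A"),
            ber(ssq=-30, p=1e-10, subject="B"),
            ber(ssq=0, p=1e-10, subject="C"),
            ber(ssq=0, p=1e-12, subject="D"),
        ]
        chosen, _ = vote_start_sites(self.CANDS, matches)
        assert chosen.nt_position == -30  # 2 vs 2, but 1e-50 beats 1e-12

    def test_rbs_adds_single_vote(self):
        matches = [ber(ssq=0, subject="A")]
        chosen, _ = vote_start_sites(
            self.CANDS, matches, rbs_votes={-30: 1, 0: 0}
        )
        # 1 BER vote for 0 vs 1 RBS vote for -30: tie -> best p wins (0)
        assert chosen.nt_position == 0
        chosen, _ = vote_start_sites(
            self.CANDS, [], rbs_votes={-30: 1, 0: 0}
        )
        assert chosen.nt_position == -30

    def test_chosen_start_never_introduces_internal_stop(self, assembly):
        gene = next(
            g
            for g in assembly.genes
            if g.id == assembly.scenarios["upstream_start_variant"]
        )
        contig = assembly.contigs["contig_A"]
        cands = enumerate_start_candidates(contig, gene)
        matches = [ber(gene_id=gene.id, ssq=-30, subject=f"S{i}")
                   for i in range(3)]
        chosen, _ = vote_start_sites(cands, matches)
        moved = apply_start(gene, chosen)
        aa = translate(contig.sequence[moved.start : moved.end])
        assert "*" not in aa[:-1]


class TestHasEvidence:
    def test_identity_below_floor_is_no_evidence(self):
        bundle = EvidenceBundle(gene_id="g", ber_matches=[ber(identity=39.9)])
        assert not has_evidence(bundle)

    def test_trusted_hmm_counts(self):
        assert has_evidence(EvidenceBundle(gene_id="g", hmm_hits=[hmm()]))

    def test_below_cutoff_hmm_does_not_count(self):
        bundle = EvidenceBundle(
            gene_id="g", hmm_hits=[hmm(score=50, cutoff=100)]
        )
        assert not has_evidence(bundle)

    def test_empty_bundle(self):
        assert not has_evidence(EvidenceBundle(gene_id="g"))
        assert not has_evidence(None)


def cds(gid, start, end, contig="c"):
    return GeneModel(id=gid, contig_id=contig, start=start, end=end,
                     strand="+")


def rna(gid, start, end, contig="c"):
    return GeneModel(id=gid, contig_id=contig, start=start, end=end,
                     strand="+", feature_type="rRNA")


def bundles(evidenced_ids):
    return {
        gid: EvidenceBundle(gene_id=gid, ber_matches=[ber(gene_id=gid)])
        for gid in evidenced_ids
    }


class TestOverlaps:
    def test_61bp_overlap_removes_evidence_free_gene(self):
        genes = [cds("a", 0, 300), cds("b", 239, 539)]
        kept, removed, decisions = curate_overlaps(genes, bundles({"a"}))
        assert [g.id for g in removed] == ["b"]
        assert decisions[0].overlap_bp == 61

    def test_60bp_overlap_is_no_action(self):
        genes = [cds("a", 0, 300), cds("b", 240, 540)]
        kept, removed, decisions = curate_overlaps(genes, bundles({"a"}))
        assert removed == [] and decisions == []

    def test_both_evidenced_flagged(self):
        genes = [cds("a", 0, 300), cds("b", 200, 500)]
        kept, removed, decisions = curate_overlaps(genes, bundles({"a", "b"}))
        assert removed == []
        assert [d.action for d in decisions] == ["flag"]

    def test_both_evidence_free_flagged_not_removed(self):
        genes = [cds("a", 0, 300), cds("b", 200, 500)]
        kept, removed, decisions = curate_overlaps(genes, bundles(set()))
        assert removed == []
        assert [d.action for d in decisions] == ["flag"]

    def test_rna_overlap_removes_evidence_free_gene(self):
        genes = [rna("r", 0, 300), cds("b", 200, 500)]
        kept, removed, _ = curate_overlaps(genes, bundles(set()))
        assert [g.id for g in removed] == ["b"]

    def test_rna_overlap_with_evidenced_gene_flagged(self):
        genes = [rna("r", 0, 300), cds("b", 200, 500)]
        kept, removed, decisions = curate_overlaps(genes, bundles({"b"}))
        assert removed == [] and [d.action for d in decisions] == ["flag"]

    def test_no_cascade_within_one_pass(self):
        # b (evidence-free) overlaps evidenced a and is removed; c overlaps
        # only b, and with both evidence-free that pair is flagged -- b's
        # removal never cascades into c's evaluation within the pass
        genes = [cds("a", 0, 300), cds("b", 200, 500), cds("c", 420, 720)]
        kept, removed, decisions = curate_overlaps(genes, bundles({"a"}))
        assert {g.id for g in removed} == {"b"}
        bc = [d for d in decisions if {d.feature_a, d.feature_b} == {"b", "c"}]
        assert [d.action for d in bc] == ["flag"]

    def test_conservation_and_order_independence(self):
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randint(2, 12)
            genes = []
            for i in range(n):
                start = rng.randrange(0, 2000, 1)
                genes.append(cds(f"g{i}", start, start + rng.randrange(90, 600, 3)))
            evid = bundles({g.id for g in genes if rng.random() < 0.5})
            kept, removed, _ = curate_overlaps(genes, evid)
            assert {g.id for g in kept} | {g.id for g in removed} == {
                g.id for g in genes
            }
            assert not ({g.id for g in kept} & {g.id for g in removed})
            assert all(not has_evidence(evid.get(g.id)) for g in removed)
            shuffled = genes[:]
            rng.shuffle(shuffled)
            kept2, removed2, _ = curate_overlaps(shuffled, evid)
            assert {g.id for g in kept2} == {g.id for g in kept}
            assert {g.id for g in removed2} == {g.id for g in removed}


class TestInterevidence:
    def test_fully_evidenced_contig_has_no_regions(self):
        contig = Contig(id="c", sequence="A" * 900)
        genes = [cds("a", 0, 450), cds("b", 450, 900)]
        assert (
            find_interevidence_regions(contig, genes, bundles({"a", "b"}))
            == []
        )

    def test_gap_plus_free_gene_plus_gap_is_one_region(self):
        contig = Contig(id="c", sequence="A" * 1500)
        genes = [cds("a", 0, 300), cds("free", 450, 750), cds("b", 900, 1200)]
        regions = find_interevidence_regions(
            contig, genes, bundles({"a", "b"})
        )
        spans = [(r.start, r.end, tuple(r.member_gene_ids)) for r in regions]
        assert (300, 900, ("free",)) in spans

    def test_empty_contig_is_one_whole_region(self):
        contig = Contig(id="c", sequence="A" * 500)
        regions = find_interevidence_regions(contig, [], {})
        assert [(r.start, r.end) for r in regions] == [(0, 500)]

    def test_regions_never_intersect_evidenced_genes(self):
        contig = Contig(id="c", sequence="A" * 2000)
        genes = [cds("a", 100, 400), cds("x", 600, 900), cds("b", 1300, 1600)]
        regions = find_interevidence_regions(contig, genes, bundles({"a", "b"}))
        for r in regions:
            for g in (genes[0], genes[2]):
                assert r.end <= g.start or r.start >= g.end

    def test_short_gaps_suppressed(self):
        contig = Contig(id="c", sequence="A" * 700)
        genes = [cds("a", 0, 300), cds("b", 350, 650)]
        regions = find_interevidence_regions(
            contig, genes, bundles({"a", "b"}), min_length=90
        )
        assert regions == []
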