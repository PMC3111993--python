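import random

import pytest

from prokannot.core import (
    EvidenceBundle,
    GO_ROOT_TERMS,
    HYPOTHETICAL,
    PipelineThresholds,
    ROLE_CELL_ENVELOPE_OTHER,
    ROLE_CONSERVED_HYPOTHETICAL,
)
from prokannot.evidence import (
    BerMatch,
    HmmHit,
    ISOLOGIES,
    LipopPrediction,
    TmhmmPrediction,
)
from prokannot.pfunc import (
    annotate_lipop,
    annotate_tmhmm,
    best_ber,
    coverage_class,
    filter_and_rank_hmm,
    filter_ber,
    pfunc_final,
    rank_ber,
    sanitize_ambiguous,
)

THR = PipelineThresholds()


def ber(
    name="protein kinase",
    identity=90.0,
    qcov=95.0,
    mcov=95.0,
    trusted=True,
    p=1e-30,
    subject="S1",
    **kw,
):
    return BerMatch(
        gene_id="g",
        subject_id=subject,
        subject_name=name,
        percent_identity=identity,
        query_coverage_pct=qcov,
        subject_coverage_pct=mcov,
        p_value=p,
        trusted=trusted,
        subject_go=[("GO:0016301", "IDA" if trusted else "IEA")],
        subject_tigr_roles=[130],
        subject_symbol="pknB",
        subject_ecs=["2.7.11.1"],
        **kw,
    )


def hmm(isology="equivalog", score=150.0, cutoff=100.0, acc="TIGR1"):
    return HmmHit(
        gene_id="g",
        accession=acc,
        total_score=score,
        trusted_cutoff=cutoff,
        isology=isology,
        hmm_name="sensor histidine kinase",
        hmm_symbol="envZ",
        go=["GO:0000155"],
        tigr_roles=[129],
    )


def bundle(ber_matches=(), hmm_hits=(), lipop=None, tmhmm=None):
    return EvidenceBundle(
        gene_id="g",
        ber_matches=list(ber_matches),
        hmm_hits=list(hmm_hits),
        lipop=lipop,
        tmhmm=tmhmm,
    )


class TestFilters:
    def test_identity_floor_boundary(self):
        matches = [ber(identity=i, subject=f"S{i}")
                   for i in (10.0, 39.99, 40.0, 95.0)]
        kept = filter_ber(matches, THR)
        assert [m.percent_identity for m in kept] == [40.0, 95.0]
        assert filter_ber(kept, THR) == kept  # idempotent

    def test_empty(self):
        assert filter_ber([], THR) == []

    def test_coverage_class_boundary(self):
        assert coverage_class(80.0, THR) == "Full"
        assert coverage_class(79.999, THR) == "Partial"


class TestSanitize:
    def test_non_trusted_ambiguous_replaced(self):
        m = sanitize_ambiguous(ber(name="putative kinase", trusted=False))
        assert m.subject_name == "conserved hypothetical protein"
        assert m.subject_go == list(GO_ROOT_TERMS)
        assert m.subject_tigr_roles == [ROLE_CONSERVED_HYPOTHETICAL]
        assert m.sanitized

    def test_trusted_never_modified(self):
        m = ber(name="putative kinase", trusted=True)
        assert sanitize_ambiguous(m) == m

    def test_word_boundary(self):
        m = ber(name="computative-like-ase", trusted=False)
        assert not sanitize_ambiguous(m, ("putative",)).sanitized

    def test_case_insensitive(self):
        m = ber(name="Probable transporter", trusted=False)
        assert sanitize_ambiguous(m).sanitized


# (trusted, qcov, mcov) -> (within rank, final rank, expected name)
BER_ROWS = [
    ((True, 95, 95), 1, 2, "protein kinase"),
    ((True, 95, 60), 2, 10, "protein kinase domain protein"),
    ((True, 60, 95), 2, 4, "protein kinase domain protein"),
    ((False, 95, 95), 3, 14, "possible protein kinase"),
    ((False, 60, 95), 4, 15, "possible protein kinase domain protein"),
    ((False, 95, 60), 4, 16, "possible protein kinase domain protein"),
]


class TestRankBer:
    @pytest.mark.parametrize("combo,within,final,name", BER_ROWS)
    def test_hierarchy_rows(self, combo, within, final, name):
        trusted, qcov, mcov = combo
        cand = rank_ber(ber(trusted=trusted, qcov=qcov, mcov=mcov), THR)
        assert cand.within_type_rank == within
        assert cand.final_rank == final
        assert cand.common_name == name

    def test_go_transfer_asymmetry_between_rank2_rows(self):
        # trusted full-query/partial-match: GO roots + unknown role
        fp = rank_ber(ber(trusted=True, qcov=95, mcov=60), THR)
        assert fp.go_terms == list(GO_ROOT_TERMS)
        # trusted partial-query/full-match: copied from match
        pf = rank_ber(ber(trusted=True, qcov=60, mcov=95), THR)
        assert pf.go_terms == [("GO:0016301", "")]
        assert pf.tigr_roles == [130]

    def test_symbol_and_ec_transfer_only_on_full_full(self):
        ff = rank_ber(ber(trusted=True), THR)
        assert ff.gene_symbol == "pknB" and ff.ec_numbers == ["2.7.11.1"]
        pf = rank_ber(ber(trusted=True, qcov=60), THR)
        assert pf.gene_symbol is None and pf.ec_numbers == []

    def test_partial_partial_yields_no_candidate(self):
        assert rank_ber(ber(qcov=60, mcov=60), THR) is None

    def test_sanitized_takes_bottom_row(self):
        m = sanitize_ambiguous(ber(name="putative kinase", trusted=False))
        cand = rank_ber(m, THR)
        assert cand.within_type_rank == 5 and cand.final_rank == 17


class TestBestBer:
    def test_lower_rank_wins(self):
        best = best_ber(
            [ber(trusted=False, subject="A"), ber(trusted=True, subject="B")],
            THR,
        )
        assert best.within_type_rank == 1 and best.provenance == "B"

    def test_tie_broken_by_p_value(self):
        best = best_ber(
            [ber(p=1e-20, subject="A"), ber(p=1e-80, subject="B")], THR
        )
        assert best.provenance == "B"

    def test_empty_is_none(self):
        assert best_ber([], THR) is None


# isology -> (within rank, final rank, name suffix expectation)
HMM_ROWS = {
    "equivalog": (1, 1, "sensor histidine kinase"),
    "equivalog_domain": (2, 3, "sensor histidine kinase"),
    "subfamily": (3, 5, "sensor histidine kinase family protein"),
    "superfamily": (4, 6, "sensor histidine kinase family protein"),
    "subfamily_domain": (5, 7, "sensor histidine kinase domain protein"),
    "domain": (6, 8, "sensor histidine kinase domain protein"),
    "pfam": (7, 9, "sensor histidine kinase family protein"),
    "hypothetical_equivalog": (7, 13, "sensor histidine kinase"),
}


class TestHmm:
    @pytest.mark.parametrize("isology", ISOLOGIES)
    def test_hierarchy_rows(self, isology):
        within, final, name = HMM_ROWS[isology]
        cand = filter_and_rank_hmm([hmm(isology=isology)])
        assert cand.within_type_rank == within
        assert cand.final_rank == final
        assert cand.common_name == name

    def test_below_cutoff_never_considered(self):
        assert filter_and_rank_hmm([hmm(score=99.9, cutoff=100)]) is None

    def test_pfam_beats_hypothetical_equivalog_on_within_tie(self):
        cand = filter_and_rank_hmm(
            [hmm("hypothetical_equivalog", acc="T1"), hmm("pfam", acc="P1")]
        )
        assert cand.final_rank == 9

    def test_unknown_isology_is_error(self):
        bad = hmm()
        bad.isology = "mystery"
        with pytest.raises(ValueError):
            filter_and_rank_hmm([bad])


class TestMotifFallbacks:
    def test_lipoprotein_annotation(self):
        cand = annotate_lipop(LipopPrediction("g", "SpII", 21.0))
        assert cand.common_name == "putative lipoprotein"
        assert cand.go_terms == [("GO:0016020", "C")]
        assert cand.tigr_roles == [ROLE_CELL_ENVELOPE_OTHER]
        assert cand.final_rank == 12

    def test_non_lipoprotein_class_is_none(self):
        assert annotate_lipop(LipopPrediction("g", "CYT", -0.2)) is None

    def test_membrane_span_threshold(self):
        assert annotate_tmhmm(TmhmmPrediction("g", 4), THR) is None
        cand = annotate_tmhmm(TmhmmPrediction("g", 5), THR)
        assert cand.common_name == "putative integral membrane protein"
        assert cand.final_rank == 11


def make_rank_bundle(final_rank):
    """A bundle whose single candidate lands exactly on the given rank."""
    if final_rank == 1:
        return bundle(hmm_hits=[hmm("equivalog")])
    if final_rank == 2:
        return bundle(ber_matches=[ber(trusted=True)])
    if final_rank == 3:
        return bundle(hmm_hits=[hmm("equivalog_domain")])
    if final_rank == 4:
        return bundle(ber_matches=[ber(trusted=True, qcov=60)])
    if final_rank == 5:
        return bundle(hmm_hits=[hmm("subfamily")])
    if final_rank == 6:
        return bundle(hmm_hits=[hmm("superfamily")])
    if final_rank == 7:
        return bundle(hmm_hits=[hmm("subfamily_domain")])
    if final_rank == 8:
        return bundle(hmm_hits=[hmm("domain")])
    if final_rank == 9:
        return bundle(hmm_hits=[hmm("pfam")])
    if final_rank == 10:
        return bundle(ber_matches=[ber(trusted=True, mcov=60)])
    if final_rank == 11:
        return bundle(tmhmm=TmhmmPrediction("g", 7))
    if final_rank == 12:
        return bundle(lipop=LipopPrediction("g", "SpII", 20.0))
    if final_rank == 13:
        return bundle(hmm_hits=[hmm("hypothetical_equivalog")])
    if final_rank == 14:
        return bundle(ber_matches=[ber(trusted=False)])
    if final_rank == 15:
        return bundle(ber_matches=[ber(trusted=False, qcov=60)])
    if final_rank == 16:
        return bundle(ber_matches=[ber(trusted=False, mcov=60)])
    if final_rank == 17:
        return bundle(
            ber_matches=[ber(name="putative kinase", trusted=False)]
        )
    raise AssertionError(final_rank)


class TestFinalHierarchy:
    @pytest.mark.parametrize("rank", range(1, 18))
    def test_every_rank_reachable_row_for_row(self, rank):
        ann = pfunc_final(make_rank_bundle(rank), THR)
        assert ann.final_rank == rank

    def test_equivalog_beats_trusted_full_full(self):
        ann = pfunc_final(
            bundle(ber_matches=[ber(trusted=True)], hmm_hits=[hmm()]), THR
        )
        assert ann.final_rank == 1
        assert ann.source_evidence.startswith("HMM:")

    def test_membrane_beats_lipoprotein(self):
        ann = pfunc_final(
            bundle(
                tmhmm=TmhmmPrediction("g", 6),
                lipop=LipopPrediction("g", "SpII", 20.0),
            ),
            THR,
        )
        assert ann.common_name == "putative integral membrane protein"
        assert ann.final_rank == 11

    def test_empty_bundle_is_hypothetical(self):
        ann = pfunc_final(bundle(), THR)
        assert ann.common_name == "hypothetical protein"
        assert ann.final_rank == HYPOTHETICAL
        assert ann.go_terms == list(GO_ROOT_TERMS)

    def test_every_output_carries_go_terms(self):
        for rank in range(1, 18):
            ann = pfunc_final(make_rank_bundle(rank), THR)
            assert len(ann.go_terms) >= 1

    def test_sanitized_name_never_appears_verbatim(self):
        ann = pfunc_final(
            bundle(ber_matches=[ber(name="putative kinase", trusted=False)]),
            THR,
        )
        assert "putative kinase" not in ann.common_name


def random_bundle(rng):
    parts = {}
    matches = []
    for i in range(rng.randint(0, 3)):
        matches.append(
            ber(
                name=rng.choice(
                    ["kinase", "putative kinase", "transporter", "ligase"]
                ),
                identity=rng.choice([30.0, 45.0, 85.0]),
                qcov=rng.choice([60.0, 85.0, 99.0]),
                mcov=rng.choice([60.0, 85.0, 99.0]),
                trusted=rng.random() < 0.5,
                p=10.0 ** -rng.randint(6, 80),
                subject=f"S{i}",
            )
        )
    hits = [
        hmm(
            isology=rng.choice(ISOLOGIES),
            score=rng.choice([50.0, 120.0, 200.0]),
            acc=f"T{i}",
        )
        for i in range(rng.randint(0, 2))
    ]
    parts["ber_matches"] = matches
    parts["hmm_hits"] = hits
    if rng.random() < 0.4:
        parts["lipop"] = LipopPrediction(
            "g", rng.choice(["SpII", "CYT"]), 10.0
        )
    if rng.random() < 0.4:
        parts["tmhmm"] = TmhmmPrediction("g", rng.randint(0, 9))
    return parts


class TestProperties:
    def test_permutation_invariance(self):
        rng = random.Random(17)
        for _ in range(300):
            parts = random_bundle(rng)
            ann1 = pfunc_final(bundle(**parts), THR)
            shuffled = dict(parts)
            shuffled["ber_matches"] = parts["ber_matches"][:]
            shuffled["hmm_hits"] = parts["hmm_hits"][:]
            rng.shuffle(shuffled["ber_matches"])
            rng.shuffle(shuffled["hmm_hits"])
            ann2 = pfunc_final(bundle(**shuffled), THR)
            assert ann1 == ann2

    def test_dominance_worse_candidate_never_changes_winner(self):
        rng = random.Random(23)
        for _ in range(300):
            parts = random_bundle(rng)
            ann1 = pfunc_final(bundle(**parts), THR)
            if ann1.final_rank == HYPOTHETICAL:
                continue
            # add a candidate strictly worse than the winner: a sanitized-
            # grade ambiguous non-trusted match (final rank 17)
            if ann1.final_rank >= 17:
                continue
            worse = ber(
                name="putative extra", trusted=False, identity=45.0,
                subject="ZZZ", p=1e-6,
            )
            parts2 = dict(parts)
            parts2["ber_matches"] = parts["ber_matches"] + [worse]
            ann2 = pfunc_final(bundle(**parts2), THR)
            assert ann2.final_rank == ann1.final_rank
            assert ann2.common_name == ann1.common_name
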