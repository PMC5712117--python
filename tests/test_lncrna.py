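import numpy as np
import pytest

from vinenc.errors import DataError
from vinenc.lncrna import (
    PipelineConfig,
    PipelineInputs,
    classify_coding,
    cluster_greedy,
    cross_accession_consensus,
    filter_expression,
    longest_orf_codons,
    orf_coding_flag,
    pairwise_identity,
    rfam_filter,
    run_pipeline,
)
from vinenc.types import AlignmentHit, CmHit, ExpressionRecord, TranscriptRecord

from .oracles import infix_edit_distance


def tr(tid, seq="ACGT" * 100, fpkm=None):
    return TranscriptRecord(id=tid, sequence=seq, fpkm=fpkm)


def hit(q, s, aln=300, bits=500.0, ev=1e-40, ident=95.0):
    return AlignmentHit(q, s, ident, aln, ev, bits)


class TestPairwiseIdentity:
    def test_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(10, 60, size=2)
            s1 = "".join(rng.choice(list("ACGT"), size=n1))
            s2 = "".join(rng.choice(list("ACGT"), size=n2))
            short, long_ = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
            expect = max(0.0, 1.0 - infix_edit_distance(short, long_) / len(short))
            assert pairwise_identity(s1, s2) == pytest.approx(expect)

    def test_disjoint_alphabets_zero(self):
        assert pairwise_identity("A" * 300, "C" * 300) == 0.0

    def test_five_percent_mismatch_copy(self):
        rng = np.random.default_rng(5)
        src = "".join(rng.choice(list("ACGT"), size=200))
        copy = list(src)
        for i in rng.choice(200, size=10, replace=False):
            copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
        assert pairwise_identity("".join(copy), src) >= 0.95


class TestClusterGreedy:
    def test_identical_sequences_merge_longer_represents(self):
        a, b = tr("t1", "ACGT" * 80), tr("t2", "ACGT" * 60)
        (c,) = cluster_greedy([b, a], 0.90)
        assert c.representative_id == "t1" and set(c.member_ids) == {"t1", "t2"}

    def test_dissimilar_sequences_stay_apart(self):
        clusters = cluster_greedy([tr("t1", "A" * 300), tr("t2", "C" * 300)], 0.90)
        assert len(clusters) == 2

    def test_mismatched_copy_joins_at_090(self):
        rng = np.random.default_rng(9)
        src = "".join(rng.choice(list("ACGT"), size=300))
        copy = list(src)
        for i in rng.choice(300, size=15, replace=False):
            copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
        clusters = cluster_greedy([tr("t1", src), tr("t2", "".join(copy))], 0.90)
        assert len(clusters) == 1

    def test_identity_bounds_validated(self):
        with pytest.raises(ValueError):
            cluster_greedy([], 0.4)


class TestExpressionFilter:
    @pytest.mark.parametrize("fpkm,kept", [(1.50, True), (1.49, False), (2.0, True)])
    def test_inclusive_boundary(self, fpkm, kept):
        k, r = filter_expression([tr("t1")], [ExpressionRecord("t1", fpkm)], 1.50)
        assert (len(k) == 1) is kept

    def test_missing_record_removed_with_reason(self):
        k, r = filter_expression([tr("t1")], [], 1.50)
        assert k == [] and r[0].status[-1][2] == "no_expression_record"


class TestClassifyCoding:
    TAXA = {"VITVI": "plant", "HUMAN": "non_plant"}

    def test_plant_hit_removed(self):
        bins = classify_coding([tr("t1")], [hit("t1", "P1_VITVI", ev=1e-30)], self.TAXA)
        assert [t.id for t in bins["plant"]] == ["t1"] and bins["no_hit"] == []

    def test_non_plant_hit_removed(self):
        bins = classify_coding([tr("t1")], [hit("t1", "P1_HUMAN", ev=1e-30)], self.TAXA)
        assert [t.id for t in bins["non_plant"]] == ["t1"]

    def test_weak_hit_lands_in_no_hit_bin(self):
        bins = classify_coding([tr("t1")], [hit("t1", "P1_VITVI", ev=1e-10)], self.TAXA, 1e-20)
        assert [t.id for t in bins["no_hit"]] == ["t1"]

    def test_best_hit_decides_not_any_hit(self):
        hits = [hit("t1", "P1_HUMAN", bits=900, ev=1e-50),
                hit("t1", "P2_VITVI", bits=100, ev=1e-30)]
        bins = classify_coding([tr("t1")], hits, self.TAXA)
        assert [t.id for t in bins["non_plant"]] == ["t1"]

    def test_unknown_organism_code_is_error(self):
        with pytest.raises(DataError, match="WHEAT"):
            classify_coding([tr("t1")], [hit("t1", "P1_WHEAT", ev=1e-30)], self.TAXA)


class TestConsensus:
    def _sets(self):
        a = [tr("a1", "A" * 250), tr("a2", "G" * 400)]
        b = [tr("b1", "C" * 300)]
        return a, b

    def test_boundary_199_dropped_200_kept(self):
        a, b = self._sets()
        assert cross_accession_consensus(a, b, [hit("a1", "b1", aln=199)], 200) == []
        out = cross_accession_consensus(a, b, [hit("a1", "b1", aln=200)], 200)
        assert [t.id for t in out] == ["b1"]  # 300 nt subject beats 250 nt query

    def test_longer_transcript_wins_tie_goes_to_query(self):
        a = [tr("a1", "A" * 300)]
        b = [tr("b1", "C" * 300)]
        out = cross_accession_consensus(a, b, [hit("a1", "b1")], 200)
        assert [t.id for t in out] == ["a1"]

    def test_shared_subject_emitted_once(self):
        a, b = self._sets()
        hits = [hit("a1", "b1", aln=250), hit("a2", "b1", aln=250)]
        out = cross_accession_consensus(a, b, hits, 200)
        ids = [t.id for t in out]
        assert sorted(ids) == sorted(set(ids))

    def test_unknown_id_is_error(self):
        a, b = self._sets()
        with pytest.raises(DataError, match="zz"):
            cross_accession_consensus(a, b, [hit("zz", "b1")], 200)


class TestRfamFilter:
    @pytest.mark.parametrize("ev,removed", [(0.009, True), (0.01, True), (0.011, False)])
    def test_boundary(self, ev, removed):
        k, r = rfam_filter([tr("t1")], [CmHit("t1", "RF00005", ev, 50.0)], 0.01)
        assert (len(r) == 1) is removed

    def test_no_hits_kept(self):
        k, r = rfam_filter([tr("t1")], [], 0.01)
        assert len(k) == 1

    def test_removal_reason_names_best_family(self):
        hits = [CmHit("t1", "RF00001", 0.001, 20.0), CmHit("t1", "RF00005", 0.002, 80.0)]
        _, (removed,) = rfam_filter([tr("t1")], hits, 0.01)
        assert "RF00005" in removed.status[-1][2]


class TestOrfFlag:
    def test_stop_codon_soup_has_no_orf(self):
        t = tr("t1", "TAA" * 100)
        kept, flagged = orf_coding_flag([t], 100)
        assert kept == [t]

    def test_long_orf_flagged(self):
        orf = "ATG" + "GCT" * 150 + "TGA"
        kept, flagged = orf_coding_flag([tr("t1", "AACC" + orf + "GGTT")], 100)
        assert [t.id for t in flagged] == ["t1"]

    def test_reverse_complement_orf_detected(self):
        orf = "ATG" + "GCT" * 150 + "TGA"
        seq = "AACC" + orf + "GGTT"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert longest_orf_codons(rc) == longest_orf_codons(seq) >= 100


def _empty_inputs():
    return PipelineInputs(
        expression_a=[], expression_b=[], protein_hits_a=[], protein_hits_b=[],
        taxon_map={}, a_vs_b_hits=[], cm_hits=[],
    )


class TestRunPipeline:
    def test_planted_truth_recovered_exactly(self, bundle, pipeline_result):
        assert pipeline_result.final_ids == bundle.truth.expected_final_ids

    def test_audit_conserves_counts(self, pipeline_result):
        for s in pipeline_result.audit:
            assert s.n_in == s.n_kept + s.n_removed
            assert s.n_removed >= 0

    def test_audit_chains_within_each_branch(self, pipeline_result):
        rows = {s.stage: s for s in pipeline_result.audit}
        for acc in "ab":
            assert rows[f"expression_{acc}"].n_in == rows[f"cluster_{acc}"].n_kept
            assert rows[f"coding_{acc}"].n_in == rows[f"expression_{acc}"].n_kept
        assert rows["consensus"].n_in == rows["coding_a"].n_kept + rows["coding_b"].n_kept
        assert rows["rfam"].n_in == rows["consensus"].n_kept
        assert rows["orf_flag"].n_in == rows["min_length"].n_kept

    def test_final_set_within_input_union_and_min_length(self, bundle, pipeline_result):
        all_ids = {r.id for r in bundle.transcripts_a + bundle.transcripts_b}
        cfg = PipelineConfig()
        for t in pipeline_result.final:
            assert t.id in all_ids and t.length >= cfg.min_lncrna_length

    def test_every_removal_has_a_logged_reason(self, bundle, pipeline_result):
        """No transcript disappears without a status entry explaining it."""
        raw_a, raw_b = bundle.transcript_records()
        res = run_pipeline(raw_a, raw_b, bundle.pipeline_inputs())
        for t in raw_a + raw_b:
            assert t.status, f"{t.id} passed through no stage"
            if t.id not in res.final_ids:
                assert any(not kept for _, kept, _ in t.status)

    def test_order_stability(self, bundle):
        rng = np.random.default_rng(0)
        raw_a, raw_b = bundle.transcript_records()
        rng.shuffle(raw_a)
        rng.shuffle(raw_b)
        res = run_pipeline(raw_a, raw_b, bundle.pipeline_inputs())
        assert res.final_ids == bundle.truth.expected_final_ids

    def test_empty_inputs_empty_audit(self):
        res = run_pipeline([], [], _empty_inputs())
        assert res.final == [] and all(s.n_in == 0 for s in res.audit)

    def test_zero_fpkm_threshold_removes_only_recordless(self):
        cfg = PipelineConfig(fpkm_min=0.0)
        t1, t2 = tr("t1", "A" * 260), tr("t2", "C" * 260)
        inputs = _empty_inputs()
        inputs.expression_a = [ExpressionRecord("t1", 0.0)]
        res = run_pipeline([t1, t2], [], inputs, cfg)
        rows = {s.stage: s for s in res.audit}
        assert rows["expression_a"].n_kept == 1 and rows["expression_a"].n_removed == 1
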