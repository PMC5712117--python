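import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vinenc.errors import DataError
from vinenc.rnastats import (
    StratifiedPlan,
    cohens_d_from_t,
    compare_groups,
    gc_content,
    ks_two_sample,
    length_corrected_mfe,
    nussinov_fold,
    stratified_sample,
    welch_t,
    welch_t_from_summary,
)
from vinenc.types import FoldResult, GeneModel, TranscriptRecord

from .oracles import brute_ks_statistic, brute_max_pairs, kolmogorov_sf_series


class TestGcContent:
    @pytest.mark.parametrize("seq,gc", [("GGCC", 1.0), ("ATAT", 0.0), ("GATC", 0.5)])
    def test_values(self, seq, gc):
        assert gc_content(seq) == gc

    def test_n_in_denominator_only(self):
        assert gc_content("GCNN") == 0.5

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestLengthCorrectedMfe:
    @pytest.mark.parametrize("mfe,length,expect", [(-100.0, 500, -0.2), (0.0, 200, 0.0)])
    def test_arithmetic(self, mfe, length, expect):
        fold = FoldResult("t", "." * length, mfe)
        assert length_corrected_mfe(fold, length) == expect

    def test_parsed_fixture_block(self, tmp_path):
        from vinenc.formats_io import read_rnafold

        p = tmp_path / "f.txt"
        p.write_text(">t1\n" + "." * 10 + " (-2.50)\n")
        (fold,) = read_rnafold(p)
        assert length_corrected_mfe(fold, 10) == pytest.approx(-0.25)


class TestWelch:
    def test_equal_groups_t_zero(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_group_summaries(self):
        t, df = welch_t_from_summary(-0.276, 0.026, 3049, -0.210, 0.041, 3049)
        assert abs(t) == pytest.approx(75.0, rel=0.01)
        assert df == pytest.approx(5.16e3, rel=0.01)

    def test_equal_n_equal_sd_collapses_to_pooled_df(self):
        _, df = welch_t_from_summary(1.0, 2.0, 30, 0.0, 2.0, 30)
        assert df == pytest.approx(58.0)

    def test_raw_equals_summary_route(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(0.3, 1.4, size=55)
        t1, df1, _ = welch_t(a, b)
        t2, df2 = welch_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t1 == pytest.approx(t2, rel=1e-12) and df1 == pytest.approx(df2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 200, size=2)
        a = rng.normal(0, 1, size=n1)
        b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=n2)
        t, df, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert df == pytest.approx(ref.df, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_variance_is_error(self):
        with pytest.raises(DataError):
            welch_t_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)


class TestCohensD:
    def test_zero_t(self):
        assert cohens_d_from_t(0.0, 50.0) == 0.0

    def test_arithmetic(self):
        assert cohens_d_from_t(5.0, 100.0) == pytest.approx(1.0)

    def test_magnitude_invariant_to_sign(self):
        assert cohens_d_from_t(-3.0, 10.0) == cohens_d_from_t(3.0, 10.0)

    def test_published_mfe_summaries_give_large_effect(self):
        t, df = welch_t_from_summary(-0.276, 0.026, 3049, -0.210, 0.041, 3049)
        d = cohens_d_from_t(t, df)
        assert d == pytest.approx(2.09, abs=0.01)

    def test_nonpositive_df_is_error(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0.0)


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 1], [2, 3])
        assert d == 1.0

    def test_hand_enumerated_example(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_statistic_matches_scipy_and_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 21, size=2)
        a = rng.normal(size=n1)
        b = rng.normal(0.4, 1.2, size=n2)
        d, p = ks_two_sample(a, b)
        assert d == pytest.approx(brute_ks_statistic(a, b), rel=1e-12)
        assert d == pytest.approx(sps.ks_2samp(a, b).statistic, rel=1e-10)
        en = n1 * n2 / (n1 + n2)
        assert p == pytest.approx(kolmogorov_sf_series(math.sqrt(en) * d), rel=1e-10)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=40)
        assert ks_two_sample(a, b) == ks_two_sample(b, a)
        t_ab, _, _ = welch_t(a, b)
        t_ba, _, _ = welch_t(b, a)
        assert t_ab == pytest.approx(-t_ba)


class TestStratifiedSample:
    POOL = [GeneModel(f"g{c}{i}", f"chr{c}", 100 * i + 1, 100 * i + 50, "+", i)
            for c in (1, 2) for i in range(10)]

    def test_plan_counts_respected(self):
        ids = stratified_sample(self.POOL, StratifiedPlan({"chr1": 2, "chr2": 1}, seed=3))
        chroms = [i[1] for i in ids]
        assert len(ids) == 3 and chroms.count("1") == 2 and chroms.count("2") == 1

    def test_same_seed_reproduces(self):
        plan = StratifiedPlan({"chr1": 4, "chr2": 3}, seed=1992)
        assert stratified_sample(self.POOL, plan) == stratified_sample(self.POOL, plan)

    def test_insufficient_pool_names_chromosome(self):
        with pytest.raises(DataError, match="chr9"):
            stratified_sample(self.POOL, StratifiedPlan({"chr9": 5}, seed=0))


class TestNussinov:
    @pytest.mark.parametrize(
        "seq,pairs", [("AAAA", 0), ("GCGC", 0), ("GGGAAACCC", 3)]
    )
    def test_known_folds(self, seq, pairs):
        n, db, mfe = nussinov_fold(seq)
        assert n == pairs and mfe == -1.0 * pairs

    def test_structure_is_consistent(self):
        n, db, _ = nussinov_fold("GGGAAACCC")
        assert db.count("(") == db.count(")") == n

    def test_invalid_character_is_error(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGX")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=12))
    def test_matches_exhaustive_enumeration(self, seq):
        n, db, _ = nussinov_fold(seq)
        assert n == brute_max_pairs(seq)
        assert db.count("(") == n

    def test_traceback_structure_is_valid_and_nested(self):
        rng = np.random.default_rng(8)
        pair_of = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 30))))
            n, db, _ = nussinov_fold(seq)
            stack, count = [], 0
            for i, ch in enumerate(db):
                if ch == "(":
                    stack.append(i)
                elif ch == ")":
                    j = stack.pop()
                    count += 1
                    assert i - j > 3
                    assert (seq[j], seq[i]) in {
                        ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
                    }
            assert not stack and count == n


def _group(prefix, n, rng, mean, sd):
    transcripts, folds = [], {}
    for i in range(n):
        length = int(rng.integers(200, 400))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        tid = f"{prefix}{i}"
        transcripts.append(TranscriptRecord(tid, seq))
        folds[tid] = FoldResult(tid, "." * length, float(rng.normal(mean, sd)) * length)
    return transcripts, folds


class TestCompareGroups:
    def test_identical_groups_all_null(self):
        rng = np.random.default_rng(2)
        t1, f1 = _group("x", 20, rng, -0.25, 0.03)
        comparisons = compare_groups(t1, f1, t1, f1)
        for c in comparisons:
            assert c.t == 0.0 and c.ks_D == 0.0 and c.d == 0.0

    def test_d_definition_holds_on_every_metric(self, bundle, pipeline_result):
        folds = bundle.evidence.folds
        coding = [t for t in bundle.transcript_records()[0] if t.id.startswith("A_cod")]
        comparisons = compare_groups(pipeline_result.final, folds, coding, folds)
        for c in comparisons:
            assert c.d == pytest.approx(2 * abs(c.t) / math.sqrt(c.df))
            assert 0 <= c.ks_D <= 1 and c.df > 0

    def test_planted_mfe_shift_detected(self, bundle, pipeline_result):
        folds = bundle.evidence.folds
        coding = [t for t in bundle.transcript_records()[0] if t.id.startswith("A_cod")]
        by_metric = {
            c.metric: c
            for c in compare_groups(pipeline_result.final, folds, coding, folds)
        }
        c = by_metric["mfe_per_nt"]
        # planted group means: lncRNA -0.210, coding -0.276
        assert c.mean1 > c.mean2
        assert c.p_t < 1e-6 and c.d > 1.0

    def test_singleton_group_is_error(self):
        rng = np.random.default_rng(3)
        t1, f1 = _group("x", 20, rng, -0.25, 0.03)
        t2, f2 = _group("y", 1, rng, -0.21, 0.04)
        with pytest.raises(DataError):
            compare_groups(t1, f1, t2, f2)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_effect_size_recovered_at_published_conditions(self, seed):
        """Two normal groups at the printed means/sds/n recover d near 2.09."""
        rng = np.random.default_rng(seed)
        coding = rng.normal(-0.276, 0.026, size=3049)
        lnc = rng.normal(-0.210, 0.041, size=3049)
        t, df, _ = welch_t(coding, lnc)
        d = cohens_d_from_t(t, df)
        assert 1.95 <= d <= 2.25
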