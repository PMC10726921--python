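"""SBS96 profiles, subsampling recapitulation, APOBEC statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radtmb import (
    MutationCatalog,
    SBS96Profile,
    adjust_pvalues,
    build_profile,
    classify_apobec,
    cosine_similarity,
    make_genome,
    pr_cs_exceeds,
    recapitulation_threshold,
    run_subsampling_experiment,
    sbs96_channel,
    subsample_catalog,
    tcw_enrichment_pvalue,
    wilcoxon_rank_sum,
    ytca_rtca_fractions,
)
from radtmb.genome_io import CHANNEL_INDEX, GenomeSequence, MutationRecord
from radtmb.signatures import TCW_INDICES
from radtmb.synthetic import ContextIndex, make_signature, simulate_catalog

from conftest import catalog_of, records_for_context


def _profile(mass: dict[int, int]) -> SBS96Profile:
    v = np.zeros(96, dtype=int)
    for i, c in mass.items():
        v[i] = c
    return SBS96Profile(v)


class TestBuildProfile:
    def test_hand_resolved_channels(self, rand_genome, rand_index):
        recs = records_for_context(rand_index, "ACG", "T", 2) + records_for_context(
            rand_index, "TCA", "G", 1
        )
        prof = build_profile(catalog_of(recs), rand_genome)
        assert prof.counts[CHANNEL_INDEX["A[C>T]G"]] == 2
        assert prof.counts[CHANNEL_INDEX["T[C>G]A"]] == 1
        assert prof.total == 3

    def test_empty_catalog(self, rand_genome):
        prof = build_profile(MutationCatalog("s"), rand_genome)
        assert prof.total == 0 and (prof.counts == 0).all()

    def test_order_invariance(self, rand_genome, rand_index):
        recs = records_for_context(rand_index, "GCT", "A", 5)
        a = build_profile(catalog_of(recs), rand_genome)
        b = build_profile(catalog_of(recs[::-1]), rand_genome)
        assert (a.counts == b.counts).all()


class TestCosine:
    def test_identical(self):
        p = _profile({0: 3, 5: 7})
        assert cosine_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint(self):
        assert cosine_similarity(_profile({0: 4}), _profile({1: 4})) == 0.0

    def test_hand_value(self):
        # (1,1,0,...) vs (1,0,0,...) -> 1/sqrt(2)
        a = _profile({0: 1, 1: 1})
        b = _profile({0: 1})
        assert cosine_similarity(a, b) == pytest.approx(1 / math.sqrt(2), abs=1e-4)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(_profile({}), _profile({0: 1}))

    @given(
        counts=st.lists(st.integers(0, 50), min_size=96, max_size=96),
        scale=st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_scale_invariant(self, counts, scale):
        v = np.array(counts)
        if v.sum() == 0:
            v[0] = 1
        a, b = SBS96Profile(v), SBS96Profile(v[::-1].copy())
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(SBS96Profile(v * scale), b) == pytest.approx(
            cosine_similarity(a, b)
        )

    def test_equals_one_iff_equal_frequencies(self):
        a = _profile({0: 2, 1: 4})
        b = _profile({0: 3, 1: 6})
        c = _profile({0: 4, 1: 4})
        assert cosine_similarity(a, b) == pytest.approx(1.0, abs=1e-12)
        assert cosine_similarity(a, c) < 1 - 1e-12


class TestSubsample:
    def test_full_size_is_identity_multiset(self, rand_genome, rand_index):
        cat = catalog_of(records_for_context(rand_index, "ACA", "T", 8))
        sub = subsample_catalog(cat, 8, np.random.default_rng(0))
        assert sorted(map(str, sub.records)) == sorted(map(str, cat.records))

    def test_seed_reproducible(self, rand_index):
        cat = catalog_of(records_for_context(rand_index, "ACA", "T", 20))
        a = subsample_catalog(cat, 5, np.random.default_rng(42))
        b = subsample_catalog(cat, 5, np.random.default_rng(42))
        assert [str(r) for r in a.records] == [str(r) for r in b.records]

    def test_oversample_errors(self, rand_index):
        cat = catalog_of(records_for_context(rand_index, "ACA", "T", 4))
        with pytest.raises(ValueError):
            subsample_catalog(cat, 5, np.random.default_rng(0))


class TestSubsamplingExperiment:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_cohort():
        genome = make_genome(60_000, seed=3)
        index = ContextIndex(genome)
        sig = make_signature("flat")
        cohort = {
            s: simulate_catalog(genome, sig, 400, s, seed=i, context_index=index)
            for i, s in enumerate(["a", "b"])
        }
        return genome, cohort

    def test_row_count(self, small_cohort):
        genome, cohort = small_cohort
        t = run_subsampling_experiment(cohort, genome, [10, 20], reps=3, seed=1)
        assert len(t) == 2 * 2 * 3

    def test_seed_bitwise_identical(self, small_cohort):
        genome, cohort = small_cohort
        t1 = run_subsampling_experiment(cohort, genome, [10, 20], reps=3, seed=1)
        t2 = run_subsampling_experiment(cohort, genome, [10, 20], reps=3, seed=1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_small_samples_skipped(self, small_cohort):
        genome, cohort = small_cohort
        t = run_subsampling_experiment(cohort, genome, [10, 5000], reps=2, seed=1)
        assert set(t["n_sub"]) == {10}

    def test_mean_cosine_nondecreasing(self, small_cohort):
        from scipy.stats import spearmanr

        genome, cohort = small_cohort
        grid = [10, 25, 50, 100, 200, 400]
        t = run_subsampling_experiment(cohort, genome, grid, reps=10, seed=7)
        means = t.groupby("n_sub")["cosine"].mean()
        rho = spearmanr(means.index, means.values).statistic
        assert rho > 0.95


class TestPrCsExceeds:
    def make_table(self, passes: int) -> pd.DataFrame:
        cosines = [0.95] * passes + [0.5] * (10 - passes)
        return pd.DataFrame(
            {"sample": "a", "n_sub": 10, "replicate": range(1, 11), "cosine": cosines}
        )

    @pytest.mark.parametrize("passes,expected", [(10, 1.0), (0, 0.0), (7, 0.7)])
    def test_proportions(self, passes, expected):
        out = pr_cs_exceeds(self.make_table(passes))
        assert out["proportion"].iloc[0] == pytest.approx(expected)

    def test_threshold_is_strict(self):
        t = pd.DataFrame(
            {"sample": "a", "n_sub": 10, "replicate": [1, 2], "cosine": [0.9, 0.91]}
        )
        assert pr_cs_exceeds(t, 0.9)["proportion"].iloc[0] == pytest.approx(0.5)


def _recap_table(success_per_n: dict[int, tuple[int, int]], reps=10) -> pd.DataFrame:
    """Table where (k, m) samples succeed/total at each n; successes have all
    replicates above 0.9, failures all below."""
    rows = []
    for n, (k, m) in success_per_n.items():
        for s in range(m):
            cs = 0.95 if s < k else 0.5
            for r in range(1, reps + 1):
                rows.append((f"s{s}", n, r, cs))
    return pd.DataFrame(rows, columns=["sample", "n_sub", "replicate", "cosine"])


class TestRecapThreshold:
    def test_all_pass_everywhere(self):
        t = _recap_table({10: (100, 100), 20: (100, 100), 30: (100, 100)})
        res = recapitulation_threshold(t)
        assert res.n_star == 10

    def test_no_n_passes(self):
        t = _recap_table({10: (30, 60), 20: (30, 60)})
        res = recapitulation_threshold(t)
        assert res.n_star is None

    def test_p_equals_binomial_tail_sum(self):
        """58/60 successes at a single n: the corrected p must equal the
        brute-force upper tail sum of Binomial(60, 0.95) at k >= 58."""
        t = _recap_table({100: (58, 60)})
        res = recapitulation_threshold(t, p0=0.95, correction="bonferroni")
        expected = sum(
            math.comb(60, i) * 0.95**i * 0.05 ** (60 - i) for i in range(58, 61)
        )
        assert res.table["p_raw"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res.table["p_adj"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_ci_lower_is_clopper_pearson(self):
        from scipy.stats import beta

        t = _recap_table({100: (58, 60)})
        res = recapitulation_threshold(t)
        assert res.table["ci_lower"].iloc[0] == pytest.approx(
            beta.ppf(0.05, 58, 3), rel=1e-9
        )

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            recapitulation_threshold(pd.DataFrame(columns=["sample", "n_sub",
                                                           "replicate", "cosine"]))


class TestClassifyApobec:
    def test_41_percent_is_hyper(self):
        v = np.ones(96, dtype=int) * 10  # 960 total
        extra = 656  # TCW mass = (40 + 656) / (960 + 656) = 0.4307 > 0.4
        v[TCW_INDICES[0]] += extra
        hyper, frac = classify_apobec(SBS96Profile(v))
        assert hyper and frac > 0.4

    def test_exactly_40_percent_is_typical(self):
        v = np.zeros(96, dtype=int)
        v[TCW_INDICES] = 10  # 40
        v[0] = 60  # total 100 -> exactly 0.40
        hyper, frac = classify_apobec(SBS96Profile(v))
        assert frac == pytest.approx(0.4)
        assert not hyper

    def test_uniform_is_typical(self):
        hyper, frac = classify_apobec(SBS96Profile(np.ones(96, dtype=int)))
        assert frac == pytest.approx(4 / 96)
        assert not hyper

    def test_zero_profile_errors(self):
        with pytest.raises(ValueError):
            classify_apobec(SBS96Profile(np.zeros(96, dtype=int)))


class TestTcwEnrichment:
    def test_k_zero(self):
        assert tcw_enrichment_pvalue(0, 50, 0.3) == pytest.approx(1.0)

    def test_closed_form_all_successes(self):
        assert tcw_enrichment_pvalue(10, 10, 0.5) == pytest.approx(2**-10)

    def test_matches_brute_force_summation(self):
        expected = sum(
            math.comb(20, i) * 0.2**i * 0.8 ** (20 - i) for i in range(7, 21)
        )
        assert tcw_enrichment_pvalue(7, 20, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_non_increasing_in_k(self):
        ps = [tcw_enrichment_pvalue(k, 30, 0.25) for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_pi0(self):
        with pytest.raises(ValueError):
            tcw_enrichment_pvalue(1, 10, 1.0)


class TestYtcaRtca:
    def test_all_ctca(self):
        # C T C A: mutated C at 1-based pos 3, -2 base C (pyrimidine)
        g = GenomeSequence({"c": "CTCAG" + "A" * 10})
        recs = [MutationRecord("s", "c", 3, "C", "T")]
        y, r = ytca_rtca_fractions(catalog_of(recs), g)
        assert (y, r) == (1.0, 0.0)

    def test_three_to_one_split(self):
        seq = "CTCAG" + "TTCAG" + "CTCAG" + "GTCAG" + "A" * 5
        g = GenomeSequence({"c": seq})
        recs = [MutationRecord("s", "c", p, "C", "T") for p in (3, 8, 13, 18)]
        y, r = ytca_rtca_fractions(catalog_of(recs), g)
        assert y == pytest.approx(0.75) and r == pytest.approx(0.25)
        assert y + r == pytest.approx(1.0)

    def test_reverse_strand_minus2(self):
        # forward "CTGAA": G>A at pos 3 is T[C>T]A on the pyrimidine strand,
        # -2 base is complement of forward pos 5 (A -> T, a pyrimidine: YTCA)
        g = GenomeSequence({"c": "CTGAA" + "C" * 10})
        recs = [MutationRecord("s", "c", 3, "G", "A")]
        y, r = ytca_rtca_fractions(catalog_of(recs), g)
        assert y == 1.0

    def test_no_tcw_errors(self):
        g = GenomeSequence({"c": "AAAAACCCCC"})
        recs = [MutationRecord("s", "c", 3, "A", "T")]
        with pytest.raises(ValueError):
            ytca_rtca_fractions(catalog_of(recs), g)


class TestWilcoxon:
    def test_complete_separation(self):
        w, _ = wilcoxon_rank_sum([10, 11, 12], [1, 2])
        assert w == 3 * 2

    def test_single_tie(self):
        w, _ = wilcoxon_rank_sum([5.0], [5.0])
        assert w == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
        y = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
        w, _ = wilcoxon_rank_sum(x, y)
        brute = sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
        )
        assert w == pytest.approx(brute)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestAdjustPvalues:
    def test_single_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_bonferroni(self):
        assert adjust_pvalues([0.01, 0.03]) == pytest.approx([0.02, 0.06])

    def test_holm_hand_stepdown(self):
        out = adjust_pvalues([0.01, 0.04, 0.03], method="holm")
        assert out == pytest.approx([0.03, 0.06, 0.06])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_holm_le_bonferroni(self, ps):
        holm = adjust_pvalues(ps, "holm")
        bonf = adjust_pvalues(ps, "bonferroni")
        assert (holm <= bonf + 1e-12).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "fdr")
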