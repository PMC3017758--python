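"""Stuart's matched-pairs test, divergence counts, and stationarity trimming."""

import numpy as np
import pytest

from phytrim import (
    Alignment,
    EmptySelectionError,
    chi2_sf,
    crude_removal,
    entropy_scores,
    pair_divergence_counts,
    sigma_scores,
    stationary_trim,
    stuart_test,
    suggest_blosum_eta,
)
from phytrim.stationary import _state_codes, _PairState


def _stuart_oracle(F):
    """Independent statistic: explicit d / V construction with a dense
    pseudo-inverse, no shared code with the implementation."""
    F = np.asarray(F, float)
    r = F.shape[0]
    rows, cols = F.sum(1), F.sum(0)
    d = (rows - cols)[: r - 1]
    V = np.zeros((r - 1, r - 1))
    for s in range(r - 1):
        for t in range(r - 1):
            if s == t:
                V[s, t] = rows[s] + cols[s] - 2 * F[s, s]
            else:
                V[s, t] = -(F[s, t] + F[t, s])
    return float(d @ np.linalg.pinv(V) @ d)


class TestStuartTest:
    def test_symmetric_counts_give_p_one(self):
        F = np.array([[5.0, 2.0], [2.0, 7.0]])
        res = stuart_test(F)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_two_state_closed_form(self):
        res = stuart_test(np.array([[0.0, 15.0], [5.0, 0.0]]))
        assert res.statistic == pytest.approx(5.0)
        assert res.df == 1
        assert res.p == pytest.approx(0.0253, abs=0.0005)

    def test_matches_brute_force_oracle_on_random_counts(self, rng):
        for _ in range(50):
            F = rng.integers(0, 40, (4, 4)).astype(float)
            assert stuart_test(F).statistic == pytest.approx(
                _stuart_oracle(F), abs=1e-9
            )

    def test_matches_oracle_on_amino_acid_counts(self, rng):
        for _ in range(5):
            F = rng.integers(0, 15, (20, 20)).astype(float)
            assert stuart_test(F).statistic == pytest.approx(
                _stuart_oracle(F), abs=1e-8
            )

    def test_invariant_under_state_relabeling(self, rng):
        F = rng.integers(0, 40, (4, 4)).astype(float)
        base = stuart_test(F).statistic
        for _ in range(5):
            perm = rng.permutation(4)
            assert stuart_test(F[np.ix_(perm, perm)]).statistic == pytest.approx(
                base, abs=1e-8
            )

    def test_degenerate_all_zero_counts(self):
        res = stuart_test(np.zeros((4, 4)))
        assert (res.statistic, res.df, res.p) == (0.0, 0, 1.0)


class TestChi2Sf:
    @pytest.mark.parametrize("x,df,expected", [
        (0.0, 1, 1.0),
        (3.841, 1, 0.0500),
        (5.991, 2, 0.0500),
        (5.0, 1, 0.02535),
    ])
    def test_tabulated_quantiles(self, x, df, expected):
        assert chi2_sf(x, df) == pytest.approx(expected, abs=2e-4)

    def test_agrees_with_numerically_integrated_density(self):
        from scipy.integrate import quad
        from scipy.stats import chi2 as chi2_dist

        for df in (1, 2, 5, 11, 19):
            for x in (0.5, 3.0, 12.0, 40.0):
                integral, _ = quad(chi2_dist(df).pdf, x, np.inf)
                assert chi2_sf(x, df) == pytest.approx(integral, abs=1e-8)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(-0.1, 1)


class TestPairCounts:
    def test_identical_sequences_diagonal(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")], "DNA")
        pc = pair_divergence_counts(aln, 0, 1)
        assert pc.n_pair == 4
        np.testing.assert_array_equal(pc.F, np.eye(4))

    def test_swapped_states(self):
        aln = Alignment([("a", "AC"), ("b", "CA")], "DNA")
        pc = pair_divergence_counts(aln, 0, 1)
        assert pc.F[0, 1] == 1 and pc.F[1, 0] == 1

    def test_gapped_columns_skipped(self):
        aln = Alignment([("a", "A-GT"), ("b", "AAGT")], "DNA")
        assert pair_divergence_counts(aln, 0, 1).n_pair == 3

    def test_degenerate_pair_raises(self):
        aln = Alignment([("a", "--"), ("b", "AC")], "DNA")
        with pytest.raises(EmptySelectionError):
            pair_divergence_counts(aln, 0, 1)


def _random_dna(rng, n, m, p_gap=0.0):
    letters = np.array(list("ACGT"))
    seqs = []
    for i in range(n):
        chars = rng.choice(letters, m)
        gaps = rng.random(m) < p_gap
        chars = np.where(gaps, "-", chars)
        seqs.append((f"s{i}", "".join(chars)))
    return Alignment(seqs, "DNA")


class TestSigmaScores:
    def test_constant_candidate_leaves_every_p_unchanged(self, rng):
        aln = _random_dna(rng, 4, 60)
        # make column 0 constant
        recs = [(nm, "A" + seq[1:]) for nm, seq in aln.records]
        aln = Alignment(recs, "DNA")
        C = np.ones(60, bool)
        C[0] = False
        scores = sigma_scores(aln, C)
        assert len(scores) == 1
        assert scores[0].sigma == pytest.approx(0.0, abs=1e-12)

    def test_matches_recomputation_from_scratch(self, rng):
        aln = _random_dna(rng, 4, 50, p_gap=0.05)
        C = rng.random(50) < 0.7
        scores = sigma_scores(aln, C)
        for sc in scores[:10]:
            sigma_direct = 0.0
            trial = C.copy()
            trial[sc.column] = True
            for i in range(4):
                for j in range(i + 1, 4):
                    with_c = stuart_test(
                        pair_divergence_counts(aln, i, j, trial).F
                    ).log_p
                    without = stuart_test(
                        pair_divergence_counts(aln, i, j, C).F
                    ).log_p
                    sigma_direct += with_c - without
            assert sc.sigma == pytest.approx(sigma_direct, abs=1e-8)


class TestCrudeRemoval:
    def test_homogeneous_alignment_untouched(self):
        # seed chosen so that all six pairwise tests already pass (min p 0.39)
        aln = _random_dna(np.random.default_rng(7), 4, 500)
        h, _ = entropy_scores(aln)
        mask = crude_removal(aln, h)
        assert mask.all()

    def test_unfixable_two_sequence_mismatch_raises(self):
        # every column is the same A/C mismatch; at a strict-enough threshold
        # no non-empty subset can look symmetric
        aln = Alignment([("a", "A" * 8), ("b", "C" * 8)], "DNA")
        h, _ = entropy_scores(aln)
        with pytest.raises(EmptySelectionError):
            crude_removal(aln, h, p_threshold=0.5)

    def test_small_sample_retention_stops_at_test_power_limit(self):
        """With the default 0.1 threshold the chi-squared test loses power on
        tiny counts, so a fixed mismatch survives at 2 columns."""
        aln = Alignment([("a", "A" * 8), ("b", "C" * 8)], "DNA")
        h, _ = entropy_scores(aln)
        mask = crude_removal(aln, h, p_threshold=0.1)
        assert mask.sum() == 2  # statistic = m, chi2_sf(2,1) ~ 0.157 > 0.1


class TestStationaryTrim:
    def test_homogeneous_alignment_fully_kept(self, rng):
        aln = _random_dna(rng, 4, 800)
        mask, report = stationary_trim(aln)
        assert mask.all()
        assert report.params["min_pairwise_p"] > 0.1

    def test_idempotent_on_own_output(self, rng):
        from phytrim import make_gc_quartet

        aln, _ = make_gc_quartet(0.3, 3000, seed=5)
        mask, _ = stationary_trim(aln)
        again, _ = stationary_trim(aln.take_columns(mask))
        assert again.all()

    def test_final_set_passes_all_pairwise_tests(self):
        from phytrim import make_gc_quartet

        aln, _ = make_gc_quartet(0.4, 4000, seed=3)
        mask, _ = stationary_trim(aln)
        codes = _state_codes(aln.take_columns(mask))
        sub = aln.take_columns(mask)
        for i in range(4):
            for j in range(i + 1, 4):
                res = stuart_test(pair_divergence_counts(sub, i, j).F)
                assert res.p > 0.1


class TestSuggestBlosum:
    def test_identical_sequences_suggest_most_stringent(self):
        aln = Alignment([("a", "ILMVILMV"), ("b", "ILMVILMV")], "AA")
        eta, rec = suggest_blosum_eta(aln)
        assert eta == 100 and rec == 90

    def test_min_of_row_maxima(self):
        # identities: a-b 40%, a-c 60%, b-c 50% -> row maxima 60, 50, 60
        aln = Alignment([
            ("a", "IIIIIIIIII"),
            ("b", "IIIILLLLLL"),
            ("c", "IIIIIILVVV"),
        ], "AA")
        eta, _ = suggest_blosum_eta(aln)
        assert eta == 50

    def test_gap_only_overlap_pairs_excluded(self):
        aln = Alignment([
            ("a", "II--"), ("b", "--LL"), ("c", "IILL"),
        ], "AA")
        eta, _ = suggest_blosum_eta(aln)  # a-b pair has no overlap
        assert eta == 100
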