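"""Column scoring, smoothing, region partitioning/merging and entropy trimming."""

import numpy as np
import pytest

from phytrim import (
    Alignment,
    SimilarityMatrix,
    blosum_target,
    column_profile,
    entropy_score,
    entropy_scores,
    entropy_trim,
    identity_matrix,
    merge_regions,
    pam_dna,
    partition_regions,
    smooth_scores,
)
from phytrim.entropy import ColumnProfile, RegionPartition


def _aa_cols(*cols):
    """Alignment whose c-th column is cols[c] (one residue per sequence)."""
    n = len(cols[0])
    seqs = ["".join(col[i] for col in cols) for i in range(n)]
    return Alignment([(f"s{i}", s) for i, s in enumerate(seqs)], "AA")


class TestColumnProfile:
    def test_constant_column(self):
        prof = column_profile(_aa_cols("AAAA"), 0)
        assert prof.g == 0.0
        assert prof.pi[0] == 1.0 and prof.pi.sum() == 1.0

    def test_gap_counted_in_g_not_pi(self):
        prof = column_profile(_aa_cols("A-AA"), 0)
        assert prof.g == pytest.approx(0.25)
        assert prof.pi[0] == 1.0

    def test_ambiguity_counts_as_gap(self):
        prof = column_profile(Alignment([("a", "A"), ("b", "N")], "DNA"), 0)
        assert prof.g == pytest.approx(0.5)

    def test_quarter_proportions(self, ilmv_column):
        prof = column_profile(ilmv_column, 0)
        assert sorted(prof.pi[prof.pi > 0]) == [0.25] * 4


class TestEntropyScore:
    @pytest.mark.parametrize("S", [identity_matrix(20), blosum_target(62)])
    def test_constant_column_scores_zero(self, S):
        assert entropy_score(column_profile(_aa_cols("LLLL"), 0), S) == 0.0

    def test_identity_worked_example(self, ilmv_column):
        h = entropy_score(column_profile(ilmv_column, 0), identity_matrix(20))
        assert h == pytest.approx(0.462, abs=0.001)

    def test_blosum50_worked_examples(self, ilmv_column, cqwy_column):
        S = blosum_target(50)
        assert entropy_score(column_profile(ilmv_column, 0), S) == pytest.approx(
            0.300, abs=0.005
        )
        assert entropy_score(column_profile(cqwy_column, 0), S) == pytest.approx(
            0.453, abs=0.005
        )

    def test_shannon_oracle_under_identity(self, rng):
        """With S = I the score must equal Shannon entropy base r."""
        for r, states in ((4, "ACGT"), (20, "ARNDCQEGHILKMFPSTWYV")):
            S = identity_matrix(r)
            for _ in range(20):
                counts = rng.integers(0, 30, r).astype(float)
                if counts.sum() == 0:
                    continue
                prof = ColumnProfile(counts=counts, g=0.0, states=states)
                p = counts[counts > 0] / counts.sum()
                shannon = float(-(p * np.log(p)).sum() / np.log(r))
                assert entropy_score(prof, S) == pytest.approx(shannon, abs=1e-12)

    def test_eigenvalues_sum_to_one_after_normalization(self, rng):
        """The normalizing factor must make the spectrum a distribution."""
        from scipy.linalg import eigh

        S = blosum_target(62).S
        for _ in range(10):
            pi = rng.dirichlet(np.ones(20))
            root = np.sqrt(pi)
            sym = S * np.outer(root, root)
            lam = eigh(sym, eigvals_only=True)
            mu = 1.0 / np.trace(np.diag(pi) @ S)
            assert (mu * lam).sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetrized_spectrum_matches_general_eigensolver(self, rng):
        """Eigenvalues via sqrt(Pi) S sqrt(Pi) must equal those of Pi S."""
        for r in (4, 20):
            for _ in range(5):
                A = rng.random((r, r))
                S = (A + A.T) / 2 + r * np.eye(r)
                pi = rng.dirichlet(np.ones(r))
                root = np.sqrt(pi)
                lam_sym = np.sort(
                    np.linalg.eigvalsh(S * np.outer(root, root))
                )
                lam_gen = np.sort(np.linalg.eigvals(np.diag(pi) @ S).real)
                np.testing.assert_allclose(lam_sym, lam_gen, atol=1e-9)

    def test_batched_scores_match_single_column_path(self, rng):
        letters = np.array(list("ACGT-"))
        seqs = ["".join(rng.choice(letters, 30)) for _ in range(6)]
        aln = Alignment([(f"s{i}", s) for i, s in enumerate(seqs)], "DNA")
        S = pam_dna(2.0, 100)
        h, g = entropy_scores(aln, S)
        for c in range(aln.m):
            assert h[c] == pytest.approx(
                entropy_score(column_profile(aln, c), S), abs=1e-12
            )


class TestSmoothing:
    def test_zero_window_is_identity(self):
        h = np.array([0.2, 0.7, 0.4])
        np.testing.assert_array_equal(smooth_scores(h, np.zeros(3), 0), h)

    def test_unweighted_window_average(self):
        out = smooth_scores(np.array([0.3, 0.6, 0.9]), np.zeros(3), 1)
        np.testing.assert_allclose(out, [0.45, 0.6, 0.75])

    def test_gapped_column_carries_no_weight(self):
        out = smooth_scores(
            np.array([0.3, 0.6, 0.9]), np.array([0.0, 1.0, 0.0]), 1
        )
        np.testing.assert_allclose(out, [0.3, 0.6, 0.9])

    def test_all_gap_window_keeps_raw_score(self):
        out = smooth_scores(np.array([0.3, 0.6]), np.ones(2), 1)
        np.testing.assert_allclose(out, [0.3, 0.6])


class TestPartition:
    def test_single_conserved_run(self):
        p = partition_regions(np.full(5, 0.1))
        assert p.runs == [(1, 5, "C")]

    def test_single_variable_run(self):
        assert partition_regions(np.full(5, 0.9)).runs == [(1, 5, "V")]

    def test_alternating_runs(self):
        p = partition_regions(np.array([0.1, 0.1, 0.9, 0.9, 0.1]))
        assert p.runs == [(1, 2, "C"), (3, 4, "V"), (5, 5, "C")]

    def test_exact_threshold_is_variable(self):
        assert partition_regions(np.array([0.5, 0.4]), 0.5).runs[0][2] == "V"

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never shrinks the conserved set."""
        h = rng.random(60)
        prev = np.zeros(60, bool)
        for thr in (0.2, 0.4, 0.6, 0.8):
            mask = partition_regions(h, thr).conserved_mask()
            assert (mask | prev == mask).all()
            prev = mask


class TestMerging:
    def test_no_variable_runs_unchanged(self):
        h = np.full(6, 0.1)
        g = np.zeros(6)
        p = partition_regions(h)
        assert merge_regions(p, h, g).runs == p.runs

    def test_low_scoring_flanked_variable_run_merges(self):
        h = np.array([0.1] * 4 + [0.6] + [0.1] * 4)
        g = np.zeros(9)
        p = partition_regions(h)
        merged = merge_regions(p, h, g)
        # combined gap-weighted mean (0.8+0.6)/9 ~ 0.156 < 0.5, no gaps
        assert merged.runs == [(1, 9, "C")]

    def test_gappy_region_not_merged(self):
        h = np.array([0.1] * 4 + [0.6] + [0.1] * 4)
        g = np.array([0.0] * 3 + [1.0] * 4 + [0.0] * 2)  # 4/9 cells gapped
        p = partition_regions(h)
        merged = merge_regions(p, h, g)
        assert any(kind == "V" for _, _, kind in merged.runs)

    def test_boundary_variable_runs_never_merge(self):
        h = np.array([0.9, 0.1, 0.1, 0.9])
        p = merge_regions(partition_regions(h), h, np.zeros(4))
        assert p.runs[0][2] == "V" and p.runs[-1][2] == "V"

    def test_fixpoint_termination_and_region_count_decrease(self, rng):
        h = rng.random(200)
        g = rng.random(200) * 0.5
        p = partition_regions(h)
        merged = merge_regions(p, h, g)
        assert merged.n_regions <= p.n_regions
        again = merge_regions(merged, h, g)
        assert again.runs == merged.runs  # already a fixpoint


class TestEntropyTrim:
    def test_constant_alignment_fully_kept(self):
        aln = Alignment([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")], "DNA")
        mask, report = entropy_trim(aln)
        assert mask.all()
        assert report.kept_columns == list(range(1, 11))

    def test_short_conserved_island_dropped_by_min_block(self):
        # 3 conserved columns inside variable surroundings, min_block=5
        h_like = ["LLL", "LLL", "LLL"]
        noise_cols = ["ARN", "DCQ", "EGH", "ILK", "MFP", "STW"]
        cols = noise_cols[:3] + h_like + noise_cols[3:]
        seqs = ["".join(c[i] for c in cols) for i in range(3)]
        seqs.append(seqs[0])  # 4 sequences
        aln = Alignment([(f"s{i}", s) for i, s in enumerate(seqs)], "AA")
        mask, _ = entropy_trim(aln, min_block=5, w=0)
        assert not mask.any() or mask.sum() >= 5

    def test_codon_mask_expands_in_triplets(self):
        aln = Alignment(
            [("a", "ATGATGATGATGATG"), ("b", "ATGATGATGATGATG")], "CODON"
        )
        mask, report = entropy_trim(aln)
        assert mask.size == 15 and mask.all()
        assert report.m == 15

    def test_all_gap_columns_never_kept(self):
        aln = Alignment([("a", "AAAAA-AAAA"), ("b", "AAAAA-AAAA")], "DNA")
        mask, _ = entropy_trim(aln, min_block=1)
        assert not mask[5]

    def test_report_partition_consistency(self, rng):
        letters = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(letters, 40)) for _ in range(8)]
        aln = Alignment([(f"s{i}", s) for i, s in enumerate(seqs)], "DNA")
        mask, report = entropy_trim(aln)
        assert set(report.kept_columns) | set(report.removed_columns) == set(
            range(1, 41)
        )
        assert (report.mask == mask).all()
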