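"""Stage-I posteriors against enumeration oracles, MEA and distances."""

import numpy as np
import pytest

from oracles import (brute_force_mea, enumerate_alignments,
                     enumerate_hmm_posterior, enumerate_pf_posterior,
                     alignment_matches)
from conftest import random_posterior, random_sequence

from probmsa.pair_posterior import (combine_rms, hmm_posterior, mea_score,
                                    pair_distance, pf_posterior,
                                    posterior_task)
from probmsa.params import PartitionParams, encode
from probmsa.sparse_store import PosteriorMatrix, densify, transpose


class TestHmmPosterior:
    def test_matches_path_enumeration_on_short_pairs(self, hmm_params):
        rng = np.random.default_rng(11)
        for _ in range(15):
            x = random_sequence(rng, rng.integers(1, 5))
            y = random_sequence(rng, rng.integers(1, 5))
            got = hmm_posterior(x, y, hmm_params).values
            want, _ = enumerate_hmm_posterior(
                encode(x, "amino"), encode(y, "amino"), hmm_params.pi,
                hmm_params.trans, hmm_params.match_emit, hmm_params.ins_emit)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_transpose_symmetry(self, hmm_params):
        rng = np.random.default_rng(12)
        x, y = random_sequence(rng, 17), random_sequence(rng, 23)
        np.testing.assert_allclose(
            hmm_posterior(x, y, hmm_params).values,
            hmm_posterior(y, x, hmm_params).values.T, atol=1e-12)

    def test_row_and_column_sums_bounded_by_one(self, hmm_params):
        rng = np.random.default_rng(13)
        for _ in range(5):
            x = random_sequence(rng, rng.integers(5, 51))
            y = random_sequence(rng, rng.integers(5, 51))
            p = hmm_posterior(x, y, hmm_params).values
            assert p.sum(axis=1).max() <= 1 + 1e-6
            assert p.sum(axis=0).max() <= 1 + 1e-6

    def test_empty_sequence_rejected(self, hmm_params):
        with pytest.raises(ValueError):
            hmm_posterior("", "ACD", hmm_params)


class TestPartitionPosterior:
    def test_matches_alignment_enumeration_on_short_pairs(self, pf_params):
        rng = np.random.default_rng(21)
        for _ in range(15):
            x = random_sequence(rng, rng.integers(1, 5))
            y = random_sequence(rng, rng.integers(1, 5))
            got = pf_posterior(x, y, pf_params).values
            want, _ = enumerate_pf_posterior(
                encode(x, "amino"), encode(y, "amino"), pf_params.scores,
                pf_params.gap_open, pf_params.gap_extend, pf_params.beta)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_beta_to_zero_limit_counts_alignments(self, pf_params):
        """As beta -> 0 the posterior tends to the alignment-counting ratio."""
        cold = PartitionParams(scores=pf_params.scores, gap_open=-2.2,
                               gap_extend=-0.1, beta=1e-9)
        x, y = "ACD", "WY"
        got = pf_posterior(x, y, cold).values
        alns = enumerate_alignments(len(x), len(y))
        count = np.zeros((len(x) + 1, len(y) + 1))
        for cols in alns:
            for m in alignment_matches(cols):
                count[m] += 1
        np.testing.assert_allclose(got, count / len(alns), atol=1e-6)

    def test_transpose_symmetry(self, pf_params):
        rng = np.random.default_rng(22)
        x, y = random_sequence(rng, 12), random_sequence(rng, 19)
        np.testing.assert_allclose(
            pf_posterior(x, y, pf_params).values,
            pf_posterior(y, x, pf_params).values.T, atol=1e-12)

    def test_invalid_beta_rejected(self, pf_params):
        with pytest.raises(ValueError):
            PartitionParams(scores=pf_params.scores, gap_open=-1.0,
                            gap_extend=-0.1, beta=0.0)


class TestCombineRms:
    def test_closed_form_values(self):
        z = np.zeros((3, 3))
        a, b = z.copy(), z.copy()
        a[1, 1], b[1, 1] = 0.6, 0.8
        out = combine_rms(PosteriorMatrix(a), PosteriorMatrix(b))
        assert out.values[1, 1] == pytest.approx(0.7071067811865476, abs=1e-12)
        assert out.values[2, 2] == 0.0

    def test_rms_of_equal_matrices_is_identity(self):
        rng = np.random.default_rng(31)
        p = random_posterior(rng, 5, 7)
        np.testing.assert_allclose(combine_rms(p, p).values, p.values,
                                   atol=1e-12)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(32)
        with pytest.raises(ValueError):
            combine_rms(random_posterior(rng, 3, 3), random_posterior(rng, 3, 4))


class TestMeaAndDistance:
    def test_zero_matrix_scores_zero(self):
        assert mea_score(PosteriorMatrix(np.zeros((4, 4)))) == 0.0

    def test_diagonal_ones_score_equals_length(self):
        v = np.zeros((4, 4))
        v[1, 1] = v[2, 2] = v[3, 3] = 1.0
        assert mea_score(PosteriorMatrix(v)) == pytest.approx(3.0)

    def test_matches_bruteforce_over_matchings(self):
        rng = np.random.default_rng(33)
        for _ in range(25):
            p = random_posterior(rng, rng.integers(1, 5), rng.integers(1, 5))
            assert mea_score(p) == pytest.approx(
                brute_force_mea(p.values), abs=1e-9)

    def test_invariant_under_transposition(self):
        rng = np.random.default_rng(34)
        p = random_posterior(rng, 4, 6)
        assert mea_score(p) == pytest.approx(mea_score(p.transpose()), abs=1e-12)

    def test_distance_limits(self):
        assert pair_distance(PosteriorMatrix(np.zeros((4, 5)))) == 1.0
        v = np.zeros((4, 4))
        v[1, 1] = v[2, 2] = v[3, 3] = 1.0
        assert pair_distance(PosteriorMatrix(v)) == 0.0

    def test_distance_from_bruteforce_mea(self):
        rng = np.random.default_rng(35)
        p = random_posterior(rng, 3, 4)
        want = 1.0 - brute_force_mea(p.values) / 3
        assert pair_distance(p) == pytest.approx(want, abs=1e-9)


class TestPosteriorTask:
    def test_identical_sequences_have_small_distance(self, hmm_params, pf_params):
        s_xy, s_yx, d = posterior_task("ACDE", "ACDE", hmm_params, pf_params)
        assert d < 0.05

    def test_transpose_is_exact(self, hmm_params, pf_params):
        s_xy, s_yx, _ = posterior_task("ACDEW", "MKY", hmm_params, pf_params)
        assert transpose(s_xy) == s_yx

    def test_sparse_equals_thresholded_dense(self, hmm_params, pf_params):
        from probmsa.pair_posterior import combine_rms as rms
        x, y = "ACDEWK", "MKYE"
        s_xy, _, _ = posterior_task(x, y, hmm_params, pf_params, tau=0.01)
        dense = rms(hmm_posterior(x, y, hmm_params),
                    pf_posterior(x, y, pf_params)).values.copy()
        dense[dense < 0.01] = 0.0
        np.testing.assert_array_equal(densify(s_xy).values, dense)

    def test_adaptive_fraction_limits_element_count(self, hmm_params, pf_params):
        import math
        x, y = "ACDEWKLMNP", "ACDEWKLMNP"
        full, _, _ = posterior_task(x, y, hmm_params, pf_params, tau=0.0)
        frac, _, _ = posterior_task(x, y, hmm_params, pf_params,
                                    adaptive_fraction=0.1)
        assert frac.nnz == math.ceil(0.1 * full.nnz)
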