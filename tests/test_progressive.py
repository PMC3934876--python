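"""Profile-profile MEA alignment, progressive construction and refinement."""

import numpy as np
import pytest

from conftest import random_table
from oracles import brute_force_mea

from probmsa.guide_tree import upgma
from probmsa.progressive import (Profile, align_profiles, profile_posterior,
                                 progressive_align, refine)


class TestProfilePosterior:
    def test_singletons_reduce_to_pairwise_posterior(self):
        rng = np.random.default_rng(90)
        table, dense = random_table(rng, [5, 7])
        a = Profile.singleton(0, 5)
        b = Profile.singleton(1, 7)
        p = profile_posterior(a, b, table, np.array([1.7, 0.3]))
        np.testing.assert_allclose(p, dense[(0, 1)], atol=1e-12)

    def test_gap_columns_contribute_zero(self):
        rng = np.random.default_rng(91)
        table, dense = random_table(rng, [4, 4])
        a = Profile((0,), np.array([[1, 0, 2, 3, 0, 4]]))  # gaps at cols 1, 4
        b = Profile.singleton(1, 4)
        p = profile_posterior(a, b, table, np.ones(2))
        assert np.all(p[2, :] == 0.0) and np.all(p[5, :] == 0.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(92)
        table, dense = random_table(rng, [5, 6, 4, 7])
        w = rng.uniform(0.5, 1.5, size=4)
        a = Profile((0, 1), np.array([[1, 2, 0, 3, 4, 5],
                                      [1, 0, 2, 3, 4, 0]]))
        b = Profile((2, 3), np.array([[1, 2, 3, 0, 4],
                                      [0, 1, 2, 3, 4]]))
        got = profile_posterior(a, b, table, w)
        want = np.zeros((a.width + 1, b.width + 1))
        denom = 0.0
        for ka, x in enumerate(a.indices):
            for kb, y in enumerate(b.indices):
                d = dense[(x, y)] if (x, y) in dense else dense[(y, x)].T
                for i in range(a.width):
                    for j in range(b.width):
                        want[i + 1, j + 1] += w[x] * w[y] * d[
                            a.resmap[ka, i], b.resmap[kb, j]]
                denom += w[x] * w[y]
        want /= denom
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_overlapping_profiles_rejected(self):
        rng = np.random.default_rng(93)
        table, _ = random_table(rng, [3, 3])
        a = Profile.singleton(0, 3)
        with pytest.raises(ValueError):
            profile_posterior(a, a, table, np.ones(2))


class TestAlignProfiles:
    def test_diagonal_posterior_gives_gapless_pairing(self):
        a = Profile.singleton(0, 3)
        b = Profile.singleton(1, 3)
        p = np.zeros((4, 4))
        p[1, 1] = p[2, 2] = p[3, 3] = 1.0
        merged = align_profiles(a, b, p)
        assert merged.width == 3
        assert np.all(merged.resmap > 0)

    def test_zero_posterior_follows_tie_rule(self):
        a = Profile.singleton(0, 2)
        b = Profile.singleton(1, 2)
        merged = align_profiles(a, b, np.zeros((3, 3)))
        # deterministic result; both sequences fully represented
        assert sorted(merged.resmap[0][merged.resmap[0] > 0]) == [1, 2]
        assert sorted(merged.resmap[1][merged.resmap[1] > 0]) == [1, 2]
        merged2 = align_profiles(a, b, np.zeros((3, 3)))
        assert np.array_equal(merged.resmap, merged2.resmap)

    def test_achieved_score_matches_bruteforce_optimum(self):
        rng = np.random.default_rng(94)
        for _ in range(30):
            wa, wb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = np.zeros((wa + 1, wb + 1))
            p[1:, 1:] = rng.random((wa, wb))
            a = Profile.singleton(0, wa)
            b = Profile.singleton(1, wb)
            merged = align_profiles(a, b, p)
            achieved = sum(
                p[merged.resmap[0, j], merged.resmap[1, j]]
                for j in range(merged.width)
                if merged.resmap[0, j] > 0 and merged.resmap[1, j] > 0)
            assert achieved == pytest.approx(brute_force_mea(p), abs=1e-9)


class TestProgressiveAlign:
    def test_three_sequences_equal_manual_composition(self):
        rng = np.random.default_rng(95)
        lengths = [5, 6, 4]
        table, _ = random_table(rng, lengths)
        w = np.ones(3)
        d = np.array([[0.0, 0.1, 0.8],
                      [0.1, 0.0, 0.8],
                      [0.8, 0.8, 0.0]])
        tree = upgma(d)
        got = progressive_align(tree, table, w, lengths)
        # manual: align (0, 1) first, then join 2
        ab = align_profiles(Profile.singleton(0, 5), Profile.singleton(1, 6),
                            profile_posterior(Profile.singleton(0, 5),
                                              Profile.singleton(1, 6), table, w))
        c = Profile.singleton(2, 4)
        # the final merge joins c (left child) with the (0,1) profile
        want = align_profiles(c, ab, profile_posterior(c, ab, table, w))
        assert got.indices == want.indices
        assert np.array_equal(got.resmap, want.resmap)

    def test_degapped_rows_reproduce_inputs(self):
        rng = np.random.default_rng(96)
        lengths = [6, 5, 7, 4]
        table, _ = random_table(rng, lengths)
        d = np.array([[0.0, 0.3, 0.5, 0.7],
                      [0.3, 0.0, 0.5, 0.7],
                      [0.5, 0.5, 0.0, 0.7],
                      [0.7, 0.7, 0.7, 0.0]])
        prof = progressive_align(upgma(d), table, np.ones(4), lengths)
        for k, idx in enumerate(prof.indices):
            nz = prof.resmap[k][prof.resmap[k] > 0]
            assert list(nz) == list(range(1, lengths[idx] + 1))


class TestRefine:
    def test_zero_repetitions_returns_input(self):
        rng = np.random.default_rng(97)
        lengths = [5, 5, 5]
        table, _ = random_table(rng, lengths)
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        prof = progressive_align(upgma(d), table, np.ones(3), lengths)
        assert refine(prof, table, np.ones(3), 0, seed=1) is prof

    def test_seeded_determinism_and_invariants(self):
        rng = np.random.default_rng(98)
        lengths = [6, 7, 5, 6]
        table, _ = random_table(rng, lengths)
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        w = np.ones(4)
        prof = progressive_align(upgma(d), table, w, lengths)
        r1 = refine(prof, table, w, 5, seed=42)
        r2 = refine(prof, table, w, 5, seed=42)
        assert np.array_equal(r1.resmap, r2.resmap)
        # invariants after refinement
        assert np.any(r1.resmap > 0, axis=0).all()  # no all-gap column
        for k, idx in enumerate(r1.indices):
            nz = r1.resmap[k][r1.resmap[k] > 0]
            assert list(nz) == list(range(1, lengths[idx] + 1))
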