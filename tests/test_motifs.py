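import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from recmotif import (
    Background,
    compute_qvalues,
    consensus_to_matrix,
    estimate_background,
    log_odds,
    revcomp,
    scan,
    scan_with_qvalues,
    score_pvalue_table,
)


def brute_force_pvalues(int_scores: np.ndarray, bg: np.ndarray):
    """Enumerate all 4^L words; return {int score: tail probability}."""
    L = int_scores.shape[0]
    words = np.stack(
        np.meshgrid(*[np.arange(4)] * L, indexing="ij"), axis=-1
    ).reshape(-1, L)
    scores = int_scores[np.arange(L), words].sum(axis=1)
    probs = bg[words].prod(axis=1)
    order = np.argsort(scores)[::-1]
    tails = np.cumsum(probs[order])
    out = {}
    for s, t in zip(scores[order], tails):
        out[int(s)] = t  # last write per score = full tail including ties
    return out


class TestMatrices:
    def test_hard_dialect(self):
        m = consensus_to_matrix("AAA", "hard")
        assert m.probs.shape == (3, 4)
        np.testing.assert_array_equal(m.probs, [[1, 0, 0, 0]] * 3)

    def test_soft_dialect(self):
        m = consensus_to_matrix("CA", "soft")
        np.testing.assert_allclose(m.probs[0], [0.01, 0.97, 0.01, 0.01])
        np.testing.assert_allclose(m.probs[1], [0.97, 0.01, 0.01, 0.01])

    def test_errors(self):
        with pytest.raises(ValueError):
            consensus_to_matrix("", "hard")
        with pytest.raises(ValueError):
            consensus_to_matrix("ACGN", "hard")
        with pytest.raises(ValueError):
            consensus_to_matrix("ACG", "fuzzy")


class TestBackground:
    def test_balanced(self):
        bg = estimate_background({"c": "ACGTACGT"})
        np.testing.assert_allclose(bg.freqs, 0.25)

    def test_homopolymer_regularized(self):
        bg = estimate_background({"c": "AAAA"})
        # strand symmetrization splits A/T evenly; zero C/G floored at 1e-6
        assert bg.freqs[1] == bg.freqs[2] > 0
        np.testing.assert_allclose(bg.freqs[0], bg.freqs[3])
        np.testing.assert_allclose(bg.freqs[0], 0.5, atol=1e-5)
        assert abs(bg.freqs.sum() - 1.0) < 1e-12

    def test_n_skipped(self):
        bg = estimate_background({"c": "ACGTNNNN"})
        np.testing.assert_allclose(bg.freqs, 0.25)

    def test_no_content_error(self):
        with pytest.raises(ValueError):
            estimate_background({"c": "NNNN"})


class TestLogOdds:
    def test_hard_match_closed_form(self, uniform_bg):
        sm = log_odds(consensus_to_matrix("A", "hard"), uniform_bg, 0.1)
        expected = math.log2(((1 + 0.1 * 0.25) / 1.1) / 0.25)
        assert abs(sm.scores[0, 0] - expected) < 1e-12
        assert abs(expected - 1.8981) < 1e-4

    def test_uniform_column_scores_zero(self, uniform_bg):
        m = consensus_to_matrix("A", "hard")
        m.probs[0] = 0.25
        sm = log_odds(m, uniform_bg, 0.37)
        np.testing.assert_allclose(sm.scores, 0.0, atol=1e-12)

    def test_soft_limit_small_pseudocount(self, uniform_bg):
        sm = log_odds(consensus_to_matrix("A", "soft"), uniform_bg, 1e-9)
        assert abs(sm.scores[0, 0] - math.log2(0.97 / 0.25)) < 1e-6
        assert abs(math.log2(0.97 / 0.25) - 1.9561) < 1e-4

    def test_zero_pseudocount_rejected_for_hard(self, uniform_bg):
        with pytest.raises(ValueError):
            log_odds(consensus_to_matrix("A", "hard"), uniform_bg, 0.0)


class TestPValueTable:
    def test_single_base_max_score(self, uniform_bg):
        sm = log_odds(consensus_to_matrix("A", "hard"), uniform_bg)
        t = score_pvalue_table(sm, uniform_bg)
        assert abs(t.p_of_int_score(t.max_score) - 0.25) < 1e-15

    def test_a11_independence_product(self, uniform_bg):
        sm = log_odds(consensus_to_matrix("A" * 11, "hard"), uniform_bg)
        t = score_pvalue_table(sm, uniform_bg)
        assert abs(t.p_of_int_score(t.max_score) - 0.25**11) < 1e-18

    @pytest.mark.parametrize("consensus", ["ACGT", "GCAGC", "AAAAAA"])
    @pytest.mark.parametrize("freqs", [(0.25,) * 4, (0.3, 0.2, 0.2, 0.3)])
    def test_matches_brute_force(self, consensus, freqs):
        bg = Background(np.array(freqs))
        sm = log_odds(consensus_to_matrix(consensus, "hard"), bg)
        t = score_pvalue_table(sm, bg)
        expected = brute_force_pvalues(t.int_scores, bg.freqs)
        for s, p in expected.items():
            assert abs(t.p_of_int_score(s) - p) < 1e-12


class TestScan:
    def test_polyA_genome(self, uniform_bg):
        occ = scan({"c": "A" * 1000}, consensus_to_matrix("A" * 11), uniform_bg)
        assert len(occ) == 990
        assert set(occ["strand"]) == {"+"}
        assert occ.attrs["n_tests"] == 2 * 990

    def test_no_matching_bases(self, uniform_bg):
        occ = scan({"c": "CG" * 500}, consensus_to_matrix("A" * 11), uniform_bg)
        assert len(occ) == 0

    def test_planted_truths_all_found(self, small_bundle):
        bg = estimate_background(small_bundle.genome)
        motif = small_bundle.truth["motif"].iloc[0]
        occ = scan(small_bundle.genome, consensus_to_matrix(motif), bg)
        found = set(zip(occ["chrom"], occ["start"]))
        for r in small_bundle.truth.itertuples():
            assert (r.chrom, r.start) in found

    def test_strand_symmetry(self, uniform_bg, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = {"c": seq}
        mirrored = {"c": revcomp(seq)}
        matrix = consensus_to_matrix("GCAGCAGCA")
        occ = scan(genome, matrix, uniform_bg, p_threshold=1e-3)
        occ_m = scan(mirrored, matrix, uniform_bg, p_threshold=1e-3)
        L = len(seq)
        flipped = {
            (L - e, "-" if s == "+" else "+")
            for e, s in zip(occ_m["end"], occ_m["strand"])
        }
        assert flipped == set(zip(occ["start"], occ["strand"]))

    def test_threshold_monotonicity(self, small_bundle):
        bg = estimate_background(small_bundle.genome)
        matrix = consensus_to_matrix("CACACACACACA")
        loose = scan(small_bundle.genome, matrix, bg, p_threshold=1e-4)
        strict = scan(small_bundle.genome, matrix, bg, p_threshold=1e-5)
        loose_set = set(zip(loose["chrom"], loose["start"], loose["strand"]))
        strict_set = set(zip(strict["chrom"], strict["start"], strict["strand"]))
        assert strict_set <= loose_set
        assert (strict["p"] <= 1e-5).all()

    def test_n_windows_skipped(self, uniform_bg):
        occ = scan({"c": "A" * 20 + "N" + "A" * 20}, consensus_to_matrix("A" * 11),
                   uniform_bg)
        spans_n = (occ["start"] <= 20) & (occ["end"] > 20)
        assert not spans_n.any()

    def test_motif_longer_than_chromosome(self, uniform_bg):
        with pytest.raises(ValueError):
            scan({"c": "ACGT"}, consensus_to_matrix("A" * 11), uniform_bg)


class TestQValues:
    def test_single_occurrence(self):
        import pandas as pd

        occ = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [3], "strand": ["+"],
             "score": [1.0], "p": [0.01]}
        )
        out = compute_qvalues(occ, n_tests=1)
        assert out["q"].iloc[0] == pytest.approx(0.01)

    def test_bh_by_hand(self):
        import pandas as pd

        occ = pd.DataFrame(
            {"chrom": "c", "start": [0, 10, 20], "end": [3, 13, 23],
             "strand": "+", "score": 1.0, "p": [0.01, 0.02, 0.03]}
        )
        out = compute_qvalues(occ, n_tests=3)
        # q_(i) = min_{j>=i} p_(j) * 3 / j = {0.03, 0.03, 0.03}
        np.testing.assert_allclose(out["q"], [0.03, 0.03, 0.03])

    @given(
        st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1, max_size=40),
        st.integers(50, 1000),
    )
    def test_q_monotone_in_p(self, pvals, n_tests):
        import pandas as pd

        occ = pd.DataFrame(
            {"chrom": "c", "start": np.arange(len(pvals)) * 10,
             "end": np.arange(len(pvals)) * 10 + 3, "strand": "+",
             "score": 1.0, "p": pvals}
        )
        out = compute_qvalues(occ, n_tests=n_tests)
        df = out.sort_values("p")
        assert np.all(np.diff(df["q"]) >= -1e-15)
        assert (out["q"] <= 1.0).all()

    def test_n_tests_too_small(self):
        import pandas as pd

        occ = pd.DataFrame(
            {"chrom": "c", "start": [0, 1], "end": [3, 4], "strand": "+",
             "score": 1.0, "p": [0.1, 0.2]}
        )
        with pytest.raises(ValueError):
            compute_qvalues(occ, n_tests=1)


def test_scan_with_qvalues_matches_two_step(small_bundle):
    bg = estimate_background(small_bundle.genome)
    matrix = consensus_to_matrix("CACACACACACA")
    one = scan_with_qvalues(small_bundle.genome, matrix, bg)
    occ = scan(small_bundle.genome, matrix, bg)
    two = compute_qvalues(occ)
    np.testing.assert_allclose(one["q"], two["q"])
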