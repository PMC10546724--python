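import itertools

import numpy as np
import pytest

from cistrans.pwm import (
    MarkovBackground,
    PWM,
    ScoreDistribution,
    build_pwm,
    encode,
    exact_threshold,
    scan,
)


def brute_force_tail(pwm: PWM, thresholds, use_binned=True):
    """Exact tail P(score >= t) by enumerating all 4^L sequences under the
    first-order background; with use_binned the matrix is discretized exactly
    as the DP does, making the comparison exact rather than bin-limited."""
    L = pwm.length
    dist = ScoreDistribution(pwm)
    m = np.round(pwm.matrix / dist.bin_width) * dist.bin_width if use_binned else pwm.matrix
    seqs = np.array(list(itertools.product(range(4), repeat=L)), dtype=np.int8)
    scores = m[np.arange(L)[None, :], seqs].sum(axis=1)
    probs = np.exp(pwm.background.log_prob(seqs))
    return np.array([probs[scores >= t - 1e-9].sum() for t in np.atleast_1d(thresholds)])


class TestBuildPwm:
    def test_uniform_column_scores_zero(self):
        pwm = build_pwm(np.full((3, 4), 10.0), pseudocount=0.0)
        np.testing.assert_allclose(pwm.matrix, 0.0, atol=1e-12)

    def test_pseudocount_formula(self):
        pwm = build_pwm(np.array([[10.0, 0, 0, 0]]), pseudocount=0.8)
        expected = np.log2(((np.array([10.0, 0, 0, 0]) + 0.8) / 13.2) / 0.25)
        np.testing.assert_allclose(pwm.matrix[0], expected)

    def test_halving_background_base_adds_one_bit(self):
        counts = np.array([[5.0, 5, 5, 5]])
        uniform = build_pwm(counts)
        skew = MarkovBackground(
            np.array([0.125, 0.375, 0.25, 0.25]),
            np.tile([0.125, 0.375, 0.25, 0.25], (4, 1)),
        )
        shifted = build_pwm(counts, background=skew)
        assert shifted.matrix[0, 0] - uniform.matrix[0, 0] == pytest.approx(1.0)

    def test_jaspar_orientation_accepted(self):
        a = build_pwm(np.arange(1, 13, dtype=float).reshape(3, 4))
        b = build_pwm(np.arange(1, 13, dtype=float).reshape(3, 4).T)
        np.testing.assert_allclose(a.matrix, b.matrix)


class TestExactThreshold:
    def test_two_column_uniform_top_sequence(self):
        # only "AA" attains the top score; uniform iid background: tail 1/16
        counts = np.array([[97.0, 1, 1, 1], [97.0, 1, 1, 1]])
        pwm = build_pwm(counts, pseudocount=0.0)
        s, dist = exact_threshold(pwm, alpha=1 / 16)
        assert dist.sf(s) == pytest.approx(1 / 16, abs=1e-12)
        assert s == pytest.approx(2 * np.log2(0.97 / 0.25), abs=2 * dist.bin_width)

    def test_alpha_one_gives_minimum_score(self):
        rng = np.random.default_rng(0)
        pwm = build_pwm(rng.integers(1, 30, (4, 4)).astype(float))
        s, dist = exact_threshold(pwm, alpha=1.0)
        assert dist.sf(s) == pytest.approx(1.0)

    def test_degenerate_motif_unusable(self):
        pwm = build_pwm(np.full((5, 4), 10.0))
        with pytest.raises(ValueError, match="unusable|tail"):
            exact_threshold(pwm, alpha=5e-5)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("L", [3, 5, 6])
    def test_dp_matches_enumeration(self, seed, L):
        rng = np.random.default_rng([seed, L])
        trans = rng.dirichlet(np.ones(4) * 4, size=4)
        bg = MarkovBackground(np.full(4, 0.25), trans)
        pwm = build_pwm(rng.integers(1, 60, (L, 4)).astype(float), background=bg)
        dist = ScoreDistribution(pwm)
        binm = np.round(pwm.matrix / dist.bin_width) * dist.bin_width
        ts = np.quantile(
            binm[np.arange(L)[None, :],
                 np.array(list(itertools.product(range(4), repeat=L)))].sum(axis=1),
            [0.5, 0.9, 0.99, 1.0],
        )
        enum = brute_force_tail(pwm, ts)
        dp = np.array([dist.sf(t) for t in ts])
        np.testing.assert_allclose(dp, enum, atol=1e-12)


class TestScan:
    @pytest.fixture()
    def sharp_pwm(self):
        rng = np.random.default_rng(1)
        counts = np.zeros((4, 6))
        for j in range(6):
            counts[rng.integers(0, 4), j] = 90
            counts[:, j] += 3
        return build_pwm(counts, tf="sharp")

    def test_planted_instance_recovered(self, sharp_pwm):
        consensus = "".join("ACGT"[i] for i in np.argmax(sharp_pwm.probs, axis=1))
        seq = "TTTTTTTT" + consensus + "TTTTTTTT"
        hits = scan({"p": seq}, sharp_pwm, alpha=1e-3)
        assert any(h.start == 8 and h.strand == "+" for h in hits)

    def test_reverse_complement_symmetry(self, sharp_pwm):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        consensus = "".join("ACGT"[i] for i in np.argmax(sharp_pwm.probs, axis=1))
        seq = "TATAGGAT" + consensus + "CCTTAGTA"
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan({"p": seq}, sharp_pwm, alpha=1e-3)
        rev = scan({"p": rc}, sharp_pwm, alpha=1e-3)
        assert sorted(round(h.score, 9) for h in fwd) == sorted(round(h.score, 9) for h in rev)
        mirrored = {(len(seq) - h.end, len(seq) - h.start) for h in rev}
        assert {(h.start, h.end) for h in fwd} == mirrored

    def test_overlapping_hits_deduplicated(self, sharp_pwm):
        consensus = "".join("ACGT"[i] for i in np.argmax(sharp_pwm.probs, axis=1))
        # two overlapping near-copies: only the better-scoring window survives
        seq = "AA" + consensus[:3] + consensus + "AAAA"
        hits = scan({"p": seq}, sharp_pwm, alpha=0.05)
        starts = [h.start for h in hits]
        assert len(starts) == len(set(starts))
        for a in hits:
            for b in hits:
                if a is not b:
                    assert abs(a.start - b.start) >= sharp_pwm.length

    def test_short_sequence_yields_nothing(self, sharp_pwm):
        assert scan({"p": "ACG"}, sharp_pwm, alpha=0.5) == []
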