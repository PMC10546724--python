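"""Position weight matrices with exact p-value thresholds.

A PWM holds log2 probability ratios of motif column frequencies (with
pseudocount) over the stationary base frequencies of a first-order Markov
background.  The null distribution of the length-L window score under that
background is computed exactly by dynamic programming over (position, previous
base, discretized score), which yields both the score threshold for a target
tail probability (5e-5 for a motif match) and p-values for arbitrary scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to int8 codes (raises on other letters)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        codes[arr == ord(b)] = i
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass(frozen=True)
class MarkovBackground:
    """First-order Markov background model over ACGT.

    ``transitions[a, b]`` is P(next=b | current=a); ``initial`` the start
    distribution.  The stationary distribution is used as the reference for
    PWM log-ratios and as the restart distribution for flanking segments.
    """

    initial: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    transitions: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.25))

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transitions, dtype=float)
        if not np.allclose(init.sum(), 1) or not np.allclose(trans.sum(axis=1), 1):
            raise ValueError("background distributions must sum to 1")
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "transitions", trans)

    @property
    def stationary(self) -> np.ndarray:
        w, v = np.linalg.eig(self.transitions.T)
        vec = np.real(v[:, np.argmin(np.abs(w - 1))])
        return vec / vec.sum()

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls()

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "MarkovBackground":
        """Empirical first-order model from a set of sequences (+1 pseudocount)."""
        init = np.ones(4)
        trans = np.ones((4, 4))
        for s in sequences:
            codes = encode(s)
            np.add.at(init, codes, 1)
            if codes.size > 1:
                np.add.at(trans, (codes[:-1], codes[1:]), 1)
        return cls(init / init.sum(), trans / trans.sum(axis=1, keepdims=True))

    def log_prob(self, codes: np.ndarray) -> np.ndarray:
        """Log probability of each row of a (n, m) code array under the chain
        started from the stationary distribution."""
        codes = np.atleast_2d(codes)
        stat = self.stationary
        lp = np.log(stat[codes[:, 0]])
        if codes.shape[1] > 1:
            lp = lp + np.log(self.transitions[codes[:, :-1], codes[:, 1:]]).sum(axis=1)
        return lp

    def sample(self, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n sequences of the given length, started from stationary."""
        out = np.empty((n, length), dtype=np.int8)
        stat = self.stationary
        out[:, 0] = rng.choice(4, size=n, p=stat)
        cum = np.cumsum(self.transitions, axis=1)
        for j in range(1, length):
            u = rng.random(n)
            out[:, j] = (u[:, None] > cum[out[:, j - 1]]).sum(axis=1)
        return out


@dataclass(frozen=True)
class PWM:
    """Log2 probability-ratio matrix for one transcription factor motif."""

    tf: str
    probs: np.ndarray  # (L, 4) column probabilities after pseudocounting
    background: MarkovBackground

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if probs.shape[0] < 1:
            raise ValueError("motif length must be >= 1")
        if not np.allclose(probs.sum(axis=1), 1):
            raise ValueError("motif columns must sum to 1")
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(L, 4) log2 ratios of column probability over background stationary."""
        return np.log2(self.probs / self.background.stationary[None, :])

    def reverse_complement_matrix(self) -> np.ndarray:
        return self.matrix[::-1, COMPLEMENT]

    def score(self, codes: np.ndarray) -> float:
        """Score one length-L encoded window on the forward strand."""
        return float(self.matrix[np.arange(self.length), codes].sum())


def build_pwm(
    counts: np.ndarray,
    background: MarkovBackground | None = None,
    tf: str = "motif",
    pseudocount: float = 0.8,
) -> PWM:
    """PWM from a position frequency matrix of base counts.

    Column probabilities are (count + pseudocount/4-spread) over the padded
    total: (c + pc) / (total + 4 pc); entries of the scoring matrix are
    log2(prob / stationary background prob).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D")
    if counts.shape[0] == 4 and counts.shape[1] != 4:
        counts = counts.T  # accept JASPAR's 4 x L layout
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every column needs at least one count")
    if background is None:
        background = MarkovBackground.uniform()
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
    return PWM(tf=tf, probs=probs, background=background)


class ScoreDistribution:
    """Exact null distribution of the window score, discretized to fixed bins.

    The DP propagates, per motif position, the joint distribution of
    (previous base, accumulated score bin) under the first-order background
    chain started from its stationary distribution.
    """

    def __init__(self, pwm: PWM, bin_width: float = 1e-3):
        self.pwm = pwm
        self.bin_width = float(bin_width)
        m = pwm.matrix
        L = pwm.length
        bins = np.round(m / self.bin_width).astype(np.int64)  # (L, 4)
        trans = pwm.background.transitions
        stat = pwm.background.stationary
        # dist[b, k]: P(first base = b, score bin offset = k); the array grows
        # by each position's bin span so its last index is the true maximum
        dist = np.zeros((4, int(bins[0].max() - bins[0].min()) + 1))
        cum_lo = int(bins[0].min())
        for b in range(4):
            dist[b, bins[0, b] - cum_lo] = stat[b]
        for i in range(1, L):
            step_lo = int(bins[i].min())
            new_width = dist.shape[1] + int(bins[i].max()) - step_lo
            new = np.zeros((4, new_width))
            for b in range(4):
                shift = bins[i, b] - step_lo
                contrib = trans[:, b] @ dist
                new[b, shift : shift + dist.shape[1]] += contrib
            dist = new
            cum_lo += step_lo
        pmf = dist.sum(axis=0)
        # scores computed from the unrounded matrix can differ from binned
        # sums by at most L * bin_width / 2; comparisons use this tolerance
        self.tol = pwm.length * self.bin_width
        self._offset = cum_lo  # bin index of pmf[0]
        self._pmf = pmf
        self._sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])

    def sf(self, score) -> np.ndarray | float:
        """P(window score >= score) under the background.

        Scores within the discretization tolerance above the top achievable
        bin are treated as the top bin (full-precision scores of real
        sequences can exceed the binned maximum by up to ``tol``)."""
        s = np.asarray(score, dtype=float)
        k = np.ceil(s / self.bin_width - 1e-9).astype(np.int64) - self._offset
        top = len(self._pmf) - 1
        k = np.where((k > top) & (s <= (top + self._offset) * self.bin_width + self.tol), top, k)
        k = np.clip(k, 0, len(self._sf) - 1)
        out = self._sf[k]
        return float(out) if np.isscalar(score) or out.ndim == 0 else out

    def threshold(self, alpha: float) -> float:
        """Smallest achievable score with tail probability <= alpha."""
        ok = np.nonzero(self._sf[: len(self._pmf)] <= alpha * (1 + 1e-9))[0]
        if ok.size == 0:
            raise ValueError(
                f"no score of motif {self.pwm.tf!r} attains tail <= {alpha}; "
                "motif too close to background to be usable"
            )
        achievable = np.nonzero(self._pmf > 0)[0]
        cand = achievable[achievable >= ok[0]]
        if cand.size == 0:
            raise ValueError(f"motif {self.pwm.tf!r} unusable at alpha={alpha}")
        return (cand[0] + self._offset) * self.bin_width


def exact_threshold(
    pwm: PWM, alpha: float = 5e-5, bin_width: float = 1e-3
) -> tuple[float, ScoreDistribution]:
    """Exact score threshold s* with P(score >= s*) <= alpha, plus the
    distribution object exposing p(s) for arbitrary scores."""
    dist = ScoreDistribution(pwm, bin_width=bin_width)
    return dist.threshold(alpha), dist


@dataclass(frozen=True)
class MotifHit:
    seq_name: str
    start: int  # 0-based offset within the scanned sequence
    end: int
    strand: str
    tf: str
    score: float
    p: float


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of every length-L window of one encoded sequence."""
    L = matrix.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(L)[None, :] + np.arange(n)[:, None]
    return matrix[np.arange(L)[None, :], codes[idx]].sum(axis=1)


def scan(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float | None = None,
    alpha: float = 5e-5,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """All windows scoring >= threshold on either strand, with overlapping
    same-TF hits collapsed to the best-scoring one (ties: leftmost, then '+').
    """
    if dist is None:
        dist = ScoreDistribution(pwm)
    if threshold is None:
        threshold = dist.threshold(alpha)
    fwd = pwm.matrix
    rev = pwm.reverse_complement_matrix()
    L = pwm.length
    hits: list[MotifHit] = []
    for name, seq in sequences.items():
        if len(seq) < L:
            continue
        codes = encode(seq)
        raw: list[tuple[int, str, float]] = []
        for strand, matrix in (("+", fwd), ("-", rev)):
            scores = _window_scores(codes, matrix)
            for i in np.nonzero(scores >= threshold - dist.tol)[0]:
                raw.append((int(i), strand, float(scores[i])))
        # collapse overlapping hits: greedy by (score desc, start asc, '+' first)
        raw.sort(key=lambda h: (-h[2], h[0], h[1]))
        taken: list[tuple[int, str, float]] = []
        for h in raw:
            if all(abs(h[0] - t[0]) >= L for t in taken):
                taken.append(h)
        for start, strand, score in sorted(taken):
            hits.append(
                MotifHit(name, start, start + L, strand, pwm.tf, score, float(dist.sf(score)))
            )
    return hits
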