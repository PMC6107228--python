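"""Ribosome-binding-site motif discovery by exact enrichment statistics.

For each k-mer pattern (k = 7 by default) we count the number of upstream
windows containing the pattern within one mismatch, and compare it with the
exact expectation under an order-m Markov background estimated from the
windows themselves.  Treating each window as an independent Bernoulli trial
with a length-dependent containment probability p_i gives

    z = (X - sum p_i) / sqrt(sum p_i (1 - p_i)).

The containment probability -- the chance that a random background window of
length L contains at least one substring within Hamming distance d of the
pattern -- is computed exactly by dynamic programming over the distribution
of the last t = max(k-1, m+1) bases, killing every transition that would
complete a word of the pattern's Hamming ball.  The top-ranked patterns are
then merged into a position frequency matrix whose informative columns
(relative entropy against the background base distribution) yield a
consensus Shine-Dalgarno string.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, upstream_sequence

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> int array over {0,1,2,3} (A,C,G,T)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | _BASE_INDEX[b]
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join(BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def hamming_ball(code: int, k: int, d: int) -> np.ndarray:
    """Codes of all k-mers within Hamming distance ``d`` of ``code``."""
    ball = {code}
    frontier = {code}
    for _ in range(d):
        nxt = set()
        for c in frontier:
            for pos in range(k):
                shift = 2 * pos
                digit = (c >> shift) & 3
                stripped = c & ~(3 << shift)
                for a in range(4):
                    if a != digit:
                        nxt.add(stripped | (a << shift))
        frontier = nxt - ball
        ball |= nxt
    return np.array(sorted(ball), dtype=np.int64)


def _all_balls(k: int, d: int) -> np.ndarray:
    """Hamming balls of every k-mer, as a (4^k, ball-size) matrix.

    Only d in {0, 1} is supported here (the ball size is then uniform:
    1 + 3k for d=1).  Row i lists the patterns matched by observed k-mer i,
    which by symmetry equals the k-mers matching pattern i.
    """
    n = 4**k
    codes = np.arange(n, dtype=np.int64)
    if d == 0:
        return codes[:, None]
    if d != 1:
        raise ValueError("only d in {0, 1} supported for bulk ranking")
    cols = [codes]
    for pos in range(k):
        shift = 2 * pos
        digit = (codes >> shift) & 3
        stripped = codes & ~(3 << shift)
        for delta in (1, 2, 3):
            cols.append(stripped | (((digit + delta) % 4) << shift))
    return np.stack(cols, axis=1)


@dataclass
class MarkovModel:
    """Order-m Markov chain over {A,C,G,T}.

    ``transitions[c, b]`` is P(next base = b | previous m bases encode to c);
    ``initial[c]`` is the distribution of the first m-mer.  All probabilities
    are strictly positive (estimation uses add-one pseudocounts).
    """

    order: int
    transitions: np.ndarray  # (4^m, 4)
    initial: np.ndarray  # (4^m,)

    def __post_init__(self):
        m = self.order
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transitions.shape != (4**m, 4):
            raise ValueError("transition matrix shape mismatch")
        if self.initial.shape != (4**m,):
            raise ValueError("initial distribution shape mismatch")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if (self.transitions <= 0).any() or (self.initial <= 0).any():
            raise ValueError("all probabilities must be positive (use pseudocounts)")

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovModel":
        m = order
        return cls(order=m, transitions=np.full((4**m, 4), 0.25),
                   initial=np.full(4**m, 1.0 / 4**m))

    @classmethod
    def from_windows(cls, windows, order: int = 3, pseudocount: float = 1.0) -> "MarkovModel":
        """Estimate from a set of windows with add-one pseudocounts.

        The initial distribution is the pooled frequency of all m-mer
        occurrences across the windows (not just window prefixes).
        """
        m = order
        mask = (1 << (2 * m)) - 1
        trans = np.full((4**m, 4), pseudocount)
        init = np.full(4**m, pseudocount)
        for w in windows:
            arr = encode_seq(w)
            ctx = 0
            for i, b in enumerate(arr):
                if i >= m:
                    trans[ctx, b] += 1
                if m > 0:
                    ctx = ((ctx << 2) | int(b)) & mask
                    if i >= m - 1:
                        init[ctx] += 1
        return cls(order=m,
                   transitions=trans / trans.sum(axis=1, keepdims=True),
                   initial=init / init.sum())

    def base_marginal(self) -> np.ndarray:
        """Single-base background distribution q(b) = sum_c pi(c) P(b|c)."""
        q = self.initial @ self.transitions
        return q / q.sum()

    def sample(self, rng: np.random.Generator, n: int, length: int) -> np.ndarray:
        """Draw ``n`` sequences of ``length`` bases as an (n, length) int array."""
        m = self.order
        if length < m:
            raise ValueError("length shorter than model order")
        out = np.empty((n, length), dtype=np.int64)
        if m > 0:
            init_codes = rng.choice(4**m, size=n, p=self.initial)
            for j in range(m):
                out[:, j] = (init_codes >> (2 * (m - 1 - j))) & 3
            ctx = init_codes
        else:
            ctx = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(self.transitions, axis=1)
        mask = (1 << (2 * m)) - 1
        for pos in range(m, length):
            u = rng.random(n)
            b = (u[:, None] > cum[ctx]).sum(axis=1)
            out[:, pos] = b
            if m > 0:
                ctx = ((ctx << 2) | b) & mask
        return out

    def sample_strings(self, rng: np.random.Generator, n: int, length: int) -> list[str]:
        arr = self.sample(rng, n, length)
        lut = np.array(list(BASES))
        return ["".join(row) for row in lut[arr]]


@dataclass
class UpstreamSet:
    """Windows of W bases immediately 5' of CDS start codons."""

    windows: list[str]
    W: int
    background: MarkovModel

    @property
    def N(self) -> int:
        return len(self.windows)


def collect_upstream(
    record: GenomeRecord, W: int = 20, k: int = 7, order: int = 3
) -> UpstreamSet:
    """Coding-strand upstream windows for every CDS of a genome.

    Windows truncated at contig ends to fewer than ``k`` bases, or containing
    N, are dropped.  The background Markov model is estimated from the
    retained windows with add-one pseudocounts.
    """
    windows = []
    for f in record.cds():
        w = upstream_sequence(record, f, W)
        if len(w) < k or "N" in w:
            continue
        windows.append(w)
    if not windows:
        raise ValueError("no usable upstream windows")
    return UpstreamSet(windows=windows, W=W,
                       background=MarkovModel.from_windows(windows, order=order))


class _SurvivalDP:
    """Shared state for containment DPs against one Markov model.

    The DP tracks the probability distribution of the last t bases of a
    growing random string, where t = max(k-1, order+1).  Because every state
    sharing its low t-1 digits feeds the same four successors with the same
    conditional probabilities, one step is a reshape-sum plus an outer
    product; pattern-specific "killed" transitions (those completing a word
    of the Hamming ball) are subtracted afterwards.
    """

    def __init__(self, model: MarkovModel, k: int):
        m = model.order
        self.k = k
        self.t = t = max(k - 1, m + 1)
        mmask = (1 << (2 * m)) - 1
        self.state_mask = (1 << (2 * t)) - 1
        # transition rows indexed by the low t-1 digits of the state
        r = np.arange(4 ** (t - 1), dtype=np.int64)
        self.tr_r = model.transitions[r & mmask]
        self.mmask = mmask
        self.model = model
        # probability of each t-mer prefix
        probs = model.initial.copy()
        for _ in range(m, t):
            ctx = np.arange(probs.size, dtype=np.int64) & mmask
            probs = (probs[:, None] * model.transitions[ctx]).reshape(-1)
        self.prefix = probs

    def _killed(self, ball: np.ndarray):
        t, k = self.t, self.k
        n_hi = 4 ** (t + 1 - k)
        if n_hi > 1:
            hi = np.arange(n_hi, dtype=np.int64) << (2 * k)
            full = (hi[:, None] + ball[None, :]).reshape(-1)
        else:
            full = ball
        s = full >> 2
        b = full & 3
        ns = full & self.state_mask
        tp = self.model.transitions[s & self.mmask, b]
        return s, ns, tp

    def _clean_prefix(self, ball: np.ndarray) -> np.ndarray:
        """Zero prefixes that already contain a ball word (only when t >= k)."""
        t, k = self.t, self.k
        v = self.prefix.copy()
        if t >= k:
            codes = np.arange(v.size, dtype=np.int64)
            kmask = (1 << (2 * k)) - 1
            bad = np.zeros(v.size, dtype=bool)
            for start in range(t - k + 1):
                sub = (codes >> (2 * (t - k - start))) & kmask
                bad |= np.isin(sub, ball)
            v[bad] = 0.0
        return v

    def survival(self, ball: np.ndarray, step_marks: np.ndarray) -> np.ndarray:
        """P(no ball word in the first t + s bases) for each s in step_marks.

        ``step_marks`` must be ascending positive ints; a mark of 0 reports
        the prefix itself (legal when t >= k).
        """
        ks, kns, ktp = self._killed(ball)
        v = self._clean_prefix(ball)
        out = np.empty(len(step_marks))
        pos = 0
        nmark = len(step_marks)
        if nmark and step_marks[0] == 0:
            out[0] = v.sum()
            pos = 1
        for step in range(1, int(step_marks[-1]) + 1 if nmark else 0):
            u = v.reshape(4, -1).sum(axis=0)
            w = (u[:, None] * self.tr_r).reshape(-1)
            corr = v[ks] * ktp
            np.subtract.at(w, kns, corr)
            v = w
            if pos < nmark and step == step_marks[pos]:
                out[pos] = v.sum()
                pos += 1
        return out


def containment_probability(
    pattern: str, L: int, model: MarkovModel, d: int = 1
) -> float:
    """Exact P(a random length-L background string contains the pattern).

    "Contains" means at least one substring within Hamming distance ``d``.
    Requires L >= k and model order <= k - 1.
    """
    k = len(pattern)
    if L < k:
        raise ValueError("window length shorter than pattern")
    if model.order > k - 1:
        raise ValueError("model order must be at most k - 1")
    dp = _SurvivalDP(model, k)
    ball = hamming_ball(encode_kmer(pattern), k, d)
    steps = np.array([L - dp.t], dtype=np.int64)
    surv = dp.survival(ball, steps)[0]
    return float(min(max(1.0 - surv, 0.0), 1.0))


@dataclass
class MotifScore:
    """One pattern's observed count, exact expectation, and z-score."""

    pattern: str
    X: int
    expected: float
    z: float
    p_by_length: dict[int, float] = field(default_factory=dict)


def rank_patterns(
    upstream: UpstreamSet, k: int = 7, d: int = 1, top: int = 20, zmin: float = 5.0
) -> tuple[list[MotifScore], bool]:
    """Score all 4^k patterns against the window set; rank by z.

    Returns the full sorted list (z descending, ties lexicographic by
    pattern) and a significance flag: True iff the ``top``-th ranked pattern
    has z > ``zmin``.
    """
    model = upstream.background
    if model.order > k - 1:
        raise ValueError("background order must be at most k - 1")
    n_pat = 4**k
    balls = _all_balls(k, d)

    # observed containment counts: each window contributes once to every
    # pattern within distance d of one of its k-mers
    X = np.zeros(n_pat, dtype=np.int64)
    lengths = []
    for w in upstream.windows:
        arr = encode_seq(w)
        L = len(arr)
        lengths.append(L)
        weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        codes = np.lib.stride_tricks.sliding_window_view(arr, k) @ weights
        matched = np.unique(balls[codes])
        X[matched] += 1

    lengths = np.asarray(lengths)
    uniq_lengths, length_counts = np.unique(lengths, return_counts=True)

    dp = _SurvivalDP(model, k)
    marks = uniq_lengths - dp.t
    if (marks < 0).any():
        raise ValueError("window shorter than DP prefix")
    p = np.empty((n_pat, len(uniq_lengths)))
    for code in range(n_pat):
        surv = dp.survival(balls[code], marks)
        p[code] = 1.0 - surv
    np.clip(p, 1e-300, 1.0, out=p)

    expected = p @ length_counts
    variance = (p * (1.0 - p)) @ length_counts
    variance = np.maximum(variance, 1e-300)
    z = (X - expected) / np.sqrt(variance)

    order = np.lexsort((np.arange(n_pat), -z))
    scores = [
        MotifScore(
            pattern=decode_kmer(int(c), k),
            X=int(X[c]),
            expected=float(expected[c]),
            z=float(z[c]),
            p_by_length={int(L): float(p[c, j]) for j, L in enumerate(uniq_lengths)},
        )
        for c in order
    ]
    significant = len(scores) >= top and scores[top - 1].z > zmin
    return scores, significant


@dataclass
class MotifProfile:
    """Aligned top patterns, weighted PFM, column information, consensus."""

    placements: list[tuple[str, int, float]]  # (pattern, offset vs anchor, weight)
    pfm: np.ndarray  # (n_columns, 4)
    column_offsets: np.ndarray  # column index -> offset relative to anchor start
    relative_entropy: np.ndarray  # bits per column
    consensus: str
    significant: bool | None = None


def _best_offset(anchor: str, pattern: str) -> int:
    """Offset in [-(k-1), k-1] maximizing positionwise agreement.

    Ties prefer the smallest |offset|, then the negative one.
    """
    k = len(anchor)
    best_off, best_agree = 0, -1
    for off in sorted(range(-(k - 1), k), key=lambda o: (abs(o), o)):
        lo = max(0, off)
        hi = min(k, k + off)
        agree = sum(anchor[j] == pattern[j - off] for j in range(lo, hi))
        if agree > best_agree:
            best_agree, best_off = agree, off
    return best_off


def build_profile(
    top: list[MotifScore],
    model: MarkovModel,
    re_threshold: float = 0.5,
    significant: bool | None = None,
) -> MotifProfile:
    """Merge ranked patterns into a consensus via a relative-entropy profile.

    The rank-1 pattern anchors the alignment at offset 0; every other
    pattern is placed at the offset that best agrees with the anchor.  A
    z-weighted position frequency matrix (add-one pseudocounts) is scored
    per column by relative entropy against the background base distribution,
    and the consensus reads the majority base over the longest contiguous
    run of informative columns that overlaps the anchor.  A column is
    informative when RE >= ``re_threshold`` *and* its majority base has
    frequency >= 0.5: a split column (e.g. 0.46/0.46 between two bases) may
    carry relative entropy yet has no majority base to read off.
    """
    if not top:
        raise ValueError("empty pattern list")
    k = len(top[0].pattern)
    anchor = top[0].pattern
    weights = [max(s.z, 0.0) for s in top]
    if sum(weights) == 0.0:
        weights = [1.0] * len(top)
    placements = [(anchor, 0, weights[0])]
    for s, w in zip(top[1:], weights[1:]):
        placements.append((s.pattern, _best_offset(anchor, s.pattern), w))

    min_off = min(p[1] for p in placements)
    max_off = max(p[1] for p in placements)
    ncol = max_off + k - min_off
    counts = np.zeros((ncol, 4))
    for pat, off, w in placements:
        for j, b in enumerate(pat):
            counts[off - min_off + j, _BASE_INDEX[b]] += w
    counts += 1.0  # pseudocounts
    pfm = counts / counts.sum(axis=1, keepdims=True)

    q = model.base_marginal()
    rel_ent = (pfm * np.log2(pfm / q)).sum(axis=1)
    rel_ent = np.maximum(rel_ent, 0.0)

    informative = (rel_ent >= re_threshold) & (pfm.max(axis=1) >= 0.5)
    anchor_cols = range(-min_off, -min_off + k)
    runs = []
    start = None
    for j in range(ncol + 1):
        if j < ncol and informative[j]:
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j))
            start = None
    overlapping = [
        (a, b) for a, b in runs if a < anchor_cols.stop and b > anchor_cols.start
    ]
    if overlapping:
        a, b = max(overlapping, key=lambda r: (r[1] - r[0], -r[0]))
        consensus = "".join(BASES[int(np.argmax(pfm[j]))] for j in range(a, b))
    else:
        consensus = anchor

    return MotifProfile(
        placements=placements,
        pfm=pfm,
        column_offsets=np.arange(min_off, max_off + k),
        relative_entropy=rel_ent,
        consensus=consensus,
        significant=significant,
    )


def count_genes_with_spacer_motif(
    record: GenomeRecord, motif: str, spacer_range: tuple[int, int] = (6, 8)
) -> int:
    """CDS count with ``motif`` ending s bases before the start codon, s in range.

    Each gene counts at most once even if several spacings match.
    """
    lo, hi = spacer_range
    lm = len(motif)
    count = 0
    for f in record.cds():
        up = upstream_sequence(record, f, hi + lm)
        for s in range(lo, hi + 1):
            end = len(up) - s
            if end >= lm and up[end - lm : end] == motif:
                count += 1
                break
    return count
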