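"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: straight per-position loops and
exhaustive enumeration, sharing no code path with the package internals
they validate.
"""
from __future__ import annotations

import numpy as np

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = "ACGT"


def brute_score(query: str, window: str, offset: int) -> float:
    """Per-position recomputation of the helix-45 alignment score."""
    total = 0.0
    for i, q in enumerate(query):
        w = window[offset + i]
        if q == w:
            total += 1.0
        elif _PAIR.get(q) == w:
            total += 0.25
    return total


def brute_best_offset(query: str, window: str, min_score: float):
    """Exhaustive enumeration of offsets, 3'-most tie-break."""
    best = None
    for off in range(len(window) - len(query) + 1):
        s = brute_score(query, window, off)
        if s >= min_score and (best is None or s >= best[1]):
            best = (off, s)
    return best


def naive_contains(window: str, pattern: str, d: int) -> bool:
    """O(L*k) scan: does window hold a substring within Hamming d of pattern?"""
    k = len(pattern)
    for i in range(len(window) - k + 1):
        if sum(a != b for a, b in zip(window[i : i + k], pattern)) <= d:
            return True
    return False


def enum_containment(pattern: str, L: int, model, d: int) -> float:
    """Exact containment probability by enumerating all 4^L strings."""
    k = len(pattern)
    n = 4**L
    codes = np.arange(n, dtype=np.int64)
    digits = np.empty((n, L), np.int8)
    for j in range(L):
        digits[:, L - 1 - j] = (codes >> (2 * j)) & 3
    m = model.order
    if m > 0:
        ctx = np.zeros(n, np.int64)
        for j in range(m):
            ctx = ctx * 4 + digits[:, j]
        probs = model.initial[ctx].copy()
    else:
        ctx = np.zeros(n, np.int64)
        probs = np.ones(n)
    for pos in range(m, L):
        probs = probs * model.transitions[ctx, digits[:, pos]]
        if m > 0:
            ctx = (ctx * 4 + digits[:, pos]) % (4**m)
    pat = np.array([_BASES.index(b) for b in pattern], np.int8)
    match = np.zeros(n, bool)
    for i in range(L - k + 1):
        match |= (digits[:, i : i + k] != pat).sum(1) <= d
    return float(probs[match].sum())


def random_markov_model(rng: np.random.Generator, order: int):
    from antisd.discovery import MarkovModel

    t = rng.gamma(1.0, 1.0, size=(4**order, 4)) + 0.05
    t /= t.sum(1, keepdims=True)
    init = rng.gamma(1.0, 1.0, size=4**order) + 0.05
    init /= init.sum()
    return MarkovModel(order=order, transitions=t, initial=init)
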