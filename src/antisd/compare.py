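"""Classify a discovered Shine-Dalgarno motif against a 13-base 16S tail.

The natural coordinate system is the "a-tail": the reverse complement of
the 13-base tail (AAAGGAGGTGATC for the consensus), along which SD motifs
pair in various registers.  Three labels are produced: presence (present /
close / absent), type (subset of the classic AGGAGG / shifted along the
tail / absent), and the best ungapped pairing register.
"""
from __future__ import annotations

from dataclasses import dataclass

from .genome_io import reverse_complement

CLASSIC_SD = "AGGAGG"


@dataclass
class ComparisonResult:
    sd: str
    tail13: str
    a_tail: str
    presence: str  # present / close / absent
    sd_type: str  # AGGAGG / shifted / absent
    best_offset: int
    best_pairings: int
    low_complexity: bool = False


def best_register(sd: str, region: str, min_overlap: int = 4):
    """Best ungapped antiparallel placement of ``sd`` along ``region``.

    The reverse complement of ``sd`` slides over ``region`` at every offset
    with at least ``min_overlap`` overlapping bases; pairings counts the
    identities within the overlap (i.e. Watson-Crick pairs between sd and
    the region read antiparallel).  Returns ``(offset, pairings)``; ties
    break to the smallest offset.  Offsets index where the first base of
    rc(sd) sits along the region (may be negative for overhangs).
    """
    if len(sd) < 4:
        raise ValueError("sd shorter than 4 bases")
    rc = reverse_complement(sd)
    n, m = len(region), len(rc)
    best = (0, -1)
    for off in range(-(m - min_overlap), n - min_overlap + 1):
        lo = max(0, off)
        hi = min(n, off + m)
        if hi - lo < min_overlap:
            continue
        pairings = sum(region[j] == rc[j - off] for j in range(lo, hi))
        if pairings > best[1]:
            best = (off, pairings)
    return best


def classify_presence(sd: str, tail13: str) -> str:
    """present: sd is an exact substring of the a-tail; close: some
    full-length placement has exactly one mismatch; else absent."""
    a_tail = reverse_complement(tail13)
    if sd in a_tail:
        return "present"
    if len(sd) <= len(a_tail):
        best_mm = min(
            sum(a != b for a, b in zip(sd, a_tail[i : i + len(sd)]))
            for i in range(len(a_tail) - len(sd) + 1)
        )
        if best_mm == 1:
            return "close"
    return "absent"


def classify_type(sd: str, tail13: str) -> str:
    """AGGAGG: sd is a subset of the classic SD; shifted: present in the
    a-tail but not a classic subset; absent otherwise."""
    if sd in CLASSIC_SD:
        return "AGGAGG"
    if sd in reverse_complement(tail13):
        return "shifted"
    return "absent"


def compare(sd: str, tail13: str, min_overlap: int = 4) -> ComparisonResult:
    """Full presence/type/register comparison of one SD against one tail.

    Single-repeated-base motifs (e.g. AAAA) are low-complexity, low-affinity
    sequences unlikely to act as an SD; they are flagged but still
    classified.
    """
    offset, pairings = best_register(sd, tail13, min_overlap=min_overlap)
    return ComparisonResult(
        sd=sd,
        tail13=tail13,
        a_tail=reverse_complement(tail13),
        presence=classify_presence(sd, tail13),
        sd_type=classify_type(sd, tail13),
        best_offset=offset,
        best_pairings=pairings,
        low_complexity=len(set(sd)) == 1,
    )
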