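"""Helix-45 anchored re-annotation of 16S rRNA 3' ends.

The 3' terminus of the mature 16S rRNA lies a fixed 13 bases past the end of
the highly conserved terminal hairpin (helix 45); the anti-Shine-Dalgarno
hexamer CCTCCT (CCUCCU in the RNA) sits inside that tail, starting five
bases after the helix.  Genome annotations frequently truncate the gene a
few bases early, cutting into the anti-SD.  This module locates helix 45 in
an oriented sequence window with a simple ungapped scorer (identity 1,
Watson-Crick complement 0.25, mismatch 0), reads off the 13-base tail and
the 23-base extended region, scores the anti-SD, and classifies each gene:
already correct, correctable by extension, helix-less, ambiguous, or a
variant tail (close to / far from the consensus anti-SD).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import GenomeRecord, RnaGeneContext, extract_context

log = logging.getLogger(__name__)

#: Last 24 bases of E. coli K-12 16S rRNA helix 45, the default search query.
DEFAULT_HELIX45 = "TAACCGTAGGGGAACCTGCGGTTG"

#: Consensus anti-Shine-Dalgarno hexamer (DNA alphabet).
ANTISD = "CCTCCT"

#: Canonical distance from the helix-45 end to the anti-SD start, in bases.
ANTISD_CANONICAL_OFFSET = 5

TAIL_LEN = 13
EXTENDED_LEN = 23

#: Gene categories (a partition).
CATEGORIES = (
    "annotated_ok",
    "reannotated",
    "no_helix45",
    "ambiguous",
    "variant_close",
    "variant_absent",
)

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Helix45Hit:
    """An ungapped placement of the helix-45 query within a window."""

    offset: int  # 0-based start within the window
    score: float
    query_length: int

    @property
    def end(self) -> int:
        """0-based position just past the aligned query (= tail start)."""
        return self.offset + self.query_length


@dataclass
class TailAnnotation:
    """Per-gene result of the 3'-end analysis."""

    feature_id: str
    taxid: str
    hit: Helix45Hit | None
    aligned24: str | None  # genome bases under the helix-45 alignment
    tail13: str | None
    extended23: str | None
    antisd_matches: int | None  # identities to CCTCCT at the canonical offset
    antisd_offset: int | None  # helix end -> exact CCTCCT start, if any
    category: str
    extension: int  # bases added to the annotated 3' end (0 when none)
    combined_score: float  # helix score + antisd matches
    corrected_end: int | None = None  # 1-based contig coord of the new 3' end
    start_coord: int = 0  # genomic start, for deterministic tie-breaking


@dataclass
class TailClassSummary:
    """Distinct helix+tail sequence classes among one taxid's 16S genes."""

    taxid: str
    gene_count: int
    class_count: int
    max_class_size: int
    majority_sequence: str
    class_table: list[tuple[str, int]]
    excluded_no_hit: int = 0


@dataclass
class ConsensusMatrix:
    """Per-column A/C/G/T frequencies over aligned 47-mers."""

    frequencies: np.ndarray  # (47, 4), rows sum to 1 where data exist
    alignment_mode: str  # 'by-helix45' or "by-3'-end"
    n_sequences: int


def score_alignment(query: str, window: str, offset: int) -> float:
    """Ungapped per-base score of ``query`` placed at ``offset`` in ``window``.

    Identity scores 1, a Watson-Crick complement pair (A<->T, C<->G) scores
    0.25, anything else (including N) scores 0.
    """
    if offset < 0 or offset + len(query) > len(window):
        raise ValueError("alignment offset out of range")
    total = 0.0
    for q, w in zip(query, window[offset : offset + len(query)]):
        if q == w:
            total += 1.0
        elif _PAIR.get(q) == w:
            total += 0.25
    return total


def _window_scores(query: str, window: str) -> np.ndarray:
    """Scores of every offset of ``query`` against ``window`` (vectorized)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    qc = np.frombuffer(
        query.translate(str.maketrans("ACGT", "TGCA")).encode(), dtype=np.uint8
    )
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    sw = sliding_window_view(w, len(query))
    return (sw == q).sum(axis=1) + 0.25 * (sw == qc).sum(axis=1)


def find_helix45(
    context: RnaGeneContext, query: str = DEFAULT_HELIX45, min_score: float = 18.0
) -> Helix45Hit | None:
    """Best-scoring placement of the helix-45 query; None below ``min_score``.

    Every offset of the coding-strand window is evaluated; ties between
    equal-scoring placements break toward the 3'-most offset, so that the
    reported tail abuts the true terminus when the helix motif is locally
    repeated.
    """
    if len(context.window) < len(query):
        log.warning("window shorter than helix-45 query for %s", context.feature.feature_id)
        return None
    scores = _window_scores(query, context.window)
    best = scores.max()
    if best < min_score:
        return None
    offset = int(np.flatnonzero(scores == best)[-1])
    return Helix45Hit(offset=offset, score=float(best), query_length=len(query))


def extract_tail(context: RnaGeneContext, hit: Helix45Hit):
    """13-base tail and 23-base extended region 3' of the helix-45 placement.

    Returns ``(tail13, extended23, ambiguous)``.  The annotation is flagged
    ambiguous when fewer than 13 genomic bases remain past the helix or the
    tail contains N; ``extended23`` is None when fewer than 23 bases remain.
    """
    window = context.window
    start = hit.end
    tail = window[start : start + TAIL_LEN]
    if len(tail) < TAIL_LEN or "N" in tail:
        return (tail if len(tail) == TAIL_LEN else None), None, True
    extended = window[start : start + EXTENDED_LEN]
    if len(extended) < EXTENDED_LEN:
        extended = None
    return tail, extended, False


def score_antisd(tail13: str) -> tuple[int, int | None]:
    """Anti-SD content of a 13-base tail.

    Returns ``(matches, offset)``: ``matches`` counts identities between the
    hexamer starting five bases after helix 45 (``tail13[5:11]``) and CCTCCT;
    ``offset`` is the distance from the helix-45 end to the start of an exact
    CCTCCT anywhere in the tail (canonically 5), or None if absent.  N bases
    count as mismatches.
    """
    if len(tail13) != TAIL_LEN:
        raise ValueError("tail must be exactly 13 bases")
    matches = sum(
        a == b for a, b in zip(tail13[ANTISD_CANONICAL_OFFSET : ANTISD_CANONICAL_OFFSET + 6], ANTISD)
    )
    pos = tail13.find(ANTISD)
    return matches, (pos if pos >= 0 else None)


def classify_gene(
    context: RnaGeneContext,
    hit: Helix45Hit | None,
    tail_result=None,
    antisd_result=None,
) -> TailAnnotation:
    """Assign one of the six categories and compute the corrected 3' end.

    ``tail_result`` / ``antisd_result`` default to recomputation from the
    hit; pass them explicitly to reuse intermediate values.
    """
    feature = context.feature
    base = dict(
        feature_id=feature.feature_id,
        taxid=feature.taxid,
        start_coord=feature.start,
    )
    if hit is None:
        return TailAnnotation(
            hit=None, aligned24=None, tail13=None, extended23=None,
            antisd_matches=None, antisd_offset=None, category="no_helix45",
            extension=0, combined_score=0.0, **base,
        )

    if tail_result is None:
        tail_result = extract_tail(context, hit)
    tail13, extended23, ambiguous = tail_result
    aligned = context.window[hit.offset : hit.end]
    if ambiguous:
        return TailAnnotation(
            hit=hit, aligned24=aligned, tail13=tail13, extended23=extended23,
            antisd_matches=None, antisd_offset=None, category="ambiguous",
            extension=0, combined_score=hit.score, **base,
        )

    if antisd_result is None:
        antisd_result = score_antisd(tail13)
    matches, sd_offset = antisd_result
    a3 = context.annotated3_offset
    tail_end = hit.end + TAIL_LEN
    extension = 0
    corrected_end = None

    if ANTISD in tail13:
        if a3 >= tail_end:
            category = "annotated_ok"
        else:
            category = "reannotated"
            extension = tail_end - a3
            if feature.strand == "+":
                corrected_end = feature.end + extension
            else:
                corrected_end = feature.start - extension
    elif matches == 5:
        category = "variant_close"
    else:
        category = "variant_absent"

    return TailAnnotation(
        hit=hit, aligned24=aligned, tail13=tail13, extended23=extended23,
        antisd_matches=matches, antisd_offset=sd_offset, category=category,
        extension=extension, combined_score=hit.score + matches,
        corrected_end=corrected_end, **base,
    )


def annotate_context(
    context: RnaGeneContext, query: str = DEFAULT_HELIX45, min_score: float = 18.0
) -> TailAnnotation:
    """find_helix45 -> extract_tail -> score_antisd -> classify_gene."""
    hit = find_helix45(context, query, min_score)
    return classify_gene(context, hit)


def annotate_record(
    record: GenomeRecord,
    query: str = DEFAULT_HELIX45,
    min_score: float = 18.0,
    flank: int = 500,
) -> list[TailAnnotation]:
    """Annotate every 16S rRNA gene of a genome."""
    return [
        annotate_context(extract_context(record, f, flank), query, min_score)
        for f in record.rrna_16s()
    ]


def select_representative(annotations: list[TailAnnotation]) -> TailAnnotation:
    """One gene per taxid: maximum helix score + anti-SD matches.

    Ties break toward the lowest genomic start coordinate.
    """
    if not annotations:
        raise ValueError("no annotations to select from")
    return max(annotations, key=lambda a: (a.combined_score, -a.start_coord))


def summarize_tail_classes(annotations: list[TailAnnotation]) -> TailClassSummary:
    """Distinct 37-base (helix 24 + tail 13) sequence classes within a taxid.

    Genes without a helix-45 hit or tail are excluded from the class table
    and counted in ``excluded_no_hit``.  The majority class is the largest;
    ties break to the lexicographically smallest sequence.
    """
    usable = [a for a in annotations if a.hit is not None and a.tail13 is not None]
    excluded = len(annotations) - len(usable)
    if not usable:
        raise ValueError("no genes with a helix-45 hit and tail")
    taxid = usable[0].taxid
    counts = Counter(a.aligned24 + a.tail13 for a in usable)
    # order: descending count, then lexicographic, so the majority is first
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return TailClassSummary(
        taxid=taxid,
        gene_count=len(usable),
        class_count=len(counts),
        max_class_size=table[0][1],
        majority_sequence=table[0][0],
        class_table=table,
        excluded_no_hit=excluded,
    )


_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def consensus_matrix(seqs: list[str], mode: str = "by-helix45") -> ConsensusMatrix:
    """Column-wise base frequencies over aligned 47-mers.

    ``by-helix45`` inputs are hit-anchored 24+13+10 strings; ``by-3'-end``
    inputs are the terminal 47 bases ending at the annotated 3' end.  N bases
    are ignored and the column renormalized.
    """
    if mode not in ("by-helix45", "by-3'-end"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if not seqs:
        raise ValueError("consensus_matrix needs at least one sequence")
    ncol = len(seqs[0])
    counts = np.zeros((ncol, 4))
    for s in seqs:
        if len(s) != ncol:
            raise ValueError("all sequences must have equal length")
        for j, b in enumerate(s):
            col = _BASE_TO_COL.get(b)
            if col is not None:
                counts[j, col] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
    return ConsensusMatrix(frequencies=freqs, alignment_mode=mode, n_sequences=len(seqs))
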