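"""Helix-45 scoring, tail extraction, anti-SD scoring and gene classification."""
import numpy as np
import pytest

from antisd.reannotate import (
    ANTISD,
    DEFAULT_HELIX45,
    annotate_context,
    annotate_record,
    classify_gene,
    consensus_matrix,
    extract_tail,
    find_helix45,
    score_alignment,
    score_antisd,
    select_representative,
    summarize_tail_classes,
)
from antisd.simulate import FixtureConfig, make_genome

from _oracles import brute_best_offset, brute_score
from conftest import ALTEROMONAS_CLASSIC, ALTEROMONAS_MINORITY, make_context

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@pytest.mark.parametrize(
    "query,window,expected",
    [
        (DEFAULT_HELIX45, DEFAULT_HELIX45, 24.0),
        # E. coli helix query vs the printed Alteromonas helix 24-mer:
        # 22 identities plus two G<->C complement positions
        (DEFAULT_HELIX45, ALTEROMONAS_CLASSIC[:24], 22.5),
        (DEFAULT_HELIX45, DEFAULT_HELIX45.translate(COMPLEMENT), 6.0),
    ],
)
def test_score_alignment_worked_examples(query, window, expected):
    assert score_alignment(query, window, 0) == expected


def test_score_alignment_out_of_range():
    with pytest.raises(ValueError):
        score_alignment("ACGT", "ACG", 0)


def test_score_alignment_bounded_and_maximal_only_on_identity(rng):
    for _ in range(200):
        q = "".join(rng.choice(list("ACGT"), 12))
        w = "".join(rng.choice(list("ACGT"), 12))
        s = score_alignment(q, w, 0)
        assert 0.0 <= s <= 12.0
        assert (s == 12.0) == (q == w)


def test_find_helix45_matches_exhaustive_enumeration(rng):
    """The sliding-window scorer agrees with brute-force enumeration."""
    for _ in range(50):
        window = "".join(rng.choice(list("ACGT"), 300))
        at = int(rng.integers(0, 300 - 24))
        window = window[:at] + DEFAULT_HELIX45 + window[at + 24 :]
        ctx = make_context(window)
        hit = find_helix45(ctx, DEFAULT_HELIX45, 18.0)
        oracle = brute_best_offset(DEFAULT_HELIX45, window, 18.0)
        assert hit is not None and oracle is not None
        assert (hit.offset, hit.score) == oracle


def test_find_helix45_absent_on_polya():
    # 5 A identities + 5 T complement positions = 6.25 < 18
    ctx = make_context("A" * 200)
    assert find_helix45(ctx, DEFAULT_HELIX45) is None
    scores = [score_alignment(DEFAULT_HELIX45, "A" * 24, 0)]
    assert scores[0] == 6.25


def test_find_helix45_embedded_alteromonas(rng):
    flank5 = "".join(rng.choice(list("CT"), 60))
    flank3 = "".join(rng.choice(list("CT"), 30))
    window = flank5 + ALTEROMONAS_CLASSIC + flank3
    hit = find_helix45(make_context(window), DEFAULT_HELIX45)
    assert hit is not None
    assert hit.offset == 60
    assert hit.score == 22.5


def test_find_helix45_tie_breaks_3prime(rng):
    window = "G" * 30 + DEFAULT_HELIX45 + "G" * 30 + DEFAULT_HELIX45 + "G" * 30
    hit = find_helix45(make_context(window), DEFAULT_HELIX45)
    assert hit.offset == 30 + 24 + 30  # the 3'-most perfect placement


@pytest.mark.parametrize(
    "embedded,tail",
    [
        (ALTEROMONAS_CLASSIC, "GATCACCTCCTTA"),
        (ALTEROMONAS_MINORITY, "GATCACCTTCAAT"),
    ],
)
def test_extract_tail_printed_alteromonas_rows(embedded, tail, rng):
    window = embedded + "".join(rng.choice(list("ACGT"), 10))
    ctx = make_context(window)
    hit = find_helix45(ctx, DEFAULT_HELIX45)
    tail13, extended23, ambiguous = extract_tail(ctx, hit)
    assert not ambiguous
    assert tail13 == tail
    assert extended23.startswith(tail13) and len(extended23) == 23


def test_extract_tail_too_short_is_ambiguous():
    window = ALTEROMONAS_CLASSIC[:-3]  # only 10 bases past helix 45
    ctx = make_context(window)
    hit = find_helix45(ctx, DEFAULT_HELIX45)
    *_, ambiguous = extract_tail(ctx, hit)
    assert ambiguous


@pytest.mark.parametrize(
    "tail,matches,offset",
    [
        ("GATCACCTCCTTA", 6, 5),  # consensus: perfect anti-SD 5 bases after helix
        ("GATCACCTCTTAG", 5, None),  # M. huakuii-style single substitution
        ("GATCACCTTCTTT", 5, None),  # S. parasanguinis-style substitution
        ("AAACATAACAACC", 1, None),  # C. hodgkinia-style tail, anti-SD gone
        ("GATCCCTCCTTAA", 3, 4),  # exact anti-SD at a non-canonical position
    ],
)
def test_score_antisd(tail, matches, offset):
    assert score_antisd(tail) == (matches, offset)


def _annotate_window(window, annotated3_offset):
    ctx = make_context(window, annotated3_offset=annotated3_offset)
    return annotate_context(ctx)


def test_classify_foreshortened_gene_reannotated(rng):
    """Annotated end 8 bases past helix 45 -> extension 5, the common case."""
    window = ALTEROMONAS_CLASSIC + "".join(rng.choice(list("ACGT"), 10))
    ann = _annotate_window(window, annotated3_offset=24 + 8)
    assert ann.category == "reannotated"
    assert ann.extension == 5


def test_classify_correctly_annotated_gene(rng):
    window = ALTEROMONAS_CLASSIC + "".join(rng.choice(list("ACGT"), 10))
    ann = _annotate_window(window, annotated3_offset=24 + 13)
    assert ann.category == "annotated_ok"
    assert ann.extension == 0


@pytest.mark.parametrize(
    "tail,category",
    [("GATCACCTCTTAG", "variant_close"), ("AAACATAACAACC", "variant_absent")],
)
def test_classify_variant_tails(tail, category, rng):
    window = ALTEROMONAS_CLASSIC[:24] + tail + "".join(rng.choice(list("ACGT"), 10))
    ann = _annotate_window(window, annotated3_offset=24 + 13)
    assert ann.category == category


def test_classify_no_helix(rng):
    ann = _annotate_window("".join(rng.choice(list("A"), 120)), 60)
    assert ann.category == "no_helix45"
    assert ann.extension == 0


def test_extension_tracks_foreshortening():
    """Foreshortening by f bases is recovered as extension exactly f."""
    for f in range(0, 11):
        genome = make_genome(FixtureConfig(seed=5, n_cds=4, foreshorten=f))
        record = genome.to_record(taxid="t")
        (ann,) = annotate_record(record)
        if f == 0:
            assert ann.category == "annotated_ok"
        else:
            assert ann.category == "reannotated"
            assert ann.extension == f
        # the tail read off the genome is unaffected by the annotation
        assert ann.tail13 == "GATCACCTCCTTA"


def test_corrected_end_in_contig_coordinates():
    genome = make_genome(FixtureConfig(seed=9, n_16s=2, n_cds=4, foreshorten=5))
    record = genome.to_record(taxid="t")
    anns = {a.feature_id: a for a in annotate_record(record)}
    for truth in genome.truth.genes_16s:
        a = anns[truth.feature_id]
        expected = truth.true_end if truth.strand == "+" else truth.true_start
        assert a.corrected_end == expected


def test_select_representative_max_then_position():
    g = make_genome(FixtureConfig(seed=2, n_16s=3, n_cds=4))
    anns = annotate_record(g.to_record(taxid="t"))
    rep = select_representative(anns)
    best = max(a.combined_score for a in anns)
    assert rep.combined_score == best
    assert rep.start_coord == min(a.start_coord for a in anns if a.combined_score == best)
    with pytest.raises(ValueError):
        select_representative([])


def _fake_annotation(helix24, tail, start=1):
    from antisd.reannotate import Helix45Hit, TailAnnotation

    return TailAnnotation(
        feature_id=f"f{start}", taxid="t", hit=Helix45Hit(0, 22.5, 24),
        aligned24=helix24, tail13=tail, extended23=None, antisd_matches=6,
        antisd_offset=5, category="annotated_ok", extension=0,
        combined_score=28.5, start_coord=start,
    )


def test_summarize_tail_classes_alteromonas_pattern():
    """2 classic + 2 minority + 1 singleton tails -> 3 classes, max size 2,
    majority the lexicographically smaller of the tied 37-mers."""
    helix = ALTEROMONAS_CLASSIC[:24]
    anns = (
        [_fake_annotation(helix, "GATCACCTCCTTA", i) for i in (1, 2)]
        + [_fake_annotation(helix, "GATCACCTTCAAT", i) for i in (3, 4)]
        + [_fake_annotation(helix, "GATCACCTAAAAT", 5)]
    )
    s = summarize_tail_classes(anns)
    assert (s.gene_count, s.class_count, s.max_class_size) == (5, 3, 2)
    assert s.majority_sequence == ALTEROMONAS_CLASSIC  # CCTTA < TTCAAT block
    assert sum(c for _, c in s.class_table) == 5


def test_summarize_tail_classes_mostly_unique():
    """Two shared + five unique 37-mers -> 6 classes, max size 2."""
    helix = "TAGCCGTAGGTGAACCTGTGGCTG"
    tails = ["AAACATAACAACC"] * 2 + [
        "AAACATAACAACA", "AAACATAACAACG", "AAACATAACAATT",
        "AAACATAACATCC", "AAACATAACGACC",
    ]
    anns = [_fake_annotation(helix, t, i) for i, t in enumerate(tails)]
    s = summarize_tail_classes(anns)
    assert (s.gene_count, s.class_count, s.max_class_size) == (7, 6, 2)


def test_consensus_matrix_properties(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 47)) for _ in range(30)]
    m = consensus_matrix(seqs, mode="by-helix45")
    assert m.n_sequences == 30
    np.testing.assert_allclose(m.frequencies.sum(axis=1), 1.0, atol=1e-9)
    # identical input: point-mass columns
    m1 = consensus_matrix([seqs[0]] * 5)
    assert (m1.frequencies.max(axis=1) == 1.0).all()
    # single-column difference: 0.5/0.5
    a = "A" * 47
    b = "A" * 23 + "C" + "A" * 23
    m2 = consensus_matrix([a, b])
    assert m2.frequencies[23, 0] == 0.5 and m2.frequencies[23, 1] == 0.5
    with pytest.raises(ValueError):
        consensus_matrix([], mode="by-helix45")


def test_category_partition_over_mixed_fixtures():
    """Every 16S gene lands in exactly one category; counts sum to gene count."""
    configs = [
        FixtureConfig(seed=1, foreshorten=5),
        FixtureConfig(seed=2, foreshorten=0),
        FixtureConfig(seed=3, helix24="A" * 24),  # helix ablated
        FixtureConfig(seed=4, tail13="GATCACCTCTTAG"),  # close variant
        FixtureConfig(seed=5, tail13="AAACATAACAACC"),  # anti-SD absent
    ]
    total, by_cat = 0, {}
    for cfg in configs:
        cfg.n_cds = 4
        record = make_genome(cfg).to_record(taxid=f"s{cfg.seed}")
        for ann in annotate_record(record):
            total += 1
            by_cat[ann.category] = by_cat.get(ann.category, 0) + 1
    assert sum(by_cat.values()) == total == len(configs)
    assert by_cat == {
        "reannotated": 1, "annotated_ok": 1, "no_helix45": 1,
        "variant_close": 1, "variant_absent": 1,
    }
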