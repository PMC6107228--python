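"""End-to-end runs: re-annotation reports and SD discovery reports.

These functions are the programmatic face of the command-line interface:
they read genomes, drive the re-annotator / motif discovery, and assemble
the tabular reports (per gene, per taxid, category summary shaped like a
re-annotation tally, tail tabulation, ranked-pattern table).  All sorts are
stable and seeded, so re-running with the same inputs reproduces the same
bytes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .compare import compare as compare_sd_tail
from .discovery import build_profile, collect_upstream, rank_patterns
from .genome_io import read_genome, write_corrected_gff
from .reannotate import (
    CATEGORIES,
    DEFAULT_HELIX45,
    TailAnnotation,
    annotate_record,
    consensus_matrix,
    select_representative,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the published procedure where
    it states them (helix threshold 18.0, k=7, d=1, top 20, z > 5)."""

    helix45_query: str = DEFAULT_HELIX45
    min_score: float = 18.0
    flank: int = 500
    W: int = 20
    k: int = 7
    d: int = 1
    top: int = 20
    zmin: float = 5.0
    markov_order: int = 3
    re_threshold: float = 0.5
    spacer_range: tuple[int, int] = (6, 8)
    out_dir: str | None = None
    seed: int = 0


def _annotation_row(a: TailAnnotation) -> dict:
    return {
        "taxid": a.taxid,
        "feature_id": a.feature_id,
        "helix45_score": a.hit.score if a.hit else "",
        "helix45_offset": a.hit.offset if a.hit else "",
        "tail13": a.tail13 or "",
        "extended23": a.extended23 or "",
        "antisd_matches": "" if a.antisd_matches is None else a.antisd_matches,
        "antisd_offset": "" if a.antisd_offset is None else a.antisd_offset,
        "noncanonical_antisd": (
            "yes"
            if a.antisd_offset is not None and a.antisd_offset != 5
            else ""
        ),
        "category": a.category,
        "extension": a.extension,
        "combined_score": a.combined_score,
    }


def run_reannotate(config: RunConfig, genomes) -> dict:
    """Re-annotate one or more genomes and build the summary tables.

    ``genomes`` is a list of ``(fasta_path, gff_path)`` or
    ``(fasta_path, gff_path, taxid)`` tuples.  Unreadable genomes are
    skipped with a logged error; an empty input list is an error.  Returns
    a dict with DataFrames ``per_gene``, ``per_taxid``, ``category_summary``,
    ``tail_counts`` and the list of annotations; writes TSVs and corrected
    GFF3s under ``config.out_dir`` when set.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("no genomes given")

    all_rows, rep_rows = [], []
    per_taxid_reps: list[TailAnnotation] = []
    all_annotations = []
    for entry in genomes:
        fasta, gff = entry[0], entry[1]
        taxid = entry[2] if len(entry) > 2 else None
        try:
            record = read_genome(fasta, gff, taxid=taxid)
        except Exception as exc:  # noqa: BLE001 - skip-and-continue contract
            log.error("skipping genome %s: %s", fasta, exc)
            continue
        annotations = annotate_record(
            record, query=config.helix45_query,
            min_score=config.min_score, flank=config.flank,
        )
        all_annotations.append((record, annotations))
        all_rows.extend(_annotation_row(a) for a in annotations)
        if annotations:
            rep = select_representative(annotations)
            per_taxid_reps.append(rep)
            rep_rows.append(_annotation_row(rep))
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stem = Path(str(gff)).stem
            write_corrected_gff(annotations, record, out / f"{stem}.corrected.gff3")
        log.info(
            "%s: %d 16S gene(s), categories %s",
            fasta,
            len(annotations),
            {c: sum(a.category == c for a in annotations) for c in CATEGORIES
             if any(a.category == c for a in annotations)},
        )

    per_gene = pd.DataFrame(all_rows).sort_values(
        ["taxid", "feature_id"], kind="stable", ignore_index=True
    ) if all_rows else pd.DataFrame()
    per_taxid = pd.DataFrame(rep_rows).sort_values(
        "taxid", kind="stable", ignore_index=True
    ) if rep_rows else pd.DataFrame()

    cat_counts = {c: 0 for c in CATEGORIES}
    for a in per_taxid_reps:
        cat_counts[a.category] += 1
    category_summary = pd.DataFrame(
        {"category": list(cat_counts), "taxids": list(cat_counts.values())}
    )

    tails = [a.tail13 for a in per_taxid_reps if a.tail13]
    tail_counts = (
        pd.Series(tails, name="tail13").value_counts().rename_axis("tail13")
        .reset_index(name="count")
        .sort_values(["count", "tail13"], ascending=[False, True],
                     kind="stable", ignore_index=True)
        if tails
        else pd.DataFrame(columns=["tail13", "count"])
    )

    # helix-anchored 47-mers (24 aligned helix bases + 23-base extended
    # region) across all genes, for the by-helix45 consensus alignment
    mers47 = [
        a.aligned24 + a.extended23
        for _, anns in all_annotations
        for a in anns
        if a.aligned24 and a.extended23
    ]
    matrix = consensus_matrix(mers47, mode="by-helix45") if mers47 else None

    result = {
        "per_gene": per_gene,
        "per_taxid": per_taxid,
        "category_summary": category_summary,
        "tail_counts": tail_counts,
        "consensus_matrix": matrix,
        "annotations": all_annotations,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("per_gene", "per_taxid", "category_summary", "tail_counts"):
            result[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
        if matrix is not None:
            pd.DataFrame(matrix.frequencies, columns=list("ACGT")).to_csv(
                out / "consensus_by_helix45.tsv", sep="\t", index=False
            )
    return result


def run_discover(config: RunConfig, fasta, gff, taxid: str | None = None) -> dict:
    """SD motif discovery for one genome, plus comparison against its tail.

    A genome with no usable CDS upstream windows is an error.  If the genome
    has no 16S gene the SD columns are still produced and the comparison
    fields are left empty.
    """
    record = read_genome(fasta, gff, taxid=taxid)
    upstream = collect_upstream(record, W=config.W, k=config.k, order=config.markov_order)
    scores, significant = rank_patterns(
        upstream, k=config.k, d=config.d, top=config.top, zmin=config.zmin
    )
    top_scores = scores[: config.top]
    profile = build_profile(
        top_scores, upstream.background,
        re_threshold=config.re_threshold, significant=significant,
    )

    patterns = pd.DataFrame(
        {
            "pattern": [s.pattern for s in top_scores],
            "X": [s.X for s in top_scores],
            "expected": [s.expected for s in top_scores],
            "z": [s.z for s in top_scores],
        }
    )

    annotations = annotate_record(
        record, query=config.helix45_query,
        min_score=config.min_score, flank=config.flank,
    )
    comparison = None
    tail13 = ""
    if annotations:
        rep = select_representative(annotations)
        if rep.tail13:
            tail13 = rep.tail13
            comparison = compare_sd_tail(profile.consensus, tail13)

    report = pd.DataFrame(
        [
            {
                "taxid": taxid or Path(str(gff)).stem,
                "sd_consensus": profile.consensus,
                "top_z": top_scores[0].z if top_scores else "",
                "significant": significant,
                "tail13": tail13,
                "presence": comparison.presence if comparison else "",
                "sd_type": comparison.sd_type if comparison else "",
                "best_offset": comparison.best_offset if comparison else "",
                "best_pairings": comparison.best_pairings if comparison else "",
                "low_complexity": comparison.low_complexity if comparison else "",
            }
        ]
    )

    result = {
        "report": report,
        "patterns": patterns,
        "profile": profile,
        "upstream": upstream,
        "comparison": comparison,
        "significant": significant,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "sd_report.tsv", sep="\t", index=False)
        patterns.to_csv(out / "sd_patterns.tsv", sep="\t", index=False)
        prof = pd.DataFrame(profile.pfm, columns=list("ACGT"))
        prof.insert(0, "offset", profile.column_offsets)
        prof["relative_entropy"] = profile.relative_entropy
        prof.to_csv(out / "sd_profile.tsv", sep="\t", index=False)
    return result
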