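"""FASTA + GFF3 genome reading, oriented window extraction, corrected-GFF writing.

Coordinates are GFF3-style (1-based, inclusive) on :class:`Feature`; every
sequence handed downstream lives in an oriented window with 0-based,
half-open indexing.  The conversion between the two conventions is confined
to this module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

KIND_16S = "rRNA-16S"
KIND_CDS = "CDS"
KIND_OTHER = "other"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One GFF3 feature. ``start``/``end`` are 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # KIND_16S / KIND_CDS / KIND_OTHER
    feature_id: str
    taxid: str = ""
    source: str = "."
    ftype: str = ""
    score: str = "."
    phase: str = "."
    attributes: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """Contig sequences plus their annotated features."""

    contigs: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def rrna_16s(self) -> list[Feature]:
        return [f for f in self.features if f.kind == KIND_16S]

    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == KIND_CDS]


@dataclass
class RnaGeneContext:
    """A 16S rRNA feature with its oriented sequence window.

    ``window`` runs 5'->3' on the coding strand: the annotated span extended
    by up to ``flank`` bases on each side, reverse-complemented for minus
    strand features, truncated silently at contig boundaries.
    ``annotated3_offset`` is the 0-based position *within the window* of the
    base just past the annotated 3' end.
    """

    feature: Feature
    window: str
    window_origin: int  # 1-based contig coordinate of window[0] (post-orientation)
    annotated3_offset: int
    truncated_5: int = 0  # bases of flank lost to the contig edge
    truncated_3: int = 0


def _is_16s(ftype: str, attributes: str) -> bool:
    return ftype.lower() == "rrna" and "16s" in attributes.lower()


def _classify_type(ftype: str, attributes: str) -> str:
    if _is_16s(ftype, attributes):
        return KIND_16S
    if ftype == "CDS":
        return KIND_CDS
    return KIND_OTHER


def _attr_value(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_genome(fasta_path, gff_path, taxid: str | None = None) -> GenomeRecord:
    """Parse a FASTA + GFF3 pair into a :class:`GenomeRecord`.

    16S rRNA genes are recognized as features of GFF type ``rRNA`` whose
    attribute column mentions "16S" (case-insensitive).  Features referencing
    unknown contigs, spanning past contig ends, or on malformed lines are
    skipped with a warning.  Multi-part rRNA features (one ID on several
    lines) are skipped: prokaryotic 16S genes are contiguous.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)
    if taxid is None:
        taxid = gff_path.stem

    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    raw: list[Feature] = []
    anon = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                log.warning("%s:%d: malformed GFF3 line skipped", gff_path.name, lineno)
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                log.warning("%s:%d: non-numeric coordinates, skipped", gff_path.name, lineno)
                continue
            if seqid not in contigs:
                log.warning(
                    "%s:%d: feature on unknown contig %r dropped", gff_path.name, lineno, seqid
                )
                continue
            if start_i < 1 or end_i > len(contigs[seqid]) or start_i > end_i:
                log.warning("%s:%d: feature span out of bounds, skipped", gff_path.name, lineno)
                continue
            if strand not in "+-":
                log.warning("%s:%d: strandless feature skipped", gff_path.name, lineno)
                continue
            fid = _attr_value(attrs, "ID")
            if fid is None:
                anon += 1
                fid = f"feature{anon:05d}"
            raw.append(
                Feature(
                    contig_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    kind=_classify_type(ftype, attrs),
                    feature_id=fid,
                    taxid=taxid,
                    source=source,
                    ftype=ftype,
                    score=score,
                    phase=phase,
                    attributes=attrs,
                )
            )

    # drop multi-part rRNA features (same ID on more than one line)
    rrna_ids = [f.feature_id for f in raw if f.kind == KIND_16S]
    multipart = {i for i in rrna_ids if rrna_ids.count(i) > 1}
    if multipart:
        log.warning("skipping multi-part rRNA features: %s", sorted(multipart))
    features = [f for f in raw if not (f.kind == KIND_16S and f.feature_id in multipart)]

    return GenomeRecord(contigs=contigs, features=features)


def extract_context(record: GenomeRecord, feature: Feature, flank: int = 500) -> RnaGeneContext:
    """Oriented window: annotated span +/- ``flank`` bases, truncated at contig ends."""
    contig = record.contigs[feature.contig_id]
    w0 = max(feature.start - 1 - flank, 0)  # 0-based half-open slice
    w1 = min(feature.end + flank, len(contig))
    trunc5_plus = flank - (feature.start - 1 - w0)
    trunc3_plus = flank - (w1 - feature.end)
    segment = contig[w0:w1]
    if feature.strand == "+":
        window = segment
        origin = w0 + 1
        a3 = feature.end - w0  # base just past the annotated 3' end
        t5, t3 = trunc5_plus, trunc3_plus
    else:
        window = reverse_complement(segment)
        origin = w1
        a3 = w1 - feature.start + 1
        t5, t3 = trunc3_plus, trunc5_plus
    return RnaGeneContext(
        feature=feature,
        window=window,
        window_origin=origin,
        annotated3_offset=a3,
        truncated_5=t5,
        truncated_3=t3,
    )


def upstream_sequence(record: GenomeRecord, feature: Feature, length: int) -> str:
    """The ``length`` bases immediately 5' of a feature, coding-strand oriented.

    Truncated at the contig boundary (may return fewer than ``length`` bases).
    """
    contig = record.contigs[feature.contig_id]
    if feature.strand == "+":
        lo = max(feature.start - 1 - length, 0)
        return contig[lo : feature.start - 1]
    hi = min(feature.end + length, len(contig))
    return reverse_complement(contig[feature.end : hi])


def write_corrected_gff(annotations, record: GenomeRecord, out_path) -> None:
    """Emit GFF3 with re-annotated 16S 3' coordinates replaced.

    ``annotations`` is an iterable of TailAnnotation (see ``reannotate``).
    Features without a matching annotation are copied verbatim; re-annotated
    16S features get their 3' coordinate (end on '+', start on '-') moved by
    the recorded extension, and every annotated 16S row carries a
    ``reannotation`` note with the original span, category and extension.
    """
    by_id = {a.feature_id: a for a in annotations}
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in record.features:
            start, end, attrs = f.start, f.end, f.attributes
            ann = by_id.get(f.feature_id)
            if ann is not None and f.kind == KIND_16S:
                if ann.category == "reannotated" and ann.extension > 0:
                    if f.strand == "+":
                        end = f.end + ann.extension
                    else:
                        start = f.start - ann.extension
                note = (
                    f"reannotation={ann.category}|original:{f.start}-{f.end}"
                    f"|extension:{ann.extension}"
                )
                attrs = f"{attrs};{note}" if attrs else note
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        f.source or ".",
                        f.ftype or (f.kind if f.kind != KIND_OTHER else "region"),
                        str(start),
                        str(end),
                        f.score or ".",
                        f.strand,
                        f.phase or ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def write_fasta(contigs: dict[str, str], out_path, width: int = 70) -> None:
    """Write contigs as wrapped FASTA."""
    with open(out_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
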