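"""Deterministic synthetic genomes and upstream-window sets with known truth.

The generator emulates the two situations the analysis targets: (a) contigs
carrying 16S rRNA genes whose 3' region is a planted helix-45 24-mer plus a
13-base tail, with the GFF3 annotation foreshortened by a configurable
number of bases; and (b) protein-coding genes a configurable fraction of
which carry a planted Shine-Dalgarno motif 5-9 bases upstream of the start
codon, over an order-m Markov background.  Everything is reproducible from
a single integer seed, and the planted count is round(rate * n), not
Bernoulli, so truth counts are exact.
"""
from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discovery import MarkovModel
from .genome_io import GenomeRecord, read_genome, reverse_complement
from .reannotate import ANTISD, DEFAULT_HELIX45, score_alignment

DEFAULT_TAIL13 = "GATCACCTCCTTA"  # E. coli consensus tail


@dataclass
class FixtureConfig:
    seed: int = 0
    contig_length: int | None = None  # None -> minimal feasible length
    n_cds: int = 100
    sd_motif: str = "AGGAGGT"
    plant_rate: float = 0.5
    spacer_range: tuple[int, int] = (5, 9)
    W: int = 20
    n_16s: int = 1
    helix24: str = DEFAULT_HELIX45
    tail13: str = DEFAULT_TAIL13
    foreshorten: int = 5
    background: MarkovModel = field(default_factory=MarkovModel.uniform)
    gap: int = 50  # minimum background bases between features
    cds_body: int = 60  # coding bases after the ATG
    rrna_lead: int = 150  # 16S body length before the helix 24-mer


@dataclass
class Rna16sTruth:
    feature_id: str
    strand: str
    annotated_start: int  # 1-based inclusive, as emitted in the GFF
    annotated_end: int
    true_start: int  # full gene including the 13-base tail
    true_end: int
    foreshorten: int
    expected_extension: int
    expected_category: str


@dataclass
class CdsTruth:
    feature_id: str
    strand: str
    planted: bool
    spacer: int | None  # bases between motif end and the start codon


@dataclass
class FixtureTruth:
    genes_16s: list[Rna16sTruth]
    cds: list[CdsTruth]

    @property
    def planted_ids(self) -> list[str]:
        return [c.feature_id for c in self.cds if c.planted]


@dataclass
class SyntheticGenome:
    fasta_text: str
    gff_text: str
    truth: FixtureTruth
    config: FixtureConfig
    contig_id: str = "contig1"

    def write(self, out_dir, stem: str = "synthetic"):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / f"{stem}.fna"
        gff = out_dir / f"{stem}.gff3"
        truth = out_dir / f"{stem}.truth.tsv"
        fasta.write_text(self.fasta_text)
        gff.write_text(self.gff_text)
        rows = ["kind\tfeature_id\tstrand\tplanted\tspacer\texpected_extension\texpected_category"]
        for g in self.truth.genes_16s:
            rows.append(
                f"16S\t{g.feature_id}\t{g.strand}\t\t\t{g.expected_extension}\t{g.expected_category}"
            )
        for c in self.truth.cds:
            rows.append(
                f"CDS\t{c.feature_id}\t{c.strand}\t{int(c.planted)}\t"
                f"{'' if c.spacer is None else c.spacer}\t\t"
            )
        truth.write_text("\n".join(rows) + "\n")
        return fasta, gff, truth

    def to_record(self, taxid: str | None = None) -> GenomeRecord:
        """Round-trip through the FASTA/GFF3 parser."""
        with tempfile.TemporaryDirectory() as tmp:
            fasta, gff, _ = self.write(tmp)
            return read_genome(fasta, gff, taxid=taxid)


def _expected_category(config: FixtureConfig, min_score: float = 18.0) -> str:
    """Category the re-annotator should assign, by construction."""
    if score_alignment(DEFAULT_HELIX45, config.helix24, 0) < min_score:
        return "no_helix45"
    tail = config.tail13
    if ANTISD in tail:
        return "reannotated" if config.foreshorten >= 1 else "annotated_ok"
    matches = sum(a == b for a, b in zip(tail[5:11], ANTISD))
    return "variant_close" if matches == 5 else "variant_absent"


def _sample_bg(model: MarkovModel, rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return model.sample_strings(rng, 1, n)[0]


def make_genome(config: FixtureConfig) -> SyntheticGenome:
    """Build a deterministic FASTA+GFF3 synthetic genome with ground truth.

    Features are laid left to right, alternating strands, separated by at
    least ``config.gap`` background bases.  16S genes end with helix24 +
    tail13 (coding orientation); their GFF3 3' coordinate is shifted 5'-ward
    by ``foreshorten``.  round(plant_rate * n_cds) CDSs carry ``sd_motif``
    ending ``spacer`` bases before the ATG, spacer drawn uniformly from
    ``spacer_range``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo_s, hi_s = cfg.spacer_range
    if cfg.W < hi_s + len(cfg.sd_motif):
        raise ValueError("W too short for the spacer range plus the motif")
    if len(cfg.helix24) != 24 or len(cfg.tail13) != 13:
        raise ValueError("helix24 must be 24 bases and tail13 13 bases")
    if cfg.foreshorten < 0 or cfg.foreshorten >= cfg.rrna_lead + 24 + 13:
        raise ValueError("foreshorten out of range")

    n_plant = int(round(cfg.plant_rate * cfg.n_cds))
    planted = set(rng.choice(cfg.n_cds, size=n_plant, replace=False).tolist())

    parts: list[str] = [_sample_bg(cfg.background, rng, cfg.gap)]
    pos = cfg.gap  # 0-based length so far
    gff_rows: list[str] = []
    truth_16s: list[Rna16sTruth] = []
    truth_cds: list[CdsTruth] = []
    exp_cat = _expected_category(cfg)
    exp_ext = cfg.foreshorten if exp_cat == "reannotated" else 0

    for i in range(cfg.n_16s):
        strand = "+" if i % 2 == 0 else "-"
        fid = f"rrna{i + 1:04d}"
        coding = _sample_bg(cfg.background, rng, cfg.rrna_lead) + cfg.helix24 + cfg.tail13
        glen = len(coding)
        inserted = coding if strand == "+" else reverse_complement(coding)
        start1 = pos + 1  # 1-based
        end1 = pos + glen
        if strand == "+":
            a_start, a_end = start1, end1 - cfg.foreshorten
        else:
            a_start, a_end = start1 + cfg.foreshorten, end1
        parts.append(inserted)
        pos += glen
        parts.append(_sample_bg(cfg.background, rng, cfg.gap))
        pos += cfg.gap
        gff_rows.append(
            "\t".join(
                ["contig1", "synth", "rRNA", str(a_start), str(a_end), ".", strand, ".",
                 f"ID={fid};product=16S ribosomal RNA"]
            )
        )
        truth_16s.append(
            Rna16sTruth(
                feature_id=fid, strand=strand,
                annotated_start=a_start, annotated_end=a_end,
                true_start=start1, true_end=end1,
                foreshorten=cfg.foreshorten,
                expected_extension=exp_ext,
                expected_category=exp_cat,
            )
        )

    for j in range(cfg.n_cds):
        strand = "+" if j % 2 == 0 else "-"
        fid = f"cds{j + 1:04d}"
        upstream = list(_sample_bg(cfg.background, rng, cfg.W))
        spacer = None
        if j in planted:
            spacer = int(rng.integers(lo_s, hi_s + 1))
            at = cfg.W - spacer - len(cfg.sd_motif)
            upstream[at : at + len(cfg.sd_motif)] = list(cfg.sd_motif)
        upstream = "".join(upstream)
        coding = upstream + "ATG" + _sample_bg(cfg.background, rng, cfg.cds_body)
        inserted = coding if strand == "+" else reverse_complement(coding)
        block_start1 = pos + 1
        if strand == "+":
            c_start = block_start1 + cfg.W  # the ATG
            c_end = pos + len(coding)
        else:
            c_start = block_start1
            c_end = pos + len(coding) - cfg.W
        parts.append(inserted)
        pos += len(coding)
        parts.append(_sample_bg(cfg.background, rng, cfg.gap))
        pos += cfg.gap
        gff_rows.append(
            "\t".join(
                ["contig1", "synth", "CDS", str(c_start), str(c_end), ".", strand, "0",
                 f"ID={fid};product=hypothetical protein"]
            )
        )
        truth_cds.append(CdsTruth(feature_id=fid, strand=strand,
                                  planted=j in planted, spacer=spacer))

    contig = "".join(parts)
    if cfg.contig_length is not None:
        if cfg.contig_length < len(contig):
            raise ValueError(
                f"contig_length {cfg.contig_length} too small for the requested "
                f"features (need {len(contig)})"
            )
        contig += _sample_bg(cfg.background, rng, cfg.contig_length - len(contig))

    lines = [">contig1"]
    for i in range(0, len(contig), 70):
        lines.append(contig[i : i + 70])
    fasta_text = "\n".join(lines) + "\n"
    gff_text = "##gff-version 3\n" + "\n".join(gff_rows) + "\n"
    return SyntheticGenome(
        fasta_text=fasta_text, gff_text=gff_text,
        truth=FixtureTruth(genes_16s=truth_16s, cds=truth_cds), config=cfg,
    )


def make_upstream_set(
    seed: int,
    N: int,
    W: int = 20,
    model: MarkovModel | None = None,
    planted_motif: str = "AGGAGGT",
    plant_rate: float = 0.5,
    spacer_range: tuple[int, int] = (5, 9),
):
    """Sample N background windows and plant a motif in round(rate*N) of them.

    The motif ends ``spacer`` bases before the window's 3' edge (the start
    codon position), spacer uniform over ``spacer_range``.  Returns
    ``(UpstreamSet, truth)`` where truth maps window index -> spacer for
    planted windows.  The UpstreamSet carries the *generating* model as its
    background: the null hypothesis is then exactly true for unplanted
    windows, which is what makes the set useful as a calibration fixture.
    """
    from .discovery import UpstreamSet  # local import to avoid cycle at module load

    if model is None:
        model = MarkovModel.uniform()
    lo_s, hi_s = spacer_range
    if W < hi_s + len(planted_motif):
        raise ValueError("W too short for the spacer range plus the motif")
    rng = np.random.default_rng(seed)
    windows = model.sample_strings(rng, N, W)
    n_plant = int(round(plant_rate * N))
    chosen = sorted(rng.choice(N, size=n_plant, replace=False).tolist())
    truth: dict[int, int] = {}
    for idx in chosen:
        spacer = int(rng.integers(lo_s, hi_s + 1))
        at = W - spacer - len(planted_motif)
        w = list(windows[idx])
        w[at : at + len(planted_motif)] = list(planted_motif)
        windows[idx] = "".join(w)
        truth[idx] = spacer
    upstream = UpstreamSet(windows=windows, W=W, background=model)
    return upstream, truth
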