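"""Reference-genome and transcript-model layer.

Loads a FASTA genome and an Ensembl-dialect GFF3 annotation, builds per-mRNA
transcript models (exon/intron/UTR boundaries, per-position reading frame in
transcript orientation) and answers positional queries: region class (5'UTR,
CDS, 3'UTR, intron, intergenic) and distance to the nearest splice junction.

Coordinates are 0-based half-open internally; every public entry point that
parses or reports genomic coordinates uses 1-based inclusive positions
(Ensembl convention). Insertion points are represented internally as "gap"
coordinates: integer g denotes the boundary between bases g-1 and g.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import gffutils
from Bio import SeqIO

from .sequences import revcomp, translate

log = logging.getLogger(__name__)


class GenomeError(ValueError):
    pass


class GenomeIndex:
    """In-memory genome: chromosome name -> uppercase nucleotide string."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end) 0-based; minus strand reverse-complemented."""
        if chrom not in self.sequences:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise GenomeError(
                f"window [{start},{end}) outside {chrom} (length {self.lengths[chrom]})"
            )
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq


def load_genome(fasta_path) -> GenomeIndex:
    """Read a (multi-)FASTA file into a GenomeIndex."""
    records = {}
    with open(fasta_path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise GenomeError(f"{fasta_path}: not FASTA (line 1 does not start with '>')")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records[rec.id] = str(rec.seq)
    if not records:
        raise GenomeError(f"{fasta_path}: no FASTA records")
    return GenomeIndex(records)


class RegionClass(Enum):
    UTR5 = "5UTR"
    UTR3 = "3UTR"
    CDS = "CDS"
    INTRON = "intron"
    INTERGENIC = "intergenic"


@dataclass
class PositionClass:
    region: RegionClass
    junction_distance: int | None  # bp to nearest exon/intron boundary; None if no junctions


@dataclass
class TranscriptModel:
    """One mRNA: intervals are 0-based half-open, listed in transcript order
    (ascending genomic for '+' strand, descending for '-')."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    frame_map: dict[int, int] = field(default_factory=dict)
    cds_incomplete: bool = False

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases, 5'->3' in transcript orientation."""
        pos = []
        for s, e in self.cds:
            block = range(s, e)
            pos.extend(reversed(block) if self.strand == "-" else block)
        return pos

    def spliced_cds(self, genome: GenomeIndex) -> str:
        parts = [genome.fetch(self.chrom, s, e, self.strand) for s, e in self.cds]
        return "".join(parts)

    def protein(self, genome: GenomeIndex) -> str:
        return translate(self.spliced_cds(genome))

    def junctions(self) -> list[int]:
        """Internal exon/intron boundaries as gap coordinates, genomic order."""
        ivals = sorted(self.exons)
        gaps = []
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            gaps.extend([e1, s2])
        return gaps

    def insertion_gap(self, terminus: str) -> int:
        """Gap coordinate for an in-frame payload at the N or C terminus:
        immediately after the start codon (N) or before the stop codon (C)."""
        pos = self.cds_positions()
        if len(pos) < 6:
            raise GenomeError(f"{self.transcript_id}: CDS too short for terminal insertion")
        if terminus == "N":
            p = pos[2]
            return p + 1 if self.strand == "+" else p
        if terminus == "C":
            p = pos[-3]
            return p if self.strand == "+" else p + 1
        raise GenomeError(f"terminus must be 'N' or 'C', got {terminus!r}")


def _frame_map(cds_positions: list[int]) -> dict[int, int]:
    return {p: i % 3 for i, p in enumerate(cds_positions)}


def _interval_list(feats, strand) -> list[tuple[int, int]]:
    ivals = sorted((f.start - 1, f.end) for f in feats)  # GFF3 1-based inclusive
    return ivals[::-1] if strand == "-" else ivals


def _subtract(exons, cds):
    """Exonic intervals minus CDS intervals (all 0-based half-open)."""
    out = []
    for s, e in sorted(exons):
        cur = [(s, e)]
        for cs, ce in sorted(cds):
            nxt = []
            for a, b in cur:
                if ce <= a or cs >= b:
                    nxt.append((a, b))
                else:
                    if a < cs:
                        nxt.append((a, cs))
                    if ce < b:
                        nxt.append((ce, b))
            cur = nxt
        out.extend(cur)
    return [iv for iv in out if iv[0] < iv[1]]


def build_transcript_models(gff3_path, genome: GenomeIndex) -> dict[str, TranscriptModel]:
    """Parse an Ensembl-dialect GFF3 into transcript models.

    Missing five_prime_UTR/three_prime_UTR features are tolerated: UTRs are
    derived as exon minus CDS, split at the CDS span. CDS features without a
    parent mRNA are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: dict[str, TranscriptModel] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        tid = mrna.attributes.get("ID", [mrna.id])[0].split(":")[-1]
        gene = mrna.attributes.get("Parent", ["?"])[0].split(":")[-1]
        strand = mrna.strand
        chrom = mrna.seqid
        if chrom not in genome.sequences:
            raise GenomeError(f"{tid}: chromosome {chrom} not in genome")
        exons = _interval_list(db.children(mrna, featuretype="exon"), strand)
        cds = _interval_list(db.children(mrna, featuretype="CDS"), strand)
        utr5 = _interval_list(db.children(mrna, featuretype="five_prime_UTR"), strand)
        utr3 = _interval_list(db.children(mrna, featuretype="three_prime_UTR"), strand)
        if not exons:
            warnings.warn(f"{tid}: no exons, skipped")
            continue
        lo, hi = min(s for s, _ in exons), max(e for _, e in exons)
        if lo < 0 or hi > genome.lengths[chrom]:
            raise GenomeError(f"{tid}: coordinates outside {chrom}")
        if cds and not (utr5 or utr3):
            # derive UTRs: exonic sequence 5' / 3' of the CDS span
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            non_cds = _subtract(exons, cds)
            left = [(s, min(e, cds_lo)) for s, e in non_cds if s < cds_lo]
            right = [(max(s, cds_hi), e) for s, e in non_cds if e > cds_hi]
            if strand == "+":
                utr5, utr3 = sorted(left), sorted(right)
            else:
                utr5, utr3 = sorted(right, reverse=True), sorted(left, reverse=True)
        model = TranscriptModel(
            transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
            exons=exons, cds=cds, utr5=utr5, utr3=utr3,
        )
        model.frame_map = _frame_map(model.cds_positions())
        n_cds = sum(e - s for s, e in cds)
        if n_cds % 3 != 0:
            model.cds_incomplete = True
            log.warning("%s: CDS length %d not a multiple of 3 (flagged incomplete)", tid, n_cds)
        models[tid] = model
    # orphan CDS check
    for f in db.features_of_type("CDS"):
        parents = f.attributes.get("Parent", [])
        if not any(p.split(":")[-1] in models for p in parents):
            warnings.warn(f"CDS at {f.seqid}:{f.start} has no parent mRNA; skipped")
    return models


def resolve_transcript(models: dict[str, TranscriptModel], tid: str) -> TranscriptModel:
    """Look up a transcript by versioned or unversioned ID."""
    if tid in models:
        return models[tid]
    base = tid.split(".")[0]
    hits = [m for k, m in models.items() if k.split(".")[0] == base]
    if not hits:
        raise GenomeError(f"unknown transcript {tid!r}")
    if len(hits) > 1:
        raise GenomeError(f"ambiguous transcript {tid!r}: {[m.transcript_id for m in hits]}")
    return hits[0]


def classify_position(pos: int, model: TranscriptModel) -> PositionClass:
    """Classify a 0-based genomic position against one transcript model."""
    junctions = model.junctions()
    jdist = None
    if junctions:
        jdist = min(pos - g + 1 if pos >= g else g - pos for g in junctions)
    for ivals, cls in (
        (model.cds, RegionClass.CDS),
        (model.utr5, RegionClass.UTR5),
        (model.utr3, RegionClass.UTR3),
    ):
        if any(s <= pos < e for s, e in ivals):
            return PositionClass(cls, jdist)
    lo, hi = model.span
    if lo <= pos < hi:
        if any(s <= pos < e for s, e in model.exons):
            # exonic but not CDS/UTR (e.g. non-coding transcript)
            return PositionClass(RegionClass.UTR3, jdist)
        return PositionClass(RegionClass.INTRON, jdist)
    return PositionClass(RegionClass.INTERGENIC, jdist)
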