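"""Deterministic synthetic mini-genomes (FASTA + GFF3 + manifest).

Stands in for a real genome + Ensembl annotation at desk scale: seeded
random background at a configurable GC fraction, genes with valid structure
(ATG...stop CDS, GT..AG introns, optional UTR features), and planted
sequence features whose exact coordinates are recorded in a manifest that
serves as ground truth for every detector in the package: protospacer
copies with chosen mismatches and PAM, homopolymer runs, GC-extreme blocks,
locus duplications and primer annealing decoys.

The same seed and spec always produce byte-identical FASTA and GFF3.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .genome import GenomeIndex, TranscriptModel, build_transcript_models
from .sequences import revcomp

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneSpec:
    name: str
    chrom: str
    start: int                 # 0-based genomic start of the transcript
    strand: str = "+"
    n_exons: int = 2
    utr5_len: int = 60
    utr3_len: int = 60
    cds_len: int = 300         # multiple of 3, including start and stop codons
    intron_len: int = 90


@dataclass
class PlantSpec:
    kind: str                  # protospacer_copy | homopolymer | gc_block | duplication | primer_site
    chrom: str
    pos: int = 0               # 0-based
    seq: str = ""              # protospacer_copy / primer_site
    mismatches: int = 0
    pam: str = ""
    pam_side: str = "3prime"
    strand: str = "+"
    base: str = "A"            # homopolymer
    length: int = 10
    gc: float = 0.9            # gc_block
    source: tuple[str, int, int] | None = None  # duplication (chrom, start, end)


@dataclass
class FixtureSpec:
    seed: int = 7
    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 20000)])
    genes: list[GeneSpec] = field(default_factory=list)
    planted: list[PlantSpec] = field(default_factory=list)
    gc: float = 0.5
    include_utr_features: bool = True


@dataclass
class Fixture:
    genome: GenomeIndex
    gff3_text: str
    manifest: list[dict]
    models: dict[str, TranscriptModel]

    def write(self, out_dir) -> tuple[Path, Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta, gff3, manifest = out / "genome.fa", out / "annotation.gff3", out / "manifest.csv"
        with open(fasta, "w") as fh:
            for name, seq in self.genome.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        gff3.write_text(self.gff3_text)
        with open(manifest, "w", newline="") as fh:
            cols = ["kind", "name", "chrom", "start", "end", "strand", "detail"]
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for row in self.manifest:
                w.writerow({c: row.get(c, "") for c in cols})
        return fasta, gff3, manifest


def _random_seq(rng, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    bases = "ACGT"
    for _ in range(n_codons - 2):
        while True:
            c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
            if c not in STOPS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _gene_layout(rng, g: GeneSpec):
    """Build the sense-strand gene sequence and local feature intervals.

    Returns (seq, exons, cds, utr5, utr3) with 0-based half-open local
    coordinates in sense (transcript) orientation."""
    if g.cds_len % 3 != 0 or g.cds_len < 6:
        raise ValueError(f"{g.name}: cds_len must be a multiple of 3 and >= 6")
    cds_seq = _random_cds(rng, g.cds_len // 3)
    # split the CDS across exons (codons may span junctions)
    base, extra = divmod(g.cds_len, g.n_exons)
    chunks = [base + (1 if i < extra else 0) for i in range(g.n_exons)]
    seq_parts, exons, cds, pos = [], [], [], 0
    consumed = 0
    for i, chunk in enumerate(chunks):
        ex_start = pos
        if i == 0:
            seq_parts.append(_random_seq(rng, g.utr5_len, 0.5))
            pos += g.utr5_len
        cds_start = pos
        seq_parts.append(cds_seq[consumed : consumed + chunk])
        consumed += chunk
        pos += chunk
        cds.append((cds_start, pos))
        if i == g.n_exons - 1:
            seq_parts.append(_random_seq(rng, g.utr3_len, 0.5))
            pos += g.utr3_len
        exons.append((ex_start, pos))
        if i < g.n_exons - 1:
            intron = "GT" + _random_seq(rng, g.intron_len - 4, 0.4) + "AG"
            seq_parts.append(intron)
            pos += g.intron_len
    utr5 = [(exons[0][0], cds[0][0])] if g.utr5_len else []
    utr3 = [(cds[-1][1], exons[-1][1])] if g.utr3_len else []
    return "".join(seq_parts), exons, cds, utr5, utr3


def _to_genomic(ivals, gene_start, gene_len, strand):
    if strand == "+":
        return [(gene_start + a, gene_start + b) for a, b in ivals]
    end = gene_start + gene_len
    return [(end - b, end - a) for a, b in ivals]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the genome, annotation and ground-truth manifest for a spec.

    Planting order is fixed (background, genes, then planted features in
    listed order, duplications acting on the current state); overlapping
    placements raise listing the conflict.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [c for c, _ in spec.chromosomes]
    seqs = {c: list(_random_seq(rng, n, spec.gc)) for c, n in spec.chromosomes}
    occupied: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    manifest: list[dict] = []
    gff_lines = ["##gff-version 3"]

    def claim(chrom, start, end, label):
        if chrom not in seqs:
            raise ValueError(f"{label}: unknown chromosome {chrom}")
        if start < 0 or end > len(seqs[chrom]):
            raise ValueError(f"{label}: [{start},{end}) outside {chrom}")
        for s, e, other in occupied[chrom]:
            if start < e and s < end:
                raise ValueError(f"infeasible packing: {label} overlaps {other} on {chrom}")
        occupied[chrom].append((start, end, label))

    def paste(chrom, start, s):
        seqs[chrom][start : start + len(s)] = list(s)

    for g in spec.genes:
        sense, exons, cds, utr5, utr3 = _gene_layout(rng, g)
        L = len(sense)
        claim(g.chrom, g.start, g.start + L, f"gene {g.name}")
        paste(g.chrom, g.start, sense if g.strand == "+" else revcomp(sense))
        tx = f"{g.name}.1"
        gex = sorted(_to_genomic(exons, g.start, L, g.strand))
        gcds = sorted(_to_genomic(cds, g.start, L, g.strand))
        g5 = sorted(_to_genomic(utr5, g.start, L, g.strand))
        g3 = sorted(_to_genomic(utr3, g.start, L, g.strand))
        gff_lines.append(
            f"{g.chrom}\tfixture\tgene\t{g.start + 1}\t{g.start + L}\t.\t{g.strand}\t.\t"
            f"ID=gene:{g.name};Name={g.name}"
        )
        gff_lines.append(
            f"{g.chrom}\tfixture\tmRNA\t{g.start + 1}\t{g.start + L}\t.\t{g.strand}\t.\t"
            f"ID=transcript:{tx};Parent=gene:{g.name}"
        )
        for a, b in gex:
            gff_lines.append(
                f"{g.chrom}\tfixture\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent=transcript:{tx}"
            )
        # CDS phase: walk in transcript order
        order = gcds if g.strand == "+" else gcds[::-1]
        cum = 0
        phases = {}
        for a, b in order:
            phases[(a, b)] = (3 - cum % 3) % 3
            cum += b - a
        for a, b in gcds:
            gff_lines.append(
                f"{g.chrom}\tfixture\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t{phases[(a, b)]}\t"
                f"Parent=transcript:{tx}"
            )
        if spec.include_utr_features:
            for ivals, ftype in ((g5, "five_prime_UTR"), (g3, "three_prime_UTR")):
                for a, b in ivals:
                    gff_lines.append(
                        f"{g.chrom}\tfixture\t{ftype}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"Parent=transcript:{tx}"
                    )
        manifest.append(
            dict(kind="gene", name=tx, chrom=g.chrom, start=g.start + 1,
                 end=g.start + L, strand=g.strand,
                 detail=f"n_exons={g.n_exons};cds_len={g.cds_len}")
        )

    for p in spec.planted:
        if p.kind == "protospacer_copy":
            core = list(p.seq.upper())
            mm_pos = []
            if p.mismatches:
                idx = rng.choice(len(core), size=p.mismatches, replace=False)
                for i in sorted(int(x) for x in idx):
                    alt = "ACGT"[(("ACGT".index(core[i])) + 1 + int(rng.integers(0, 3))) % 4]
                    if alt == core[i]:
                        alt = "ACGT"[("ACGT".index(core[i]) + 1) % 4]
                    core[i] = alt
                    mm_pos.append(i + 1)  # PAM-distal = 1 for a 3' PAM
            site = "".join(core)
            full = site + p.pam if p.pam_side == "3prime" else p.pam + site
            placed = full if p.strand == "+" else revcomp(full)
            claim(p.chrom, p.pos, p.pos + len(placed), "protospacer copy")
            paste(p.chrom, p.pos, placed)
            if p.pam_side == "3prime":
                spacer_start = p.pos if p.strand == "+" else p.pos + len(p.pam)
            else:
                spacer_start = p.pos + len(p.pam) if p.strand == "+" else p.pos
            manifest.append(
                dict(kind="protospacer_copy", name="", chrom=p.chrom,
                     start=spacer_start + 1, end=spacer_start + len(site),
                     strand=p.strand,
                     detail=f"mismatches={p.mismatches};mm_pos={'/'.join(map(str, mm_pos))};pam={p.pam}")
            )
        elif p.kind == "homopolymer":
            run = p.base * p.length
            claim(p.chrom, p.pos, p.pos + p.length, "homopolymer")
            paste(p.chrom, p.pos, run)
            manifest.append(
                dict(kind="homopolymer", name="", chrom=p.chrom, start=p.pos + 1,
                     end=p.pos + p.length, strand="+", detail=f"base={p.base};length={p.length}")
            )
        elif p.kind == "gc_block":
            block = _random_seq(rng, p.length, p.gc)
            claim(p.chrom, p.pos, p.pos + p.length, "gc block")
            paste(p.chrom, p.pos, block)
            manifest.append(
                dict(kind="gc_block", name="", chrom=p.chrom, start=p.pos + 1,
                     end=p.pos + p.length, strand="+", detail=f"gc={p.gc}")
            )
        elif p.kind == "primer_site":
            placed = p.seq.upper() if p.strand == "+" else revcomp(p.seq.upper())
            claim(p.chrom, p.pos, p.pos + len(placed), "primer site")
            paste(p.chrom, p.pos, placed)
            manifest.append(
                dict(kind="primer_site", name="", chrom=p.chrom, start=p.pos + 1,
                     end=p.pos + len(placed), strand=p.strand, detail="")
            )
        elif p.kind == "duplication":
            sc, ss, se = p.source
            block = "".join(seqs[sc][ss:se])
            claim(p.chrom, p.pos, p.pos + len(block), "duplication")
            paste(p.chrom, p.pos, block)
            manifest.append(
                dict(kind="duplication", name="", chrom=p.chrom, start=p.pos + 1,
                     end=p.pos + len(block), strand="+",
                     detail=f"source={sc}:{ss + 1}-{se}")
            )
        else:
            raise ValueError(f"unknown planted feature kind {p.kind!r}")

    genome = GenomeIndex({c: "".join(s) for c, s in seqs.items()})
    gff3_text = "\n".join(gff_lines) + "\n"
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(gff3_text)
        tmp = fh.name
    try:
        models = build_transcript_models(tmp, genome)
    finally:
        os.unlink(tmp)
    return Fixture(genome=genome, gff3_text=gff3_text, manifest=manifest, models=models)


def reference_panel() -> list[tuple[str, float]]:
    """Fixed primer panel with frozen melting temperatures.

    The stored Tm values were computed once with an independent
    nearest-neighbor implementation under the package's standard conditions;
    the embedded engine must agree within 0.5 degrees C.
    """
    text = (resources.files("knockin.data") / "reference_primer_panel.csv").read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return [(r["sequence"], float(r["tm"])) for r in csv.DictReader(io.StringIO(body))]
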