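"""Mutational recoding of HDR donors.

Two recoding jobs are supported, mirroring the design levels
``prevent_recut`` and ``full``:

* **re-cut prevention** — find the fewest single-base donor mutations that
  bring the maximal CFD score across the whole donor (both strands) below a
  threshold (default 0.03), so the Cas/guide complex can neither cut the
  donor nor re-cut the repaired allele;
* **repair-track recoding** — additionally mutate the cut-to-insert region
  so that DNA repair cannot resolve before the payload is incorporated.

Inside coding sequence only silent (synonymous) substitutions are used,
choosing maximally divergent non-rare codons; in non-coding sequence,
complement transversions at a density of at most one per three bases.
Splice-junction neighbourhoods and the payload itself are never mutated.
"""

from __future__ import annotations

import csv
import io
import statistics
from dataclasses import dataclass, field
from importlib import resources

from Bio.Data import CodonTable

from .cfd import CFDModel, cfd_score, max_cfd_in_donor
from .genome import TranscriptModel
from .sequences import TRANSVERSION, revcomp

_COMP = str.maketrans("ACGT", "TGCA")


def _build_synonyms() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)  # stops are their own synonym group
    return {c: sorted(group) for group in by_aa.values() for c in group}


SYNONYMS = _build_synonyms()
AA_OF = {c: ("*" if c in CodonTable.unambiguous_dna_by_id[1].stop_codons
             else CodonTable.unambiguous_dna_by_id[1].forward_table[c])
         for c in SYNONYMS}


@dataclass
class CodonUsageTable:
    organism: str
    freq: dict[str, float]

    @classmethod
    def load(cls, organism: str = "human") -> "CodonUsageTable":
        name = f"codon_usage_{organism}.csv"
        text = (resources.files("knockin.data") / name).read_text()
        body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
        freq = {r["codon"]: float(r["freq"]) for r in csv.DictReader(io.StringIO(body))}
        return cls(organism=organism, freq=freq)

    def eligible(self, codon: str) -> bool:
        """Non-rare: usage >= 7.0e-3 and >= half the median of the codon's
        synonym group."""
        f = self.freq[codon]
        med = statistics.median(self.freq[c] for c in SYNONYMS[codon])
        return f >= 7.0e-3 and f >= 0.5 * med


def synonymous_substitution(codon: str, usage: CodonUsageTable) -> str | None:
    """Maximally divergent non-rare synonym of a codon, or None.

    Ties on divergence break to the highest-usage codon, then alphabetical.
    """
    if codon not in SYNONYMS:
        raise ValueError(f"not a standard codon: {codon!r}")
    cands = [c for c in SYNONYMS[codon] if c != codon and usage.eligible(c)]
    if not cands:
        return None
    def key(c):
        diff = sum(a != b for a, b in zip(c, codon))
        return (-diff, -usage.freq[c], c)
    return sorted(cands, key=key)[0]


@dataclass
class Mutation:
    offset: int          # donor offset, + strand
    ref: str
    alt: str
    mclass: str          # "silent" | "noncoding_transversion"
    region: str          # "recut" | "repair_track"


@dataclass
class RecodingPlan:
    mutations: list[Mutation] = field(default_factory=list)
    residual_max_cfd: float = 0.0
    level: str = "none"
    above_threshold: bool = False   # re-cut target not reachable under constraints

    def apply(self, seq: str) -> str:
        out = list(seq)
        for m in self.mutations:
            if out[m.offset] != m.ref:
                raise ValueError(f"plan/sequence mismatch at offset {m.offset}")
            out[m.offset] = m.alt
        return "".join(out)

    def revert(self, seq: str) -> str:
        out = list(seq)
        for m in self.mutations:
            if out[m.offset] != m.alt:
                raise ValueError(f"plan/sequence mismatch at offset {m.offset}")
            out[m.offset] = m.ref
        return "".join(out)


@dataclass
class DonorContext:
    """A donor sequence annotated with its coding structure and no-touch sets.

    ``codons`` lists donor offsets of each complete codon in reading order
    (three offsets per codon, transcript orientation); for minus-strand
    transcripts the read base is the complement of the donor (+ strand) base.
    ``protected`` holds splice-protected offsets, ``immutable`` payload
    offsets and anything else recoding must never touch.
    """

    seq: str
    strand: str = "+"    # transcript strand relative to the donor sequence
    codons: list[tuple[int, int, int]] = field(default_factory=list)
    protected: set[int] = field(default_factory=set)
    immutable: set[int] = field(default_factory=set)
    usage: CodonUsageTable | None = None

    def __post_init__(self):
        self.offset_to_codon = {
            o: i for i, trip in enumerate(self.codons) for o in trip
        }
        if self.usage is None:
            self.usage = CodonUsageTable.load("human")

    def read_codon(self, seq: str, idx: int) -> str:
        trip = self.codons[idx]
        bases = [seq[o] for o in trip]
        if self.strand == "-":
            bases = [b.translate(_COMP) for b in bases]
        return "".join(bases)

    def is_coding(self, offset: int) -> bool:
        return offset in self.offset_to_codon

    def touchable(self, offset: int) -> bool:
        return offset not in self.protected and offset not in self.immutable

    def silent_alternatives(self, seq: str, offset: int) -> list[str]:
        """Alternative bases at a coding offset whose codon stays synonymous
        and non-rare."""
        idx = self.offset_to_codon[offset]
        trip = self.codons[idx]
        pos_in_codon = trip.index(offset)
        codon = self.read_codon(seq, idx)
        alts = []
        for b in "ACGT":
            if b == seq[offset]:
                continue
            rb = b.translate(_COMP) if self.strand == "-" else b
            new = codon[:pos_in_codon] + rb + codon[pos_in_codon + 1 :]
            if AA_OF.get(new) == AA_OF.get(codon) and self.usage.eligible(new):
                alts.append(b)
        return alts


def splice_protection_mask(
    model: TranscriptModel,
    window_start: int,
    window_end: int,
    exon_width: int = 3,
    intron_width: int = 6,
) -> set[int]:
    """Window offsets (0-based, relative to window_start) within the
    protected neighbourhood of any exon/intron junction: ``exon_width``
    exonic and ``intron_width`` intronic bases on each side, clipped to the
    window."""
    exonic = lambda p: any(s <= p < e for s, e in model.exons)
    mask: set[int] = set()
    for gap in model.junctions():
        for side in (-1, +1):
            # walk outward from the junction on each side
            p = gap - 1 if side < 0 else gap
            width = exon_width if exonic(p) else intron_width
            lo = p - width + 1 if side < 0 else p
            hi = p + 1 if side < 0 else p + width
            for g in range(lo, hi):
                if window_start <= g < window_end:
                    mask.add(g - window_start)
    return mask


def _pam_span(model: CFDModel, off: int, strand: str) -> tuple[int, int]:
    enz = model.enzyme
    total = enz.spacer_length + enz.pam_length
    if (enz.pam_side == "3prime") == (strand == "+"):
        return off + total - enz.pam_length, off + total
    return off, off + enz.pam_length


def _window_score(seq: str, protospacer: str, model: CFDModel,
                  off: int, strand: str) -> float:
    total = model.enzyme.spacer_length + model.enzyme.pam_length
    if strand == "+":
        site = seq[off : off + total]
    else:
        site = revcomp(seq[off : off + total])
    return cfd_score(protospacer, site, model)


def _candidates_at(ctx: DonorContext, seq: str, offsets, coding_only: bool):
    cands = []
    for o in offsets:
        if o < 0 or o >= len(seq) or not ctx.touchable(o):
            continue
        ref = seq[o]
        if ctx.is_coding(o):
            for alt in ctx.silent_alternatives(seq, o):
                cands.append((o, ref, alt, "silent"))
        elif not coding_only and ref in TRANSVERSION:
            cands.append((o, ref, TRANSVERSION[ref], "noncoding_transversion"))
    return cands


def plan_recut_mutations(
    ctx: DonorContext,
    protospacer: str,
    model: CFDModel,
    threshold: float = 0.03,
    priority: str = "PAM_first",
    coding_only: bool = False,
    max_rounds: int = 30,
) -> RecodingPlan:
    """Greedy fewest-mutation search bringing the donor's maximal CFD below
    ``threshold``.

    Each round re-scans the whole donor, takes the worst window, and applies
    the single allowed mutation in it that minimizes the (global, window)
    CFD pair. With ``priority="PAM_first"`` PAM-region mutations are tried
    first and spacer mutations only when no PAM mutation reduces the window
    score (``"protospacer_first"`` reverses this). If the threshold cannot be
    reached under the constraints the best-effort plan is returned flagged
    ``above_threshold``.
    """
    if priority not in ("PAM_first", "protospacer_first"):
        raise ValueError(f"unknown priority {priority!r}")
    plan = RecodingPlan(level="prevent_recut")
    seq = ctx.seq
    for _ in range(max_rounds):
        score, off, strand = max_cfd_in_donor(seq, protospacer, model)
        if score < threshold:
            plan.residual_max_cfd = score
            return plan
        total = model.enzyme.spacer_length + model.enzyme.pam_length
        pam_lo, pam_hi = _pam_span(model, off, strand)
        window = range(off, off + total)
        pam_offsets = [o for o in window if pam_lo <= o < pam_hi]
        spacer_offsets = [o for o in window if not pam_lo <= o < pam_hi]
        first, second = (
            (pam_offsets, spacer_offsets)
            if priority == "PAM_first"
            else (spacer_offsets, pam_offsets)
        )
        best = None
        for group in (first, second):
            for o, ref, alt, mclass in _candidates_at(ctx, seq, group, coding_only):
                trial = seq[:o] + alt + seq[o + 1 :]
                wscore = _window_score(trial, protospacer, model, off, strand)
                if wscore >= score:
                    continue
                gscore = max_cfd_in_donor(trial, protospacer, model)[0]
                key = (gscore, wscore, o, alt)
                if best is None or key < best[0]:
                    best = (key, o, ref, alt, mclass, trial)
            if best is not None:
                break  # priority group succeeded
        if best is None:
            plan.residual_max_cfd = score
            plan.above_threshold = True
            return plan
        _, o, ref, alt, mclass, seq = best
        plan.mutations.append(Mutation(o, ref, alt, mclass, "recut"))
    plan.residual_max_cfd = max_cfd_in_donor(seq, protospacer, model)[0]
    plan.above_threshold = plan.residual_max_cfd >= threshold
    return plan


def plan_repair_track_mutations(
    ctx: DonorContext,
    cut_gap: int,
    insert_gap: int,
    already_mutated: set[int] | None = None,
) -> RecodingPlan:
    """Recode the cut-to-insert region (donor gap coordinates).

    Complete codons inside the region get a maximally divergent non-rare
    synonymous substitution; non-coding bases get complement transversions
    at most one per three bases (>= 2 untouched bases between consecutive
    transversions), scanning from the cut toward the insertion site.
    """
    plan = RecodingPlan(level="full")
    lo, hi = min(cut_gap, insert_gap), max(cut_gap, insert_gap)
    if lo == hi:
        return plan
    region = set(range(lo, hi))
    taken = set(already_mutated or ())
    seq = ctx.seq
    # codon-level silent recoding
    for idx, trip in enumerate(ctx.codons):
        if not all(o in region and ctx.touchable(o) and o not in taken for o in trip):
            continue
        codon = ctx.read_codon(seq, idx)
        if codon not in SYNONYMS:
            continue
        new = synonymous_substitution(codon, ctx.usage)
        if new is None:
            continue
        for pos_in_codon, o in enumerate(trip):
            nb = new[pos_in_codon]
            if ctx.strand == "-":
                nb = nb.translate(_COMP)
            if nb != seq[o]:
                plan.mutations.append(Mutation(o, seq[o], nb, "silent", "repair_track"))
                seq = seq[:o] + nb + seq[o + 1 :]
                taken.add(o)
    # non-coding transversions, scanning cut -> insert
    order = range(lo, hi) if cut_gap <= insert_gap else range(hi - 1, lo - 1, -1)
    last: int | None = None
    for o in order:
        if ctx.is_coding(o) or not ctx.touchable(o) or o in taken:
            continue
        if last is not None and abs(o - last) < 3:
            continue
        ref = seq[o]
        if ref not in TRANSVERSION:
            continue
        alt = TRANSVERSION[ref]
        plan.mutations.append(Mutation(o, ref, alt, "noncoding_transversion", "repair_track"))
        seq = seq[:o] + alt + seq[o + 1 :]
        last = o
    return plan


def plan_recoding(
    ctx: DonorContext,
    protospacer: str | None,
    model: CFDModel | None,
    level: str,
    cut_gap: int | None = None,
    insert_gap: int | None = None,
    threshold: float = 0.03,
    priority: str = "PAM_first",
    coding_only: bool = False,
) -> RecodingPlan:
    """Full recoding driver for one donor: re-cut prevention and, at level
    ``full``, repair-track recoding; residual CFD is re-scanned over the
    final mutated donor."""
    if level == "none" or protospacer is None or model is None:
        plan = RecodingPlan(level="none")
        if protospacer is not None and model is not None:
            plan.residual_max_cfd = max_cfd_in_donor(ctx.seq, protospacer, model)[0]
        return plan
    plan = plan_recut_mutations(
        ctx, protospacer, model, threshold=threshold,
        priority=priority, coding_only=coding_only,
    )
    if level == "full" and cut_gap is not None and insert_gap is not None:
        ctx2 = DonorContext(
            seq=plan.apply(ctx.seq), strand=ctx.strand, codons=ctx.codons,
            protected=ctx.protected, immutable=ctx.immutable, usage=ctx.usage,
        )
        track = plan_repair_track_mutations(
            ctx2, cut_gap, insert_gap,
            already_mutated={m.offset for m in plan.mutations},
        )
        plan.mutations.extend(track.mutations)
        plan.level = "full"
    final = plan.apply(ctx.seq)
    plan.residual_max_cfd = max_cfd_in_donor(final, protospacer, model)[0]
    plan.above_threshold = plan.residual_max_cfd >= threshold
    return plan
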