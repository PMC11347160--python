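"""HDR donor assembly: homology arms + payload, synthesis-feasibility flags,
arm trimming for dsDNA, and length-capped ssODNs with strand-polarity
selection.

The donor templates homology-directed repair: a payload flanked by arms
identical to the genome around the insertion point. dsDNA donors default to
500-bp arms and are checked against commercial-synthesis constraints
(homopolymers, extreme or skewed GC); ssODN donors are capped at a total
length (default 200 nt) and need a strand-polarity choice, which in ``auto``
mode follows the synthesis-dependent strand-annealing preference: the
favored strand depends on whether the cut lies 5' or 3' of the insertion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cfd import CFDModel
from .genome import GenomeIndex, TranscriptModel
from .guides import GuideCandidate
from .recoding import (
    CodonUsageTable,
    DonorContext,
    RecodingPlan,
    plan_recoding,
    splice_protection_mask,
)
from .sequences import revcomp


@dataclass
class DonorSpec:
    mode: str = "dsDNA"                  # "dsDNA" | "ssODN"
    arm5_len: int = 500
    arm3_len: int = 500
    ssodn_max_len: int = 200
    recoding_level: str = "full"         # "none" | "prevent_recut" | "full"
    strand_mode: str = "auto"            # auto|target|non_target|transcribed|non_transcribed
    trim_enabled: bool = False
    min_arm_len: int = 100
    forbidden_motifs: tuple[str, ...] = ()
    cfd_threshold: float = 0.03
    recut_priority: str = "PAM_first"
    coding_only: bool = False


@dataclass
class HomopolymerRun:
    offset: int
    base: str
    length: int


@dataclass
class SynthesisFlags:
    homopolymers: list[HomopolymerRun] = field(default_factory=list)
    gc_global_flag: bool = False
    gc_global_pct: float = 0.0
    gc_skew_flag: bool = False
    gc_skew_pct: float | None = None     # None when sequence < 50 bp (not evaluated)
    forbidden_motif_hits: list[tuple[str, int]] = field(default_factory=list)

    @property
    def any_flag(self) -> bool:
        return bool(self.homopolymers) or self.gc_global_flag or self.gc_skew_flag \
            or bool(self.forbidden_motif_hits)


def _homopolymer_runs(seq: str) -> list[HomopolymerRun]:
    """Maximal runs of >=10 A/T or >=6 G/C."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        b, length = seq[i], j - i
        if (b in "AT" and length >= 10) or (b in "GC" and length >= 6):
            runs.append(HomopolymerRun(i, b, length))
        i = j
    return runs


def flag_synthesis_problems(seq: str, forbidden_motifs=()) -> SynthesisFlags:
    """Evaluate the dsDNA synthesis flags on a donor sequence.

    Homopolymers: >=10 consecutive A or T, or >=6 consecutive G or C.
    Global GC: flagged outside (25%, 65%]. Window skew: flagged when any two
    50-bp windows (stride 1) differ in GC content by more than 52 points;
    not evaluated (``gc_skew_pct`` None) for sequences under 50 bp.
    """
    if not seq:
        raise ValueError("empty sequence")
    flags = SynthesisFlags(homopolymers=_homopolymer_runs(seq))
    gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (gc == ord("G")) | (gc == ord("C"))
    pct = 100.0 * is_gc.mean()
    flags.gc_global_pct = float(pct)
    flags.gc_global_flag = pct > 65.0 or pct < 25.0
    if len(seq) >= 50:
        w = np.lib.stride_tricks.sliding_window_view(is_gc, 50).mean(axis=1) * 100.0
        skew = float(w.max() - w.min())
        flags.gc_skew_pct = skew
        flags.gc_skew_flag = skew > 52.0
    for motif in forbidden_motifs:
        for probe in {motif.upper(), revcomp(motif.upper())}:
            start = seq.find(probe)
            while start != -1:
                flags.forbidden_motif_hits.append((motif, start))
                start = seq.find(probe, start + 1)
    flags.forbidden_motif_hits.sort(key=lambda t: (t[1], t[0]))
    return flags


@dataclass
class DonorDesign:
    chrom: str
    mode: str
    strand: str                  # reporting strand: '+' for dsDNA; chosen for ssODN
    window_start: int            # genomic 0-based start of the full (untrimmed) window
    window_end: int
    insert_gap: int              # genomic gap coordinate of payload insertion
    payload: str                 # payload as inserted on the genome + strand
    full_seq: str                # untrimmed, recoded donor on the genome + strand
    trim5: int = 0               # bases trimmed from each arm's distal end
    trim3: int = 0
    plan: RecodingPlan = field(default_factory=RecodingPlan)
    flags: SynthesisFlags = field(default_factory=SynthesisFlags)
    cut_gap: int | None = None   # genomic cut coordinate of the chosen guide
    guide: GuideCandidate | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def payload_span(self) -> tuple[int, int]:
        """Payload interval in full-donor (+ strand) offsets."""
        p5 = self.insert_gap - self.window_start
        return p5, p5 + len(self.payload)

    @property
    def arm5_len(self) -> int:
        return self.payload_span[0] - self.trim5

    @property
    def arm3_len(self) -> int:
        return (len(self.full_seq) - self.trim3) - self.payload_span[1]

    @property
    def seq_plus(self) -> str:
        """Trimmed donor on the genome + strand."""
        return self.full_seq[self.trim5 : len(self.full_seq) - self.trim3]

    @property
    def sequence(self) -> str:
        """Final donor sequence on the reporting strand."""
        return self.seq_plus if self.strand == "+" else revcomp(self.seq_plus)

    def donor_offset(self, genomic_pos: int) -> int:
        """Map a genomic position into full-donor (+ strand) offsets."""
        if genomic_pos < self.insert_gap:
            return genomic_pos - self.window_start
        return genomic_pos - self.window_start + len(self.payload)

    @property
    def cut_gap_donor(self) -> int | None:
        if self.cut_gap is None:
            return None
        if self.cut_gap <= self.insert_gap:
            return self.cut_gap - self.window_start
        return self.cut_gap - self.window_start + len(self.payload)

    @property
    def effective_arm_lens(self) -> tuple[int, int]:
        """Arm lengths excluding recoded stretches: contiguous unrecoded
        homology measured from each distal end."""
        p5, p3 = self.payload_span
        a5 = [m.offset for m in self.plan.mutations if self.trim5 <= m.offset < p5]
        a3 = [m.offset for m in self.plan.mutations
              if p3 <= m.offset < len(self.full_seq) - self.trim3]
        eff5 = (min(a5) - self.trim5) if a5 else self.arm5_len
        eff3 = ((len(self.full_seq) - self.trim3) - (max(a3) + 1)) if a3 else self.arm3_len
        return eff5, eff3

    def reconstruct_reference(self) -> str:
        """Strip the payload and revert every recoding mutation, yielding the
        genomic window byte-for-byte (round-trip invariant)."""
        unrecoded = self.plan.revert(self.full_seq)
        p5, p3 = self.payload_span
        return unrecoded[:p5] + unrecoded[p3:]


def select_ssodn_strand(
    cut_gap: int,
    insert_gap: int,
    guide_strand: str,
    transcript_strand: str | None,
    mode: str = "auto",
) -> str:
    """Strand polarity for an ssODN donor.

    ``auto`` follows the strand-annealing polarity rule: a cut 5' of the
    insertion (on the + strand) favors the minus strand and vice versa; when
    cut and insertion coincide the guide's non-target strand is used.
    ``target``/``non_target`` return the strand carrying the protospacer /
    its complement; ``transcribed``/``non_transcribed`` return the template /
    sense strand of the transcript and require transcript context.
    """
    flip = {"+": "-", "-": "+"}
    if mode == "auto":
        if cut_gap < insert_gap:
            return "-"
        if cut_gap > insert_gap:
            return "+"
        return flip[guide_strand]
    if mode == "target":
        return guide_strand
    if mode == "non_target":
        return flip[guide_strand]
    if mode in ("transcribed", "non_transcribed"):
        if transcript_strand is None:
            raise ValueError(f"strand mode {mode!r} requires transcript context")
        return flip[transcript_strand] if mode == "transcribed" else transcript_strand
    raise ValueError(f"unknown strand mode {mode!r}")


def trim_arms(design: DonorDesign, min_arm_len: int, forbidden_motifs=()) -> DonorDesign:
    """Shorten each homology arm from its distal end, one flagged feature at
    a time, until the arm is free of homopolymers and forbidden motifs or
    the minimum arm length is reached — whichever happens first. Remaining
    flags are re-reported, never dropped. GC-content flags are report-only."""
    design = replace(design)
    for arm in ("5", "3"):
        while True:
            cur_len = design.arm5_len if arm == "5" else design.arm3_len
            if cur_len <= min_arm_len:
                break
            p5, p3 = design.payload_span
            if arm == "5":
                armseq = design.full_seq[design.trim5 : p5]
            else:
                armseq = design.full_seq[p3 : len(design.full_seq) - design.trim3]
            feats = [(r.offset, r.offset + r.length) for r in _homopolymer_runs(armseq)]
            fl = flag_synthesis_problems(armseq, forbidden_motifs) if forbidden_motifs else None
            if fl:
                feats += [(o, o + len(m)) for m, o in fl.forbidden_motif_hits]
            if not feats:
                break
            if arm == "5":
                # distal end is the arm start; proximal edge of a feature is its end
                fs, fe = min(feats)  # most distal feature first
                new_len = cur_len - fe
            else:
                # distal end is the arm end; proximal edge is the feature start
                fs, fe = max(feats)
                new_len = fs
            new_len = max(new_len, min_arm_len)
            if new_len >= cur_len:
                break
            delta = cur_len - new_len
            if arm == "5":
                design.trim5 += delta
            else:
                design.trim3 += delta
    design.flags = flag_synthesis_problems(design.seq_plus, forbidden_motifs)
    return design


def cap_ssodn(design: DonorDesign, max_len: int = 200) -> DonorDesign:
    """Shorten arms (distal-first, larger-slack arm first) until the total
    donor length is at most ``max_len``. The payload is never truncated and
    the cut-to-insert region is kept inside the donor; if those constraints
    exceed the cap, raises naming the minimum feasible cap."""
    design = replace(design)
    p5, p3 = design.payload_span
    prot_lo, prot_hi = p5, p3
    cd = design.cut_gap_donor
    if cd is not None:
        prot_lo, prot_hi = min(prot_lo, cd), max(prot_hi, cd)
    lo_keep = min(p5, prot_lo)
    hi_keep = max(p3, prot_hi)
    required = hi_keep - lo_keep
    if required > max_len:
        raise ValueError(
            f"ssODN cap {max_len} infeasible: payload plus cut-to-insert region "
            f"needs at least {required} nt"
        )
    L = len(design.full_seq)
    while (L - design.trim3) - design.trim5 > max_len:
        slack5 = lo_keep - design.trim5
        slack3 = (L - design.trim3) - hi_keep
        if slack5 <= 0 and slack3 <= 0:
            break
        if slack5 >= slack3:
            design.trim5 += 1
        else:
            design.trim3 += 1
    return design


def build_donor(
    genome: GenomeIndex,
    chrom: str,
    insert_gap: int,
    payload: str,
    spec: DonorSpec,
    guide: GuideCandidate | None = None,
    model: TranscriptModel | None = None,
    cfd_model: CFDModel | None = None,
    usage: CodonUsageTable | None = None,
) -> DonorDesign:
    """Assemble, recode and finalize one HDR donor.

    ``insert_gap`` is the genomic gap coordinate of the payload insertion
    and ``payload`` is given on the genome + strand. Arms are clipped at
    chromosome ends with a warning.
    """
    payload = payload.upper()
    if payload and any(b not in "ACGT" for b in payload):
        raise ValueError("payload contains non-ACGT characters")
    if spec.mode not in ("dsDNA", "ssODN"):
        raise ValueError(f"unknown donor mode {spec.mode!r}")
    arm5 = spec.arm5_len if spec.mode == "dsDNA" else spec.ssodn_max_len
    arm3 = spec.arm3_len if spec.mode == "dsDNA" else spec.ssodn_max_len
    warns = []
    start = insert_gap - arm5
    end = insert_gap + arm3
    if start < 0 or end > genome.lengths[chrom]:
        start = max(0, start)
        end = min(genome.lengths[chrom], end)
        warns.append(f"homology arms clipped to chromosome bounds [{start},{end})")
        warnings.warn(warns[-1])
    raw = (
        genome.fetch(chrom, start, insert_gap)
        + payload
        + genome.fetch(chrom, insert_gap, end)
    )
    design = DonorDesign(
        chrom=chrom, mode=spec.mode, strand="+",
        window_start=start, window_end=end, insert_gap=insert_gap,
        payload=payload, full_seq=raw,
        cut_gap=guide.cut_gap if guide else None, guide=guide,
        warnings=warns,
    )
    # donor context: codon structure + splice protection mapped into donor offsets
    codons, protected = [], set()
    tstrand = "+"
    if model is not None and model.chrom == chrom:
        tstrand = model.strand
        pos = model.cds_positions()
        for i in range(0, len(pos) - len(pos) % 3, 3):
            trip = pos[i : i + 3]
            if all(start <= p < end for p in trip):
                codons.append(tuple(design.donor_offset(p) for p in trip))
        protected = {
            design.donor_offset(start + o)
            for o in splice_protection_mask(model, start, end)
        }
    p5, p3 = design.payload_span
    ctx = DonorContext(
        seq=raw, strand=tstrand, codons=codons, protected=protected,
        immutable=set(range(p5, p3)), usage=usage,
    )
    cut_d = design.cut_gap_donor
    ins_d = None
    if cut_d is not None:
        ins_d = p5 if design.cut_gap <= insert_gap else p3
    design.plan = plan_recoding(
        ctx,
        guide.protospacer if guide else None,
        cfd_model,
        spec.recoding_level,
        cut_gap=cut_d, insert_gap=ins_d,
        threshold=spec.cfd_threshold,
        priority=spec.recut_priority,
        coding_only=spec.coding_only,
    )
    design.full_seq = design.plan.apply(raw)
    if spec.mode == "ssODN":
        if guide is None:
            raise ValueError("ssODN design requires a guide (strand polarity)")
        design.strand = select_ssodn_strand(
            guide.cut_gap, insert_gap, guide.strand,
            model.strand if model else None, spec.strand_mode,
        )
        design = cap_ssodn(design, spec.ssodn_max_len)
        design.flags = flag_synthesis_problems(design.seq_plus, spec.forbidden_motifs)
    else:
        design.flags = flag_synthesis_problems(design.seq_plus, spec.forbidden_motifs)
        if spec.trim_enabled:
            if spec.min_arm_len > min(design.arm5_len, design.arm3_len):
                warnings.warn("min_arm_len exceeds current arm length; trimming skipped")
            else:
                design = trim_arms(design, spec.min_arm_len, spec.forbidden_motifs)
    return design
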