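"""Genotyping-primer design for amplicon sequencing of edited loci.

Given the edit coordinate, a locus window is extracted (430 bp short-read /
4000 bp long-read, centered), primer candidates are enumerated and filtered
on thermodynamics (Tm 57-63 C, deltaTm <= 3 C, GC 20-80%, length 18-25 nt,
3' self/pair complementarity caps), position (each primer at least 100 /
1000 bp from the edit site, so one primer binds outside the homology arms)
and product size (250-350 / 3300-3700 bp). Surviving pairs are screened for
unintended genome-wide products: annealing sites within the mismatch budget
(exact final 3' base required) on opposite strands with converging 3' ends
within 6 kb fail the pair, over all of fwd+rev, fwd+fwd and rev+rev. When
nothing passes, up to six relaxation attempts loosen deltaTm (+1 C at
attempts 1-3) and the product-size ceiling (+step at attempts 2, 4, 6,
with the locus window extended to match). Up to three passing pairs are
reported by thermodynamic penalty.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeIndex
from .sequences import gc_fraction, revcomp
from .thermo import melting_temperature

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PrimerMode:
    name: str
    extract_len: int
    min_edit_distance: int
    product_range: tuple[int, int]
    relax_size_step: int
    relax_extend: int


SHORT = PrimerMode("short", 430, 100, (250, 350), 80, 40)
LONG = PrimerMode("long", 4000, 1000, (3300, 3700), 300, 150)
MODES = {"short": SHORT, "long": LONG}


@dataclass(frozen=True)
class PrimerConstraints:
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    max_tm_diff: float = 3.0
    gc_min: float = 20.0
    gc_max: float = 80.0
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 25
    max_self_any: int = 8
    max_self_end: int = 3
    max_pair_any: int = 8
    max_pair_end: int = 3


@dataclass
class PrimerCandidate:
    sequence: str
    tm: float
    gc: float            # percent
    chrom: str
    start: int           # 0-based genomic start of the annealing interval
    strand: str          # '+' forward primer, '-' reverse primer

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AnnealingSite:
    chrom: str
    start: int
    strand: str
    mismatches: int
    three_prime_exact: bool = True
    length: int = 0


@dataclass
class OffTargetProduct:
    chrom: str
    size: int
    combo: str           # "fwd+rev" | "fwd+fwd" | "rev+rev"
    plus_start: int
    minus_end: int


@dataclass
class PrimerPairReport:
    fwd: PrimerCandidate
    rev: PrimerCandidate
    product_size: int              # unedited-allele product
    annealing_temp: float          # advisory: min(pair Tm) - 1
    offtarget_products: list[OffTargetProduct] = field(default_factory=list)
    verdict: str = "pass"
    attempt: int = 0
    penalty: float = 0.0


def comp_any(a: str, b: str) -> int:
    """Max complementary bases in any ungapped antiparallel alignment of two
    primers (a 5'->3' against b 3'->5')."""
    br = b[::-1]
    best = 0
    for shift in range(-(len(br) - 1), len(a)):
        n = 0
        for i in range(max(0, shift), min(len(a), shift + len(br))):
            if a[i] == br[i - shift].translate(_COMP):
                n += 1
        best = max(best, n)
    return best


def comp_end(a: str, b: str) -> int:
    """Max run of consecutive complementary bases anchored at a's 3' end in
    any ungapped antiparallel alignment against b."""
    br = b[::-1]
    best = 0
    last = len(a) - 1
    for shift in range(-(len(br) - 1), len(a)):
        if not (shift <= last < shift + len(br)):
            continue
        n = 0
        i = last
        while i >= max(0, shift) and a[i] == br[i - shift].translate(_COMP):
            n += 1
            i -= 1
        best = max(best, n)
    return best


def extract_locus(
    genome: GenomeIndex, chrom: str, edit_gap: int, mode: PrimerMode, extension: int = 0
) -> tuple[str, int]:
    """Locus window centered on the edit coordinate; returns (sequence,
    genomic start). Clipped at chromosome ends with a warning."""
    if not 0 <= edit_gap <= genome.lengths[chrom]:
        raise ValueError(f"edit site {edit_gap} outside {chrom}")
    half = mode.extract_len // 2 + extension
    lo, hi = edit_gap - half, edit_gap + half
    if lo < 0 or hi > genome.lengths[chrom]:
        warnings.warn(f"locus window clipped to chromosome bounds on {chrom}")
        lo, hi = max(0, lo), min(genome.lengths[chrom], hi)
    return genome.fetch(chrom, lo, hi), lo


def _singles(
    locus: str, locus_start: int, chrom: str, edit_gap: int,
    mode: PrimerMode, cons: PrimerConstraints, strand: str,
) -> list[PrimerCandidate]:
    out = []
    n = len(locus)
    for L in range(cons.len_min, cons.len_max + 1):
        for i in range(n - L + 1):
            g_start = locus_start + i
            g_end = g_start + L
            if strand == "+":
                if edit_gap - g_end < mode.min_edit_distance:
                    continue
                seq = locus[i : i + L]
            else:
                if g_start - edit_gap < mode.min_edit_distance:
                    continue
                seq = revcomp(locus[i : i + L])
            if "N" in seq:
                continue
            gc = 100.0 * gc_fraction(seq)
            if not cons.gc_min <= gc <= cons.gc_max:
                continue
            tm = melting_temperature(seq)
            if not cons.tm_min <= tm <= cons.tm_max:
                continue
            if comp_any(seq, seq) > cons.max_self_any:
                continue
            if comp_end(seq, seq) > cons.max_self_end:
                continue
            out.append(PrimerCandidate(seq, tm, gc, chrom, g_start, strand))
    return out


def enumerate_candidates(
    locus: str,
    locus_start: int,
    chrom: str,
    edit_gap: int,
    mode: PrimerMode,
    constraints: PrimerConstraints = PrimerConstraints(),
    max_tm_diff: float | None = None,
    product_range: tuple[int, int] | None = None,
) -> list[PrimerPairReport]:
    """All primer pairs passing thermodynamic, positional and product-size
    filters (off-target screening not yet applied), sorted by penalty."""
    cons = constraints
    dtm = cons.max_tm_diff if max_tm_diff is None else max_tm_diff
    lo, hi = mode.product_range if product_range is None else product_range
    fwd = _singles(locus, locus_start, chrom, edit_gap, mode, cons, "+")
    rev = _singles(locus, locus_start, chrom, edit_gap, mode, cons, "-")
    rev.sort(key=lambda p: p.end)
    ends = [p.end for p in rev]
    pairs = []
    for f in fwd:
        i0 = bisect.bisect_left(ends, f.start + lo)
        i1 = bisect.bisect_right(ends, f.start + hi)
        for r in rev[i0:i1]:
            if abs(f.tm - r.tm) > dtm:
                continue
            if comp_any(f.sequence, r.sequence) > cons.max_pair_any:
                continue
            if comp_end(f.sequence, r.sequence) > cons.max_pair_end:
                continue
            if comp_end(r.sequence, f.sequence) > cons.max_pair_end:
                continue
            size = r.end - f.start
            penalty = (
                abs(f.tm - cons.tm_opt) + abs(r.tm - cons.tm_opt)
                + 0.1 * (abs(f.length - cons.len_opt) + abs(r.length - cons.len_opt))
            )
            pairs.append(
                PrimerPairReport(
                    fwd=f, rev=r, product_size=size,
                    annealing_temp=min(f.tm, r.tm) - 1.0, penalty=penalty,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.fwd.start, p.rev.start, p.fwd.length, p.rev.length))
    return pairs


def find_annealing_sites(
    primer: str, genome: GenomeIndex, aligner_mode: str = "fast"
) -> list[AnnealingSite]:
    """All genomic annealing sites of a primer within the mismatch budget
    (fast: <=3, sensitive: <=4) whose final 3' base matches exactly."""
    max_mm = {"fast": 3, "sensitive": 4}[aligner_mode]
    L = len(primer)
    sites = []
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        for strand in ("+", "-"):
            probe = primer if strand == "+" else revcomp(primer)
            q = np.frombuffer(probe.encode(), dtype=np.uint8)
            wins = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm = (wins != q).sum(axis=1)
            for j in np.nonzero(mm <= max_mm)[0]:
                j = int(j)
                # the primer's final 3' base must match the genome exactly
                if strand == "+":
                    if seq[j + L - 1] != primer[-1]:
                        continue
                else:
                    if seq[j] != primer[-1].translate(_COMP):
                        continue
                sites.append(AnnealingSite(chrom, j, strand, int(mm[j]), True, L))
    return sites


def detect_unintended_products(
    fwd_sites: list[AnnealingSite],
    rev_sites: list[AnnealingSite],
    intended: tuple[str, int, int] | None = None,
    max_size: int = 6000,
) -> list[OffTargetProduct]:
    """Convergent opposite-strand site pairs within ``max_size``, over the
    fwd+rev, fwd+fwd and rev+rev combinations. ``intended`` is the intended
    product (chrom, fwd start, rev end), excluded by coordinate identity."""
    combos = [
        ("fwd+rev", fwd_sites, rev_sites),
        ("fwd+fwd", fwd_sites, fwd_sites),
        ("rev+rev", rev_sites, rev_sites),
    ]
    out = []
    seen = set()
    for name, sa, sb in combos:
        for a in sa:
            if a.strand != "+":
                continue
            for b in sb:
                if b.strand != "-" or b.chrom != a.chrom:
                    continue
                b_end = b.start + b.length
                size = b_end - a.start
                if size <= 0 or size > max_size:
                    continue
                if intended and name == "fwd+rev" and (a.chrom, a.start, b_end) == intended:
                    continue
                key = (name, a.chrom, a.start, b_end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(OffTargetProduct(a.chrom, size, name, a.start, b_end))
    out.sort(key=lambda p: (p.chrom, p.plus_start, p.minus_end, p.combo))
    return out


def relaxed_constraints(
    mode: PrimerMode, attempt: int, cons: PrimerConstraints = PrimerConstraints()
) -> tuple[float, tuple[int, int], int]:
    """(deltaTm cap, product range, locus extension) for one attempt of the
    six-step relaxation ladder: deltaTm +1 C at attempts 1-3, product-size
    ceiling +step (and window +extension) at attempts 2, 4 and 6."""
    if not 0 <= attempt <= 6:
        raise ValueError("attempt must be in 0..6")
    dtm = cons.max_tm_diff + min(attempt, 3)
    n_size = sum(1 for a in (2, 4, 6) if a <= attempt)
    lo, hi = mode.product_range
    return dtm, (lo, hi + n_size * mode.relax_size_step), n_size * mode.relax_extend


def design_genotyping_primers(
    genome: GenomeIndex,
    chrom: str,
    edit_gap: int,
    mode: str | PrimerMode = "short",
    aligner_mode: str = "fast",
    constraints: PrimerConstraints = PrimerConstraints(),
    max_offtarget_size: int = 6000,
    n_pairs: int = 3,
) -> tuple[list[PrimerPairReport], str | None]:
    """Design up to ``n_pairs`` genotyping primer pairs for one edit site.

    Returns (reports, failure_reason); failure_reason is None on success and
    set when all attempts (0 plus six relaxations) are exhausted.
    """
    if isinstance(mode, str):
        mode = MODES[mode]
    site_cache: dict[str, list[AnnealingSite]] = {}

    def sites_for(seq: str) -> list[AnnealingSite]:
        if seq not in site_cache:
            site_cache[seq] = find_annealing_sites(seq, genome, aligner_mode)
        return site_cache[seq]

    for attempt in range(0, 7):
        dtm, prange, ext = relaxed_constraints(mode, attempt, constraints)
        locus, locus_start = extract_locus(genome, chrom, edit_gap, mode, ext)
        pairs = enumerate_candidates(
            locus, locus_start, chrom, edit_gap, mode,
            constraints, max_tm_diff=dtm, product_range=prange,
        )
        passing = []
        for pair in pairs:
            fs = sites_for(pair.fwd.sequence)
            rs = sites_for(pair.rev.sequence)
            intended = (chrom, pair.fwd.start, pair.rev.end)
            prods = detect_unintended_products(fs, rs, intended, max_offtarget_size)
            pair.offtarget_products = prods
            pair.attempt = attempt
            pair.verdict = "fail" if prods else "pass"
            if pair.verdict == "pass":
                passing.append(pair)
                if len(passing) >= n_pairs:
                    break
        if passing:
            return passing[:n_pairs], None
    return [], "no primer pair free of unintended products after six relaxation attempts"
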