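"""Guide-RNA engine: protospacer enumeration, off-target search, MIT
specificity aggregation, and the three-factor composite ranking.

A guide is scored by the product of three weights in [0, 1]:

* on-target specificity weight — piecewise-linear in the aggregated MIT
  specificity score (0 below 45, 1 above 65, linear between);
* cut-to-insert distance weight — Gaussian exp(-d^2/110), d in bp;
* position weight — optional penalty for cuts in the 5'UTR or close to a
  splice junction.

The off-target search is an exhaustive scan of every FASTA record on both
strands for sites within ``max_mismatches`` of the protospacer flanked by
one of the enzyme's off-target PAMs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .enzymes import CasEnzyme
from .genome import GenomeIndex, RegionClass, TranscriptModel, classify_position
from .sequences import iupac_regex, matches_iupac, revcomp


def _load_mit_weights() -> list[float]:
    text = (resources.files("knockin.data") / "mit_hsu_weights.tsv").read_text()
    weights = {}
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        pos, w = line.split("\t")
        weights[int(pos)] = float(w)
    return [weights[i] for i in range(1, 21)]


MIT_WEIGHTS = _load_mit_weights()  # index 0 = PAM-distal position 1


@dataclass
class OffTargetHit:
    chrom: str
    start: int          # 0-based spacer start
    strand: str
    mismatch_positions: list[int]   # spacer indices, PAM-distal = 1
    pam_seq: str
    mit_hit_score: float = 0.0


@dataclass
class GuideCandidate:
    protospacer: str
    pam: str
    chrom: str
    start: int        # 0-based half-open spacer interval
    end: int
    strand: str
    cut_gap: int      # gap coordinate of the nominal cut
    offtargets: list[OffTargetHit] = field(default_factory=list)
    specificity_score: float | None = None   # 0-100 scale
    w_spec: float | None = None
    w_dist: float | None = None
    w_pos: float | None = None
    composite: float | None = None
    distance_to_insert: int | None = None

    @property
    def cut_site_1based(self) -> int:
        """1-based position of the base immediately 3' of the cut (+ strand)."""
        return self.cut_gap + 1


def enumerate_protospacers(
    genome: GenomeIndex, enzyme: CasEnzyme, chrom: str, start: int, end: int
) -> list[GuideCandidate]:
    """All spacer+PAM occurrences on both strands fully inside [start, end).

    Spacers overlapping N are dropped (the [ACGT] spacer pattern excludes
    them). Returns unscored candidates.
    """
    window = genome.fetch(chrom, start, end)
    total = enzyme.spacer_length + enzyme.pam_length
    if len(window) < total:
        return []
    if enzyme.pam_side == "3prime":
        pat = iupac_regex("N" * enzyme.spacer_length + enzyme.pam)
        spacer_off = 0
    else:
        pat = iupac_regex(enzyme.pam + "N" * enzyme.spacer_length)
        spacer_off = enzyme.pam_length
    out = []
    for strand, seq in (("+", window), ("-", revcomp(window))):
        for i in range(len(seq) - total + 1):
            m = pat.match(seq, i)
            if not m:
                continue
            sub = seq[i : i + total]
            if "N" in sub:
                continue
            spacer = sub[spacer_off : spacer_off + enzyme.spacer_length]
            pam = sub[:spacer_off] if spacer_off else sub[enzyme.spacer_length :]
            s_local = i + spacer_off
            if strand == "+":
                g_start = start + s_local
            else:
                g_start = start + len(window) - (s_local + enzyme.spacer_length)
            g_end = g_start + enzyme.spacer_length
            out.append(
                GuideCandidate(
                    protospacer=spacer, pam=pam, chrom=chrom,
                    start=g_start, end=g_end, strand=strand,
                    cut_gap=enzyme.cut_gap(g_start, g_end, strand),
                )
            )
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def _mismatch_positions(enzyme: CasEnzyme, spacer: str, site: str) -> list[int]:
    """1-based spacer indices of mismatches, PAM-distal = 1."""
    n = enzyme.spacer_length
    pos = []
    for i, (a, b) in enumerate(zip(spacer, site)):
        if a != b:
            # for a 3' PAM the spacer 5' end is PAM-distal; for a 5' PAM it
            # is PAM-proximal, so numbering runs from the 3' end instead
            pos.append(i + 1 if enzyme.pam_side == "3prime" else n - i)
    return sorted(pos)


def find_offtargets(
    guide: GuideCandidate,
    genome: GenomeIndex,
    enzyme: CasEnzyme,
    max_mismatches: int = 4,
) -> list[OffTargetHit]:
    """Exhaustive genome scan for off-target sites of one guide.

    A site qualifies if it is within ``max_mismatches`` of the protospacer
    and flanked on the PAM side by one of the enzyme's off-target PAMs. The
    on-target location itself is excluded. Scores each hit with the MIT
    single-hit formula.
    """
    n = enzyme.spacer_length
    plen = enzyme.pam_length
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < n + plen:
            continue
        for strand in ("+", "-"):
            query = guide.protospacer if strand == "+" else revcomp(guide.protospacer)
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            wins = np.lib.stride_tricks.sliding_window_view(arr, n)
            mm = (wins != q).sum(axis=1)
            for j in np.nonzero(mm <= max_mismatches)[0]:
                j = int(j)
                site_plus = seq[j : j + n]
                # PAM location in + strand coordinates
                if (enzyme.pam_side == "3prime") == (strand == "+"):
                    pam_lo, pam_hi = j + n, j + n + plen
                else:
                    pam_lo, pam_hi = j - plen, j
                if pam_lo < 0 or pam_hi > len(seq):
                    continue
                pam_plus = seq[pam_lo:pam_hi]
                pam = pam_plus if strand == "+" else revcomp(pam_plus)
                if not any(matches_iupac(pam, p) for p in enzyme.offtarget_pams):
                    continue
                if chrom == guide.chrom and j == guide.start and strand == guide.strand:
                    continue  # the on-target site
                site = site_plus if strand == "+" else revcomp(site_plus)
                mmpos = _mismatch_positions(enzyme, guide.protospacer, site)
                hits.append(
                    OffTargetHit(
                        chrom=chrom, start=j, strand=strand,
                        mismatch_positions=mmpos, pam_seq=pam,
                        mit_hit_score=mit_hit_score(mmpos),
                    )
                )
    return hits


def mit_hit_score(mismatch_positions: list[int]) -> float:
    """MIT (Hsu) single-hit score in [0, 100] for one off-target site.

    Product of per-position weights, a mean-pairwise-distance term and a
    mismatch-count term; 0 mismatches scores 100.
    """
    m = len(mismatch_positions)
    if m == 0:
        return 100.0
    for p in mismatch_positions:
        if not 1 <= p <= 20:
            raise ValueError(f"mismatch position {p} outside [1, 20]")
    score = 1.0
    for p in mismatch_positions:
        score *= 1.0 - MIT_WEIGHTS[p - 1]
    if m > 1:
        pairs = [
            abs(a - b)
            for i, a in enumerate(mismatch_positions)
            for b in mismatch_positions[i + 1 :]
        ]
        mean_dist = sum(pairs) / len(pairs)
        score *= 1.0 / (((19.0 - mean_dist) / 19.0) * 4.0 + 1.0)
    score *= 1.0 / (m * m)
    return score * 100.0


def aggregate_specificity(hits: list[OffTargetHit]) -> float:
    """Aggregated guide specificity on the 0-100 scale:
    100 x 100 / (100 + sum of off-target MIT hit scores)."""
    return 100.0 * 100.0 / (100.0 + sum(h.mit_hit_score for h in hits))


def specificity_weight(score: float) -> float:
    """0 below 45, 1 above 65, linear in between."""
    if score <= 45.0:
        return 0.0
    if score >= 65.0:
        return 1.0
    return (score - 45.0) / 20.0


def distance_weight(cut_to_insert: float) -> float:
    """Gaussian cut-to-insert distance weight exp(-d^2/110)."""
    if cut_to_insert < 0:
        raise ValueError("distance must be >= 0")
    return math.exp(-(cut_to_insert**2) / 110.0)


@dataclass(frozen=True)
class PositionWeightConfig:
    """Penalty shape for cuts in regulatory regions. The published rule gives
    the penalized regions (5'UTR, splice junctions) but not numeric values;
    these defaults penalize without hard-excluding and are configurable."""

    utr5_weight: float = 0.4
    junction_weight: float = 0.1
    exon_margin: int = 2     # bp from junction on the exon side at full penalty
    intron_margin: int = 6   # bp from junction on the intron side at full penalty
    ramp: int = 10           # bp over which the penalty relaxes linearly to 1


def position_weight(
    cut_gap: int,
    model: TranscriptModel | None,
    enabled: bool = True,
    config: PositionWeightConfig = PositionWeightConfig(),
) -> float:
    """Positional penalty for a cut site; 1.0 when disabled or no transcript
    context. Evaluates both bases flanking the cut and keeps the lower weight."""
    if not enabled or model is None:
        return 1.0
    w = 1.0
    for p in (cut_gap - 1, cut_gap):
        pc = classify_position(p, model)
        if pc.region == RegionClass.UTR5:
            w = min(w, config.utr5_weight)
        if pc.junction_distance is not None and pc.region != RegionClass.INTERGENIC:
            margin = (
                config.intron_margin
                if pc.region == RegionClass.INTRON
                else config.exon_margin
            )
            jd = pc.junction_distance
            if jd <= margin:
                w = min(w, config.junction_weight)
            elif jd <= margin + config.ramp:
                frac = (jd - margin) / config.ramp
                w = min(w, config.junction_weight + (1.0 - config.junction_weight) * frac)
    return w


def score_guides(
    candidates: list[GuideCandidate],
    genome: GenomeIndex,
    enzyme: CasEnzyme,
    insert_gap: int,
    model: TranscriptModel | None = None,
    position_enabled: bool = True,
    max_mismatches: int = 4,
    position_config: PositionWeightConfig = PositionWeightConfig(),
) -> list[GuideCandidate]:
    """Fill in off-targets, the three weights and the composite for each
    candidate, in place."""
    for g in candidates:
        g.offtargets = find_offtargets(g, genome, enzyme, max_mismatches)
        g.specificity_score = aggregate_specificity(g.offtargets)
        g.distance_to_insert = abs(g.cut_gap - insert_gap)
        g.w_spec = specificity_weight(g.specificity_score)
        g.w_dist = distance_weight(g.distance_to_insert)
        g.w_pos = position_weight(g.cut_gap, model, position_enabled, position_config)
        g.composite = g.w_spec * g.w_dist * g.w_pos
    return candidates


def rank_guides(
    candidates: list[GuideCandidate], insert_gap: int, k: int
) -> list[GuideCandidate]:
    """Top-k guides by composite score, descending.

    Ties break deterministically: smaller cut-to-insert distance, then higher
    specificity, then leftmost genomic coordinate, then strand.
    """
    if not candidates:
        warnings.warn("no guide candidates in the search window")
        return []
    scored = [g for g in candidates if g.composite is not None]
    scored.sort(
        key=lambda g: (
            -g.composite,
            abs(g.cut_gap - insert_gap),
            -g.specificity_score,
            g.chrom,
            g.start,
            g.strand,
        )
    )
    return scored[: max(k, 0)]


def design_guides(
    genome: GenomeIndex,
    enzyme: CasEnzyme,
    chrom: str,
    insert_gap: int,
    k: int = 1,
    search_radius: int = 50,
    model: TranscriptModel | None = None,
    position_enabled: bool = True,
    max_mismatches: int = 4,
) -> list[GuideCandidate]:
    """Enumerate, score and rank guides whose cut falls within
    ``search_radius`` bp of the insertion gap. The radius default (50 bp)
    is bounded by the Gaussian distance weight, which is negligible beyond it."""
    margin = enzyme.spacer_length + enzyme.pam_length
    lo = max(0, insert_gap - search_radius - margin)
    hi = min(genome.lengths[chrom], insert_gap + search_radius + margin)
    cands = enumerate_protospacers(genome, enzyme, chrom, lo, hi)
    cands = [g for g in cands if abs(g.cut_gap - insert_gap) <= search_radius]
    score_guides(
        cands, genome, enzyme, insert_gap,
        model=model, position_enabled=position_enabled, max_mismatches=max_mismatches,
    )
    return rank_guides(cands, insert_gap, k)
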