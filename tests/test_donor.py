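"""Donor assembly, synthesis flags, arm trimming, ssODN cap and polarity."""

import random

import pytest

from knockin.cfd import CFDModel, max_cfd_in_donor
from knockin.donor import (
    DonorSpec,
    build_donor,
    flag_synthesis_problems,
    select_ssodn_strand,
)
from knockin.enzymes import SpCas9
from knockin.genome import GenomeIndex
from knockin.guides import design_guides
from knockin.sequences import revcomp, translate

CFD = CFDModel.load("SpCas9")


def _background(n, seed=11):
    """Random sequence free of homopolymer runs (alternating-pair base)."""
    rng = random.Random(seed)
    out = []
    prev = ""
    for _ in range(n):
        b = rng.choice("ACGT")
        while out and b == out[-1]:
            b = rng.choice("ACGT")
        out.append(b)
    return "".join(out) + prev


# --- flags ------------------------------------------------------------------

@pytest.mark.parametrize(
    "run,expect",
    [("A" * 9, False), ("A" * 10, True), ("T" * 10, True),
     ("G" * 5, False), ("G" * 6, True), ("C" * 6, True), ("C" * 5, False)],
)
def test_homopolymer_flag_boundaries_exact(run, expect):
    sep = "A" if run[0] in "GC" else "G"  # prevent accidental run extension
    seq = _background(60) + sep + run + sep + _background(60, seed=13)
    flags = flag_synthesis_problems(seq)
    hits = [r for r in flags.homopolymers if r.base == run[0] and r.length >= len(run)]
    assert bool(hits) == expect


def test_homopolymer_offset_reported():
    seq = _background(40) + "A" * 11 + _background(40, seed=17)
    (r,) = flag_synthesis_problems(seq).homopolymers
    assert (r.offset, r.base, r.length) == (40, "A", 11)


def _exact_gc_seq(n, gc_pct):
    n_gc = round(n * gc_pct / 100)
    bases = ["G", "C"] * (n_gc // 2 + 1) + ["A", "T"] * n
    seq = []
    g = a = 0
    for i in range(n):
        if g < n_gc and (i % 2 == 0 or a >= n - n_gc):
            seq.append("GC"[g % 2])
            g += 1
        else:
            seq.append("AT"[a % 2])
            a += 1
    # interleave to avoid runs and skew
    return "".join(seq)


@pytest.mark.parametrize("pct,expect", [(60, False), (65, False), (66, True),
                                        (25, False), (24, True)])
def test_global_gc_flag_boundary(pct, expect):
    seq = _exact_gc_seq(1000, pct)
    flags = flag_synthesis_problems(seq)
    assert flags.gc_global_pct == pytest.approx(pct, abs=0.2)
    assert flags.gc_global_flag == expect


def test_gc_window_skew_flag():
    skewed = "GC" * 25 + "AT" * 50 + "GC" * 25  # 100% vs 0% windows
    flags = flag_synthesis_problems(skewed)
    assert flags.gc_skew_flag and flags.gc_skew_pct > 52
    assert not flag_synthesis_problems(_exact_gc_seq(500, 50)).gc_skew_flag


def test_gc_skew_not_evaluated_below_window_size():
    flags = flag_synthesis_problems("ACGT" * 10)  # 40 nt
    assert flags.gc_skew_pct is None and not flags.gc_skew_flag


def test_forbidden_motif_hits_both_strands():
    seq = _background(30) + "GAATTC" + _background(30, seed=19)
    flags = flag_synthesis_problems(seq, forbidden_motifs=("GAATTC",))
    assert ("GAATTC", 30) in flags.forbidden_motif_hits


# --- assembly ---------------------------------------------------------------

def _donor_genome(seed=23, n=3000):
    rng = random.Random(seed)
    return GenomeIndex({"c": "".join(rng.choice("ACGT") for _ in range(n))})


def test_empty_payload_no_recoding_is_genomic_window():
    g = _donor_genome()
    spec = DonorSpec(recoding_level="none")
    d = build_donor(g, "c", 1500, "", spec)
    assert d.sequence == g.fetch("c", 1000, 2000)
    assert d.arm5_len == d.arm3_len == 500


def test_payload_inserted_at_gap():
    g = _donor_genome()
    d = build_donor(g, "c", 1500, "ATGGTG", DonorSpec(recoding_level="none"))
    assert d.sequence == g.fetch("c", 1000, 1500) + "ATGGTG" + g.fetch("c", 1500, 2000)
    assert len(d.sequence) == 1006


def test_payload_validation():
    g = _donor_genome()
    with pytest.raises(ValueError, match="non-ACGT"):
        build_donor(g, "c", 1500, "ATGX", DonorSpec())


def test_arms_clipped_at_chromosome_start_with_warning():
    g = _donor_genome()
    with pytest.warns(UserWarning, match="clipped"):
        d = build_donor(g, "c", 100, "", DonorSpec(recoding_level="none"))
    assert d.arm5_len == 100 and d.arm3_len == 500


def test_c_terminal_payload_abuts_stop_codon(fx):
    """The payload's 5' junction touches the last sense codon."""
    m = fx.models["FIXG1.1"]
    gap = m.insertion_gap("C")
    payload = "GAAGGTGGC"
    d = build_donor(fx.genome, m.chrom, gap, payload, DonorSpec(recoding_level="none"))
    p5, p3 = d.payload_span
    # donor sequence downstream of the payload starts with the stop codon
    stop = d.full_seq[p3 : p3 + 3]
    assert stop == m.spliced_cds(fx.genome)[-3:]


def test_recut_recoding_in_donor_context(fx):
    m = fx.models["FIXG1.1"]
    gap = m.insertion_gap("C")
    guides = design_guides(fx.genome, SpCas9, m.chrom, gap, k=1, model=m)
    d = build_donor(
        fx.genome, m.chrom, gap, "GAAGGTGGCTCT",
        DonorSpec(recoding_level="prevent_recut"),
        guide=guides[0], model=m, cfd_model=CFD,
    )
    assert d.plan.residual_max_cfd < 0.03 or d.plan.above_threshold
    assert max_cfd_in_donor(d.full_seq, guides[0].protospacer, CFD)[0] == \
        d.plan.residual_max_cfd


# --- trimming ---------------------------------------------------------------

def _genome_with_run(offset_from_payload, run="A" * 12, seed=29):
    """Chromosome whose 5' arm contains one homopolymer at a chosen distance
    from the payload junction (insertion gap at 1000, arm 500)."""
    bg = _background(3000, seed=seed)
    start = 1000 - offset_from_payload - len(run)
    seq = bg[:start] + run + bg[start + len(run):]
    return GenomeIndex({"c": seq}), start


def test_trim_removes_distal_homopolymer():
    g, run_start = _genome_with_run(450)
    spec = DonorSpec(recoding_level="none", trim_enabled=True, min_arm_len=100)
    d = build_donor(g, "c", 1000, "ATG", spec)
    assert 100 <= d.arm5_len <= 450
    assert not [r for r in d.flags.homopolymers if r.length >= 10]


def test_trim_halts_at_min_arm_len_and_keeps_flag():
    g, run_start = _genome_with_run(50)
    spec = DonorSpec(recoding_level="none", trim_enabled=True, min_arm_len=100)
    d = build_donor(g, "c", 1000, "ATG", spec)
    assert d.arm5_len == 100
    assert [r for r in d.flags.homopolymers if r.length >= 10], \
        "unremovable homopolymer must stay flagged"


def test_trim_noop_without_flags():
    g = GenomeIndex({"c": _background(3000)})
    spec = DonorSpec(recoding_level="none", trim_enabled=True, min_arm_len=100)
    d = build_donor(g, "c", 1500, "ATG", spec)
    assert d.arm5_len == d.arm3_len == 500


def test_trim_never_increases_flags_nor_undershoots_min():
    for off in (30, 120, 260, 430):
        g, _ = _genome_with_run(off, seed=31 + off)
        spec = DonorSpec(recoding_level="none", trim_enabled=True, min_arm_len=100)
        d = build_donor(g, "c", 1000, "ATG", spec)
        untrimmed = build_donor(g, "c", 1000, "ATG",
                                DonorSpec(recoding_level="none"))
        assert d.arm5_len >= 100 and d.arm3_len >= 100
        assert len(d.flags.homopolymers) <= len(untrimmed.flags.homopolymers)


# --- ssODN ------------------------------------------------------------------

def _ssodn_design(payload_len=60, seed=37, **spec_kw):
    g = _donor_genome(seed=seed)
    gap = 1500
    guides = design_guides(g, SpCas9, "c", gap, k=1)
    assert guides
    payload = _background(payload_len, seed=seed + 1)
    spec = DonorSpec(mode="ssODN", recoding_level="none", **spec_kw)
    return build_donor(g, "c", gap, payload, spec, guide=guides[0], cfd_model=CFD), guides[0]


def test_ssodn_total_length_capped_at_default_200():
    d, _ = _ssodn_design(60)
    assert len(d.sequence) <= 200
    assert len(d.payload) == 60
    assert d.arm5_len <= 70 + 20 and d.arm3_len <= 70 + 20  # near-symmetric split
    assert d.arm5_len + d.arm3_len + 60 == len(d.sequence)


def test_ssodn_cap_is_a_fixpoint_below_the_cap():
    from knockin.donor import cap_ssodn

    d, _ = _ssodn_design(60, ssodn_max_len=150)
    assert len(d.sequence) == 150
    again = cap_ssodn(d, 400)  # already under this cap: unchanged
    assert (again.trim5, again.trim3) == (d.trim5, d.trim3)
    assert again.sequence == d.sequence


def test_ssodn_keeps_cut_site_inside_donor():
    d, guide = _ssodn_design(120)
    cd = d.cut_gap_donor
    assert d.trim5 <= cd <= len(d.full_seq) - d.trim3


def test_ssodn_infeasible_cap_names_minimum():
    with pytest.raises(ValueError, match="at least"):
        _ssodn_design(250)


def test_ssodn_payload_never_truncated():
    d, _ = _ssodn_design(150)
    assert d.payload in d.seq_plus


# --- strand polarity --------------------------------------------------------

def test_auto_strand_rule():
    assert select_ssodn_strand(100, 120, "+", None) == "-"   # cut 5' of insert
    assert select_ssodn_strand(140, 120, "+", None) == "+"   # cut 3' of insert
    assert select_ssodn_strand(120, 120, "+", None) == "-"   # non-target default
    assert select_ssodn_strand(120, 120, "-", None) == "+"


def test_target_and_transcript_strand_modes():
    assert select_ssodn_strand(0, 10, "-", None, "target") == "-"
    assert select_ssodn_strand(0, 10, "-", None, "non_target") == "+"
    assert select_ssodn_strand(0, 10, "+", "-", "transcribed") == "+"
    assert select_ssodn_strand(0, 10, "+", "-", "non_transcribed") == "-"
    with pytest.raises(ValueError, match="transcript"):
        select_ssodn_strand(0, 10, "+", None, "transcribed")


def test_strand_rule_antisymmetric_under_mirroring():
    """Reverse-complementing the locus maps (cut, insert, guide strand) to
    (L-cut, L-insert, flipped) and must flip the auto choice."""
    L = 5000
    flip = {"+": "-", "-": "+"}
    for cut, ins, gs in [(100, 130, "+"), (300, 250, "-"), (42, 42, "+"), (42, 42, "-")]:
        fwd = select_ssodn_strand(cut, ins, gs, None)
        mirrored = select_ssodn_strand(L - cut, L - ins, flip[gs], None)
        assert mirrored == flip[fwd]


# --- reconstruction ---------------------------------------------------------

@pytest.mark.parametrize("mode", ["dsDNA", "ssODN"])
def test_reference_reconstruction_with_full_recoding(fx, mode):
    m = fx.models["FIXG2.1"]
    gap = m.insertion_gap("N")
    guides = design_guides(fx.genome, SpCas9, m.chrom, gap, k=1, model=m)
    payload = revcomp("GAAGGTGGCTCTGGA")  # minus-strand gene: genome-oriented
    d = build_donor(
        fx.genome, m.chrom, gap, payload, DonorSpec(mode=mode),
        guide=guides[0], model=m, cfd_model=CFD,
    )
    assert d.reconstruct_reference() == fx.genome.fetch(m.chrom, d.window_start, d.window_end)


def test_effective_arms_exclude_recoded_stretches(fx):
    m = fx.models["FIXG1.1"]
    gap = m.insertion_gap("C")
    guides = design_guides(fx.genome, SpCas9, m.chrom, gap, k=1, model=m)
    d = build_donor(
        fx.genome, m.chrom, gap, "GAAGGTGGCTCT", DonorSpec(recoding_level="full"),
        guide=guides[0], model=m, cfd_model=CFD,
    )
    eff5, eff3 = d.effective_arm_lens
    assert eff5 <= d.arm5_len and eff3 <= d.arm3_len
    if d.plan.mutations:
        assert (eff5, eff3) != (d.arm5_len, d.arm3_len)


def test_translation_preserved_across_randomized_designs(fx):
    """Full recoding never changes the encoded protein (sampled designs)."""
    rng = random.Random(41)
    for _ in range(8):
        tid = rng.choice(["FIXG1.1", "FIXG2.1"])
        m = fx.models[tid]
        gap = m.insertion_gap(rng.choice("NC"))
        guides = design_guides(fx.genome, SpCas9, m.chrom, gap, k=1, model=m)
        if not guides:
            continue
        payload = "".join(rng.choice("ACGT") for _ in range(3 * rng.randint(2, 8)))
        d = build_donor(
            fx.genome, m.chrom, gap, payload, DonorSpec(recoding_level="full"),
            guide=guides[0], model=m, cfd_model=CFD,
        )
        # write the recoded arms back into the chromosome and re-translate
        window = d.plan.apply(fx.genome.fetch(m.chrom, d.window_start, d.window_end)
                              [: d.insert_gap - d.window_start]
                              + payload
                              + fx.genome.fetch(m.chrom, d.insert_gap, d.window_end))
        p5, p3 = d.payload_span
        stripped = window[:p5] + window[p3:]
        chrom_seq = fx.genome.sequences[m.chrom]
        edited = chrom_seq[: d.window_start] + stripped + chrom_seq[d.window_end :]
        g2 = GenomeIndex({m.chrom: edited})
        assert m.protein(g2) == m.protein(fx.genome)
        # audit: stored residual equals an independent re-scan
        assert max_cfd_in_donor(d.full_seq, guides[0].protospacer, CFD)[0] == \
            d.plan.residual_max_cfd
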