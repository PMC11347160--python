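"""CFD scoring, re-cut recoding plans, repair-track recoding, codon logic."""

import itertools
import random
import statistics

import pytest

from knockin.cfd import CFDModel, cfd_score, max_cfd_in_donor
from knockin.recoding import (
    SYNONYMS,
    AA_OF,
    CodonUsageTable,
    DonorContext,
    plan_recut_mutations,
    plan_repair_track_mutations,
    splice_protection_mask,
    synonymous_substitution,
)
from knockin.sequences import revcomp

MODEL = CFDModel.load("SpCas9")
SPACER = "GACGTCTAGCTAGGCTAACT"


def test_cfd_perfect_site_scores_one():
    assert cfd_score(SPACER, SPACER + "AGG", MODEL) == 1.0


def test_cfd_pam_proximal_mismatch_worse_than_distal():
    distal = list(SPACER)
    distal[0] = "C" if distal[0] != "C" else "A"
    proximal = list(SPACER)
    proximal[19] = "C" if proximal[19] != "C" else "A"
    s_d = cfd_score(SPACER, "".join(distal) + "AGG", MODEL)
    s_p = cfd_score(SPACER, "".join(proximal) + "AGG", MODEL)
    assert s_p < s_d


def test_cfd_disrupted_pam_below_threshold():
    assert cfd_score(SPACER, SPACER + "ACC", MODEL) <= 0.03
    assert cfd_score(SPACER, SPACER + "AGA", MODEL) == pytest.approx(0.069444444)


def test_cfd_non_acgt_site_base_uses_minimal_factor():
    site = "N" + SPACER[1:] + "AGG"
    expected = min(
        v for (p, g, _), v in MODEL.mismatch_scores.items()
        if p == 1 and g == SPACER[0]
    )
    assert cfd_score(SPACER, site, MODEL) == pytest.approx(expected)


def test_max_cfd_finds_intact_site_and_is_strand_symmetric():
    rng = random.Random(1)
    pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    donor = pad(30) + SPACER + "TGG" + pad(30)
    score, off, strand = max_cfd_in_donor(donor, SPACER, MODEL)
    assert score == 1.0 and off == 30 and strand == "+"
    score_rc, off_rc, strand_rc = max_cfd_in_donor(revcomp(donor), SPACER, MODEL)
    assert score_rc == 1.0 and strand_rc == "-"
    assert off_rc == 30  # same window, mirrored coordinates


# --- re-cut planning -------------------------------------------------------

CODING_DONOR = "GCT" * 10 + "AGG" + "GCT" * 10   # spacer at [10,30), PAM codon AGG
CODING_SPACER = CODING_DONOR[10:30]


def _coding_ctx(protected=frozenset()):
    codons = [(i, i + 1, i + 2) for i in range(0, len(CODING_DONOR) - 2, 3)]
    return DonorContext(seq=CODING_DONOR, codons=codons, protected=set(protected))


def _protein(ctx, seq):
    from knockin.sequences import translate
    return translate("".join(seq[o] for trip in ctx.codons for o in trip))


def test_recut_noop_when_already_below_threshold():
    ctx = DonorContext(seq="ACGT" * 20)
    plan = plan_recut_mutations(ctx, SPACER, MODEL)
    assert plan.mutations == [] and not plan.above_threshold


def test_recut_prioritizes_pam_and_stays_silent():
    ctx = _coding_ctx()
    plan = plan_recut_mutations(ctx, CODING_SPACER, MODEL)
    assert plan.mutations, "intact site must be recoded"
    assert 30 <= plan.mutations[0].offset < 33, "first mutation in the PAM"
    assert plan.residual_max_cfd < 0.03 and not plan.above_threshold
    assert all(m.mclass == "silent" for m in plan.mutations)
    assert _protein(ctx, plan.apply(CODING_DONOR)) == _protein(ctx, CODING_DONOR)


def test_recut_protospacer_first_priority_starts_in_spacer():
    ctx = _coding_ctx()
    plan = plan_recut_mutations(ctx, CODING_SPACER, MODEL, priority="protospacer_first")
    assert plan.mutations[0].offset < 30
    assert plan.residual_max_cfd < 0.03


def test_recut_protected_pam_falls_back_to_spacer():
    ctx = _coding_ctx(protected={30, 31, 32})
    plan = plan_recut_mutations(ctx, CODING_SPACER, MODEL)
    assert plan.mutations and all(m.offset < 30 for m in plan.mutations)
    # audit with an independent full-donor re-scan
    mutated = plan.apply(CODING_DONOR)
    assert max_cfd_in_donor(mutated, CODING_SPACER, MODEL)[0] == plan.residual_max_cfd
    assert plan.residual_max_cfd < 0.03


def test_recut_infeasible_is_flagged_not_silent():
    """Everything locked: the plan is empty and flagged above threshold."""
    ctx = _coding_ctx(protected=set(range(len(CODING_DONOR))))
    plan = plan_recut_mutations(ctx, CODING_SPACER, MODEL)
    assert plan.above_threshold and plan.mutations == []
    assert plan.residual_max_cfd == 1.0


def _noncoding_ctx(protected=frozenset()):
    rng = random.Random(3)
    pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    donor = pad(15) + SPACER + "TGG" + pad(15)
    return DonorContext(seq=donor, protected=set(protected)), donor


def test_recut_noncoding_uses_transversions():
    ctx, donor = _noncoding_ctx()
    plan = plan_recut_mutations(ctx, SPACER, MODEL)
    assert plan.residual_max_cfd < 0.03
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    assert all((m.ref, m.alt) in pairs for m in plan.mutations)


def test_recut_minimality_vs_exhaustive_search():
    """For plans of <= 3 mutations, no smaller constrained mutation set can
    reach the threshold (exhaustive subset enumeration)."""
    # protect the PAM so a single PAM knock-out is unavailable
    ctx, donor = _noncoding_ctx(protected={35, 36, 37})
    plan = plan_recut_mutations(ctx, SPACER, MODEL)
    k = len(plan.mutations)
    assert 1 <= k <= 3
    assert plan.residual_max_cfd < 0.03
    from knockin.sequences import TRANSVERSION

    allowed = [o for o in range(len(donor)) if ctx.touchable(o)]
    for size in range(1, k):
        for subset in itertools.combinations(allowed, size):
            trial = list(donor)
            for o in subset:
                trial[o] = TRANSVERSION[trial[o]]
            assert max_cfd_in_donor("".join(trial), SPACER, MODEL)[0] >= 0.03, (
                f"smaller plan {subset} beats the greedy plan"
            )


# --- repair track ----------------------------------------------------------

def test_repair_track_empty_when_cut_equals_insert():
    ctx, _ = _noncoding_ctx()
    plan = plan_repair_track_mutations(ctx, 20, 20)
    assert plan.mutations == []


def test_repair_track_noncoding_density_and_purity():
    ctx, donor = _noncoding_ctx()
    plan = plan_repair_track_mutations(ctx, 10, 25)
    assert 1 <= len(plan.mutations) <= 5
    offsets = sorted(m.offset for m in plan.mutations)
    assert all(10 <= o < 25 for o in offsets)
    assert all(b - a >= 3 for a, b in zip(offsets, offsets[1:]))
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    assert all((m.ref, m.alt) in pairs for m in plan.mutations)


def test_repair_track_recodes_codons_but_never_met():
    seq = "ATG" + "CTG" * 4 + "ATG" + "GCT" * 3
    codons = [(i, i + 1, i + 2) for i in range(0, len(seq), 3)]
    ctx = DonorContext(seq=seq, codons=codons)
    plan = plan_repair_track_mutations(ctx, 0, len(seq))
    mutated = plan.apply(seq)
    assert mutated[:3] == "ATG" and mutated[15:18] == "ATG"
    assert mutated != seq
    assert _protein(ctx, mutated) == _protein(ctx, seq)


def test_repair_track_respects_protection():
    ctx, donor = _noncoding_ctx(protected=set(range(10, 18)))
    plan = plan_repair_track_mutations(ctx, 10, 25)
    assert all(m.offset >= 18 for m in plan.mutations)


# --- synonymous substitution ----------------------------------------------

UNIFORM = CodonUsageTable("synthetic", {c: 1 / 64 for c in SYNONYMS})


def _oracle_synonym(codon, usage):
    med = {aa: statistics.median(usage.freq[c] for c in SYNONYMS[codon])
           for aa, codon_ in [(AA_OF[codon], codon)]}[AA_OF[codon]]
    elig = [c for c in SYNONYMS[codon]
            if c != codon and usage.freq[c] >= 7e-3 and usage.freq[c] >= med / 2]
    if not elig:
        return None
    best = sorted(
        elig,
        key=lambda c: (-sum(a != b for a, b in zip(c, codon)), -usage.freq[c], c),
    )
    return best[0]


def test_met_has_no_synonym():
    assert synonymous_substitution("ATG", UNIFORM) is None
    assert synonymous_substitution("TGG", UNIFORM) is None


def test_rare_codon_never_chosen():
    freq = dict(UNIFORM.freq)
    freq["TTA"] = 6.0e-3  # below the 7e-3 floor
    table = CodonUsageTable("synthetic", freq)
    assert synonymous_substitution("CTG", table) != "TTA"
    assert synonymous_substitution("CTG", table) == _oracle_synonym("CTG", table)


def test_half_median_rule_excludes_relatively_rare_codons():
    freq = dict(UNIFORM.freq)
    for c in ("CTT", "CTC", "CTA", "CTG", "TTG"):
        freq[c] = 0.04
    freq["TTA"] = 0.01  # >= 7e-3 but < half the group median
    table = CodonUsageTable("synthetic", freq)
    assert not table.eligible("TTA")
    assert synonymous_substitution("CTG", table) != "TTA"


@pytest.mark.parametrize("codon", ["CTG", "GCT", "AGG", "TAA", "TCG", "AAA"])
def test_substitution_matches_bruteforce_oracle(codon):
    for table in (UNIFORM, CodonUsageTable.load("human")):
        assert synonymous_substitution(codon, table) == _oracle_synonym(codon, table)


def test_substitution_is_maximally_divergent_under_uniform_table():
    got = synonymous_substitution("CTG", UNIFORM)
    max_diff = max(
        sum(a != b for a, b in zip(c, "CTG")) for c in SYNONYMS["CTG"] if c != "CTG"
    )
    assert sum(a != b for a, b in zip(got, "CTG")) == max_diff


# --- splice protection ------------------------------------------------------

def test_splice_mask_covers_gt_ag_and_exon_margin(plus_model):
    m = plus_model
    intron_lo, intron_hi = m.exons[0][1], m.exons[1][0]
    w0, w1 = intron_lo - 50, intron_lo + 50
    mask = splice_protection_mask(m, w0, w1)
    # first two intronic bases (the GT donor motif) and the 6-base window
    for g in range(intron_lo, intron_lo + 6):
        assert g - w0 in mask
    # 3 exonic bases before the junction
    for g in range(intron_lo - 3, intron_lo):
        assert g - w0 in mask
    assert (intron_lo - 4) - w0 not in mask
    assert (intron_lo + 6) - w0 not in mask


def test_splice_mask_empty_without_junctions(plus_model):
    mask = splice_protection_mask(plus_model, 0, 100)
    assert mask == set()


def test_splice_mask_clipped_at_window_edge(plus_model):
    junction = plus_model.exons[0][1]
    mask = splice_protection_mask(plus_model, junction - 200, junction + 3)
    assert mask and max(mask) <= 202  # nothing beyond the window
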