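# Methods

This note records the models, parameter choices and numerical conventions
behind `knockin`, and what its synthetic benchmarks do and do not show.

## Coordinates and cut-site geometry

External interfaces (submission CSV, results CSV, GenBank, GFF3/FASTA) use
1-based inclusive coordinates; internally everything is 0-based half-open.
Insertion points and cut sites are *gap coordinates*: integer g denotes the
boundary between bases g−1 and g, which makes cut-to-insert distances exact
integers with no off-by-one ambiguity. SpCas9 and SpCas9-VQR are modeled as
blunt cutters between spacer positions 17/18 (3 bp 5′ of the PAM).
enAsCas12a cuts staggered distal to its 5′ PAM; the two nicks are collapsed
to a single nominal coordinate after spacer position 18, since only one
number is needed for the distance weight. Cas12a is enumerated and scored
with a 20-nt spacer to match the scoring-table dimensions.

## Guide scoring

Off-target search is an exhaustive scan of every FASTA record, both
strands, for sites within 4 mismatches of the protospacer flanked by a
permissive PAM (SpCas9: NGG/NGA/NAG; VQR: NGA/NGG; Cas12a: TTTN). At the
genome sizes this package targets (fixtures up to ~100 kb) an indexed
aligner buys nothing, and the exhaustive scan is oracle-testable: the test
suite checks it base-by-base against an independent nested-loop
implementation.

Each hit gets the MIT/Hsu single-hit score: the product over mismatch
positions of (1 − w_p) with the published 20-position weight vector
(vendored in `data/mit_hsu_weights.tsv`), times a mean-pairwise-distance
term 1/(((19−d̄)/19)·4+1) for ≥ 2 mismatches, times 1/m², times 100.
Aggregation is 100·100/(100+Σ); the ×100 rescaling puts the score on the
0–100 scale on which the 45/65 weighting thresholds are defined.

The position weight penalizes cuts in the 5′UTR (0.4) and within a junction
neighbourhood (0.1 inside 2 exonic / 6 intronic bp, relaxing linearly to
1.0 over the next 10 bp). The penalized *regions* are principled (promoter-
proximal UTR elements, splice signals); the numeric values are this
package's own calibration, deliberately exposed in
`PositionWeightConfig` because no published values exist to match. 3′UTR
cuts are not penalized. Ranking ties break by cut distance, then
specificity, then leftmost coordinate, so output order is reproducible.

## CFD model and recoding

Re-cut potential uses CFD-style scoring: a per-window product of one factor
per mismatched spacer position and a PAM factor. The SpCas9 PAM factors are
the published CFD PAM values (NGG = 1, NAG = 0.259, NGA = 0.069, ...). The
*mismatch* factor tables shipped here are synthetic stand-ins, generated
from a deterministic positional model (tolerance falling from 0.95 at the
PAM-distal end to 0.04 in the seed; transitions ×1.18, transversions ×0.82)
that reproduces the published qualitative structure; file headers say so
explicitly. The VQR and Cas12a PAM tables are likewise constructed from the
enzymes' known PAM preferences. All thresholds (default 0.03) operate on
scores from these tables, so the recoding machinery is self-consistent and
fully testable; absolute agreement with published per-mismatch values is
not claimed.

Re-cut planning is greedy: re-scan the whole donor (both strands), take the
worst window, apply the single admissible mutation that minimizes the
(global max, window) score pair, repeat. PAM-region mutations are tried
first by default. Admissible mutations are synonymous single-base changes
inside CDS (the new codon must not be rare: usage ≥ 7×10⁻³ and ≥ half the
synonym-group median) and complement transversions (A↔T, G↔C — GC-content
preserving) elsewhere; splice-protected positions (3 exonic + 6 intronic
bases around every junction) and the payload are never touched. Greedy is
not provably minimal, so the suite verifies minimality by exhaustive subset
search on every ≤3-mutation plan it samples, restricting candidates to
windows already at/above threshold (mutations elsewhere cannot lower those
windows' scores — window scores depend only on their own bases).
Infeasibility (e.g. a fully protected window) is a flagged outcome, not an
error.

Repair-track recoding replaces every codon fully inside the cut-to-insert
region with its maximally divergent non-rare synonym (ties: highest usage,
then alphabetical) and places complement transversions in non-coding
stretches with ≥ 2 untouched bases between consecutive mutations, scanning
from the cut toward the insertion. Only the human codon-usage table is
vendored; any `CodonUsageTable` can be injected per design.

## Donors

dsDNA donors default to 500/500 bp arms; synthesis flags follow the three
printed families (homopolymers ≥ 10 A/T or ≥ 6 G/C; global GC > 65 % or
< 25 %; > 52-point GC difference between any two 50-bp windows, stride 1,
not evaluated under 50 bp). Arm trimming removes one flagged feature at a
time from the distal end — cutting to just past the feature's
payload-proximal edge, re-evaluating, repeating — and halts at the minimum
arm length or a clean arm, whichever first; GC flags are report-only since
trimming cannot reliably fix a compositional property. ssODN donors are
capped at 200 nt by trimming whichever arm has more slack, never truncating
the payload or the cut-to-insert region. The auto strand rule (cut 5′ of
insert → minus strand; 3′ → plus; tie → guide non-target strand) is
centralized in `select_ssodn_strand` and covered by a mirror-antisymmetry
property test, so a sign-convention change is a one-line fix. "Transcribed"
strand means the template strand (the complement of the mRNA-sense strand).
Effective arm lengths report the contiguous unrecoded homology measured
from each distal end.

## Genotyping primers

Melting temperatures come from an in-repo nearest-neighbor model (unified
Allawi/SantaLucia parameters, SantaLucia-1998 entropic salt correction with
divalent cations folded in via the von Ahsen equivalent: 50 mM monovalent +
120·√(1.5−0.6) mM, 50 nM primer). The tests require ≤ 0.5 °C agreement with
an independent NN implementation on a frozen reference panel; measured
agreement is exact. Primer-dimer screening reinterprets the Primer3
alignment-score caps as complementary-base counts in the best ungapped
antiparallel alignment (any ≤ 8, 3′-anchored run ≤ 3, for self and pair).
Annealing-site search requires an exact final 3′ base and ≤ 3 mismatches
(fast mode) or ≤ 4 (sensitive). The relaxation ladder is cumulative — ΔTm
+1 °C at attempts 1–3 (3→6 °C), product-size ceiling +80/+300 bp at
attempts 2, 4, 6 with the locus window extended by 40/150 bp per step — the
most literal consistent reading of the overlapping attempt lists, kept in
one function (`relaxed_constraints`) so an alternative schedule is a local
change. Pairs rank by |Tm−60| deviations plus 0.1·|len−20| penalties; up to
three passing pairs are returned with an advisory annealing temperature of
min(Tm)−1 °C.

## Synthetic genomes

`knockin.fixtures` generates the study conditions: seeded uniform-ACGT
background at 50 % GC, genes with ATG…stop CDS (no internal stops), GT…AG
introns and UTRs, and planted ground-truth features (protospacer copies
with chosen mismatches/PAM, homopolymers, GC blocks, duplications, primer
decoys) recorded in a manifest. Standard scales are 6–60 kb chromosomes —
large enough for unique primer design and off-target statistics, small
enough that every search has a brute-force oracle. What these fixtures do
not emulate: repeats and segmental duplications (except when planted),
isochore GC structure, alternative isoforms, SNPs. Passing tests therefore
demonstrate the correctness of the rules and searches, not genome-scale
success rates; quantities that depend on real-genome composition (fractions
of loci with homopolymer-free arms, genome-wide recoding success) are out
of scope here.

## Limitations

No on-target activity prediction (deliberately: activity models are
enzyme- and cell-type-specific); no prime-editing designs; no junction-
specific genotyping strategies; recoding never touches the payload, and
non-coding regulatory elements overlapping the arms may still be disrupted
by recoding — users who care should select `recoding_level: none`.
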