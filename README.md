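# knockin

Design engine for CRISPR/Cas **insertional knock-in** experiments: it picks
the guide RNA, builds the homology-directed-repair (HDR) donor, and designs
the genotyping primers — the three reagents every knock-in needs. It is
aimed at researchers tagging genes (fluorescent proteins, degrons, epitope
tags) or inserting payloads at arbitrary genomic coordinates, and runs
end-to-end on real genome FASTA + Ensembl GFF3 pairs or on the synthetic
mini-genomes it can generate itself — no downloads required.

Supported enzymes: SpCas9 (NGG), SpCas9-VQR (NGA) and enAsCas12a (5′ TTTV).

## The rules it implements

**Guide ranking.** Every protospacer whose cut site lies within ±50 bp of
the insertion point is scored by the product of three weights in [0, 1]:

* *on-target specificity* — each off-target site with up to 4 mismatches and
  a permissive PAM (NGG/NGA/NAG for SpCas9) gets an MIT/Hsu single-hit
  score; these aggregate to S = 100·100/(100 + Σ hits), and the weight is 0
  for S < 45, 1 for S > 65, linear between;
* *cut-to-insert distance* — w = exp(−d²/110), d in bp, so guides cutting
  more than ~20 bp from the insertion are strongly disfavored;
* *position* (optional) — penalties for cuts in the 5′UTR or near splice
  junctions.

**Donor construction and recoding.** The donor is payload + homology arms
(dsDNA: 500 bp arms; ssODN: total capped at 200 nt). If the guide's
protospacer+PAM survives in the donor, the allele can be (re-)cut; the
package computes the CFD (cutting frequency determination) score of every
window on both donor strands and introduces the fewest mutations that push
the maximum below 0.03 — synonymous codon swaps only inside CDS (maximally
divergent, never rare codons, never near splice junctions), complement
transversions elsewhere. "Full" recoding also mutates the cut-to-insert
repair track (≤ 1 base in 3 in non-coding sequence). dsDNA donors are
checked against synthesis constraints (homopolymers ≥ 10 A/T or ≥ 6 G/C,
global GC outside 25–65 %, > 52-point GC skew between 50-bp windows) with
optional arm trimming; ssODN strand polarity follows the strand-annealing
repair preference.

**Genotyping primers.** From a 430-bp (short-read) or 4-kb (long-read)
window around the edit, candidate pairs must satisfy Primer3-style
thermodynamics (Tm 57–63 °C, ΔTm ≤ 3 °C, GC 20–80 %, 18–25 nt), keep both
primers ≥ 100 bp (short) / 1000 bp (long) from the edit site and produce a
250–350 bp (short) / 3300–3700 bp (long) amplicon. Pairs with convergent
annealing sites (≤ 3 mismatches, exact 3′ base) within 6 kb anywhere in the
genome are rejected; failing that, six relaxation attempts loosen ΔTm and
the product-size ceiling before giving up.

## Worked example

`python examples/01_rank_guides.py` builds a synthetic two-exon gene and
ranks SpCas9 guides at its C terminus:

```
insertion site: chr1:4448 (C terminus of DEMO.1)

rank  protospacer           PAM  cut       d   spec   w_spec w_dist w_pos  composite
   1  GAGGGACCGATTTTAATGCC  TGG  4446      2   100.0  1.000  0.964  1.000  0.9643
   2  TGATGCCCAGGCATTAAAAT  CGG  4451      3   100.0  1.000  0.921  1.000  0.9214
   ...
   5  ACGTCTAATTGAACTCTTGA  GGG  4464     16   100.0  1.000  0.098  1.000  0.0976
```

All guides here are perfectly specific (no off-target site within 4
mismatches, S = 100 so w_spec = 1); the ranking is decided by the distance
weight — a cut 2 bp from the insertion scores exp(−4/110) ≈ 0.964, one
16 bp away only 0.098. `examples/02_design_recoded_donor.py` then builds a
1018-nt dsDNA donor for that locus and prints the four silent mutations
(residual max CFD 0.0264 < 0.03) that protect it from re-cutting;
`examples/04_genotyping_primers.py` returns three primer pairs with 259–344
bp products on a unique locus and, on a locus duplicated across
chromosomes, correctly returns none.

The same pipeline is scriptable from the shell:

```bash
knockin fixtures --seed 7 --out fix/
knockin design --genome fix/genome.fa --gff3 fix/annotation.gff3 \
    --submission submission.csv --out out/
```

which writes `results.csv`, a re-submittable parameter echo, and one
annotated GenBank file per donor.

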