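"""Design short-read genotyping primers for an edited locus.

Extracts a 430-bp window around the edit site, filters candidates with
Primer3-style thermodynamic rules (Tm 57-63 C, GC 20-80%, length 18-25 nt,
deltaTm <= 3 C), keeps both primers >= 100 bp from the edit site (outside
typical homology arms), demands a 250-350 bp product, and rejects any pair
with convergent off-target annealing sites within 6 kb anywhere in the
genome. A duplicated locus therefore yields no primers at all.
"""

import random

from knockin import GenomeIndex, design_genotyping_primers

rng = random.Random(77)
chr1 = "".join(rng.choice("ACGT") for _ in range(12000))
genome = GenomeIndex({"chr1": chr1})
edit = 6000

pairs, failure = design_genotyping_primers(genome, "chr1", edit, mode="short")
print(f"unique locus: {len(pairs)} primer pairs")
for i, p in enumerate(pairs, 1):
    print(f"  pair {i} (attempt {p.attempt}): {p.fwd.sequence} / {p.rev.sequence}")
    print(f"    product {p.product_size} bp, Tm {p.fwd.tm:.1f}/{p.rev.tm:.1f} C, "
          f"suggested annealing {p.annealing_temp:.1f} C")

# now duplicate the locus on a second chromosome, as in segmental duplications
dup = GenomeIndex({"chr1": chr1, "chr2": chr1[edit - 800 : edit + 800]})
pairs2, failure2 = design_genotyping_primers(dup, "chr1", edit, mode="short")
print(f"\nduplicated locus: {len(pairs2)} primer pairs")
print(f"  reason: {failure2}")
print("\nEvery candidate pair amplifies the duplicate too, so all are"
      "\nrejected — even after the six constraint-relaxation attempts.")
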