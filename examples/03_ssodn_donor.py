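"""Design a length-capped ssODN donor with automatic strand selection.

ssODN donors are capped at 200 nt total (chemical synthesis limit), the
payload is never truncated, and the strand polarity follows the
strand-annealing repair preference: a cut 5' of the insertion favors the
minus strand, a cut 3' favors the plus strand.
"""

import random

from knockin import CFDModel, DonorSpec, GenomeIndex, SpCas9, build_donor, design_guides

rng = random.Random(5)
genome = GenomeIndex({"c": "".join(rng.choice("ACGT") for _ in range(4000))})
site = 2000
payload = "".join(rng.choice("ACGT") for _ in range(60))

guide = design_guides(genome, SpCas9, "c", site, k=1)[0]
donor = build_donor(
    genome, "c", site, payload, DonorSpec(mode="ssODN", recoding_level="prevent_recut"),
    guide=guide, cfd_model=CFDModel.load(SpCas9),
)
rel = "5' of" if guide.cut_gap < site else ("3' of" if guide.cut_gap > site else "at")
print(f"cut {rel} the insertion site ({guide.distance_to_insert} bp away)")
print(f"ssODN: {len(donor.sequence)} nt total (cap 200), strand {donor.strand}")
print(f"arms {donor.arm5_len}/{donor.arm3_len} nt around a {len(payload)}-nt payload")
print(f"sequence:\n{donor.sequence}")
print("\nThe reported sequence is the single synthesized strand; ordering the"
      "\nfavored polarity measurably improves knock-in at distal cut sites.")
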