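"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import re

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# purine <-> pyrimidine partner used for deterministic transversions;
# the complement transversion preserves GC content.
TRANSVERSION = {"A": "T", "T": "A", "G": "C", "C": "G"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (standard code); trailing partial codon ignored."""
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq, pattern))


def iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[p]}]" for p in pattern))


def expand_iupac(pattern: str) -> list[str]:
    """All concrete ACGT sequences matching an IUPAC pattern."""
    seqs = [""]
    for p in pattern:
        seqs = [s + b for s in seqs for b in IUPAC[p]]
    return seqs


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "GCgc") / len(seq)
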