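"""Cas enzyme definitions: PAM geometry, spacer length, cut-site arithmetic.

Cut sites are "gap" coordinates: integer g is the boundary between bases
g-1 and g. SpCas9 and its VQR variant cut bluntly between spacer positions
17 and 18 (3 bp 5' of the PAM); enAsCas12a cuts staggered distal to the PAM,
collapsed here to a single nominal coordinate after spacer position 18
(counting from the PAM-proximal end). Only one coordinate is needed for the
cut-to-insert distance weight.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CasEnzyme:
    name: str
    pam: str                 # IUPAC pattern of the canonical PAM
    pam_side: str            # "3prime" (Cas9-type) or "5prime" (Cas12a-type)
    spacer_length: int
    offtarget_pams: tuple[str, ...]
    cut_from_pam_proximal: int  # bases between PAM-proximal spacer end and cut

    @property
    def pam_length(self) -> int:
        return len(self.pam)

    def cut_gap(self, spacer_start: int, spacer_end: int, strand: str) -> int:
        """Genomic gap coordinate of the cut for a spacer at [start, end)."""
        d = self.cut_from_pam_proximal
        if self.pam_side == "3prime":
            return spacer_end - d if strand == "+" else spacer_start + d
        return spacer_start + d if strand == "+" else spacer_end - d


SpCas9 = CasEnzyme("SpCas9", "NGG", "3prime", 20, ("NGG", "NGA", "NAG"), 3)
SpCas9_VQR = CasEnzyme("SpCas9-VQR", "NGA", "3prime", 20, ("NGA", "NGG"), 3)
enAsCas12a = CasEnzyme("enAsCas12a", "TTTV", "5prime", 20, ("TTTN",), 18)

ENZYMES = {e.name: e for e in (SpCas9, SpCas9_VQR, enAsCas12a)}


def get_enzyme(name: str) -> CasEnzyme:
    if name not in ENZYMES:
        raise KeyError(f"unknown Cas enzyme {name!r}; known: {sorted(ENZYMES)}")
    return ENZYMES[name]
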