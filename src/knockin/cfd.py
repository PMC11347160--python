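"""Cutting Frequency Determination (CFD) scoring of donor re-cut potential.

A CFD score in [0, 1] estimates residual Cas cutting of a site that differs
from the guide's protospacer/PAM: the product of one factor per mismatched
spacer position and one factor for the PAM. The SpCas9 PAM factors are the
published values; the mismatch tables shipped with this package are
synthetic stand-ins (see the data-file headers) with the published
qualitative structure: PAM-proximal (seed) mismatches are most deleterious
and transitions are more tolerated than transversions.

Spacer positions are indexed 1..20 along the protospacer 5'->3'; for
3'-PAM enzymes position 1 is PAM-distal, for 5'-PAM enzymes PAM-proximal.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources

from .enzymes import CasEnzyme, get_enzyme
from .sequences import revcomp

_MISMATCH_FILES = {
    "SpCas9": "cfd_mismatch_spcas9_synthetic.csv",
    "SpCas9-VQR": "cfd_mismatch_spcas9_synthetic.csv",  # variant shares the Cas9 table
    "enAsCas12a": "cfd_mismatch_cas12a_synthetic.csv",
}
_PAM_FILES = {
    "SpCas9": "cfd_pam_spcas9.csv",
    "SpCas9-VQR": "cfd_pam_vqr_synthetic.csv",
    "enAsCas12a": "cfd_pam_cas12a_synthetic.csv",
}


def _read_csv(name: str):
    text = (resources.files("knockin.data") / name).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return list(csv.DictReader(io.StringIO(body)))


@dataclass
class CFDModel:
    enzyme: CasEnzyme
    mismatch_scores: dict[tuple[int, str, str], float]
    pam_scores: dict[str, float]

    @classmethod
    def load(cls, enzyme: CasEnzyme | str) -> "CFDModel":
        if isinstance(enzyme, str):
            enzyme = get_enzyme(enzyme)
        mm = {
            (int(r["position"]), r["guide"], r["site"]): float(r["factor"])
            for r in _read_csv(_MISMATCH_FILES[enzyme.name])
        }
        pam = {r["pam"]: float(r["factor"]) for r in _read_csv(_PAM_FILES[enzyme.name])}
        return cls(enzyme=enzyme, mismatch_scores=mm, pam_scores=pam)

    def pam_factor(self, pam: str) -> float:
        key = pam[1:] if self.enzyme.name in ("SpCas9", "SpCas9-VQR") else pam
        return self.pam_scores.get(key, 0.0)

    def mismatch_factor(self, position: int, guide_base: str, site_base: str) -> float:
        if guide_base == site_base:
            return 1.0
        try:
            return self.mismatch_scores[(position, guide_base, site_base)]
        except KeyError:
            # non-ACGT site base: treat as mismatched with the minimal factor
            vals = [
                v for (p, g, _), v in self.mismatch_scores.items()
                if p == position and g == guide_base
            ]
            return min(vals) if vals else 0.0


def cfd_score(protospacer: str, site: str, model: CFDModel) -> float:
    """CFD of a candidate site against a guide.

    ``site`` carries the PAM on the enzyme's PAM side: spacer+PAM for 3'-PAM
    enzymes, PAM+spacer for Cas12a; both read on the protospacer strand.
    """
    enz = model.enzyme
    n, plen = enz.spacer_length, enz.pam_length
    if len(site) != n + plen:
        raise ValueError(f"site length {len(site)} != spacer+PAM {n + plen}")
    if enz.pam_side == "3prime":
        spacer_site, pam = site[:n], site[n:]
    else:
        pam, spacer_site = site[:plen], site[plen:]
    score = model.pam_factor(pam)
    if score == 0.0:
        return 0.0
    for i, (g, s) in enumerate(zip(protospacer, spacer_site)):
        score *= model.mismatch_factor(i + 1, g, s)
        if score == 0.0:
            break
    return score


def max_cfd_in_donor(
    donor: str, protospacer: str, model: CFDModel
) -> tuple[float, int, str]:
    """Maximum CFD over every spacer+PAM window on both strands of the donor.

    Returns (score, offset of the window start in donor + strand coordinates,
    strand). All positions are considered, including payload and junctions.
    """
    enz = model.enzyme
    total = enz.spacer_length + enz.pam_length
    best = (0.0, 0, "+")
    for strand, seq in (("+", donor), ("-", revcomp(donor))):
        for i in range(len(seq) - total + 1):
            s = cfd_score(protospacer, seq[i : i + total], model)
            if s > best[0]:
                off = i if strand == "+" else len(donor) - (i + total)
                best = (s, off, strand)
    return best
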