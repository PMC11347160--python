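"""Nearest-neighbor DNA melting temperature.

Unified NN parameters (Allawi & SantaLucia 1997/1998 set, the same table
Primer3-class tools use), entropic salt correction 0.368*(N-1)*ln[Na+]
(SantaLucia 1998) with divalent cations folded into an equivalent monovalent
concentration (von Ahsen: [Na+]eq = [Na+] + 120*sqrt([Mg2+]-[dNTP])), and a
fixed primer concentration. Defaults are PCR-like: 50 mM monovalent,
1.5 mM Mg2+, 0.6 mM dNTPs, 50 nM primer.
"""

from __future__ import annotations

import math

# 5'->3' dinucleotide stack -> (dH kcal/mol, dS cal/mol/K)
NN_STACKS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
R = 1.987  # cal/mol/K


def melting_temperature(
    seq: str,
    na_mM: float = 50.0,
    mg_mM: float = 1.5,
    dntp_mM: float = 0.6,
    primer_nM: float = 50.0,
) -> float:
    """Tm in degrees C of a primer against its perfect complement."""
    seq = seq.upper()
    if len(seq) < 2 or any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid primer sequence {seq!r}")
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = INIT_AT if term in "AT" else INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_STACKS[seq[i : i + 2]]
        dh += h
        ds += s
    mon = na_mM
    if mg_mM > dntp_mM:
        mon += 120.0 * math.sqrt(mg_mM - dntp_mM)
    ds += 0.368 * (len(seq) - 1) * math.log(mon * 1e-3)
    return 1000.0 * dh / (ds + R * math.log(primer_nM * 1e-9)) - 273.15
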