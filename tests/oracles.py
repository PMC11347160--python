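"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: plain nested-loop
scans over every window of every strand.
"""

from knockin.sequences import matches_iupac, revcomp


def naive_offtargets(guide, genome, enzyme, max_mm=4):
    """All off-target sites by direct per-window mismatch counting."""
    out = set()
    n, plen = enzyme.spacer_length, enzyme.pam_length
    for chrom, seq in genome.sequences.items():
        for j in range(len(seq) - n + 1):
            for strand in "+-":
                window = seq[j : j + n]
                site = window if strand == "+" else revcomp(window)
                mm = sum(a != b for a, b in zip(guide.protospacer, site))
                if mm > max_mm:
                    continue
                if (enzyme.pam_side == "3prime") == (strand == "+"):
                    pam_plus = seq[j + n : j + n + plen]
                else:
                    pam_plus = seq[j - plen : j] if j >= plen else ""
                if len(pam_plus) != plen:
                    continue
                pam = pam_plus if strand == "+" else revcomp(pam_plus)
                if not any(matches_iupac(pam, p) for p in enzyme.offtarget_pams):
                    continue
                if (chrom, j, strand) == (guide.chrom, guide.start, guide.strand):
                    continue
                out.add((chrom, j, strand, mm))
    return out


def naive_pcr_products(fwd, rev, genome, max_size=6000, max_mm=3):
    """Brute-force in-silico PCR: nested scan for annealing sites with an
    exact 3' base, then all convergent combinations within the size cap."""

    def naive_sites(primer):
        out = []
        L = len(primer)
        for chrom, seq in genome.sequences.items():
            for j in range(len(seq) - L + 1):
                w = seq[j : j + L]
                if sum(a != b for a, b in zip(primer, w)) <= max_mm and w[-1] == primer[-1]:
                    out.append((chrom, j, "+", L))
                wrc = revcomp(w)
                if sum(a != b for a, b in zip(primer, wrc)) <= max_mm and wrc[-1] == primer[-1]:
                    out.append((chrom, j, "-", L))
        return out

    f, r = naive_sites(fwd), naive_sites(rev)
    prods = set()
    for combo, sa, sb in (("fwd+rev", f, r), ("fwd+fwd", f, f), ("rev+rev", r, r)):
        for ca, ja, sta, La in sa:
            for cb, jb, stb, Lb in sb:
                if sta != "+" or stb != "-" or ca != cb:
                    continue
                size = jb + Lb - ja
                if 0 < size <= max_size:
                    prods.add((combo, ca, ja, jb + Lb))
    return prods
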