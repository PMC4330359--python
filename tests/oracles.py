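"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the implementation's code paths: the equilibrium
oracle uses hand-written nested bisection (no scipy), the scanner oracle
its own IUPAC table and position-by-position loop, and the intersection
oracle a quadratic all-pairs sweep.
"""

from __future__ import annotations

# --- four-microstate mass balance by nested bisection -----------------------

def oracle_equilibrium(kd_s, kd_p, omega, d_tot, s_tot, p_tot, iters=200):
    """Free concentrations and microstate fractions by pure bisection."""

    def d_free(s, p):
        return d_tot / (1 + s / kd_s + p / kd_p + omega * s * p / (kd_s * kd_p))

    def p_implied(s, p):
        d = d_free(s, p)
        return p * (1 + d / kd_p + omega * s * d / (kd_s * kd_p))

    def s_implied(s, p):
        d = d_free(s, p)
        return s * (1 + d / kd_s + omega * p * d / (kd_s * kd_p))

    def solve_p(s):
        lo, hi = 0.0, p_tot
        if p_tot == 0:
            return 0.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if p_implied(s, mid) < p_tot:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if s_tot == 0:
        s = 0.0
    else:
        lo, hi = 0.0, s_tot
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if s_implied(mid, solve_p(mid)) < s_tot:
                lo = mid
            else:
                hi = mid
        s = 0.5 * (lo + hi)
    p = solve_p(s)
    d = d_free(s, p)
    f_free = d / d_tot
    f_sox = (s * d / kd_s) / d_tot
    f_pax = (p * d / kd_p) / d_tot
    f_dimer = (omega * s * p * d / (kd_s * kd_p)) / d_tot
    return (s, p, d), (f_free, f_sox, f_pax, f_dimer)


# --- exhaustive composite-motif scan ----------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def oracle_revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def _matches(word, seq, pos):
    return all(seq[pos + i].upper() in _IUPAC[w] for i, w in enumerate(word.upper()))


def oracle_scan(sox, pax, gap, seq, flipped=False, both_strands=True):
    """All (span_start, span_end, strand) composite hits, forward coords."""
    pax_eff = oracle_revcomp(pax) if flipped else pax.upper()
    span = len(sox) + gap + len(pax)
    hits = []
    for pos in range(len(seq) - span + 1):
        if _matches(sox, seq, pos) and _matches(pax_eff, seq, pos + len(sox) + gap):
            hits.append((pos, pos + span, "+"))
    if both_strands:
        rc = oracle_revcomp(seq)
        for pos in range(len(rc) - span + 1):
            if _matches(sox, rc, pos) and _matches(pax_eff, rc, pos + len(sox) + gap):
                start = len(seq) - pos - span
                hits.append((start, start + span, "-"))
    return sorted(hits, key=lambda h: (h[0], h[1], h[2] != "+"))


# --- quadratic interval intersection ----------------------------------------

def oracle_intersect(a, b, min_overlap=1):
    """Co-bound regions from all-pairs intersection spans, then merged.

    a, b: lists of (chrom, start, end).  Returns sorted disjoint regions.
    """
    spans = []
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca != cb:
                continue
            s, e = max(sa, sb), min(ea, eb)
            if e - s >= min_overlap:
                spans.append((ca, s, e))
    spans.sort()
    merged = []
    for chrom, s, e in spans:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged
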