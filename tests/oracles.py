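"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (exhaustive enumeration, published
thermodynamic tables summed by hand) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math
from functools import lru_cache

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_nw_score(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Maximum affine-gap score over ALL global alignments (enumeration).

    An alignment is a path of (diag, up, left) moves; a gap run of length k
    costs gap_open + (k-1)*gap_extend.  Exponential — lengths <= ~7 only.
    """

    best = [-math.inf]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "d")
        if i < len(a):
            g = gap_extend if last == "u" else gap_open
            walk(i + 1, j, score + g, "u")
        if j < len(b):
            g = gap_extend if last == "l" else gap_open
            walk(i, j + 1, score + g, "l")

    walk(0, 0, 0.0, "d")
    return best[0]


def exact_site_search(template: str, primer: str) -> list[tuple[int, str]]:
    """All exact occurrences of primer (+ strand) and its reverse
    complement (- strand) in a linear template, via str.find."""
    rc = "".join(_COMP[c] for c in reversed(primer))
    out = []
    for strand, pat in (("+", primer), ("-", rc)):
        start = template.find(pat)
        while start != -1:
            out.append((start, strand))
            start = template.find(pat, start + 1)
    return sorted(out)


def complementary_run_brute(a: str, b: str) -> int:
    """Longest antiparallel Watson-Crick run between two oligos, by trying
    every pair of run start positions."""
    best = 0
    for i0 in range(len(a)):
        for j0 in range(len(b) - 1, -1, -1):
            t = 0
            while (i0 + t < len(a) and j0 - t >= 0
                   and _COMP[a[i0 + t]] == b[j0 - t]):
                t += 1
            best = max(best, t)
    return best


# SantaLucia (1998) unified nearest-neighbor parameters:
# dH kcal/mol, dS cal/(mol K), 5'->3' dinucleotide over its complement.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def tm_nearest_neighbor(seq: str, na_mM: float = 50.0,
                        oligo_nM: float = 250.0) -> float:
    """Unified NN melting temperature, summed by hand.

    Entropy salt correction 0.368*(N-1)*ln[Na+]; duplex concentration term
    R*ln(CT/2) for non-self-complementary oligos at equal strand
    concentrations.
    """
    s = seq.upper()
    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        inc = _INIT_AT if end in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(s) - 1):
        d = s[i:i + 2]
        if d not in _NN:
            d = "".join(_COMP[c] for c in reversed(d))
        dh += _NN[d][0]
        ds += _NN[d][1]
    ds += 0.368 * (len(s) - 1) * math.log(na_mM / 1000.0)
    ct = (oligo_nM - oligo_nM / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(ct)) - 273.15


def k2p_distance(p: float, q: float) -> float:
    """Kimura two-parameter closed form from transition/transversion
    proportions."""
    return (-0.5 * math.log(1.0 - 2.0 * p - q)
            - 0.25 * math.log(1.0 - 2.0 * q))


@lru_cache(maxsize=None)
def _codon_table2():
    from Bio.Seq import Seq
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                table[a + b + c] = str(Seq(a + b + c).translate(table=2))
    return table


def translate_table2(dna: str) -> str:
    """Codon-by-codon translation using Biopython's table-2 lookup (kept
    separate from the package's own translation loop)."""
    t = _codon_table2()
    return "".join(t[dna[i:i + 3]]
                   for i in range(0, len(dna) - len(dna) % 3, 3))
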