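"""In-silico PCR: binding-site search, amplicon prediction, specificity.

The mismatch model is ungapped: a primer footprint is compared base-by-base
at every template offset on both strands (wrapping the origin on circular
templates).  A site is reported when total mismatches and 3'-terminal
mismatches (within the last ``clamp`` bases of the primer) are both within
tolerance; the defaults (2 total, 0 in the terminal 5 nt) encode the
standard observation that 3' mismatches block polymerase extension.

Product length is inclusive of both primer footprints: forward 5' end to
the reverse primer's 5' end on the sense strand.  Amplicon melt temperature
uses the long-duplex %GC formula and is indicative only (~+/- 2 C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import needleman_wunsch
from .divergence import p_distance
from .genomes import AnnotatedMitogenome, reverse_complement


class PCRError(ValueError):
    pass


@dataclass(frozen=True)
class BindingSite:
    """An ungapped primer footprint on a template strand.

    ``start`` is the 0-based forward-strand position of the footprint's
    leftmost base (modulo template length on circular templates).  On the
    plus strand the primer's 3' end sits at ``start + length - 1``; on the
    minus strand it sits at ``start``.
    """

    template_id: str
    primer_name: str
    strand: str
    start: int
    length: int
    total_mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    sequence: str
    forward_site: BindingSite
    reverse_site: BindingSite
    estimated_melt_celsius: float

    @property
    def product_length_bp(self) -> int:
        return len(self.sequence)


def _template_seq(template) -> tuple[str, str, bool]:
    if isinstance(template, AnnotatedMitogenome):
        return template.sequence.upper(), template.accession, template.circular
    return str(template).upper(), "template", False


def _mismatch_profile(tpl: np.ndarray, primer: np.ndarray, n: int,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-offset total and per-position mismatch counts via shifted slices.

    ``tpl`` may be extended past ``n`` for circular wrap; offsets run over
    [0, n).  Returns (total mismatches, mismatches in first 5, in last 5)
    per offset — the caller picks the 3'-relevant end by strand.
    """
    L = primer.shape[0]
    noffsets = tpl.shape[0] - L + 1
    total = np.zeros(noffsets, dtype=np.int32)
    head = np.zeros(noffsets, dtype=np.int32)
    tail = np.zeros(noffsets, dtype=np.int32)
    for j in range(L):
        mm = (tpl[j:j + noffsets] != primer[j]).astype(np.int32)
        total += mm
        if j < 5:
            head += mm
        if j >= L - 5:
            tail += mm
    return total[:n], head[:n], tail[:n]


def find_binding_sites(template, primer_seq: str, primer_name: str = "primer",
                       max_mismatch: int = 2,
                       max_three_prime_mismatch: int = 0,
                       clamp: int = 5) -> list[BindingSite]:
    """Scan both strands for primer footprints within mismatch tolerance.

    ``template`` is an :class:`AnnotatedMitogenome` or a plain sequence
    (treated as linear).  The 3' clamp counts mismatches within the primer's
    terminal ``clamp`` bases (default 5).
    """
    if max_three_prime_mismatch > max_mismatch:
        raise PCRError("3' mismatch bound exceeds total mismatch bound")
    seq, tid, circular = _template_seq(template)
    p = primer_seq.upper()
    if set(p) - set("ACGT"):
        raise PCRError("primer must be unambiguous ACGT")
    L = len(p)
    if L == 0 or L > len(seq):
        return []
    ext = seq + seq[:L - 1] if circular else seq
    tpl = np.frombuffer(ext.encode(), dtype=np.uint8)
    n = len(seq) if circular else len(seq) - L + 1
    if n <= 0:
        return []
    sites: list[BindingSite] = []
    fwd = np.frombuffer(p.encode(), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(p).encode(), dtype=np.uint8)
    if clamp != 5:
        # general clamp: fall back to recount below
        pass
    for strand, arr in (("+", fwd), ("-", rev)):
        total, head, tail = _mismatch_profile(tpl, arr, n)
        # plus strand: primer 3' end is the footprint's right end;
        # minus strand: the right end of revcomp(primer) is the primer's 5'
        three = tail if strand == "+" else head
        if clamp != 5:
            three = np.zeros_like(total)
            for j in (range(L - clamp, L) if strand == "+" else range(clamp)):
                if 0 <= j < L:
                    three += (tpl[j:j + (tpl.shape[0] - L + 1)][:n]
                              != arr[j]).astype(np.int32)
        ok = np.flatnonzero((total <= max_mismatch)
                            & (three <= max_three_prime_mismatch))
        for s in ok:
            sites.append(BindingSite(
                template_id=tid, primer_name=primer_name, strand=strand,
                start=int(s), length=L, total_mismatches=int(total[s]),
                three_prime_mismatches=int(three[s])))
    return sites


def amplicon_melt_celsius(seq: str, na_mM: float = 50.0) -> float:
    """Long-duplex %GC melt estimate: 81.5 + 0.41*GC% - 675/N + salt term."""
    gc = 100.0 * sum(seq.upper().count(c) for c in "GC") / len(seq)
    return 81.5 + 0.41 * gc - 675.0 / len(seq) + 16.6 * np.log10(na_mM / 1e3)


def predict_amplicons(template, fwd: str, rev: str,
                      size_range: tuple[int, int] = (80, 400),
                      max_mismatch: int = 2,
                      max_three_prime_mismatch: int = 0,
                      ) -> list[AmpliconPrediction]:
    """Pair forward (+ strand) with reverse (- strand) binding sites.

    The product runs from the forward footprint's 5' end to the reverse
    primer's 5' end on the sense strand, inclusive; on circular templates
    products may cross the origin.
    """
    lo, hi = size_range
    if lo > hi or lo < 1:
        raise PCRError("empty product size range")
    seq, tid, circular = _template_seq(template)
    n = len(seq)
    fsites = [s for s in find_binding_sites(template, fwd, "forward",
                                            max_mismatch,
                                            max_three_prime_mismatch)
              if s.strand == "+"]
    rsites = [s for s in find_binding_sites(template, rev, "reverse",
                                            max_mismatch,
                                            max_three_prime_mismatch)
              if s.strand == "-"]
    out: list[AmpliconPrediction] = []
    for fs in fsites:
        for rs in rsites:
            end = rs.start + rs.length      # reverse 5' end + 1, sense coords
            if circular:
                product_len = (end - fs.start) % n
                if product_len == 0:
                    product_len = n
            else:
                product_len = end - fs.start
            if not (lo <= product_len <= hi):
                continue
            if product_len < fs.length + rs.length:
                continue                    # footprints must not overlap
            if circular:
                stop = fs.start + product_len
                product = (seq[fs.start:stop] if stop <= n
                           else seq[fs.start:] + seq[:stop - n])
            else:
                product = seq[fs.start:end]
            out.append(AmpliconPrediction(
                template_id=tid, sequence=product, forward_site=fs,
                reverse_site=rs,
                estimated_melt_celsius=round(amplicon_melt_celsius(product),
                                             1)))
    out.sort(key=lambda a: (a.forward_site.start, a.product_length_bp))
    return out


def specificity_matrix(fwd: str, rev: str,
                       panel: Sequence[AnnotatedMitogenome],
                       target: str,
                       size_range: tuple[int, int] = (80, 400),
                       max_mismatch: int = 2,
                       max_three_prime_mismatch: int = 0,
                       ) -> tuple[pd.DataFrame, bool]:
    """Panel-wide amplification table and the exclusivity verdict.

    Exclusive iff every template that yields >= 1 predicted amplicon
    belongs to the target species, and the target itself amplifies.
    """
    if not panel:
        raise PCRError("empty template panel")
    rows = []
    exclusive = True
    target_amplified = False
    for g in panel:
        products = predict_amplicons(g, fwd, rev, size_range, max_mismatch,
                                     max_three_prime_mismatch)
        is_target = target in (g.species, g.accession)
        amplifies = len(products) > 0
        if amplifies and not is_target:
            exclusive = False
        if amplifies and is_target:
            target_amplified = True
        rows.append({"template": g.accession, "species": g.species,
                     "is_target": is_target, "amplifies": amplifies,
                     "n_products": len(products),
                     "product_lengths": ",".join(
                         str(p.product_length_bp) for p in products)})
    return pd.DataFrame(rows), exclusive and target_amplified


def intraspecific_variability(amplicons: Sequence[str],
                              ) -> tuple[float, np.ndarray]:
    """Max pairwise p-distance (percent) among specimens' amplicons.

    Each pair is globally aligned before the p-distance; returns the
    maximum and the full percent matrix.
    """
    if len(amplicons) < 2:
        raise PCRError("need >= 2 amplicon sequences")
    n = len(amplicons)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = needleman_wunsch(amplicons[i], amplicons[j])
            mat[i, j] = mat[j, i] = 100.0 * p_distance(*aln.rows)
    return float(np.nanmax(mat)), mat
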