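"""Species-specific primer design on a candidate marker alignment.

A *diagnostic position* is an alignment column where the target species'
base differs from the base of every non-target row (rows gapped there are
ignored but counted).  Primer windows are enumerated over the de-gapped
target sequence, constrained on length, GC, melting temperature,
self-structure and cross-dimerisation, and required to cover diagnostic
positions — with at least one in the 3' terminal bases, where a template
mismatch blocks polymerase extension in non-target species.

Melting temperatures offer three models: Wallace's 2AT+4GC rule, the
GC/salt-adjusted formula 81.5 + 0.41*GC% - 675/N + 16.6*log10[Na+], and
unified nearest-neighbor thermodynamics (default; Biopython's
implementation with configurable monovalent-cation and oligo
concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .align import Alignment
from .genomes import reverse_complement

_UNAMBIG = set("ACGT")


class PrimerError(ValueError):
    pass


def _check_unambiguous(seq: str) -> str:
    s = seq.upper()
    if not s or set(s) - _UNAMBIG:
        raise PrimerError(f"primer sequences must be unambiguous ACGT, got "
                          f"{seq!r}")
    return s


def base_composition(seq: str) -> tuple[int, int, int, int]:
    """(A, T, C, G) counts, case-insensitive."""
    s = _check_unambiguous(seq)
    return (s.count("A"), s.count("T"), s.count("C"), s.count("G"))


def gc_content(seq: str) -> float:
    """GC percentage rounded half-up to one decimal."""
    s = _check_unambiguous(seq)
    frac = 100.0 * (s.count("G") + s.count("C")) / len(s)
    return math.floor(frac * 10 + 0.5) / 10


def melting_temperature(seq: str, model: str = "nearest_neighbor",
                        na_mM: float = 50.0, oligo_nM: float = 250.0,
                        ) -> float:
    """Primer melting temperature in Celsius.

    ``wallace``: 2(A+T) + 4(G+C).  ``gc_salt_adjusted``:
    81.5 + 0.41*GC% - 675/N + 16.6*log10[Na+].  ``nearest_neighbor``
    (default): unified NN thermodynamics at the given monovalent-cation
    (mM) and oligo (nM) concentrations.
    """
    s = _check_unambiguous(seq)
    if model == "wallace":
        a, t, c, g = base_composition(s)
        return float(2 * (a + t) + 4 * (g + c))
    if model == "gc_salt_adjusted":
        gc = (s.count("G") + s.count("C")) / len(s) * 100.0
        return 81.5 + 0.41 * gc - 675.0 / len(s) + 16.6 * math.log10(
            na_mM / 1000.0)
    if model == "nearest_neighbor":
        if len(s) < 8:
            raise PrimerError("nearest-neighbor model needs >= 8 nt")
        return float(_mt.Tm_NN(s, Na=na_mM, dnac1=oligo_nM, dnac2=oligo_nM))
    raise PrimerError(f"unknown Tm model {model!r}")


def _max_complementary_run(a: str, b: str) -> int:
    """Longest ungapped complementary run between a and b over all offsets.

    Computed by exact substring matching of a against reverse_complement(b):
    a run of k complementary bases in the duplex a(5'->3') : b(3'<-5')
    corresponds to a length-k common substring of a and revcomp(b).
    """
    rb = reverse_complement(b)
    best = 0
    n, m = len(a), len(rb)
    for shift in range(-(m - 1), n):
        run = 0
        for i in range(max(0, shift), min(n, m + shift)):
            if a[i] == rb[i - shift]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def _three_prime_run(a: str, b: str) -> int:
    """Longest complementary run anchored at either primer's 3' terminus."""
    rb = reverse_complement(b)
    best = 0
    # runs ending exactly at a's 3' end
    for shift in range(-(len(rb) - 1), len(a)):
        i = len(a) - 1
        j = i - shift
        run = 0
        while i >= 0 and 0 <= j < len(rb) and a[i] == rb[j]:
            run += 1
            i -= 1
            j -= 1
        best = max(best, run)
    # symmetric: runs ending at b's 3' end
    ra = reverse_complement(a)
    for shift in range(-(len(ra) - 1), len(b)):
        i = len(b) - 1
        j = i - shift
        run = 0
        while i >= 0 and 0 <= j < len(ra) and b[i] == ra[j]:
            run += 1
            i -= 1
            j -= 1
        best = max(best, run)
    return best


def cross_dimer_score(fwd: str, rev: str) -> tuple[int, int]:
    """(max complementary run, 3'-anchored run) between two primers."""
    a, b = _check_unambiguous(fwd), _check_unambiguous(rev)
    return _max_complementary_run(a, b), _three_prime_run(a, b)


@dataclass(frozen=True)
class PrimerConstraints:
    """Design thresholds; all are configuration, none hard-coded downstream.

    The paper-style reference design (a 290 bp product) sits inside the
    default product range.  Tm defaults admit pairs spanning wide Tm because
    annealing is set per pair; self/cross-complementarity limits are runs of
    perfectly complementary bases.
    """

    length_range: tuple[int, int] = (18, 32)
    tm_range: tuple[float, float] = (50.0, 80.0)
    max_tm_difference: float = 8.0
    gc_range: tuple[float, float] = (30.0, 70.0)
    product_size_range: tuple[int, int] = (80, 400)
    max_self_complementary_run: int = 6
    max_hairpin_stem: int = 6
    max_cross_complementary_run: int = 6
    max_three_prime_cross_run: int = 4
    min_diagnostic_positions: int = 1
    three_prime_window: int = 5
    tm_model: str = "nearest_neighbor"

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.tm_range, self.gc_range,
                       self.product_size_range):
            if lo > hi:
                raise PrimerError("empty constraint range")


@dataclass(frozen=True)
class PrimerCandidate:
    """An oriented oligo with composition/thermodynamic attributes.

    ``target_start`` is the 0-based position of the window on the de-gapped
    marker (sense strand); reverse primers are written 5'->3' on the
    antisense strand.  ``diagnostic_positions`` are offsets within the
    primer (5'->3') where the target differs from every non-target row.
    """

    name: str
    sequence: str
    orientation: str
    target_start: int
    tm_celsius: float
    diagnostic_positions: tuple[int, ...] = ()

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return base_composition(self.sequence)


def self_structure_flags(seq: str, constraints: PrimerConstraints | None = None,
                         ) -> tuple[int, int, bool]:
    """(max self-dimer run, max hairpin stem, passes) for one oligo.

    Self-dimer: longest complementary run of the sequence against itself in
    any offset.  Hairpin: longest stem formed by a prefix pairing with a
    reverse-complemented suffix across a loop of >= 3 nt.
    """
    c = constraints or PrimerConstraints()
    s = _check_unambiguous(seq)
    dimer = _max_complementary_run(s, s)
    stem = 0
    n = len(s)
    for i in range(n):          # stem start
        for j in range(n - 1, i + 2, -1):   # paired base
            run = 0
            x, y = i, j
            while x < y - 3 and s[x] == reverse_complement(s[y]):
                run += 1
                x += 1
                y -= 1
            stem = max(stem, run)
    ok = dimer <= c.max_self_complementary_run and stem <= c.max_hairpin_stem
    return dimer, stem, ok


def diagnostic_columns(msa: Alignment, target: str) -> dict[int, int]:
    """Map alignment column -> number of non-target rows gapped there, for
    every column where the target base differs from all ungapped non-target
    rows.  Columns where the target itself is gapped/ambiguous never count.
    """
    trow = msa.row(target)
    others = [r for i, r in zip(msa.ids, msa.rows) if i != target]
    if not others:
        raise PrimerError("need at least one non-target row")
    out: dict[int, int] = {}
    for col in range(msa.column_count):
        tb = trow[col]
        if tb not in _UNAMBIG:
            continue
        gapped = 0
        diagnostic = True
        for row in others:
            ob = row[col]
            if ob not in _UNAMBIG:
                gapped += 1
                continue
            if ob == tb:
                diagnostic = False
                break
        if diagnostic and gapped < len(others):
            out[col] = gapped
    return out


@dataclass(frozen=True)
class PrimerPairDesign:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_length: int


def _window_ok(seq: str, c: PrimerConstraints) -> str | None:
    """Constraint check for a single window; returns rejection reason."""
    gc = gc_content(seq)
    if not (c.gc_range[0] <= gc <= c.gc_range[1]):
        return "gc"
    tm = melting_temperature(seq, c.tm_model)
    if not (c.tm_range[0] <= tm <= c.tm_range[1]):
        return "tm"
    dimer, stem, ok = self_structure_flags(seq, c)
    if not ok:
        return "self_structure"
    return None


def design_primer_pairs(marker_msa: Alignment, target: str,
                        constraints: PrimerConstraints | None = None,
                        name_tag: str = "Tgt", max_pairs: int = 20,
                        max_windows_per_orientation: int = 300,
                        ) -> tuple[list[PrimerPairDesign], dict[str, int]]:
    """Enumerate species-specific primer pairs on the marker.

    Windows over the de-gapped target sequence must satisfy all individual
    constraints and carry >= ``min_diagnostic_positions`` diagnostic
    positions with at least one inside the 3' terminal window; forward and
    reverse windows pair when the implied product (inclusive of both
    footprints, measured on the de-gapped target) lies within the size
    range.  Pairs are ranked by (3'-proximal diagnostic count, total
    diagnostic count, |Tm_f - Tm_r|).  Returns the ranked designs plus
    per-constraint rejection counts for diagnosability.

    To keep pairing tractable on highly divergent markers, at most
    ``max_windows_per_orientation`` windows per orientation (the most
    diagnostic ones) enter the pairing stage.
    """
    c = constraints or PrimerConstraints()
    if target not in marker_msa.ids:
        raise PrimerError(f"target {target!r} not in alignment")
    if len(marker_msa.ids) < 3:
        raise PrimerError("need >= 2 non-target rows")
    diag_cols = diagnostic_columns(marker_msa, target)
    trow = marker_msa.row(target)
    # map alignment columns to de-gapped target positions
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(trow):
        if ch != "-":
            col_to_pos[col] = pos
            pos += 1
    seq = trow.replace("-", "")
    diag_pos = sorted(col_to_pos[c0] for c0 in diag_cols if c0 in col_to_pos)

    rejections = {"ambiguous": 0, "gc": 0, "tm": 0, "self_structure": 0,
                  "diagnostic": 0, "three_prime": 0, "product_size": 0,
                  "cross_dimer": 0, "tm_difference": 0}
    w = c.three_prime_window
    fwd_cands: list[tuple[int, int, tuple[int, ...]]] = []
    rev_cands: list[tuple[int, int, tuple[int, ...]]] = []
    lo, hi = c.length_range
    for start in range(0, len(seq) - lo + 1):
        for length in range(lo, min(hi, len(seq) - start) + 1):
            window = seq[start:start + length]
            if set(window) - _UNAMBIG:
                rejections["ambiguous"] += 1
                continue
            inside = tuple(p - start for p in diag_pos
                           if start <= p < start + length)
            if len(inside) < c.min_diagnostic_positions:
                rejections["diagnostic"] += 1
                continue
            # forward primer: 3' end at the window end; reverse primer:
            # 3' end maps to the window start on the sense strand
            fwd_ok = any(off >= length - w for off in inside)
            rev_offsets = tuple(sorted(length - 1 - off for off in inside))
            rev_ok = any(off >= length - w for off in rev_offsets)
            if fwd_ok:
                fwd_cands.append((start, length, inside))
            else:
                rejections["three_prime"] += 1
            if rev_ok:
                rev_cands.append((start, length, rev_offsets))

    def window_rank(win):
        start, length, diag = win
        clamp = sum(1 for o in diag if o >= length - w)
        return (-clamp, -len(diag), start)

    # thermodynamic/composition checks are costly: evaluate in diagnosticity
    # order and stop once enough windows per orientation are accepted
    def evaluate(cands):
        accepted: list[tuple[int, int, tuple[int, ...], float]] = []
        for start, length, diag in sorted(cands, key=window_rank):
            if len(accepted) >= max_windows_per_orientation:
                break
            window = seq[start:start + length]
            reason = _window_ok(window, c)
            if reason:
                rejections[reason] += 1
                continue
            accepted.append((start, length, diag,
                             melting_temperature(window, c.tm_model)))
        return accepted

    fwd_windows = evaluate(fwd_cands)
    rev_windows = evaluate(rev_cands)

    designs: list[tuple[tuple, PrimerPairDesign]] = []
    pmin, pmax = c.product_size_range
    for fs, fl, fdiag, ftm in fwd_windows:
        for rs, rl, rdiag, rtm in rev_windows:
            product = (rs + rl) - fs
            if not (pmin <= product <= pmax) or rs < fs + fl:
                rejections["product_size"] += 1
                continue
            if abs(ftm - rtm) > c.max_tm_difference:
                rejections["tm_difference"] += 1
                continue
            fseq = seq[fs:fs + fl]
            rseq = reverse_complement(seq[rs:rs + rl])
            run, run3 = cross_dimer_score(fseq, rseq)
            if (run > c.max_cross_complementary_run
                    or run3 > c.max_three_prime_cross_run):
                rejections["cross_dimer"] += 1
                continue
            clamp = (sum(1 for o in fdiag if o >= fl - w)
                     + sum(1 for o in rdiag if o >= rl - w))
            key = (-clamp, -(len(fdiag) + len(rdiag)), abs(ftm - rtm),
                   fs, rs)
            designs.append((key, PrimerPairDesign(
                forward=PrimerCandidate(
                    name="F_" + name_tag, sequence=fseq,
                    orientation="forward", target_start=fs, tm_celsius=ftm,
                    diagnostic_positions=fdiag),
                reverse=PrimerCandidate(
                    name="R_" + name_tag, sequence=rseq,
                    orientation="reverse", target_start=rs, tm_celsius=rtm,
                    diagnostic_positions=rdiag),
                product_length=product)))
    designs.sort(key=lambda t: t[0])
    ranked = []
    for i, (_, d) in enumerate(designs[:max_pairs], start=1):
        ranked.append(PrimerPairDesign(
            forward=PrimerCandidate(
                name=f"{i}_F_{name_tag}", sequence=d.forward.sequence,
                orientation="forward", target_start=d.forward.target_start,
                tm_celsius=d.forward.tm_celsius,
                diagnostic_positions=d.forward.diagnostic_positions),
            reverse=PrimerCandidate(
                name=f"{i}_R_{name_tag}", sequence=d.reverse.sequence,
                orientation="reverse", target_start=d.reverse.target_start,
                tm_celsius=d.reverse.tm_celsius,
                diagnostic_positions=d.reverse.diagnostic_positions),
            product_length=d.product_length))
    return ranked, rejections


def primer_report(primers: list[PrimerCandidate]) -> pd.DataFrame:
    """Composition report with the standard publication columns."""
    rows = []
    for p in primers:
        a, t, cc, g = p.counts
        rows.append({"Name": p.name, "Sequence (5'-3')": p.sequence.lower(),
                     "Tm C": round(p.tm_celsius, 1), "CG%": p.gc_percent,
                     "nt": p.length_nt, "A": a, "T": t, "C": cc, "G": g,
                     "diagnostic_positions":
                         ",".join(map(str, p.diagnostic_positions))})
    return pd.DataFrame(rows)


#: The published reference primer set for the Pink dentex NAD2 marker
#: (inputs to the in-silico screening examples; Tm as printed).
REFERENCE_PRIMERS: dict[str, str] = {
    "1_F_Gib": "gcttcttctagccctaggaattacatcaacc",
    "1_R_Gib": "ctttgatatgaagccggtgagtgggggc",
    "2_F_Gib": "gcttcttctagccctaggaattac",
    "2_R_Gib": "ctttgatatgaagccggtgagtg",
}
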