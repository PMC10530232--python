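"""Pairwise and progressive multiple alignment.

The aligner is a classic affine-gap Needleman-Wunsch (Gotoh) with fixed
tie-breaking (diagonal > up > left), used both for pairwise alignment and,
over column-frequency profiles, for progressive MSA along a neighbor-joining
guide tree.  For genome-scale pairwise comparison (~16-17 kb mitogenomes)
an edit-distance global aligner (edlib) provides a fast unit-cost mode; the
divergence statistics downstream are aligner-agnostic consumers of
:class:`Alignment`, and externally produced aligned FASTA is accepted
everywhere an alignment is.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import _nw
from .genomes import read_fasta
from .trees import DistanceMatrix, nj_tree


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Maximisation-convention scores; gap penalties must be <= 0.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be <= 0")


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over IUPAC + '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i:i + 70] + "\n")

    @classmethod
    def read_fasta(cls, source) -> "Alignment":
        pairs = read_fasta(source)
        return cls(ids=tuple(p[0] for p in pairs),
                   rows=tuple(p[1] for p in pairs))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _ops_to_rows(a: str, b: str, ops: np.ndarray) -> tuple[str, str]:
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == _nw.DIAG:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == _nw.UP:
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb)


def needleman_wunsch(a: str, b: str, scheme: ScoringScheme | None = None,
                     band: int = 0,
                     ids: tuple[str, str] = ("a", "b"),
                     ) -> tuple[Alignment, float]:
    """Optimal global alignment under affine-gap scoring.

    ``band`` > 0 restricts the search to a diagonal band of that half-width
    (plus the length difference), trading optimality guarantees for speed on
    near-identical sequences; 0 means the full matrix.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    scheme = scheme or ScoringScheme()
    a, b = a.upper(), b.upper()
    score, ops = _nw.nw_chars(_encode(a), _encode(b), scheme.match,
                              scheme.mismatch, scheme.gap_open,
                              scheme.gap_extend, band)
    ra, rb = _ops_to_rows(a, b, ops)
    return Alignment(ids=ids, rows=(ra, rb)), float(score)


def genome_align(a: str, b: str, ids: tuple[str, str] = ("a", "b"),
                 ) -> Alignment:
    """Fast unit-cost global alignment for genome-length sequences."""
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return Alignment(ids=ids,
                     rows=(nice["query_aligned"], nice["target_aligned"]))


def _aligned_p_distance(ra: str, rb: str) -> float:
    """Raw substitution proportion over gap-free ACGT columns (guide-tree
    distances only; the statistics module owns the public p-distance)."""
    diff = comp = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            comp += 1
            if x != y:
                diff += 1
    return diff / comp if comp else 1.0


def _profile(rows: list[str], symbols: str) -> np.ndarray:
    k = len(symbols)
    idx = {c: i for i, c in enumerate(symbols)}
    ncols = len(rows[0])
    prof = np.zeros((ncols, k), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            if c in idx:
                prof[j, idx[c]] += 1.0
    prof /= len(rows)
    return prof


def _merge(rows_a: list[str], rows_b: list[str], scheme: ScoringScheme,
           symbols: str, band: int) -> list[str]:
    fa = _profile(rows_a, symbols)
    fb = _profile(rows_b, symbols)
    _, ops = _nw.nw_profiles(fa, fb, scheme.match, scheme.mismatch,
                             scheme.gap_open, scheme.gap_extend, band)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    for op in ops:
        if op == _nw.DIAG:
            cols_a.append(i); cols_b.append(j); i += 1; j += 1
        elif op == _nw.UP:
            cols_a.append(i); cols_b.append(None); i += 1
        else:
            cols_a.append(None); cols_b.append(j); j += 1
    for r, row in enumerate(rows_a):
        out_a[r] = "".join(row[c] if c is not None else "-" for c in cols_a)
    for r, row in enumerate(rows_b):
        out_b[r] = "".join(row[c] if c is not None else "-" for c in cols_b)
    return out_a + out_b


def progressive_msa(seqs: list[str], scheme: ScoringScheme | None = None,
                    ids: list[str] | None = None, band: int = 0,
                    ) -> Alignment:
    """Progressive MSA along an NJ guide tree of pairwise p-distances.

    Profiles are merged by profile-profile Needleman-Wunsch with
    column-frequency scoring; output row order equals input order.
    Sequences longer than ~3 kb use the unit-cost genome aligner for the
    guide-tree distance stage.
    """
    if len(seqs) < 2:
        raise AlignmentError("progressive MSA needs at least 2 sequences")
    scheme = scheme or ScoringScheme()
    seqs = [s.upper() for s in seqs]
    names = list(ids) if ids is not None else [f"s{i}" for i in range(len(seqs))]
    if len(names) != len(seqs):
        raise AlignmentError("ids and seqs length mismatch")
    symbols = "".join(sorted(set("".join(seqs)) - {"-"}))

    if len(seqs) == 2:
        aln, _ = needleman_wunsch(seqs[0], seqs[1], scheme, band=band)
        return Alignment(ids=tuple(names), rows=aln.rows)

    n = len(seqs)
    longest = max(len(s) for s in seqs)
    fast_guide = longest > 3000 or band > 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fast_guide:
                pair = genome_align(seqs[i], seqs[j])
                ra, rb = pair.rows
            else:
                pair, _ = needleman_wunsch(seqs[i], seqs[j], scheme, band=band)
                ra, rb = pair.rows
            d[i, j] = d[j, i] = _aligned_p_distance(ra, rb)
    # guide-tree leaf labels are indices to keep duplicates unambiguous
    guide = nj_tree(DistanceMatrix(ids=[str(i) for i in range(n)], values=d))

    def build(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            k = int(node.taxon.label)
            return [k], [seqs[k]]
        children = [build(c) for c in node.child_nodes()]
        order, rows = children[0]
        for sub_order, sub_rows in children[1:]:
            rows = _merge(rows, sub_rows, scheme, symbols, band)
            order = order + sub_order
        return order, rows

    order, rows = build(guide.seed_node)
    by_input = sorted(range(len(order)), key=lambda k: order[k])
    return Alignment(ids=tuple(names),
                     rows=tuple(rows[k] for k in by_input))
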