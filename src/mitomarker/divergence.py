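"""Divergence statistics for barcode-marker ranking.

Given a panel of annotated mitogenomes and one target species, this module
computes the battery of statistics that drives candidate-marker choice:

* whole-genome Hamming dissimilarity (alignment columns that differ,
  counting gap columns as differences);
* per-gene p-distance under pairwise deletion (gap/ambiguous sites
  excluded from numerator and denominator);
* Tamura-Nei (TN93) model-corrected distances, which separate the two
  transition classes (A<->G, C<->T) from transversions under unequal base
  frequencies;
* a neighbor-joining tree on whole-genome TN93 distances, from which the
  target's nearest relative is read (sister taxon);
* variable-site counts under complete deletion (every column containing a
  gap or ambiguity in any row removed first), at nucleotide and amino-acid
  level.

Genes are ranked primarily by their p-distance between the target and its
nearest relative: the discrimination bottleneck is the most similar
species, not the panel average.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Alignment, ScoringScheme, genome_align, progressive_msa
from .genomes import (PCG_ORDER, AnnotatedMitogenome, extract_gene,
                      translate_mito)
from .trees import DistanceMatrix, nearest_leaf, nj_tree

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


def _codes(row: str) -> np.ndarray:
    return np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)


def _valid_mask(codes: np.ndarray, alphabet: np.ndarray) -> np.ndarray:
    return np.isin(codes, alphabet)


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites where either row carries a gap or an ambiguity code are excluded
    from both numerator and denominator.  NaN when no site is comparable.
    """
    a, b = _codes(row_a), _codes(row_b)
    if a.shape != b.shape:
        raise ValueError("rows must have equal (aligned) lengths")
    ok = _valid_mask(a, _NT) & _valid_mask(b, _NT)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((a[ok] != b[ok]).sum() / n)


def hamming_dissimilarity_percent(genome_a, genome_b) -> float:
    """Whole-genome dissimilarity in percent, Fig-2 convention.

    The two genomes are globally aligned; the statistic is
    100 * (mismatch columns + gap columns) / total columns, i.e. indels
    count as differences (unlike p-distance).
    """
    a = genome_a.sequence if isinstance(genome_a, AnnotatedMitogenome) else genome_a
    b = genome_b.sequence if isinstance(genome_b, AnnotatedMitogenome) else genome_b
    if not a or not b:
        raise ValueError("empty genome sequence")
    aln = genome_align(a, b)
    ra, rb = (_codes(r) for r in aln.rows)
    diff = int((ra != rb).sum())          # includes gap columns
    return 100.0 * diff / aln.column_count


def tn93_distance(row_a: str, row_b: str,
                  freqs: Sequence[float] | None = None) -> float:
    """Tamura-Nei (1993) distance between two aligned rows.

    Uses the two transition proportions (P1 purine, P2 pyrimidine), the
    transversion proportion Q, and base frequencies pooled over both rows
    (or ``freqs`` = (piA, piC, piG, piT) when given), with pairwise deletion
    of gap/ambiguous sites.  Returns NaN when a logarithm argument is <= 0
    (saturation) or no site is comparable.
    """
    a, b = _codes(row_a), _codes(row_b)
    if a.shape != b.shape:
        raise ValueError("rows must have equal (aligned) lengths")
    ok = _valid_mask(a, _NT) & _valid_mask(b, _NT)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    a, b = a[ok], b[ok]
    A, C, G, T = (ord(x) for x in "ACGT")
    p1 = float((((a == A) & (b == G)) | ((a == G) & (b == A))).sum()) / n
    p2 = float((((a == C) & (b == T)) | ((a == T) & (b == C))).sum()) / n
    diff = float((a != b).sum()) / n
    q = diff - p1 - p2
    if freqs is None:
        pooled = np.concatenate([a, b])
        pi = np.array([float((pooled == x).sum()) for x in (A, C, G, T)])
        pi /= pi.sum()
    else:
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    if pr <= 0 or py <= 0:
        return float("nan")
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pt * pc / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    terms = 0.0
    for k, p_trans, denom in ((k1, p1, pr), (k2, p2, py)):
        if k > 0:
            arg = 1.0 - p_trans / k - q / (2.0 * denom)
            if arg <= 0:
                return float("nan")
            terms -= k * np.log(arg)
        elif p_trans > 0:
            return float("nan")
    arg = 1.0 - q / (2.0 * pr * py)
    if arg <= 0:
        return float("nan")
    terms -= k3 * np.log(arg)
    return float(terms)


def count_variable_sites(rows: Sequence[str],
                         alphabet: str = "ACGT") -> tuple[int, int]:
    """(variable, total) site counts under complete deletion.

    Every column containing any character outside ``alphabet`` in any row
    (gaps, ambiguities) is removed first; a column is variable when >= 2
    distinct states remain among the rows.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    mat = np.vstack([_codes(r) for r in rows])
    ab = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    keep = np.isin(mat, ab).all(axis=0)
    sub = mat[:, keep]
    total = int(sub.shape[1])
    if total == 0:
        warnings.warn("no complete columns; (0, 0) returned")
        return (0, 0)
    variable = int((sub != sub[0]).any(axis=0).sum())
    return (variable, total)


def pairwise_matrix(alignment: Alignment, metric: str = "p",
                    ) -> DistanceMatrix:
    """Pairwise distance matrix over alignment rows ('p' or 'tn93')."""
    fn = {"p": p_distance, "tn93": tn93_distance}[metric]
    n = len(alignment.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(alignment.rows[i], alignment.rows[j])
    return DistanceMatrix(ids=list(alignment.ids), values=d)


def whole_genome_tree(panel: Sequence[AnnotatedMitogenome]):
    """NJ tree on pairwise whole-genome TN93 distances (species-labelled)."""
    n = len(panel)
    ids = [g.species for g in panel]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = genome_align(panel[i].sequence, panel[j].sequence)
            d[i, j] = d[j, i] = tn93_distance(*aln.rows)
    dm = DistanceMatrix(ids=ids, values=d)
    return nj_tree(dm), dm


def _panel_target(panel: Sequence[AnnotatedMitogenome], target: str,
                  ) -> AnnotatedMitogenome:
    hits = [g for g in panel if target in (g.species, g.accession)]
    if len(hits) != 1:
        raise ValueError(f"target {target!r} matches {len(hits)} panel genomes")
    return hits[0]


def gene_divergence_table(panel: Sequence[AnnotatedMitogenome], target: str,
                          genes: Sequence[str] = PCG_ORDER,
                          scheme: ScoringScheme | None = None,
                          band: int = 0,
                          nearest: str | None = None,
                          amino_acid: bool = True) -> pd.DataFrame:
    """Per-gene divergence battery for the target species.

    For each gene: panel orthologs are multiply aligned; the row reports the
    mean p-distance from the target to every other species, the p-distance
    to the target's nearest relative (sister taxon on the whole-genome TN93
    NJ tree, unless ``nearest`` overrides it), and variable-site counts at
    nucleotide and amino-acid level under complete deletion.  Genes missing
    from some genome are flagged incomplete and computed over the rest.
    """
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 genomes")
    tgt = _panel_target(panel, target)
    if nearest is None:
        if len(panel) == 2:
            nearest = next(g.species for g in panel if g is not tgt)
        else:
            tree, _ = whole_genome_tree(panel)
            nearest = nearest_leaf(tree, tgt.species)
    rows = []
    for gene in genes:
        members, seqs = [], []
        for g in panel:
            try:
                seqs.append(extract_gene(g, gene))
                members.append(g)
            except Exception:
                continue
        complete = len(members) == len(panel)
        if tgt not in members or len(members) < 2:
            rows.append(dict(gene=gene, mean_p_to_panel=np.nan,
                             p_to_nearest=np.nan, nearest_species=nearest,
                             var_nt=0, total_nt=0, var_aa=0, total_aa=0,
                             complete=False))
            continue
        ids = [g.species for g in members]
        msa = progressive_msa(seqs, scheme, ids=ids, band=band)
        trow = msa.row(tgt.species)
        ps = [p_distance(trow, msa.rows[i]) for i, s in enumerate(ids)
              if members[i] is not tgt]
        mean_p = float(np.nanmean(ps)) if ps else np.nan
        p_near = (p_distance(trow, msa.row(nearest))
                  if nearest in ids else np.nan)
        var_nt, total_nt = count_variable_sites(msa.rows)
        if amino_acid:
            prots = [translate_mito(s) for s in seqs]
            aa_msa = progressive_msa(prots, scheme, ids=ids, band=band)
            var_aa, total_aa = count_variable_sites(
                aa_msa.rows, alphabet="ACDEFGHIKLMNPQRSTVWY")
        else:
            var_aa = total_aa = 0
        rows.append(dict(gene=gene, mean_p_to_panel=mean_p,
                         p_to_nearest=p_near, nearest_species=nearest,
                         var_nt=var_nt, total_nt=total_nt,
                         var_aa=var_aa, total_aa=total_aa,
                         complete=complete))
    df = pd.DataFrame(rows)
    df["var_nt_fraction"] = np.where(df.total_nt > 0,
                                     df.var_nt / df.total_nt.clip(lower=1), 0.0)
    # integer-percent presentation columns; raw proportions stay alongside
    df["mean_p_percent"] = (df.mean_p_to_panel * 100).round(0)
    df["p_nearest_percent"] = (df.p_to_nearest * 100).round(0)
    df["var_nt_percent"] = (df.var_nt_fraction * 100).round(0)
    return df


def rank_markers(table: pd.DataFrame) -> tuple[list[str], str]:
    """Order candidate genes; best marker first.

    Primary key: p-distance to the nearest relative (descending); ties by
    mean panel p-distance, then nucleotide variable-site fraction, then
    gene name.  Warns when even the winner shows zero divergence.
    """
    if table.empty:
        raise ValueError("empty divergence table")
    df = table.copy()
    df["_pn"] = df.p_to_nearest.fillna(-1.0)
    df["_mp"] = df.mean_p_to_panel.fillna(-1.0)
    df = df.sort_values(["_pn", "_mp", "var_nt_fraction", "gene"],
                        ascending=[False, False, False, True],
                        kind="mergesort")
    order = df.gene.tolist()
    winner = order[0]
    top = df.iloc[0]
    if not (top._pn > 0 or top._mp > 0):
        warnings.warn(f"winner {winner} shows zero divergence; "
                      "panel may be uninformative")
    return order, winner
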