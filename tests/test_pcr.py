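"""In-silico PCR: binding-site search, amplicons, specificity."""

import numpy as np
import pytest

from mitomarker.genomes import AnnotatedMitogenome, GeneFeature, \
    reverse_complement
from mitomarker.pcr import (PCRError, find_binding_sites,
                            intraspecific_variability, predict_amplicons,
                            specificity_matrix)
from oracles import exact_site_search


def _linear(seq, acc="T1"):
    return AnnotatedMitogenome(acc, "sp", seq, circular=False,
                               features=(GeneFeature("x", 0, len(seq)),))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def test_exact_search_matches_string_oracle(rng):
    """With zero mismatch tolerance the scanner must equal plain substring
    search of the primer and its reverse complement."""
    for _ in range(10):
        tpl = _random_seq(rng, 500)
        primer = _random_seq(rng, 15)
        pos = int(rng.integers(0, 400))
        strand = rng.random() < 0.5
        planted = primer if strand else reverse_complement(primer)
        tpl = tpl[:pos] + planted + tpl[pos + len(planted):]
        sites = find_binding_sites(tpl, primer, max_mismatch=0,
                                   max_three_prime_mismatch=0)
        assert sorted((s.start, s.strand) for s in sites) \
            == exact_site_search(tpl, primer)


def test_mismatch_thresholds(rng):
    tpl = _random_seq(rng, 200)
    primer = tpl[50:75]
    mutated = list(primer)
    for i in (5, 10, 15):   # 3 internal mismatches, none in terminal 5 nt
        mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
    tpl2 = tpl[:50] + "".join(mutated) + tpl[75:]
    # the template now mismatches the primer at 3 positions
    assert find_binding_sites(tpl2, primer, max_mismatch=2) == []
    hits = find_binding_sites(tpl2, primer, max_mismatch=3)
    assert [(h.start, h.total_mismatches) for h in hits] == [(50, 3)]


def test_three_prime_clamp_blocks_terminal_mismatch(rng):
    tpl = _random_seq(rng, 200)
    primer = tpl[100:124]
    bad = primer[:-1] + {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[-1]]
    assert find_binding_sites(tpl, bad, max_mismatch=2,
                              max_three_prime_mismatch=0) == []
    hits = find_binding_sites(tpl, bad, max_mismatch=2,
                              max_three_prime_mismatch=1)
    assert hits and hits[0].three_prime_mismatches == 1


def test_strand_symmetry(rng):
    """Sites of P on T map one-to-one onto sites of revcomp(P) on
    revcomp(T) with mirrored coordinates and flipped strands."""
    tpl = _random_seq(rng, 300)
    primer = tpl[40:60]
    tpl = tpl[:200] + reverse_complement(primer) + tpl[220:]
    n = len(tpl)
    fwd_sites = find_binding_sites(tpl, primer, max_mismatch=1,
                                   max_three_prime_mismatch=1)
    mirror = find_binding_sites(reverse_complement(tpl),
                                reverse_complement(primer),
                                max_mismatch=1, max_three_prime_mismatch=1)
    # revcomp of both template and primer preserves the strand label and
    # mirrors the footprint coordinates
    mapped = sorted((n - (s.start + s.length), s.strand) for s in mirror)
    assert sorted((s.start, s.strand) for s in fwd_sites) == mapped


def test_amplicon_length_on_linear_template(rng):
    """Constructed fixture: forward at 100, reverse complement at 369,
    primer lengths 31/28 -> a single 297 bp product."""
    fwd = _random_seq(rng, 31)
    rev = _random_seq(rng, 28)
    tpl = _random_seq(rng, 1000)
    tpl = tpl[:100] + fwd + tpl[131:]
    tpl = tpl[:369] + reverse_complement(rev) + tpl[397:]
    prods = predict_amplicons(_linear(tpl), fwd, rev, size_range=(80, 400))
    assert len(prods) == 1
    assert prods[0].product_length_bp == 297
    assert prods[0].sequence == tpl[100:397]


def test_amplicon_across_circular_origin(rng):
    fwd = _random_seq(rng, 20)
    rev = _random_seq(rng, 20)
    n = 1000
    tpl = _random_seq(rng, n)
    # forward starts 50 bp before the origin; reverse footprint ends 100
    # bp after it: product = 50 + 100 = 150
    tpl = tpl[:n - 50] + fwd + tpl[n - 30:]
    tpl = tpl[:80] + reverse_complement(rev) + tpl[100:]
    genome = AnnotatedMitogenome("C1", "sp", tpl, circular=True)
    prods = predict_amplicons(genome, fwd, rev, size_range=(80, 400))
    assert [p.product_length_bp for p in prods] == [150]
    assert prods[0].sequence == tpl[n - 50:] + tpl[:100]


def test_rotation_invariance_of_circular_predictions(rng):
    fwd, rev = _random_seq(rng, 20), _random_seq(rng, 20)
    tpl = _random_seq(rng, 800)
    tpl = tpl[:100] + fwd + tpl[120:]
    tpl = tpl[:300] + reverse_complement(rev) + tpl[320:]
    base = AnnotatedMitogenome("R0", "sp", tpl, circular=True)
    products = {p.sequence for p in
                predict_amplicons(base, fwd, rev, (80, 400))}
    for rot in (57, 413, 699):
        rotated = AnnotatedMitogenome(
            "R1", "sp", tpl[rot:] + tpl[:rot], circular=True)
        got = {p.sequence for p in
               predict_amplicons(rotated, fwd, rev, (80, 400))}
        assert got == products


def test_products_rescan_with_zero_mismatches(rng):
    fwd, rev = _random_seq(rng, 22), _random_seq(rng, 22)
    tpl = _random_seq(rng, 600)
    tpl = tpl[:50] + fwd + tpl[72:]
    tpl = tpl[:350] + reverse_complement(rev) + tpl[372:]
    for p in predict_amplicons(_linear(tpl), fwd, rev, (80, 400)):
        assert p.sequence.startswith(fwd)
        assert p.sequence.endswith(reverse_complement(rev))


def test_specificity_trivial_and_engineered_offtarget(rng):
    fwd, rev = _random_seq(rng, 24), _random_seq(rng, 24)
    body = _random_seq(rng, 500)
    target = _linear(body[:60] + fwd + body[84:300]
                     + reverse_complement(rev) + body[324:], acc="TGT")
    target = AnnotatedMitogenome("TGT", "Target sp", target.sequence,
                                 circular=False)
    clean = AnnotatedMitogenome("OFF1", "Other sp", _random_seq(rng, 500),
                                circular=False)
    matrix, exclusive = specificity_matrix(fwd, rev, [target, clean],
                                           "Target sp")
    assert exclusive
    assert matrix.amplifies.tolist() == [True, False]
    # engineered perfect-match off-target flips the verdict
    hot = AnnotatedMitogenome("OFF2", "Other sp 2", target.sequence,
                              circular=False)
    matrix, exclusive = specificity_matrix(fwd, rev, [target, clean, hot],
                                           "Target sp")
    assert not exclusive
    assert matrix.set_index("template").loc["OFF2", "amplifies"]


def test_intraspecific_variability_proportions():
    base = "ACGT" * 73 # 292 -> use 290
    amp = base[:290]
    mutated = amp[:100] + ("C" if amp[100] != "C" else "T") + amp[101:]
    two = list(amp)
    for i in (50, 150):
        two[i] = "C" if two[i] != "C" else "T"
    two = "".join(two)
    mx, mat = intraspecific_variability([amp] * 8 + [mutated] * 2)
    assert mx == pytest.approx(100 / 290, rel=1e-6)
    mx2, _ = intraspecific_variability([amp] * 9 + [two])
    assert mx2 == pytest.approx(200 / 290, rel=1e-6)
    mx0, _ = intraspecific_variability([amp, amp])
    assert mx0 == 0.0
    with pytest.raises(PCRError):
        intraspecific_variability([amp])
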