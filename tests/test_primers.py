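"""Primer design: composition arithmetic, thermodynamics, specificity."""

import pytest

from mitomarker.align import Alignment
from mitomarker.genomes import reverse_complement
from mitomarker.primers import (REFERENCE_PRIMERS, PrimerConstraints,
                                PrimerError, base_composition,
                                cross_dimer_score, design_primer_pairs,
                                diagnostic_columns, gc_content,
                                melting_temperature, primer_report,
                                self_structure_flags)
from oracles import complementary_run_brute, tm_nearest_neighbor


@pytest.mark.parametrize("name,length,gc,counts", [
    ("1_F_Gib", 31, 45.2, (8, 9, 10, 4)),
    ("1_R_Gib", 28, 57.1, (5, 7, 4, 12)),
    ("2_F_Gib", 24, 45.8, (5, 8, 7, 4)),
    ("2_R_Gib", 23, 47.8, (5, 7, 3, 8)),
])
def test_reference_primer_composition(name, length, gc, counts):
    """Length, GC% and A/T/C/G counts of the published marker primers."""
    seq = REFERENCE_PRIMERS[name]
    assert len(seq) == length
    assert gc_content(seq) == gc
    assert base_composition(seq) == counts


def test_gc_and_composition_agree(rng):
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), rng.integers(8, 40)))
        a, t, c, g = base_composition(seq)
        assert a + t + c + g == len(seq)
        assert gc_content(seq) == pytest.approx(100 * (c + g) / len(seq),
                                                abs=0.05)
    assert gc_content("ATAT") == 0.0


def test_ambiguous_primer_rejected():
    with pytest.raises(PrimerError):
        gc_content("ACGN")
    with pytest.raises(PrimerError):
        base_composition("")


def test_wallace_and_salt_adjusted_tm():
    assert melting_temperature("AAAAAAAA", model="wallace") == 16
    assert melting_temperature("GGGGGGGG", model="wallace") == 32
    # formula spot check: 20-mer, 50% GC, 50 mM Na+
    seq = "ACGT" * 5
    expected = 81.5 + 0.41 * 50 - 675 / 20 + 16.6 * (-1.3010299956639813)
    assert melting_temperature(seq, model="gc_salt_adjusted") == pytest.approx(
        expected, abs=1e-6)


def test_nearest_neighbor_tm_against_hand_summed_oracle(rng):
    """The NN model must agree with an independent hand-summed unified
    nearest-neighbor calculation at the same ionic conditions."""
    for seq in list(REFERENCE_PRIMERS.values()) + [
            "".join(rng.choice(list("ACGT"), 22)) for _ in range(5)]:
        ours = melting_temperature(seq)
        ref = tm_nearest_neighbor(seq)
        assert ours == pytest.approx(ref, abs=0.05)
        assert 40 < ours < 80


def test_nearest_neighbor_needs_8nt():
    with pytest.raises(PrimerError):
        melting_temperature("ACGT")


def test_self_structure_examples():
    # palindromic oligo dimerizes with itself over its full length
    run, _, ok = self_structure_flags("ACGTACGT")
    assert run == 8 and not ok
    # A/C-only oligo cannot pair with itself at all
    run, stem, ok = self_structure_flags("ACCCAACC")
    assert run <= 2 and ok
    # poly-A: no A:A pairing exists
    run, _, ok = self_structure_flags("AAAAAAAA")
    assert run == 0 and ok


def test_complementary_runs_match_brute_force(rng):
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), rng.integers(8, 20)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(8, 20)))
        run, _ = cross_dimer_score(a, b)
        assert run == complementary_run_brute(a, b)


def test_cross_dimer_symmetry_and_examples(rng):
    assert cross_dimer_score("AAAA", "TTTT")[0] == 4
    assert cross_dimer_score("AAAA", "AAAA")[0] == 0
    for _ in range(10):
        a = "".join(rng.choice(list("ACGT"), 15))
        b = "".join(rng.choice(list("ACGT"), 15))
        assert cross_dimer_score(a, b) == cross_dimer_score(b, a)


def test_published_pair_passes_default_thresholds():
    c = PrimerConstraints()
    run, run3 = cross_dimer_score(REFERENCE_PRIMERS["1_F_Gib"],
                                  REFERENCE_PRIMERS["1_R_Gib"])
    assert run <= c.max_cross_complementary_run
    assert run3 <= c.max_three_prime_cross_run
    for seq in ("1_F_Gib", "1_R_Gib"):
        _, _, ok = self_structure_flags(REFERENCE_PRIMERS[seq], c)
        assert ok


def _marker_msa(rng, n_rows=5, length=400, diag_at=(150, 380)):
    """Synthetic marker alignment with engineered target-unique columns."""
    base = rng.choice(list("ACGT"), length)
    rows = []
    for r in range(n_rows):
        row = base.copy()
        for i in rng.choice(length, 12, replace=False):
            row[i] = rng.choice(list("ACGT"))
        rows.append(row)
    target = rows[0]
    for col in diag_at:
        others = {rows[r][col] for r in range(1, n_rows)}
        free = [c for c in "ACGT" if c not in others]
        target[col] = free[0]
    return Alignment(ids=tuple(f"sp{r}" for r in range(n_rows)),
                     rows=tuple("".join(r) for r in rows))


def test_identical_rows_yield_no_design_with_diagnosable_rejections():
    rows = ("ACGTACGTACGT" * 10,) * 4
    msa = Alignment(ids=("t", "a", "b", "c"), rows=rows)
    designs, rejections = design_primer_pairs(msa, "t")
    assert designs == []
    assert rejections["diagnostic"] > 0


def test_designed_primers_cover_engineered_columns(rng):
    msa = _marker_msa(rng)
    cols = diagnostic_columns(msa, "sp0")
    assert {150, 380} <= set(cols)
    constraints = PrimerConstraints(product_size_range=(150, 320),
                                    tm_range=(40, 90), gc_range=(20, 80))
    designs, rej = design_primer_pairs(msa, "sp0", constraints)
    assert designs, f"no designs; rejections {rej}"
    for d in designs:
        f, r = d.forward, d.reverse
        # every returned primer re-passes the individual checks
        assert constraints.length_range[0] <= f.length_nt
        assert f.diagnostic_positions and r.diagnostic_positions
        assert any(o >= f.length_nt - constraints.three_prime_window
                   for o in f.diagnostic_positions)
        run, run3 = cross_dimer_score(f.sequence, r.sequence)
        assert run <= constraints.max_cross_complementary_run
        # reverse primer sits on the antisense strand: locating its
        # reverse complement on the marker reproduces the product length
        marker = msa.degapped("sp0")
        rc = reverse_complement(r.sequence)
        rstart = marker.find(rc)
        assert rstart >= 0
        assert (rstart + len(rc)) - f.target_start == d.product_length
        assert constraints.product_size_range[0] <= d.product_length \
            <= constraints.product_size_range[1]


def test_primer_report_columns():
    msa_rng = __import__("numpy").random.default_rng(5)
    msa = _marker_msa(msa_rng)
    designs, _ = design_primer_pairs(
        msa, "sp0", PrimerConstraints(product_size_range=(150, 320),
                                      tm_range=(40, 90), gc_range=(20, 80)))
    report = primer_report([designs[0].forward, designs[0].reverse])
    assert list(report.columns)[:9] == ["Name", "Sequence (5'-3')", "Tm C",
                                        "CG%", "nt", "A", "T", "C", "G"]
    assert report.iloc[0]["nt"] == designs[0].forward.length_nt
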