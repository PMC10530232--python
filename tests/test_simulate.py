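"""Simulator: determinism, model calibration, ground-truth planting."""

import dendropy
import numpy as np
import pytest

from mitomarker.align import Alignment, progressive_msa
from mitomarker.divergence import p_distance, whole_genome_tree
from mitomarker.genomes import MITO_STOP_CODONS, extract_gene, translate_mito
from mitomarker.pcr import specificity_matrix
from mitomarker.primers import PrimerConstraints, design_primer_pairs
from mitomarker.simulate import (SimulationConfig, SimulationError,
                                 default_config, expected_p_distance,
                                 plant_diagnostic_region, simulate_panel)
from mitomarker.trees import same_topology


def test_seed_determinism():
    p1, t1 = simulate_panel(default_config(n_taxa=5, seed=42))
    p2, t2 = simulate_panel(default_config(n_taxa=5, seed=42))
    assert [g.sequence for g in p1] == [g.sequence for g in p2]
    assert t1.newick == t2.newick
    p3, _ = simulate_panel(default_config(n_taxa=5, seed=43))
    assert [g.sequence for g in p3] != [g.sequence for g in p1]


def test_zero_branch_lengths_give_identical_genomes():
    cfg = default_config(n_taxa=4, seed=9)
    for node in cfg.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = 0.0
    panel, _ = simulate_panel(cfg)
    assert len({g.sequence for g in panel}) == 1


def test_invalid_configs_rejected():
    cfg = default_config(n_taxa=3, seed=0)
    with pytest.raises(SimulationError):
        SimulationConfig(tree=cfg.tree, base_freqs=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(SimulationError):
        SimulationConfig(tree=cfg.tree, gene_rate_multipliers={"NAD2": -1})
    with pytest.raises(SimulationError):
        SimulationConfig(tree=cfg.tree, kappa1=0)


def test_realized_divergence_matches_closed_form():
    """Two taxa separated by 0.2 expected substitutions/site: the realized
    proportion of differing sites must match the TN93 closed-form
    expectation within Monte-Carlo error over 10 replicates."""
    tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
    expected = expected_p_distance(0.2)
    vals = []
    for seed in range(10):
        cfg = SimulationConfig(tree=tree, seed=seed)
        panel, _ = simulate_panel(cfg)
        a = extract_gene(panel[0], "COI")
        b = extract_gene(panel[1], "COI")
        vals.append(p_distance(a, b))
    mean = float(np.mean(vals))
    # MC standard error ~ sqrt(p(1-p)/(n*reps)) ~ 0.003; stop-codon
    # rejection biases coding sites slightly downward
    assert mean == pytest.approx(expected, abs=0.015)


def test_divergence_monotone_in_branch_length():
    means = []
    for t in (0.02, 0.08, 0.25):
        tree = dendropy.Tree.get(data=f"(A:{t / 2},B:{t / 2});",
                                 schema="newick")
        ps = []
        for seed in range(3):
            panel, _ = simulate_panel(SimulationConfig(tree=tree, seed=seed))
            ps.append(p_distance(extract_gene(panel[0], "NAD5"),
                                 extract_gene(panel[1], "NAD5")))
        means.append(np.mean(ps))
    assert means[0] < means[1] < means[2]


def test_no_internal_stops_in_simulated_genes(panel8):
    panel, _ = panel8
    for g in panel[:3]:
        for gene in ("NAD2", "COI", "NAD6"):
            _, stops = translate_mito(extract_gene(g, gene), with_flags=True)
            assert stops == ()


def test_tree_recovery_from_simulated_panels():
    """NJ on whole-genome TN93 distances recovers the generating topology
    (internal branches >= 0.02 by construction)."""
    hits = 0
    for seed in (1, 2, 3):
        cfg = default_config(n_taxa=6, seed=seed)
        panel, truth = simulate_panel(cfg)
        tree, _ = whole_genome_tree(panel)
        hits += same_topology(tree, truth.tree)
    assert hits >= 2


def test_planted_sites_drive_design_and_specificity():
    """On an otherwise-uninformative panel, two planted target-unique sites
    290 bp apart are the only possible primer anchors: every design must
    cover them and the resulting pair amplifies the target exclusively."""
    cfg = default_config(n_taxa=5, seed=17)
    for node in cfg.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = 0.0
    panel, _ = simulate_panel(cfg)
    target = panel[0].species
    planted = plant_diagnostic_region(panel, target, "NAD2",
                                      offsets=(120, 410))
    seqs = [extract_gene(g, "NAD2") for g in planted]
    msa = progressive_msa(seqs, ids=[g.species for g in planted], band=16)
    constraints = PrimerConstraints(product_size_range=(260, 320),
                                    tm_range=(40, 90), gc_range=(20, 80))
    designs, rej = design_primer_pairs(msa, target, constraints)
    assert designs, f"no designs; rejections {rej}"
    best = designs[0]
    assert 260 <= best.product_length <= 320
    # windows must cover the planted offsets
    f, r = best.forward, best.reverse
    assert f.target_start <= 120 < f.target_start + f.length_nt
    assert r.target_start <= 410 < r.target_start + r.length_nt
    matrix, exclusive = specificity_matrix(
        f.sequence, r.sequence, planted, target, size_range=(260, 320))
    assert exclusive


def test_plant_zero_sites_yields_no_design():
    cfg = default_config(n_taxa=4, seed=9)
    for node in cfg.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length = 0.0
    panel, _ = simulate_panel(cfg)   # identical genomes: no diagnostics
    seqs = [extract_gene(g, "NAD2") for g in panel]
    msa = Alignment(ids=tuple(g.species for g in panel), rows=tuple(seqs))
    designs, rejections = design_primer_pairs(msa, panel[0].species)
    assert designs == []
    assert rejections["diagnostic"] > 0


def test_plant_requested_base_conflict_raises():
    cfg = default_config(n_taxa=4, seed=9)
    panel, _ = simulate_panel(cfg)
    others = [extract_gene(g, "NAD2")[5] for g in panel[1:]]
    with pytest.raises(SimulationError):
        plant_diagnostic_region(panel, panel[0].species, "NAD2",
                                offsets=(5,), bases=(others[0],))


def test_minus_strand_gene_is_simulated_in_coding_frame(panel8):
    panel, _ = panel8
    nad6 = extract_gene(panel[0], "NAD6")
    feat = panel[0].feature_by_name("NAD6")
    assert feat.strand == "-"
    assert nad6[-3:] in MITO_STOP_CODONS or len(nad6) % 3 != 0
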