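"""Synthetic mitogenome panels with known ground truth.

Panels emulate the input of a marker-discovery study: a set of annotated
circular genomes carrying the 13 vertebrate protein-coding genes at
realistic lengths, evolved along a known tree under a Tamura-Nei (TN93)
substitution model with per-gene rate multipliers, assembled in the
canonical vertebrate mitochondrial gene order (NAD6 on the minus strand)
with low-divergence spacer tracts between genes.

Substitutions are simulated by per-site exponential waiting times under the
TN93 rate matrix (exact stochastic simulation), so realized substitution
counts can be audited against the model's closed-form expectation
(:func:`expected_p_distance`).  Coding realism: internal stop codons are
rejection-resampled (the affected codon is re-evolved from its parent
state), keeping amino-acid variability meaningful.  Optional indels are
confined to spacer tracts so gene alignments stay codon-clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genomes import (MITO_STOP_CODONS, PCG_ORDER, AnnotatedMitogenome,
                      GeneFeature, extract_gene, reverse_complement)

#: Default gene lengths (nt): totals typical of sparid mitogenomes.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "NAD1": 975, "NAD2": 1047, "COI": 1566, "COII": 691, "COIII": 786,
    "ATP8": 165, "ATP6": 684, "NAD3": 351, "NAD4L": 297, "NAD4": 1386,
    "NAD5": 1839, "NAD6": 522, "CYTB": 1141,
}

_NTS = np.array(list("ACGT"))
_IDX = {c: i for i, c in enumerate("ACGT")}
_STOPS = {tuple(_IDX[c] for c in s) for s in MITO_STOP_CODONS}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the simulator needs, with study-realistic defaults.

    Branch lengths are expected substitutions/site at rate multiplier 1;
    ``base_freqs`` is (piA, piC, piG, piT); ``kappa1``/``kappa2`` are the
    purine (A<->G) and pyrimidine (C<->T) transition/transversion rate
    ratios (vertebrate mtDNA is strongly transition-biased, pyrimidine
    transitions most of all).  ``indel_rate`` is per spacer site per unit
    branch length; indels never touch coding sequence.
    """

    tree: dendropy.Tree
    seed: int = 0
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    gene_rate_multipliers: dict[str, float] = field(default_factory=dict)
    base_freqs: tuple[float, float, float, float] = (0.28, 0.29, 0.16, 0.27)
    kappa1: float = 6.0
    kappa2: float = 12.0
    indel_rate: float = 0.0
    indel_mean_length: float = 2.0
    spacer_length: int = 30
    spacer_rate_multiplier: float = 0.1

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-8 or min(self.base_freqs) <= 0:
            raise SimulationError("base frequencies must be positive and sum to 1")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise SimulationError("transition/transversion ratios must be > 0")
        for g, m in self.gene_rate_multipliers.items():
            if m <= 0:
                raise SimulationError(f"rate multiplier for {g} must be > 0")
        for g, n in self.gene_lengths.items():
            if n < 6:
                raise SimulationError(f"gene {g} too short ({n} nt)")
        if self.indel_rate < 0 or self.indel_mean_length <= 0:
            raise SimulationError("invalid indel parameters")


def rate_matrix(base_freqs, kappa1: float, kappa2: float) -> np.ndarray:
    """TN93 generator in ACGT order, scaled to one expected sub/site/unit."""
    pa, pc, pg, pt = base_freqs
    pi = np.array([pa, pc, pg, pt])
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = {i, j}
            if pair == {_IDX["A"], _IDX["G"]}:
                k = kappa1
            elif pair == {_IDX["C"], _IDX["T"]}:
                k = kappa2
            else:
                k = 1.0
            Q[i, j] = k * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def expected_p_distance(total_branch_length: float, base_freqs=(0.28, 0.29,
                        0.16, 0.27), kappa1: float = 6.0,
                        kappa2: float = 12.0) -> float:
    """Closed-form expected proportion of differing sites between two
    sequences separated by ``total_branch_length`` at stationarity."""
    Q = rate_matrix(base_freqs, kappa1, kappa2)
    P = expm(Q * total_branch_length)
    pi = np.asarray(base_freqs)
    return float((pi * (1.0 - np.diag(P))).sum())


def _evolve_sites(states: np.ndarray, t: float, Q: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Exact per-site Gillespie simulation for branch length t."""
    out = states.copy()
    rates = -np.diag(Q)
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    jump /= rates[:, None]
    jump_cdf = np.cumsum(jump, axis=1)
    remaining = np.full(out.shape[0], t)
    active = np.arange(out.shape[0])
    while active.size:
        s = out[active]
        dt = rng.exponential(1.0 / rates[s])
        hit = dt < remaining[active]
        idx = active[hit]
        if idx.size:
            u = rng.random(idx.size)
            out[idx] = (u[:, None] < jump_cdf[out[idx]]).argmax(axis=1)
            remaining[idx] -= dt[hit]
        active = idx
    return out


def _fix_internal_stops(child: np.ndarray, parent: np.ndarray, t: float,
                        Q: np.ndarray, rng: np.random.Generator,
                        n_coding: int) -> np.ndarray:
    """Re-evolve codons that became internal stops (rejection resampling)."""
    for _ in range(200):
        bad = [k for k in range(0, n_coding - 3, 3)
               if tuple(child[k:k + 3]) in _STOPS]
        if not bad:
            return child
        for k in bad:
            child[k:k + 3] = _evolve_sites(parent[k:k + 3], t, Q, rng)
    raise SimulationError("stop-codon resampling did not converge")


def _root_gene(length: int, pi: np.ndarray, rng: np.random.Generator,
               ) -> np.ndarray:
    """Root CDS: stationary-frequency codons, no internal stops; genes whose
    length is not a codon multiple end in a declared incomplete stop tail."""
    n_coding = length - length % 3
    seq = rng.choice(4, size=length, p=pi)
    for k in range(0, n_coding - 3, 3):
        while tuple(seq[k:k + 3]) in _STOPS:
            seq[k:k + 3] = rng.choice(4, size=3, p=pi)
    if length % 3 == 0:
        seq[n_coding - 3:n_coding] = [_IDX[c] for c in "TAA"]
    else:
        seq[n_coding:] = _IDX["T"]
    return seq


@dataclass
class GroundTruth:
    """What the generator knows: the true tree and realized divergences."""

    tree: dendropy.Tree
    newick: str
    gene_divergence: pd.DataFrame      # per gene: mean realized pairwise p
    planted: list[dict] = field(default_factory=list)

    def write(self, tree_path, table_path) -> None:
        with open(tree_path, "w") as fh:
            fh.write(self.newick + "\n")
        self.gene_divergence.to_csv(table_path, sep="\t", index=False)


def random_tree(n_taxa: int, rng: np.random.Generator,
                branch_range: tuple[float, float] = (0.02, 0.08),
                ) -> dendropy.Tree:
    """Random binary topology by sequential joins; uniform branch lengths."""
    if n_taxa < 2:
        raise SimulationError("need >= 2 taxa")
    labels = [f"Species_{i + 1:02d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        node.edge.length = float(rng.uniform(*branch_range))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(*branch_range))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
    tree.seed_node = root
    return tree


def default_config(n_taxa: int = 8, seed: int = 0,
                   nad2_multiplier: float = 1.0, **overrides,
                   ) -> SimulationConfig:
    """Study-condition config: a random n-taxon panel; optionally a faster
    NAD2 (the marker-recovery experiments use multiplier 3.0)."""
    rng = np.random.default_rng(seed)
    tree = random_tree(n_taxa, rng)
    mult = {"NAD2": nad2_multiplier} if nad2_multiplier != 1.0 else {}
    return SimulationConfig(tree=tree, seed=seed,
                            gene_rate_multipliers=mult, **overrides)


def marker_recovery_experiment(n_replicates: int = 50, n_taxa: int = 8,
                               multiplier: float = 3.0, gene: str = "NAD2",
                               seed: int = 0, band: int = 24) -> float:
    """Fraction of seeded replicate panels on which the fast gene wins.

    Each replicate simulates a fresh random panel with ``gene`` evolving
    ``multiplier`` times faster, runs the per-gene divergence battery and
    marker ranking, and scores whether ``gene`` ranks first.  The study
    condition for marker-ranking recovery is 50 replicates of 8 taxa at
    multiplier 3.0.
    """
    from .divergence import gene_divergence_table, rank_markers
    wins = 0
    for r in range(n_replicates):
        cfg = default_config(n_taxa=n_taxa, seed=(seed + r) % 2**31,
                             nad2_multiplier=1.0)
        cfg = replace(cfg, gene_rate_multipliers={gene: multiplier})
        panel, _ = simulate_panel(cfg)
        table = gene_divergence_table(panel, panel[0].species, band=band,
                                      amino_acid=False)
        _, winner = rank_markers(table)
        wins += winner == gene
    return wins / n_replicates


def simulate_panel(config: SimulationConfig,
                   ) -> tuple[list[AnnotatedMitogenome], GroundTruth]:
    """Evolve a panel of annotated circular genomes along ``config.tree``.

    Deterministic under a fixed seed.  Returns the genomes (one per leaf,
    in taxon-namespace order) and the ground truth (true tree, per-gene
    realized mean pairwise p-distance).
    """
    rng = np.random.default_rng(config.seed)
    Q = rate_matrix(config.base_freqs, config.kappa1, config.kappa2)
    pi = np.array(config.base_freqs)
    genes = [g for g in PCG_ORDER if g in config.gene_lengths]
    if not genes:
        raise SimulationError("no genes configured")

    # root state: per-gene CDS plus spacers (one spacer before each gene)
    root: dict[str, np.ndarray] = {}
    for g in genes:
        root[g] = _root_gene(config.gene_lengths[g], pi, rng)
        root[f"spacer_{g}"] = rng.choice(4, size=config.spacer_length, p=pi)

    def gene_mult(g: str) -> float:
        if g.startswith("spacer_"):
            return config.spacer_rate_multiplier
        return config.gene_rate_multipliers.get(g, 1.0)

    leaf_states: dict[str, dict[str, np.ndarray]] = {}

    def walk(node, state: dict[str, np.ndarray]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            new: dict[str, np.ndarray] = {}
            for g, parent_seq in state.items():
                if t == 0:
                    evolved = parent_seq.copy()
                else:
                    evolved = _evolve_sites(parent_seq, t * gene_mult(g), Q,
                                            rng)
                    if not g.startswith("spacer_"):
                        n_coding = len(evolved) - len(evolved) % 3
                        evolved = _fix_internal_stops(
                            evolved, parent_seq, t * gene_mult(g), Q, rng,
                            n_coding)
                new[g] = evolved
            if child.is_leaf():
                leaf_states[child.taxon.label] = new
            else:
                walk(child, new)

    walk(config.tree.seed_node, root)

    def spacer_with_indels(arr: np.ndarray, rng_local) -> np.ndarray:
        if config.indel_rate <= 0:
            return arr
        # depth proxy: apply indels once per leaf at the tree height scale
        height = max((leaf.distance_from_root()
                      for leaf in config.tree.leaf_node_iter()), default=0.0)
        n_events = rng_local.poisson(config.indel_rate * arr.size * height)
        out = arr
        for _ in range(n_events):
            ln = 1 + rng_local.poisson(config.indel_mean_length - 1)
            pos = int(rng_local.integers(0, max(1, out.size)))
            if rng_local.random() < 0.5 and out.size > ln:
                out = np.delete(out, slice(pos, pos + ln))
            else:
                ins = rng_local.choice(4, size=ln, p=pi)
                out = np.insert(out, pos, ins)
        return out

    panel: list[AnnotatedMitogenome] = []
    taxa = [t.label for t in config.tree.taxon_namespace]
    for i, label in enumerate(taxa):
        state = leaf_states[label]
        parts: list[str] = []
        feats: list[GeneFeature] = []
        pos = 0
        for g in genes:
            spacer = "".join(_NTS[spacer_with_indels(state[f"spacer_{g}"],
                                                     rng)])
            parts.append(spacer)
            pos += len(spacer)
            seq = "".join(_NTS[state[g]])
            strand = "-" if g == "NAD6" else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            feats.append(GeneFeature(raw_label=g, start=pos,
                                     end=pos + len(seq), strand=strand,
                                     canonical_name=g))
            pos += len(seq)
        panel.append(AnnotatedMitogenome(
            accession=f"SYN{config.seed % 10000:04d}_{i + 1:02d}",
            species=label, sequence="".join(parts), circular=True,
            features=tuple(feats)))

    rows = []
    for g in genes:
        ps = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                a = leaf_states[taxa[i]][g]
                b = leaf_states[taxa[j]][g]
                ps.append(float((a != b).mean()))
        rows.append({"gene": g, "mean_pairwise_p": float(np.mean(ps)),
                     "max_pairwise_p": float(np.max(ps))})
    truth = GroundTruth(tree=config.tree,
                        newick=config.tree.as_string(schema="newick").strip(),
                        gene_divergence=pd.DataFrame(rows))
    return panel, truth


def plant_primer_sites(panel: list[AnnotatedMitogenome], target: str,
                       gene: str, fwd: str, rev: str, product_length: int,
                       offset: int = 0) -> list[AnnotatedMitogenome]:
    """Plant a literal primer pair into the target's gene (synthetic fixture).

    Writes ``fwd`` at gene offset ``offset`` and the reverse complement of
    ``rev`` so that the implied product (inclusive of both footprints, on
    the gene's coding strand) is exactly ``product_length``.  Off-target
    genomes are untouched; with realistic panel divergence they carry no
    binding sites within any small mismatch tolerance, so the expected
    amplicon length and exclusivity are known a priori.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if product_length < len(fwd) + len(rev):
        raise SimulationError("product shorter than the two footprints")
    tgt_idx = [i for i, g in enumerate(panel)
               if target in (g.species, g.accession)]
    if len(tgt_idx) != 1:
        raise SimulationError(f"target {target!r} matches {len(tgt_idx)} genomes")
    k = tgt_idx[0]
    tgt = panel[k]
    feat = tgt.feature_by_name(gene)
    if offset < 0 or offset + product_length > feat.length:
        raise SimulationError("primer sites do not fit inside the gene")
    gene_seq = list(extract_gene(tgt, gene))
    gene_seq[offset:offset + len(fwd)] = fwd
    rc = reverse_complement(rev)
    end = offset + product_length
    gene_seq[end - len(rev):end] = rc
    new_gene = "".join(gene_seq)
    seq = list(tgt.sequence)
    n = len(seq)
    placed = new_gene if feat.strand == "+" else reverse_complement(new_gene)
    for i, ch in enumerate(placed):
        seq[(feat.start + i) % n] = ch
    out = list(panel)
    out[k] = replace(tgt, sequence="".join(seq))
    return out


def plant_diagnostic_region(panel: list[AnnotatedMitogenome], target: str,
                            gene: str, offsets, bases=None,
                            ) -> list[AnnotatedMitogenome]:
    """Engineer target-unique bases at given offsets within a gene.

    For each offset (0-based on the gene's coding strand) the target
    genome's base is replaced by one differing from every non-target panel
    species at that position (auto-chosen unless ``bases`` gives it; a
    requested base equal to an off-target base is an error).  Returns a new
    panel; ground-truth primer windows over these offsets are diagnostic by
    construction.
    """
    tgt_idx = [i for i, g in enumerate(panel)
               if target in (g.species, g.accession)]
    if len(tgt_idx) != 1:
        raise SimulationError(f"target {target!r} matches {len(tgt_idx)} genomes")
    k = tgt_idx[0]
    tgt = panel[k]
    feat = tgt.feature_by_name(gene)
    gene_len = feat.length
    others = [extract_gene(g, gene) for i, g in enumerate(panel) if i != k]
    new_seq = list(tgt.sequence)
    bases = list(bases) if bases is not None else [None] * len(offsets)
    if len(bases) != len(offsets):
        raise SimulationError("offsets and bases length mismatch")
    for off, base in zip(offsets, bases):
        if not (0 <= off < gene_len):
            raise SimulationError(f"offset {off} outside {gene} (len {gene_len})")
        taken = {o[off] for o in others if off < len(o)}
        if base is not None:
            base = base.upper()
            if base in taken:
                raise SimulationError(
                    f"requested base {base} at offset {off} equals an "
                    f"off-target base")
        else:
            free = [c for c in "ACGT" if c not in taken]
            if not free:
                raise SimulationError(
                    f"no base distinguishes the target at offset {off}")
            base = free[0]
        if feat.strand == "+":
            pos = (feat.start + off) % len(tgt.sequence)
            new_seq[pos] = base
        else:
            pos = (feat.end - 1 - off) % len(tgt.sequence)
            new_seq[pos] = reverse_complement(base)
    out = list(panel)
    out[k] = replace(tgt, sequence="".join(new_seq))
    return out
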