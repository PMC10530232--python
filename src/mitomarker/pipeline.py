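"""End-to-end orchestration: panel in -> marker ranking -> primers -> screen.

``run_pipeline`` wires the stages together and writes every number it
reports to a machine-readable file (TSV/JSON/FASTA/Newick) under the output
directory, plus a manifest recording the configuration hash and all
thresholds, so a run is reproducible and auditable.  Re-running with the
same config and inputs is bit-identical: every tie-break downstream is
deterministic and the only randomness (the simulator) is seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .align import ScoringScheme, progressive_msa
from .divergence import (gene_divergence_table, hamming_dissimilarity_percent,
                         rank_markers, whole_genome_tree)
from .genomes import (PCG_ORDER, AnnotatedMitogenome, extract_gene,
                      parse_genbank_multi, write_gene_fasta)
from .pcr import specificity_matrix
from .primers import (PrimerConstraints, design_primer_pairs, primer_report)

log = logging.getLogger("mitomarker")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration mirrored by the CLI flags."""

    input_paths: list[str] = field(default_factory=list)
    target: str = ""
    genes: tuple[str, ...] = PCG_ORDER
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    band: int = 0
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    max_mismatch: int = 2
    max_three_prime_mismatch: int = 0
    output_dir: str = "mitomarker_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = dataclasses.asdict(self.scheme)
        d["constraints"] = dataclasses.asdict(self.constraints)
        return d


@dataclass
class RunReport:
    status: str
    winner: str | None
    ranking: list[str]
    nearest_species: str | None
    exclusive: bool | None
    output_dir: str
    warnings: list[str] = field(default_factory=list)


def load_panel(paths: Sequence[str]) -> list[AnnotatedMitogenome]:
    panel: list[AnnotatedMitogenome] = []
    for p in paths:
        panel.extend(parse_genbank_multi(p))
    return panel


def run_pipeline(config: RunConfig,
                 panel: Sequence[AnnotatedMitogenome] | None = None,
                 ) -> RunReport:
    """Execute the full analysis; any stage failure names the stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    if panel is None:
        try:
            panel = load_panel(config.input_paths)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
    if not any(config.target in (g.species, g.accession) for g in panel):
        raise PipelineError("load", f"target {config.target!r} not in panel")
    log.info("load: %d genomes", len(panel))
    tgt = next(g for g in panel
               if config.target in (g.species, g.accession))

    # whole-genome dissimilarity + tree
    try:
        rows = []
        for g in panel:
            if g is tgt:
                continue
            rows.append({"species": g.species, "accession": g.accession,
                         "hamming_percent": round(
                             hamming_dissimilarity_percent(tgt, g), 2)})
        import pandas as pd
        pd.DataFrame(rows).sort_values("hamming_percent").to_csv(
            out / "hamming.tsv", sep="\t", index=False)
        if len(panel) >= 3:
            tree, dm = whole_genome_tree(panel)
            dm.write_phylip(out / "distances.phylip")
            with open(out / "tree.nwk", "w") as fh:
                fh.write(tree.as_string(schema="newick"))
        log.info("divergence: whole-genome table and tree written")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("whole_genome", str(exc)) from exc

    # per-gene battery and ranking
    try:
        table = gene_divergence_table(panel, config.target,
                                      genes=config.genes,
                                      scheme=config.scheme, band=config.band)
        table.to_csv(out / "gene_divergence.tsv", sep="\t", index=False)
        import warnings as _w
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            ranking, winner = rank_markers(table)
            warnings_log += [str(c.message) for c in caught]
        nearest = table.nearest_species.iloc[0]
        log.info("rank: winner %s (nearest relative %s)", winner, nearest)
    except Exception as exc:
        raise PipelineError("divergence", str(exc)) from exc

    # primer design on the winning marker
    try:
        members = [g for g in panel
                   if winner in {f.canonical_name for f in g.features}]
        seqs = [extract_gene(g, winner) for g in members]
        msa = progressive_msa(seqs, config.scheme,
                              ids=[g.species for g in members],
                              band=config.band)
        designs, rejections = design_primer_pairs(
            msa, tgt.species, config.constraints, name_tag="Tgt")
        if designs:
            primers = [p for d in designs for p in (d.forward, d.reverse)]
            primer_report(primers).to_csv(out / "primers.tsv", sep="\t",
                                          index=False)
            write_gene_fasta([(tgt, f"primer_{p.name}", p.sequence)
                              for p in primers], out / "primers.fasta")
        log.info("design: %d pairs (rejections: %s)", len(designs),
                 {k: v for k, v in rejections.items() if v})
    except Exception as exc:
        raise PipelineError("primer_design", str(exc)) from exc

    # specificity screen of the best pair
    exclusive = None
    if designs:
        try:
            best = designs[0]
            matrix, exclusive = specificity_matrix(
                best.forward.sequence, best.reverse.sequence, panel,
                tgt.species,
                size_range=config.constraints.product_size_range,
                max_mismatch=config.max_mismatch,
                max_three_prime_mismatch=config.max_three_prime_mismatch)
            matrix.to_csv(out / "specificity.tsv", sep="\t", index=False)
            log.info("screen: exclusivity %s", exclusive)
        except Exception as exc:
            raise PipelineError("insilico_pcr", str(exc)) from exc
        status = "ok"
    else:
        status = "no diagnostic sites"
        warnings_log.append("no primer pair satisfied the constraints; "
                            f"rejection counts: {rejections}")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "n_genomes": len(panel),
        "target": tgt.species,
        "nearest_species": nearest,
        "ranking": ranking,
        "winner": winner,
        "n_primer_pairs": len(designs),
        "exclusive": exclusive,
        "status": status,
        "warnings": warnings_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return RunReport(status=status, winner=winner, ranking=ranking,
                     nearest_species=nearest, exclusive=exclusive,
                     output_dir=str(out), warnings=warnings_log)
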