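"""Annotated mitogenome I/O and protein-coding gene extraction.

Vertebrate mitogenomes are circular molecules of ~16-17 kb carrying 13
protein-coding genes (PCGs).  Public annotations name those genes in several
dialects (``ND2``/``NAD2``, ``COX1``/``COI``, ``COB``/``CYTB`` ...); this
module normalises them through an editable synonym table shipped as package
data, represents features in 0-based half-open coordinates on the forward
strand, and extracts genes in coding orientation, including features that
wrap the circular origin.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: Canonical names of the 13 vertebrate mitochondrial protein-coding genes,
#: in canonical genome order (NAD6 lies on the minus strand).
PCG_ORDER: tuple[str, ...] = (
    "NAD1", "NAD2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "NAD3", "NAD4L", "NAD4", "NAD5", "NAD6", "CYTB",
)

PCG_NAMES: frozenset[str] = frozenset(PCG_ORDER)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class GenomeError(ValueError):
    """Malformed record or inconsistent feature request."""


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval in 0-based half-open forward-strand coordinates.

    ``canonical_name`` is one of :data:`PCG_NAMES` or ``None`` when the raw
    annotation label could not be resolved (non-PCG features such as tRNAs
    stay unresolved on purpose).  For features wrapping the circular origin,
    ``end`` may exceed the genome length; positions are taken modulo length.
    """

    raw_label: str
    start: int
    end: int
    strand: str = "+"
    canonical_name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise GenomeError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedMitogenome:
    """A (typically circular) mitochondrial genome with typed gene features."""

    accession: str
    species: str
    sequence: str
    circular: bool = True
    features: tuple[GeneFeature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError("empty genome sequence")
        if not self.accession or not self.species:
            raise GenomeError("accession and species must be non-empty")
        n = len(self.sequence)
        for f in self.features:
            limit = 2 * n if self.circular else n
            if f.end > limit or (not self.circular and f.end > n):
                raise GenomeError(
                    f"feature {f.raw_label!r} [{f.start},{f.end}) outside "
                    f"genome of length {n}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, canonical_name: str) -> GeneFeature:
        hits = [f for f in self.features if f.canonical_name == canonical_name]
        if len(hits) != 1:
            present = sorted({f.canonical_name for f in self.features
                              if f.canonical_name})
            raise GenomeError(
                f"{self.accession}: expected exactly one {canonical_name} "
                f"feature, found {len(hits)}; resolved genes: {present}")
        return hits[0]


# -- gene-name resolution ----------------------------------------------------

def _normalise(label: str) -> str:
    return "".join(ch for ch in label.lower() if ch not in " -_")


def _load_synonyms() -> dict[str, str]:
    text = (resources.files("mitomarker") / "data" / "gene_synonyms.yaml"
            ).read_text()
    table = yaml.safe_load(text)
    lookup: dict[str, str] = {}
    for canonical, synonyms in table.items():
        lookup[_normalise(canonical)] = canonical
        for raw in synonyms:
            lookup[_normalise(str(raw))] = canonical
    return lookup


_SYNONYMS = _load_synonyms()


def resolve_gene_name(raw_label: str) -> str | None:
    """Map an annotation label to a canonical PCG name.

    Returns ``None`` (the explicit "unresolved" marker) for labels outside
    the synonym table — never a guess.
    """
    if not raw_label:
        raise GenomeError("empty gene label")
    return _SYNONYMS.get(_normalise(raw_label))


# -- GenBank / FASTA I/O -----------------------------------------------------

def _feature_from_location(loc, raw_label: str, genome_len: int) -> GeneFeature:
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-wrapping join(x..L, 1..y) -> [x, L + y)
        if (len(parts) == 2 and int(parts[1].end) == genome_len
                and int(parts[0].start) == 0):
            start = int(parts[1].start)
            end = genome_len + int(parts[0].end)
        else:
            raise GenomeError(
                f"unsupported compound location for {raw_label!r}: {loc}")
    else:
        start, end = int(loc.start), int(loc.end)
    return GeneFeature(raw_label=raw_label, start=start, end=end,
                       strand=strand,
                       canonical_name=resolve_gene_name(raw_label))


def _record_to_genome(record: SeqRecord) -> AnnotatedMitogenome:
    if len(record.seq) == 0:
        raise GenomeError(f"record {record.id}: missing ORIGIN sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    species = record.annotations.get("organism", "") or record.description
    features: list[GeneFeature] = []
    seen: set[tuple[int, int, str]] = set()
    # CDS features carry the authoritative PCG intervals; bare 'gene'
    # features are kept only when no CDS covers the same locus.
    for kind in ("CDS", "gene"):
        for feat in record.features:
            if feat.type != kind:
                continue
            quals = feat.qualifiers
            raw = (quals.get("gene") or quals.get("product")
                   or quals.get("note") or [feat.type])[0]
            gf = _feature_from_location(feat.location, raw, len(record.seq))
            key = (gf.start, gf.end, gf.strand)
            dup = key in seen or any(
                gf.canonical_name is not None
                and gf.canonical_name == prev.canonical_name
                for prev in features)
            if not dup:
                seen.add(key)
                features.append(gf)
    return AnnotatedMitogenome(
        accession=record.id, species=species.strip(),
        sequence=str(record.seq).upper(), circular=circular,
        features=tuple(sorted(features, key=lambda f: (f.start, f.end))))


def parse_genbank(source) -> AnnotatedMitogenome:
    """Parse a single GenBank flat-file record into an annotated genome.

    ``source`` may be a path or an open text stream.  GenBank's 1-based
    inclusive coordinates become 0-based half-open; ``complement(...)``
    features get strand ``-``.
    """
    try:
        record = SeqIO.read(source, "genbank")
    except ValueError as exc:
        raise GenomeError(f"malformed GenBank record: {exc}") from exc
    return _record_to_genome(record)


def parse_genbank_multi(source) -> list[AnnotatedMitogenome]:
    """Parse a multi-record GenBank flat file."""
    try:
        return [_record_to_genome(r) for r in SeqIO.parse(source, "genbank")]
    except ValueError as exc:
        raise GenomeError(f"malformed GenBank record: {exc}") from exc


def _genome_to_record(genome: AnnotatedMitogenome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence), id=genome.accession, name=genome.accession[:16],
        description=genome.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
        })
    n = len(genome.sequence)
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.end > n:  # wraps the origin
            loc = CompoundLocation([SimpleLocation(f.start, n, strand),
                                    SimpleLocation(0, f.end - n, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        record.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": [f.raw_label]}))
    return record


def write_genbank(genomes: AnnotatedMitogenome | Iterable[AnnotatedMitogenome],
                  path) -> None:
    """Write one or more genomes as a GenBank flat file (round-trip safe)."""
    if isinstance(genomes, AnnotatedMitogenome):
        genomes = [genomes]
    records = [_genome_to_record(g) for g in genomes]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_gene_fasta(entries: Sequence[tuple[AnnotatedMitogenome, str, str]],
                     path) -> None:
    """Write gene sequences with ``>accession|species|gene`` headers.

    ``entries`` holds (genome, canonical gene name, sequence) triples.
    """
    with open(path, "w") as fh:
        for genome, gene, seq in entries:
            fh.write(f">{genome.accession}|{genome.species}|{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(source) -> list[tuple[str, str]]:
    """Read a (possibly aligned) FASTA file as (id, sequence) pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]


# -- gene extraction and translation ----------------------------------------

def extract_gene(genome: AnnotatedMitogenome, canonical_name: str) -> str:
    """Return a PCG's sequence in coding orientation.

    Minus-strand features are reverse-complemented; features wrapping the
    circular origin are read through the junction.
    """
    f = genome.feature_by_name(canonical_name)
    n = len(genome.sequence)
    if f.end <= n:
        seq = genome.sequence[f.start:f.end]
    else:
        if not genome.circular:
            raise GenomeError(
                f"{canonical_name} wraps the origin of a linear genome")
        seq = genome.sequence[f.start:] + genome.sequence[:f.end - n]
    return reverse_complement(seq) if f.strand == "-" else seq


_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_MITO_CODONS = dict(_MITO_TABLE.forward_table)
for _stop in _MITO_TABLE.stop_codons:  # TAA, TAG, AGA, AGG
    _MITO_CODONS[_stop] = "*"

#: Stop codons of the vertebrate mitochondrial code (NCBI table 2).
MITO_STOP_CODONS: frozenset[str] = frozenset(_MITO_TABLE.stop_codons)


def translate_mito(dna: str, with_flags: bool = False):
    """Translate a CDS under the vertebrate mitochondrial code (table 2).

    A trailing incomplete codon is dropped (mitochondrial CDSs commonly end
    in a partial stop completed by polyadenylation); a terminal stop codon
    closing a non-empty protein is dropped; internal stops are retained as
    ``'*'``; codons containing non-ACGT characters translate to ``'X'``.

    With ``with_flags=True`` returns ``(protein, internal_stop_positions)``.
    """
    if len(dna) < 3:
        raise GenomeError("sequence shorter than one codon")
    dna = dna.upper()
    protein = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        protein.append(_MITO_CODONS.get(codon, "X")
                       if set(codon) <= set("ACGT") else "X")
    if len(protein) > 1 and protein[-1] == "*":
        protein.pop()
    prot = "".join(protein)
    if with_flags:
        return prot, tuple(i for i, aa in enumerate(prot) if aa == "*")
    return prot
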