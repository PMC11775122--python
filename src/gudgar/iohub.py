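"""Readers and writers for the formats the pipeline touches, plus run configuration.

Coordinates are 1-based inclusive everywhere (the GFF3 convention); any
half-open arithmetic is internal and never serialized.  Trees are held as
:class:`dendropy.Tree` objects throughout the package.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("gudgar")

#: the 20 canonical amino acids, alphabetical one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: search alphabet: canonical residues plus the ambiguity code X
PROTEIN_ALPHABET = AMINO_ACIDS + "X"
DNA_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates on its contig plus the protein product."""

    genome_id: str
    contig_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive, >= start
    strand: str  # "+" or "-"
    locus_tag: str
    product: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.protein_seq:
            raise ValueError(f"empty protein sequence for {self.locus_tag}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with documented defaults.

    A serialized config plus the same inputs and seed reproduces a run
    byte-for-byte.  ``subseed(name)`` derives a stable per-module seed.
    """

    seed: int = 0
    # profsearch
    e_cutoff: float = 1e-10
    pseudocount_weight: float = 1.0
    gap_open: float = -11.0
    gap_extend: float = -1.0
    n_shuffles: int = 200
    # pathcall
    grammar: str = "(gudD|garD)&(gudL|garL)&garR"
    excluded_families: str = "garK"
    # neighborhood
    max_gap_bp: int = 500
    min_identity: float = 30.0
    # phylo
    max_gap_fraction: float = 0.97
    conservation_min: float = 0.9
    d_max: float = 10.0
    min_foreign: int = 2
    min_host: int = 4
    host_purity: float = 0.9
    support_min: int = 75
    # abundance
    kmer_size: int = 21
    min_frac: float = 0.5
    min_total_reads: int = 5_000_000

    def subseed(self, module: str) -> int:
        """Deterministic per-module sub-seed: CRC32 of 'module:seed', < 2^31."""
        return zlib.crc32(f"{module}:{self.seed}".encode()) % (2**31)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            setattr(cfg, key, type(current)(value) if not isinstance(current, str) else value)
        return cfg


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path, alphabet: str | None = None) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased, wrapped lines concatenated, order preserved.
    If *alphabet* is given, characters outside it raise a ``ValueError``
    naming the record and the offending character.  An empty file yields an
    empty list.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else title
            seq = seq.upper()
            if alphabet is not None:
                bad = set(seq) - set(alphabet)
                if bad:
                    raise ValueError(
                        f"record {name!r}: character {sorted(bad)[0]!r} outside "
                        f"alphabet {alphabet!r}"
                    )
            records.append((name, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def parse_gff3(path: str | Path, protein_fasta: str | Path) -> list[GeneRecord]:
    """Read CDS features from a GFF3 file and attach protein sequences.

    Gene identity is the ``ID`` attribute, falling back to ``locus_tag``.
    The companion protein FASTA must be keyed by the same identifiers.
    """
    proteins = dict(parse_fasta(protein_fasta, alphabet=PROTEIN_ALPHABET))
    records: list[GeneRecord] = []
    seen: set[tuple[str, str]] = set()
    genome_default = Path(path).stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            contig, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype != "CDS":
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            locus = attr_map.get("ID") or attr_map.get("locus_tag")
            if locus is None:
                raise ValueError(f"{path}: line {lineno}: CDS without ID/locus_tag attribute")
            genome = attr_map.get("genome_id", genome_default)
            key = (genome, locus)
            if key in seen:
                raise ValueError(f"duplicate locus_tag {locus!r} in genome {genome!r}")
            seen.add(key)
            if locus not in proteins:
                raise ValueError(f"CDS {locus!r} has no matching protein in {protein_fasta}")
            records.append(
                GeneRecord(
                    genome_id=genome,
                    contig_id=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    locus_tag=locus,
                    product=attr_map.get("product", ""),
                    protein_seq=proteins[locus],
                )
            )
    return records


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus_tag};genome_id={g.genome_id};product={g.product}"
            fh.write(
                "\t".join(
                    [g.contig_id, "gudgar", "CDS", str(g.start), str(g.end), ".", g.strand, "0", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def _check_parens(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced '(' — {depth} unclosed at end of input")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; missing branch lengths are read as 0.

    Integer internal-node labels are interpreted as bootstrap-style support
    values (0-100) and kept as node labels.
    """
    _check_parens(text)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    return out.getvalue().strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, keep_labels: Iterable[str]) -> dendropy.Tree:
    """Keep only *keep_labels*; collapse unary nodes, summing branch lengths.

    Pairwise path lengths between kept leaves are preserved.
    """
    keep = list(dict.fromkeys(keep_labels))
    if not keep:
        raise ValueError("keep_labels is empty")
    have = set(leaf_labels(tree))
    unknown = [lab for lab in keep if lab not in have]
    if unknown:
        raise ValueError(f"unknown leaf label(s): {', '.join(unknown)}")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    pruned.purge_taxon_namespace()
    for edge in pruned.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return pruned
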