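"""Gene-neighborhood analysis: operon inference, candidate discovery, synteny.

This automates the manual procedure that found the alternative aldolase and
ABC transporter: infer operons as runs of consecutive same-strand genes with
small intergenic gaps, flag co-operonic genes lacking a pathway hit as
candidate pathway members, and compare gene clusters across genomes by
greedy best-identity matching of their proteins (clinker-style links).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gudgar.iohub import GeneRecord
from gudgar.phylo import pairwise_identity
from gudgar.profsearch import HomologyHit


@dataclass
class Operon:
    genome_id: str
    contig_id: str
    strand: str
    genes: list[GeneRecord]  # sorted by start

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def infer_operons(genes: Sequence[GeneRecord], max_gap_bp: int = 500) -> list[Operon]:
    """Partition one genome's genes into operons.

    Genes are ordered positionally along each contig; positionally consecutive
    genes stay in the same operon while they share a strand and the intergenic
    gap (next.start - prev.end - 1) is at most *max_gap_bp*.  A strand change
    always splits, regardless of gap; overlapping same-strand genes count as
    gap 0.  Singleton operons are allowed, and every gene lands in exactly one
    operon.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    genomes = {g.genome_id for g in genes}
    if len(genomes) > 1:
        raise ValueError(f"genes from multiple genomes: {sorted(genomes)}")
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.locus_tag))
    operons: list[Operon] = []
    current: list[GeneRecord] = []
    for gene in ordered:
        if current:
            prev = current[-1]
            gap = max(gene.start - prev.end - 1, 0)
            if (
                gene.contig_id == prev.contig_id
                and gene.strand == prev.strand
                and gap <= max_gap_bp
            ):
                current.append(gene)
                continue
            operons.append(
                Operon(current[0].genome_id, current[0].contig_id, current[0].strand, current)
            )
            current = []
        current.append(gene)
    if current:
        operons.append(
            Operon(current[0].genome_id, current[0].contig_id, current[0].strand, current)
        )
    return operons


@dataclass(frozen=True)
class Candidate:
    genome_id: str
    locus_tag: str
    product: str
    n_pathway_co_members: int
    operon_size: int
    co_member_families: tuple[str, ...]


def candidate_members(
    operons: Sequence[Operon], pathway_hits: Iterable[HomologyHit]
) -> list[Candidate]:
    """Unannotated members of hit-containing operons, ranked as candidates.

    For every operon containing at least one pathway-family hit, every member
    without a hit is emitted, ranked by (number of pathway-hit co-members
    descending, operon size ascending, locus_tag).
    """
    hit_family: dict[tuple[str, str], str] = {
        (h.genome_id, h.locus_tag): h.family_id for h in pathway_hits
    }
    out: list[Candidate] = []
    for op in operons:
        fams = [
            hit_family[(g.genome_id, g.locus_tag)]
            for g in op.genes
            if (g.genome_id, g.locus_tag) in hit_family
        ]
        if not fams:
            continue
        for g in op.genes:
            if (g.genome_id, g.locus_tag) in hit_family:
                continue
            out.append(
                Candidate(
                    genome_id=g.genome_id,
                    locus_tag=g.locus_tag,
                    product=g.product,
                    n_pathway_co_members=len(fams),
                    operon_size=len(op),
                    co_member_families=tuple(sorted(fams)),
                )
            )
    out.sort(key=lambda c: (-c.n_pathway_co_members, c.operon_size, c.locus_tag))
    return out


# ---------------------------------------------------------------------------
# cluster synteny links


@dataclass
class ClusterLink:
    pairs: list[tuple[str, str, float]]  # (locusA, locusB, percent identity)

    @property
    def n_shared(self) -> int:
        return len(self.pairs)


def cluster_similarity(
    clusterA_genes: Sequence[GeneRecord],
    clusterB_genes: Sequence[GeneRecord],
    min_identity: float = 30.0,
) -> ClusterLink:
    """Greedy one-to-one matching of two clusters' genes by percent identity.

    All cross-cluster pairs are scored by global pairwise identity, then
    matched greedily in descending identity order (ties by locus-tag pair);
    each gene participates in at most one pair, and pairs below *min_identity*
    are discarded.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity must be in [0, 100]")
    scored = []
    for ga in clusterA_genes:
        for gb in clusterB_genes:
            ident = pairwise_identity(ga.protein_seq, gb.protein_seq)
            if ident >= min_identity:
                scored.append((ident, ga.locus_tag, gb.locus_tag))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    for ident, la, lb in scored:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        pairs.append((la, lb, ident))
    return ClusterLink(pairs=pairs)


# ---------------------------------------------------------------------------
# TSV export


def write_operons(operons: Sequence[Operon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tcontig_id\tstrand\tstart\tend\tn_genes\tloci\n")
        for op in operons:
            s, e = op.span
            loci = ",".join(g.locus_tag for g in op.genes)
            fh.write(f"{op.genome_id}\t{op.contig_id}\t{op.strand}\t{s}\t{e}\t{len(op)}\t{loci}\n")


def write_candidates(cands: Sequence[Candidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgenome_id\tlocus_tag\tproduct\tn_co_members\toperon_size\tco_member_families\n")
        for rank, c in enumerate(cands, 1):
            fams = ",".join(c.co_member_families)
            fh.write(
                f"{rank}\t{c.genome_id}\t{c.locus_tag}\t{c.product}\t"
                f"{c.n_pathway_co_members}\t{c.operon_size}\t{fams}\n"
            )


def write_links(link: ClusterLink, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tidentity\n")
        for la, lb, ident in link.pairs:
            fh.write(f"{la}\t{lb}\t{ident:.2f}\n")
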