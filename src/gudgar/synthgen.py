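"""Synthetic species trees, protein families, genomes, reads and count matrices.

The generator emulates the statistical structure of the pipeline's real
inputs: genomes carrying a planted gud/gar gene cluster in one of two operon
layouts (an E. coli-like permease layout and an E. clostridioformis-like
ABC-transporter layout), protein families diverged along a pure-birth species
tree with optional horizontal transfer of the cluster into a foreign clade,
and negative-binomial count matrices with a planted disease-group effect.
Every generator is a pure function of its inputs and seed, and every dataset
is emitted with a truth table so downstream precision/recall is computable.

Protein evolution is indel-free (per-site Markov substitution), so the true
alignment of any family is the identity mapping; see docs/methods.md.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from gudgar.iohub import AMINO_ACIDS, GeneRecord

# Robinson-Robinson amino-acid background frequencies, indexed like AMINO_ACIDS
BACKGROUND_FREQS = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
        0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
        0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: gene families making up the planted cluster layouts (Fig-style organization:
#: permease layout gudP-gudD-garL-garR; ABC-transporter layout garA-garB-garC-gudD-gudL-garR)
LAYOUTS = {
    "ecoli_like": ["gudP", "gudD", "garL", "garR"],
    "clostridioformis_like": ["garA", "garB", "garC", "gudD", "gudL", "garR"],
}
CORE_FAMILIES = sorted({f for fams in LAYOUTS.values() for f in fams} | {"garD", "garK"})
#: families whose loss breaks the minimum-viable-pathway grammar, per layout
_CRITICAL = {
    "ecoli_like": ["gudD", "garL", "garR"],
    "clostridioformis_like": ["gudD", "gudL", "garR"],
}

_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "L": ["CTG", "CTC", "TTA", "TTG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
}


@dataclass
class SimSpec:
    """Parameters of one synthetic dataset.

    Defaults define the standard study conditions used throughout the test
    suite: 50 taxa, moderate within-family divergence (mean pairwise identity
    around 60-65%, the scale of the identities the screen is designed for),
    40% of genomes pathway-positive, and a twofold planted count effect in
    the disease groups.
    """

    n_taxa: int = 50
    birth_rate: float = 1.0
    aa_substitution_rate: float = 0.15
    pathway_layouts: tuple[str, ...] = ("ecoli_like", "clostridioformis_like")
    fraction_with_pathway: float = 0.4
    fraction_decoy: float = 0.2
    hgt_events: tuple[tuple[str, str], ...] = ()
    nb_mean: float = 50.0
    nb_dispersion: float = 5.0
    effect_log2fc: float = 1.0
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.aa_substitution_rate <= 0:
            raise ValueError("rates must be > 0")
        if not 0.0 <= self.fraction_with_pathway <= 1.0:
            raise ValueError("fraction_with_pathway must be in [0, 1]")
        unknown = set(self.pathway_layouts) - set(LAYOUTS)
        if unknown:
            raise ValueError(f"unknown layout(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int, birth_rate: float, seed: int, clade_separation: float = 0.0
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with leaves relabeled sp1..spN.

    *clade_separation* lengthens the stems of the two clades flanking the
    root by a fixed amount of time each, deepening the split between the two
    simulated 'phyla' (phylum-level divergence is much older than the
    within-clade radiations) while keeping the tree ultrametric.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if clade_separation < 0:
        raise ValueError("clade_separation must be >= 0")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon.label = f"sp{i}"
    tree.seed_node.edge.length = 0.0
    if clade_separation > 0:
        for child in tree.seed_node.child_nodes():
            child.edge.length = (child.edge.length or 0.0) + clade_separation
    return tree


def phylum_groups(tree: dendropy.Tree) -> dict[str, str]:
    """Assign leaves to two 'phylum' groups: the two clades flanking the root."""
    children = tree.seed_node.child_nodes()
    groups: dict[str, str] = {}
    names = ["Bacillota", "Fusobacteriota"]
    for child, name in zip(children[:2], names):
        for leaf in child.leaf_iter():
            groups[leaf.taxon.label] = name
    for child in children[2:]:  # polytomous root: lump extras with the first group
        for leaf in child.leaf_iter():
            groups[leaf.taxon.label] = names[0]
    return groups


# ---------------------------------------------------------------------------
# protein families


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, branch_length: float, rate: float, rng: np.random.Generator) -> str:
    p_sub = 1.0 - math.exp(-rate * branch_length)
    out = list(seq)
    hits = rng.random(len(seq)) < p_sub
    for i in np.flatnonzero(hits):
        cur = out[i]
        probs = BACKGROUND_FREQS.copy()
        j = AMINO_ACIDS.find(cur)
        if j >= 0:
            probs[j] = 0.0
        probs /= probs.sum()
        out[i] = AMINO_ACIDS[rng.choice(20, p=probs)]
    return "".join(out)


def evolve_family(
    root_protein: str, tree: dendropy.Tree, rate: float, seed: int
) -> dict[str, str]:
    """Indel-free evolution of *root_protein* down *tree*.

    Each site substitutes along a branch with probability 1 - exp(-rate * L);
    the replacement is drawn from the background frequency table excluding the
    current residue.  All leaves keep the root's length, so the true alignment
    is the identity mapping.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if len(root_protein) < 50:
        raise ValueError("root protein must be >= 50 residues")
    rng = np.random.default_rng(seed)
    seqs: dict[dendropy.Node, str] = {tree.seed_node: root_protein}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        seqs[node] = _mutate(parent_seq, node.edge.length or 0.0, rate, rng)
    return {n.taxon.label: s for n, s in seqs.items() if n.is_leaf()}


def seed_alignment(
    family_history: dict[str, str], n_seqs: int, seed: int
) -> list[tuple[str, str]]:
    """Pick *n_seqs* leaf sequences of an indel-free family as a seed alignment."""
    rng = np.random.default_rng(seed)
    leaves = sorted(family_history)
    chosen = rng.choice(len(leaves), size=min(n_seqs, len(leaves)), replace=False)
    return [(leaves[i], family_history[leaves[i]]) for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# genomes with planted clusters


def back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        syn = _SYNONYMS.get(aa)
        codons.append(syn[rng.integers(len(syn))] if syn else _CODONS.get(aa, "NNN"))
    codons.append("TAA")
    return "".join(codons)


@dataclass
class SyntheticGenome:
    genome_id: str
    genes: list[GeneRecord]
    nt_seqs: dict[str, str]  # locus_tag -> nucleotide CDS


@dataclass
class GenomeTruth:
    genome_id: str
    layout: str  # layout name, "decoy:<layout>-<deleted family>", or "none"
    families_present: frozenset[str]
    satisfied: bool
    cluster_loci: tuple[str, ...] = ()


def _grammar_satisfied(families: frozenset[str]) -> bool:
    # minimum viable pathway: (GudD or GarD) and (GudL or GarL) and GarR
    return (
        bool({"gudD", "garD"} & families)
        and bool({"gudL", "garL"} & families)
        and "garR" in families
    )


def plant_genomes(
    tree: dendropy.Tree,
    sim_spec: SimSpec,
    n_complete: int | None = None,
    n_decoy: int | None = None,
    n_distractors: int = 24,
    family_histories: dict[str, dict[str, str]] | None = None,
) -> tuple[list[SyntheticGenome], dict[str, GenomeTruth], dict[str, dict[str, str]]]:
    """Build one annotated genome per leaf, planting clusters and decoys.

    Returns (genomes, truth table, family histories).  A fraction of genomes
    receive a complete cluster in one of the configured layouts; decoys lack
    one grammar-critical family; the rest carry no cluster gene.  Pass
    *family_histories* (e.g. after :func:`inject_hgt`) to reuse pre-evolved
    families.
    """
    rng = np.random.default_rng(sim_spec.seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(leaves)

    if family_histories is None:
        family_histories = evolve_all_families(tree, sim_spec, n_distractors=n_distractors)
    distractor_fams = sorted(f for f in family_histories if f.startswith("dst"))

    if n_complete is None:
        n_complete = int(round(sim_spec.fraction_with_pathway * n))
    if n_decoy is None:
        n_decoy = int(round(sim_spec.fraction_decoy * n))
    if n_complete < 1:
        import warnings

        warnings.warn("fraction_with_pathway too small: no pathway planted", stacklevel=2)
    order = list(rng.permutation(n))
    positives = [leaves[i] for i in order[:n_complete]]
    decoys = [leaves[i] for i in order[n_complete : n_complete + n_decoy]]

    layouts = list(sim_spec.pathway_layouts)
    genomes: list[SyntheticGenome] = []
    truth: dict[str, GenomeTruth] = {}
    for leaf in leaves:
        grng = np.random.default_rng(rng.integers(2**31))
        n_genes = int(grng.integers(50, 201))
        if leaf in positives:
            layout = layouts[positives.index(leaf) % len(layouts)]
            cluster = list(LAYOUTS[layout])
            label = layout
        elif leaf in decoys:
            layout = layouts[decoys.index(leaf) % len(layouts)]
            cluster = list(LAYOUTS[layout])
            deleted = _CRITICAL[layout][int(grng.integers(len(_CRITICAL[layout])))]
            cluster.remove(deleted)
            label = f"decoy:{layout}-{deleted}"
        else:
            cluster, label = [], "none"

        # gene roster: one copy of each distractor family, fillers, and the cluster
        slots: list[tuple[str, str]] = [
            (fam, family_histories[fam][leaf]) for fam in distractor_fams
        ]
        while len(slots) + len(cluster) < n_genes:
            slots.append(("filler", random_protein(int(grng.integers(100, 401)), grng)))
        grng.shuffle(slots)
        insert_at = int(grng.integers(0, len(slots) + 1))
        cluster_strand = "+" if grng.random() < 0.5 else "-"

        genes: list[GeneRecord] = []
        nt_seqs: dict[str, str] = {}
        cluster_loci: list[str] = []
        pos = int(grng.integers(100, 1000))
        idx = 0

        def add_gene(protein: str, product: str, strand: str, gap: int) -> str:
            nonlocal pos, idx
            idx += 1
            locus = f"{leaf}_g{idx:04d}"
            start = pos + gap
            end = start + 3 * len(protein) + 2  # CDS plus stop codon
            genes.append(
                GeneRecord(
                    genome_id=leaf,
                    contig_id=f"{leaf}_c1",
                    start=start,
                    end=end,
                    strand=strand,
                    locus_tag=locus,
                    product=product,
                    protein_seq=protein,
                )
            )
            nt_seqs[locus] = back_translate(protein, grng)
            pos = end
            return locus

        for slot_i, (fam, protein) in enumerate(slots):
            if slot_i == insert_at:
                for ci, cfam in enumerate(cluster):
                    locus = add_gene(
                        family_histories[cfam][leaf],
                        f"{cfam} homolog",
                        cluster_strand,
                        int(grng.integers(20, 151)) if ci else int(grng.integers(600, 5001)),
                    )
                    cluster_loci.append(locus)
            strand = "+" if grng.random() < 0.5 else "-"
            add_gene(protein, fam, strand, int(grng.integers(600, 5001)))
        if insert_at == len(slots):
            for ci, cfam in enumerate(cluster):
                locus = add_gene(
                    family_histories[cfam][leaf],
                    f"{cfam} homolog",
                    cluster_strand,
                    int(grng.integers(20, 151)) if ci else int(grng.integers(600, 5001)),
                )
                cluster_loci.append(locus)

        fams_present = frozenset(cluster)
        genomes.append(SyntheticGenome(genome_id=leaf, genes=genes, nt_seqs=nt_seqs))
        truth[leaf] = GenomeTruth(
            genome_id=leaf,
            layout=label,
            families_present=fams_present,
            satisfied=_grammar_satisfied(fams_present),
            cluster_loci=tuple(cluster_loci),
        )
    return genomes, truth, family_histories


def evolve_all_families(
    tree: dendropy.Tree,
    sim_spec: SimSpec,
    n_distractors: int = 24,
    root_length_range: tuple[int, int] = (250, 450),
) -> dict[str, dict[str, str]]:
    """Evolve every core and distractor family along the species tree."""
    rng = np.random.default_rng(sim_spec.seed + 1)
    names = CORE_FAMILIES + [f"dst{i:02d}" for i in range(1, n_distractors + 1)]
    out: dict[str, dict[str, str]] = {}
    for name in names:
        root = random_protein(int(rng.integers(*root_length_range)), rng)
        out[name] = evolve_family(
            root, tree, sim_spec.aa_substitution_rate, seed=int(rng.integers(2**31))
        )
        out[name]["__root__"] = root
    return out


# ---------------------------------------------------------------------------
# horizontal gene transfer


def inject_hgt(
    family_histories: dict[str, dict[str, str]],
    donor_clade: set[str] | list[str],
    recipient_leaf: str,
    seed: int,
    families: list[str] | None = None,
    transfer_divergence: float = 0.05,
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Replace *recipient_leaf*'s cluster-gene sequences with donor-derived copies.

    The recipient's sequence for each family is re-drawn by evolving a randomly
    chosen donor-clade member's sequence over a short branch
    (*transfer_divergence* expected substitutions/site), so in the gene tree
    the recipient nests inside the donor clade while the species tree is
    unchanged.  Returns the modified histories and an event record.
    """
    donors = sorted(set(donor_clade))
    if recipient_leaf in donors:
        raise ValueError("donor clade and recipient must be disjoint")
    rng = np.random.default_rng(seed)
    if families is None:
        families = sorted(f for f in family_histories if not f.startswith("dst"))
    out = {fam: dict(hist) for fam, hist in family_histories.items()}
    donor = donors[int(rng.integers(len(donors)))]
    for fam in families:
        hist = out[fam]
        if recipient_leaf not in hist:
            raise ValueError(f"recipient {recipient_leaf!r} not in family {fam!r}")
        if donor not in hist:
            raise ValueError(f"donor {donor!r} not in family {fam!r}")
        hist[recipient_leaf] = _mutate(hist[donor], transfer_divergence, 1.0, rng)
    event = {"donor": donor, "recipient": recipient_leaf, "families": ",".join(families)}
    return out, event


# ---------------------------------------------------------------------------
# counts and reads

GROUPS = ("nonIBD", "UC", "CD")
DEFAULT_COUNT_FAMILIES = ("gudD", "garD", "garL", "gudL", "garR")


def simulate_counts(
    n_per_group: int,
    nb_mean: float,
    nb_dispersion: float,
    effect_log2fc: float,
    seed: int,
    families: tuple[str, ...] = DEFAULT_COUNT_FAMILIES,
    pathway_families: tuple[str, ...] | None = None,
    libsize_range: tuple[float, float] = (1e5, 1e6),
):
    """Negative-binomial count matrix over three disease groups.

    UC and CD means are scaled by 2**effect_log2fc for *pathway_families*
    (default: all families).  Library sizes are drawn log-uniform within
    *libsize_range*, and expected counts scale with each sample's depth
    relative to the geometric-mean depth (deeper samples map more reads, the
    structure CPM normalization is meant to remove); with a degenerate range
    the counts are plain NB(nb_mean, dispersion).
    """
    from gudgar.abundance import CountMatrix

    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for each group")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if pathway_families is None:
        pathway_families = families
    sample_ids, groups, rows, libsizes = [], [], [], []
    r = nb_dispersion
    ref_depth = math.sqrt(libsize_range[0] * libsize_range[1])
    for group in GROUPS:
        for i in range(1, n_per_group + 1):
            lo, hi = math.log(libsize_range[0]), math.log(libsize_range[1])
            lib = int(math.exp(rng.uniform(lo, hi)))
            row = []
            for fam in families:
                mu = nb_mean * (lib / ref_depth)
                if group in ("UC", "CD") and fam in pathway_families:
                    mu *= 2.0**effect_log2fc
                p = r / (r + mu)
                row.append(int(rng.negative_binomial(r, p)))
            sample_ids.append(f"{group}_{i:03d}")
            groups.append(group)
            rows.append(row)
            libsizes.append(max(lib, sum(row)))
    import pandas as pd

    counts = pd.DataFrame(rows, index=sample_ids, columns=list(families))
    return CountMatrix(
        counts=counts,
        library_size=pd.Series(libsizes, index=sample_ids),
        group=pd.Series(groups, index=sample_ids),
    )


def simulate_reads(
    gene_catalog: list[tuple[str, str]],
    abundances: list[float],
    read_length: int,
    error_rate: float,
    seed: int,
    n_reads: int = 10_000,
) -> list[tuple[str, str]]:
    """Draw reads from catalog genes proportional to abundance x gene length.

    Start positions are uniform; substitution errors occur at *error_rate*
    per base.  Read names encode the true source gene ("r<i>|<gene_id>").
    """
    if len(abundances) != len(gene_catalog):
        raise ValueError("abundances must match catalog length")
    weights = np.array(
        [a * len(seq) for a, (_, seq) in zip(abundances, gene_catalog)], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("all abundances are zero")
    for gid, seq in gene_catalog:
        if len(seq) < read_length:
            raise ValueError(f"catalog gene {gid!r} shorter than read_length")
    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    picks = rng.choice(len(gene_catalog), size=n_reads, p=probs)
    bases = "ACGT"
    reads = []
    for i, gi in enumerate(picks):
        gid, seq = gene_catalog[gi]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        frag = list(seq[start : start + read_length])
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            for j in errs:
                choices = [b for b in bases if b != frag[j]]
                frag[j] = choices[int(rng.integers(3))]
        reads.append((f"r{i}|{gid}", "".join(frag)))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
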