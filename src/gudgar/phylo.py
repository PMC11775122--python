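"""Alignment utilities, distance gene trees, ancestral states, HGT signals.

Gene trees are built from Poisson-corrected distances with neighbor joining,
ancestral states are reconstructed with Fitch parsimony, clade-diagnostic
residues are columns conserved in a focal clade but absent from the
reconstructed ancestral state, and horizontal transfer is detected as a clade
of one taxonomic group nesting inside another group's clade in the gene tree.
Distance/parsimony methods stand in for likelihood ones deliberately: the
downstream calls rest on topology-level signals (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align

from gudgar.iohub import parse_fasta

GAP = "-"


# ---------------------------------------------------------------------------
# MSA container


@dataclass
class MSA:
    """An ordered multiple sequence alignment with '-' gaps."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        L = len(self.records[0][1])
        if any(len(s) != L for _, s in self.records):
            raise ValueError("alignment rows have unequal lengths")
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.records]

    def column(self, c: int) -> list[str]:
        return [s[c] for _, s in self.records]

    def row(self, label: str) -> str:
        for lab, s in self.records:
            if lab == label:
                return s
        raise KeyError(label)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        return cls(records=parse_fasta(path))


# ---------------------------------------------------------------------------
# identity & trimming

_nw_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0, gap_score=-1
)


def pairwise_identity(seqA: str, seqB: str) -> float:
    """Percent identity: matching columns over columns with >= 1 residue.

    Equal-length inputs are treated as already aligned (gaps allowed);
    unequal-length inputs are first aligned globally with match +1 /
    mismatch 0 / linear gap -1.
    """
    if len(seqA) != len(seqB):
        aln = _nw_aligner.align(seqA.replace(GAP, ""), seqB.replace(GAP, ""))[0]
        seqA, seqB = str(aln[0]), str(aln[1])
    cols = sum(1 for x, y in zip(seqA, seqB) if x != GAP or y != GAP)
    if cols == 0:
        raise ValueError("both sequences are all-gap")
    matches = sum(1 for x, y in zip(seqA, seqB) if x == y and x != GAP)
    return 100.0 * matches / cols


def trim_msa(msa: MSA, max_gap_fraction: float = 0.97) -> tuple[MSA, list[int]]:
    """Drop columns whose gap fraction strictly exceeds *max_gap_fraction*.

    Returns the trimmed MSA and the 0-based indices of the kept columns
    (column provenance).  Exactly-at-threshold columns are kept.
    """
    if not 0.0 < max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    n_rows = len(msa.records)
    keep = [
        c
        for c in range(msa.n_columns)
        if sum(s[c] == GAP for _, s in msa.records) / n_rows <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("trimming removed every column")
    trimmed = [(lab, "".join(s[c] for c in keep)) for lab, s in msa.records]
    return MSA(records=trimmed), keep


# ---------------------------------------------------------------------------
# distances


def distance_matrix(msa: MSA, d_max: float = 10.0) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch proportion over mutually non-gap columns; saturated
    pairs (1 - p <= exp(-d_max)) are capped at *d_max*.  A pair with no
    mutually non-gap columns is an error.
    """
    labels = msa.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 rows")
    arr = np.array([list(s) for _, s in msa.records])
    nongap = arr != GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no shared non-gap columns for {labels[i]!r}/{labels[j]!r}")
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            q = 1.0 - p
            d = d_max if q <= math.exp(-d_max) else -math.log(q)
            D[i, j] = D[j, i] = d
    return D, labels


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei Q-criterion, Studier-Keppler updates).

    Returns an unrooted tree (trifurcating seed node).  Negative branch
    lengths are clamped to 0 with the deficit moved to the sibling branch.
    Ties in Q resolve to the lexicographically smallest pair of subtree keys
    (a subtree's key is its smallest leaf label).  Exact on additive inputs.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    taxa = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    keys: dict[int, str] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(lab)
        nodes[i] = node
        keys[i] = lab

    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, (i, j))
                if best is None or cand < best:
                    best = cand
        _, _, (i, j) = best
        dij = d(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li  # move deficit to the sibling
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # final three-point join
    a, b, c = sorted(active, key=lambda k: keys[k])
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony


@dataclass
class FitchResult:
    tree: dendropy.Tree  # the (possibly polytomy-resolved) tree the pass ran on
    sets: dict  # node -> frozenset of states (bottom-up pass)
    assigned: dict  # node -> state (top-down pass)
    score: int

    @property
    def root_set(self) -> frozenset:
        return self.sets[self.tree.seed_node]


def fitch_states(
    tree: dendropy.Tree,
    leaf_states: Mapping[str, str | None],
    alphabet: Iterable[str] | None = None,
) -> FitchResult:
    """Fitch parsimony over categorical leaf states.

    Bottom-up: a node's set is the intersection of its children's sets when
    non-empty, else their union (+1 to the score).  Top-down: the root takes
    the lexicographically smallest member of its set; each child keeps its
    parent's state when possible, else the lexicographically smallest.
    Leaves with a ``None``/missing state are uninformative (full alphabet).
    Polytomies are resolved deterministically (in child order) first; the
    returned result references the resolved tree.
    """
    work = tree.clone(depth=1)
    work.is_rooted = True  # Fitch runs on the seed-rooted topology
    work.resolve_polytomies(limit=2, update_bipartitions=False)
    alpha = frozenset(alphabet) if alphabet else frozenset(
        s for s in leaf_states.values() if s is not None
    )
    if not alpha:
        raise ValueError("no informative leaf states")

    sets: dict = {}
    score = 0
    for node in work.postorder_node_iter():
        if node.is_leaf():
            state = leaf_states.get(node.taxon.label)
            sets[node] = frozenset([state]) if state is not None else alpha
        else:
            cur = None
            for child in node.child_nodes():
                if cur is None:
                    cur = sets[child]
                else:
                    inter = cur & sets[child]
                    if inter:
                        cur = inter
                    else:
                        cur = cur | sets[child]
                        score += 1
            sets[node] = cur

    assigned: dict = {}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            assigned[node] = min(sets[node])
        else:
            parent_state = assigned[node.parent_node]
            assigned[node] = parent_state if parent_state in sets[node] else min(sets[node])
    return FitchResult(tree=work, sets=sets, assigned=assigned, score=score)


# ---------------------------------------------------------------------------
# clade-diagnostic residues


@dataclass(frozen=True)
class ResidueChange:
    column: int  # 1-based alignment column
    ancestral_state: str
    derived_state: str
    clade_conservation: float


def column_entropy(residues: Sequence[str]) -> float:
    """Shannon entropy (nats) of the non-gap residues of one column."""
    res = [r for r in residues if r != GAP]
    if not res:
        return 0.0
    counts: dict[str, int] = {}
    for r in res:
        counts[r] = counts.get(r, 0) + 1
    n = len(res)
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def diagnostic_residues(
    msa: MSA,
    tree: dendropy.Tree,
    focal_clade_leaves: Iterable[str],
    conservation_min: float = 0.9,
) -> tuple[list[ResidueChange], np.ndarray]:
    """Columns conserved in the focal clade but foreign to its ancestor.

    Per column, the focal clade's modal residue and conservation are compared
    with the Fitch state set at the focal clade's parent node, computed with
    the focal leaves masked as uninformative so the ancestral state is driven
    by the rest of the tree.  A change is reported when conservation >=
    *conservation_min* and the modal residue is absent from the ancestral
    set.  Also returns the per-column Shannon entropy over all rows.
    """
    focal = set(focal_clade_leaves)
    if not focal:
        raise ValueError("empty focal clade")
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # the seed node is the root by convention here
    mrca = tree.mrca(taxon_labels=sorted(focal))
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    if clade_leaves != focal:
        raise ValueError(
            f"focal set is not monophyletic: clade adds {sorted(clade_leaves - focal)}"
        )
    labels_in_msa = set(msa.labels)
    missing = focal - labels_in_msa
    if missing:
        raise ValueError(f"focal leaves absent from alignment: {sorted(missing)}")

    entropies = np.empty(msa.n_columns)
    changes: list[ResidueChange] = []
    for c in range(msa.n_columns):
        col = {lab: s[c] for lab, s in msa.records}
        entropies[c] = column_entropy(list(col.values()))
        focal_res = [col[lab] for lab in focal if col[lab] != GAP]
        if not focal_res:
            continue
        counts: dict[str, int] = {}
        for r in focal_res:
            counts[r] = counts.get(r, 0) + 1
        modal = min(r for r in counts if counts[r] == max(counts.values()))
        conservation = counts[modal] / len(focal_res)
        if conservation < conservation_min:
            continue
        # ancestral state from the rest of the tree: mask the focal clade
        states: dict[str, str | None] = {}
        for leaf in tree.leaf_node_iter():
            lab = leaf.taxon.label
            if lab in focal or lab not in col or col[lab] == GAP:
                states[lab] = None
            else:
                states[lab] = col[lab]
        if all(s is None for s in states.values()):
            continue
        result = fitch_states(tree, states)
        work_mrca = result.tree.mrca(taxon_labels=sorted(focal))
        parent = work_mrca.parent_node or work_mrca
        ancestral_set = result.sets[parent]
        if modal not in ancestral_set:
            changes.append(
                ResidueChange(
                    column=c + 1,
                    ancestral_state=result.assigned[parent],
                    derived_state=modal,
                    clade_conservation=conservation,
                )
            )
    return changes, entropies


# ---------------------------------------------------------------------------
# gene-tree / species-tree incongruence


@dataclass(frozen=True)
class IncongruenceEvent:
    foreign_clade_leaves: frozenset
    foreign_group: str
    host_group: str
    host_clade_leaves: frozenset
    support: int | None


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    rooted = tree.clone(depth=1)
    og = rooted.find_node_with_taxon_label(outgroup_label)
    if og is None:
        raise ValueError(f"outgroup {outgroup_label!r} not in tree")
    rooted.to_outgroup_position(og, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def _edge_support(node: dendropy.Node) -> int | None:
    label = node.label
    if label is None:
        return None
    try:
        return int(float(label))
    except ValueError:
        return None


def detect_nested_clades(
    gene_tree: dendropy.Tree,
    leaf_groups: Mapping[str, str],
    min_foreign: int = 2,
    min_host: int = 4,
    host_purity: float = 0.9,
    support_min: int = 75,
) -> list[IncongruenceEvent]:
    """Find group-pure clades nested inside a clade of another group.

    A maximal clade C whose leaves all belong to group g is reported when the
    smallest proper ancestor P with at least *min_host* leaves has at least
    *host_purity* of its non-C leaves in a single group h != g, and the branch
    subtending C has support >= *support_min* (the support filter is skipped
    when supports are absent).  The host ancestor must not be the root: a
    root-level split between pure groups is the concordant topology, not
    nesting.  Unrooted trees are midpoint-rooted first.  Events are sorted by
    foreign clade size, descending.
    """
    unknown = [
        lf.taxon.label
        for lf in gene_tree.leaf_node_iter()
        if lf.taxon.label not in leaf_groups
    ]
    if unknown:
        raise ValueError(f"leaves without group label: {sorted(unknown)}")

    tree = gene_tree
    if len(tree.seed_node.child_nodes()) > 2 or not tree.is_rooted:
        tree = midpoint_root(gene_tree)

    leafsets: dict = {}
    groupsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
        groupsets[node] = {leaf_groups[lab] for lab in leafsets[node]}

    events: list[IncongruenceEvent] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if len(groupsets[node]) != 1:
            continue
        g = next(iter(groupsets[node]))
        parent = node.parent_node
        if parent is not None and groupsets[parent] == {g}:
            continue  # not maximal
        C = leafsets[node]
        if len(C) < min_foreign:
            continue
        P = parent
        while P is not None and len(leafsets[P]) < min_host:
            P = P.parent_node
        if P is None or P is tree.seed_node:
            continue
        rest = leafsets[P] - C
        if not rest:
            continue
        counts: dict[str, int] = {}
        for lab in rest:
            counts[leaf_groups[lab]] = counts.get(leaf_groups[lab], 0) + 1
        host_group = max(sorted(counts), key=lambda k: counts[k])
        if host_group == g:
            continue
        if counts[host_group] / len(rest) < host_purity:
            continue
        # true nesting: the context immediately above the host clade must also
        # be majority host-group, otherwise C is merely sister to an h clade
        # (the reciprocal of a real event, or a concordant split)
        context = leafsets[P.parent_node] - leafsets[P]
        if context:
            ctx_counts: dict[str, int] = {}
            for lab in context:
                ctx_counts[leaf_groups[lab]] = ctx_counts.get(leaf_groups[lab], 0) + 1
            ctx_major = max(sorted(ctx_counts), key=lambda k: ctx_counts[k])
            if ctx_major != host_group:
                continue
        support = _edge_support(node)
        if support is not None and support < support_min:
            continue
        events.append(
            IncongruenceEvent(
                foreign_clade_leaves=C,
                foreign_group=g,
                host_group=host_group,
                host_clade_leaves=leafsets[P],
                support=support,
            )
        )
    events.sort(key=lambda e: (-len(e.foreign_clade_leaves), sorted(e.foreign_clade_leaves)))
    return events


# ---------------------------------------------------------------------------
# optional NJ bootstrap


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=lambda s: sorted(s)))
    return out


def bootstrap_nj(msa: MSA, n_replicates: int = 100, seed: int = 0, d_max: float = 10.0) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports on internal nodes."""
    D, labels = distance_matrix(msa, d_max=d_max)
    ref = nj_tree(D, labels)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    cols = msa.n_columns
    for _ in range(n_replicates):
        idx = rng.integers(0, cols, size=cols)
        rep = MSA(records=[(lab, "".join(s[c] for c in idx)) for lab, s in msa.records])
        try:
            Dr, _ = distance_matrix(rep, d_max=d_max)
        except ValueError:
            continue
        for bp in _bipartitions(nj_tree(Dr, labels)):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(labels)
    for node in ref.preorder_internal_node_iter():
        if node is ref.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            key = min(side, all_leaves - side, key=lambda s: sorted(s))
            node.label = str(round(100.0 * counts.get(key, 0) / n_replicates))
    return ref
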