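"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by exhaustive enumeration or a
closed form, never by calling the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# local alignment: exhaustive enumeration over all gapped local alignments


def brute_force_local_score(sub: np.ndarray, qidx: list[int], go: float, ge: float) -> float:
    """Best score over every gapped local alignment of a query vs profile columns.

    *sub* is (L x A) per-column residue scores; an alignment is any monotone
    sequence of ops starting and ending with a match; a maximal run of k
    identical gap ops costs go + (k-1)*ge.  Trailing/leading gaps only lower
    the score, so restricting to match-bounded alignments is exact.
    """
    L = sub.shape[0]
    n = len(qidx)
    best = 0.0

    def rec(i: int, j: int, score: float, last: str) -> None:
        # a match has just been consumed at column i-1 / query j-1
        nonlocal best
        if score > best:
            best = score
        # extend with a match
        if i < L and j < n:
            rec(i + 1, j + 1, score + sub[i, qidx[j]], "M")
        # gap in query (skip profile columns), must resume with a match
        for skip in range(1, L - i):
            cost = go + (skip - 1) * ge
            if i + skip < L and j < n:
                rec(i + skip + 1, j + 1, score + cost + sub[i + skip, qidx[j]], "M")
        # gap in profile (skip query residues)
        for skip in range(1, n - j):
            cost = go + (skip - 1) * ge
            if i < L and j + skip < n:
                rec(i + 1, j + skip + 1, score + cost + sub[i, qidx[j + skip]], "M")

    for i0 in range(L):
        for j0 in range(n):
            rec(i0 + 1, j0 + 1, sub[i0, qidx[j0]], "M")
    return max(best, 0.0)


# ---------------------------------------------------------------------------
# pathway grammar truth table


def minimum_viable_pathway(present: set[str]) -> bool:
    """Literal truth-table of the default grammar: a dehydratase (gudD or
    garD), an aldolase (gudL or garL) and the reductase garR; garK ignored."""
    return (
        ("gudD" in present or "garD" in present)
        and ("gudL" in present or "garL" in present)
        and "garR" in present
    )


# ---------------------------------------------------------------------------
# operons: transitive closure with union-find


def operon_partition_union_find(genes) -> list[frozenset]:
    """Partition locus tags by union over positionally adjacent compatible pairs."""
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.locus_tag))
    parent = {g.locus_tag: g.locus_tag for g in ordered}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for prev, cur in zip(ordered, ordered[1:]):
        gap = max(cur.start - prev.end - 1, 0)
        if prev.contig_id == cur.contig_id and prev.strand == cur.strand and gap <= 500:
            union(prev.locus_tag, cur.locus_tag)
    groups: dict[str, set[str]] = {}
    for g in ordered:
        groups.setdefault(find(g.locus_tag), set()).add(g.locus_tag)
    return [frozenset(v) for v in groups.values()]


# ---------------------------------------------------------------------------
# matching: optimal one-to-one assignment by enumeration


def optimal_matching_score(weights: dict[tuple[int, int], float]) -> tuple[int, float]:
    """(max pairs, max total weight among max-cardinality matchings) by brute force."""
    a_ids = sorted({a for a, _ in weights})
    b_ids = sorted({b for _, b in weights})
    best = (0, 0.0)
    for size in range(min(len(a_ids), len(b_ids)), 0, -1):
        found = False
        for a_sub in itertools.combinations(a_ids, size):
            for b_perm in itertools.permutations(b_ids, size):
                pairs = list(zip(a_sub, b_perm))
                if all(p in weights for p in pairs):
                    total = sum(weights[p] for p in pairs)
                    best = max(best, (size, total))
                    found = True
        if found:
            break
    return best


# ---------------------------------------------------------------------------
# Fitch: exhaustive minimization over internal labelings


def exhaustive_parsimony_score(tree, leaf_states: dict[str, str], states: list[str]) -> int:
    """Minimum substitution count over all internal-node labelings of a
    dendropy tree (rooted, any degree)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = math.inf
    for labeling in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(internals, labeling))
        for lf in leaves:
            assign[lf] = leaf_states[lf.taxon.label]
        score = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and assign[node] != assign[node.parent_node]
        )
        best = min(best, score)
    return int(best)


# ---------------------------------------------------------------------------
# Mann-Whitney exact p by enumeration


def mann_whitney_exact_enumeration(a: list[float], b: list[float]) -> tuple[float, float]:
    """(U of group a, two-sided exact p) by enumerating every group assignment.

    Requires tie-free pooled data.  p = 2 * min(P(U <= u), P(U >= u)), capped
    at 1, under the permutation null.
    """
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n1 + n2, "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(pooled, 1)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r1 = sum(r + 1 for r in combo)
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = float(np.mean(us <= u_obs))
    p_ge = float(np.mean(us >= u_obs))
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# random additive trees for NJ recovery


def random_binary_tree_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random binary topology with branch lengths in [0.1, 1.0] as Newick."""
    nodes = [(lab, None) for lab in labels]  # (newick, None)
    items = [f"{lab}:{rng.uniform(0.1, 1.0):.6f}" for lab in labels]
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]}):{rng.uniform(0.1, 1.0):.6f}"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return f"({items[0]},{items[1]});"


def leaf_path_lengths(tree) -> dict[tuple[str, str], float]:
    """Pairwise leaf-to-leaf path lengths of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    return {
        (x, y): pdm.distance(taxa[x], taxa[y])
        for x, y in itertools.combinations(labels, 2)
    }
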