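import math

import numpy as np
import pytest

from gudgar import iohub, phylo, synthgen
from gudgar.phylo import (
    MSA,
    column_entropy,
    detect_nested_clades,
    diagnostic_residues,
    distance_matrix,
    fitch_states,
    nj_tree,
    pairwise_identity,
    trim_msa,
)

from _oracles import (
    exhaustive_parsimony_score,
    leaf_path_lengths,
    random_binary_tree_newick,
)


# ---------------------------------------------------------------------------
# identity


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKV", "MKV") == 100.0

    def test_two_of_three(self):
        assert pairwise_identity("MKV", "MAV") == pytest.approx(66.67, abs=0.01)

    def test_gap_columns_counted_when_one_residue(self):
        # gap vs residue is a counted (non-matching) column; gap vs gap is not
        assert pairwise_identity("M-KV", "MAKV") == pytest.approx(75.0)
        assert pairwise_identity("M--V", "M--V") == pytest.approx(100.0)

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("---", "---")

    def test_matches_hand_count_on_random_pairs(self, rng):
        alphabet = list("ACDEFG-")
        for _ in range(50):
            n = int(rng.integers(5, 40))
            a = "".join(rng.choice(alphabet, size=n))
            b = "".join(rng.choice(alphabet, size=n))
            cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
            if not cols:
                continue
            matches = sum(1 for x, y in cols if x == y and x != "-")
            assert pairwise_identity(a, b) == pytest.approx(100.0 * matches / len(cols))

    def test_unequal_lengths_aligned_globally(self):
        assert pairwise_identity("MKVA", "MKA") > 0.0


# ---------------------------------------------------------------------------
# trimming


class TestTrimMsa:
    def _msa_with_gap_column(self, n_gaps, n_rows=100):
        rows = []
        for i in range(n_rows):
            first = "-" if i < n_gaps else "M"
            rows.append((f"r{i}", first + "KV"))
        return MSA(records=rows)

    def test_column_over_threshold_removed(self):
        msa = self._msa_with_gap_column(98)
        trimmed, kept = trim_msa(msa, 0.97)
        assert trimmed.n_columns == 2
        assert kept == [1, 2]

    def test_column_exactly_at_threshold_kept(self):
        msa = self._msa_with_gap_column(97)
        trimmed, _ = trim_msa(msa, 0.97)
        assert trimmed.n_columns == 3

    def test_idempotent(self, rng):
        rows = [
            (f"r{i}", "".join(rng.choice(list("MKV-"), size=30, p=[0.2, 0.2, 0.2, 0.4])))
            for i in range(20)
        ]
        msa = MSA(records=rows)
        once, _ = trim_msa(msa, 0.5)
        twice, _ = trim_msa(once, 0.5)
        assert once.records == twice.records

    def test_everything_removed_rejected(self):
        msa = MSA(records=[("a", "--"), ("b", "--"), ("c", "M-")])
        with pytest.raises(ValueError):
            trim_msa(msa, 0.1)


# ---------------------------------------------------------------------------
# distances


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        D, _ = distance_matrix(MSA(records=[("a", "MKVL"), ("b", "MKVL")]))
        assert D[0, 1] == 0.0

    def test_half_different_gives_ln2(self):
        D, _ = distance_matrix(MSA(records=[("a", "MKVL"), ("b", "MKAC")]))
        assert D[0, 1] == pytest.approx(math.log(2.0))

    def test_saturation_capped(self):
        D, _ = distance_matrix(MSA(records=[("a", "MKVL"), ("b", "ACDE")]), d_max=10.0)
        assert D[0, 1] == 10.0

    def test_symmetric_zero_diagonal(self, rng):
        rows = [
            (f"r{i}", "".join(rng.choice(list("MKVACD-"), size=50)))
            for i in range(8)
        ]
        D, _ = distance_matrix(MSA(records=rows))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_disjoint_gap_patterns_rejected(self):
        msa = MSA(records=[("a", "MK--"), ("b", "--VL")])
        with pytest.raises(ValueError, match="a.*b"):
            distance_matrix(msa)


# ---------------------------------------------------------------------------
# neighbor joining


class TestNjTree:
    def test_four_taxon_worked_example(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)): additive, so NJ is exact
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(D, labels)
        d = leaf_path_lengths(tree)
        for (x, y), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert d[(x, y)] == pytest.approx(expected, abs=1e-9)
        # topology AB|CD: the path A-B shares no edge with C-D
        newick = iohub.write_newick(tree)
        assert ("A" in newick) and ("B" in newick)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 5], [4, 0, 7], [5, 7, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        d = leaf_path_lengths(tree)
        assert d[("a", "b")] == pytest.approx(4.0)
        assert d[("a", "c")] == pytest.approx(5.0)
        assert d[("b", "c")] == pytest.approx(7.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError):
            nj_tree(D, ["a", "b", "c"])

    def test_exact_recovery_from_random_additive_matrices(self, rng):
        for trial in range(30):
            labels = [f"t{i}" for i in range(10)]
            true = iohub.parse_newick(random_binary_tree_newick(labels, rng))
            true_d = leaf_path_lengths(true)
            n = len(labels)
            D = np.zeros((n, n))
            for (x, y), v in true_d.items():
                i, j = labels.index(x), labels.index(y)
                D[i, j] = D[j, i] = v
            rec = nj_tree(D, labels)
            rec_d = leaf_path_lengths(rec)
            for k, v in true_d.items():
                assert rec_d[k] == pytest.approx(v, abs=1e-6)
            # path-length equality over all pairs implies identical topology
            # for trees with positive internal branches (additive uniqueness)


# ---------------------------------------------------------------------------
# Fitch parsimony


class TestFitch:
    def test_forced_two_state(self):
        tree = iohub.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = fitch_states(tree, {"A": "M", "B": "M", "C": "Y", "D": "Y"})
        assert res.root_set == {"M", "Y"}
        assert res.score == 1

    def test_uniform_leaves_score_zero(self):
        tree = iohub.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = fitch_states(tree, {l: "M" for l in "ABCD"})
        assert res.score == 0
        assert res.assigned[res.tree.seed_node] == "M"

    def test_missing_state_is_uninformative(self):
        tree = iohub.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = fitch_states(tree, {"A": "M", "B": None, "C": "M", "D": "M"})
        assert res.score == 0

    def test_matches_enumeration_oracle(self, rng):
        states = ["A", "C", "G", "T"]
        for trial in range(60):
            n_leaves = int(rng.integers(3, 8))
            n_states = int(rng.integers(2, 5))
            labels = [f"l{i}" for i in range(n_leaves)]
            tree = iohub.parse_newick(random_binary_tree_newick(labels, rng))
            leaf_states = {
                lab: states[int(rng.integers(n_states))] for lab in labels
            }
            res = fitch_states(tree, leaf_states, alphabet=states[:n_states])
            expected = exhaustive_parsimony_score(tree, leaf_states, states[:n_states])
            assert res.score == expected, f"trial {trial}"


# ---------------------------------------------------------------------------
# diagnostic residues


class TestDiagnosticResidues:
    @pytest.fixture
    def setup(self):
        # 8 leaves, focal clade = {F1..F4}; column 3 is the planted Y->M
        # change, column 5 the planted N->K change, others uniform
        tree = iohub.parse_newick(
            "(((F1:1,F2:1):1,(F3:1,F4:1):1):1,((O1:1,O2:1):1,(O3:1,O4:1):1):1);"
        )
        rows = []
        for lab in ["F1", "F2", "F3", "F4", "O1", "O2", "O3", "O4"]:
            focal = lab.startswith("F")
            seq = "AC" + ("M" if focal else "Y") + "D" + ("K" if focal else "N") + "E"
            rows.append((lab, seq))
        return tree, MSA(records=rows)

    def test_planted_columns_recovered_exactly(self, setup):
        tree, msa = setup
        changes, entropies = diagnostic_residues(msa, tree, ["F1", "F2", "F3", "F4"])
        assert [(c.column, c.ancestral_state, c.derived_state) for c in changes] == [
            (3, "Y", "M"),
            (5, "N", "K"),
        ]
        assert all(c.clade_conservation == 1.0 for c in changes)

    def test_uniform_column_not_reported_entropy_zero(self, setup):
        tree, msa = setup
        changes, entropies = diagnostic_residues(msa, tree, ["F1", "F2", "F3", "F4"])
        assert entropies[0] == 0.0
        assert all(c.column != 1 for c in changes)

    def test_half_half_column_entropy_ln2(self, setup):
        _, msa = setup
        assert column_entropy(list("MMMMYYYY")) == pytest.approx(math.log(2.0))

    def test_non_monophyletic_focal_rejected(self, setup):
        tree, msa = setup
        with pytest.raises(ValueError, match="monophyletic"):
            diagnostic_residues(msa, tree, ["F1", "O1"])

    def test_conservation_threshold_filters(self, setup):
        tree, _ = setup
        rows = [
            (lab, ("M" if lab in ("F1", "F2") else "V") + "A")
            for lab in ["F1", "F2", "F3", "F4", "O1", "O2", "O3", "O4"]
        ]
        # focal clade is 2 M + 2 V at column 1: conservation 0.5 < 0.9
        changes, _ = diagnostic_residues(MSA(records=rows), tree, ["F1", "F2", "F3", "F4"])
        assert changes == []


# ---------------------------------------------------------------------------
# nested clades (HGT signal)


class TestDetectNestedClades:
    GROUPS = {
        "B1": "Bacillota", "B2": "Bacillota", "B3": "Bacillota", "B4": "Bacillota",
        "F1": "Fusobacteriota", "F2": "Fusobacteriota",
    }

    def test_nested_foreign_clade_reported(self):
        t = iohub.parse_newick("((B1:1,B2:1):1,((F1:1,F2:1):1,(B3:1,B4:1):1):1);")
        events = detect_nested_clades(t, self.GROUPS)
        assert len(events) == 1
        e = events[0]
        assert e.foreign_clade_leaves == {"F1", "F2"}
        assert e.foreign_group == "Fusobacteriota"
        assert e.host_group == "Bacillota"

    def test_concordant_tree_clean(self):
        t = iohub.parse_newick("((B1:1,B2:1):1,(F1:1,F2:1):1);")
        groups = {k: self.GROUPS[k] for k in ["B1", "B2", "F1", "F2"]}
        assert detect_nested_clades(t, groups) == []

    def test_support_filter(self):
        t = iohub.parse_newick("((B1:1,B2:1):1,((F1:1,F2:1)50:1,(B3:1,B4:1)90:1):1);")
        assert detect_nested_clades(t, self.GROUPS, support_min=75) == []
        assert len(detect_nested_clades(t, self.GROUPS, support_min=40)) == 1

    def test_unknown_group_rejected(self):
        t = iohub.parse_newick("((B1:1,B2:1):1,(F1:1,XX:1):1);")
        with pytest.raises(ValueError, match="XX"):
            detect_nested_clades(t, self.GROUPS)

    def test_min_foreign_threshold(self):
        groups = dict(self.GROUPS, B5="Bacillota")
        t = iohub.parse_newick(
            "(((B1:1,B2:1):1,F2:1):1,((F1:1,B3:1):1,(B4:1,B5:1):1):1);"
        )
        assert detect_nested_clades(t, groups, min_foreign=2) == []
        found = detect_nested_clades(t, groups, min_foreign=1)
        assert len(found) == 1 and found[0].foreign_clade_leaves == {"F1"}

    def test_injected_transfer_flagged_in_simulation(self, hgt_events_sample):
        detected, clean_nulls, n = hgt_events_sample
        assert detected / n >= 0.9
        assert clean_nulls / n >= 0.9


@pytest.fixture(scope="module")
def hgt_events_sample():
    """20-replicate spot check of the HGT simulation (the full 100-replicate
    run lives in the acceptance suite)."""
    detected = clean = n = 20
    det = cln = 0
    for s in range(n):
        events, recipient = _hgt_replicate(s, with_hgt=True)
        det += int(
            bool(events)
            and all(recipient in e.foreign_clade_leaves for e in events)
        )
        events0, _ = _hgt_replicate(s, with_hgt=False)
        cln += int(events0 == [])
    return det, cln, n


def _hgt_replicate(seed, with_hgt):
    tree = synthgen.simulate_species_tree(20, 1.0, seed, clade_separation=1.0)
    groups = synthgen.phylum_groups(tree)
    rng = np.random.default_rng(seed + 10_000)
    root = synthgen.random_protein(300, rng)
    hist = synthgen.evolve_family(root, tree, 0.15, seed=seed + 20_000)
    sizes = {g: sum(1 for v in groups.values() if v == g) for g in set(groups.values())}
    donor_group = max(sizes, key=lambda g: (sizes[g], g))
    donors = sorted(l for l, g in groups.items() if g == donor_group)
    recips = sorted(l for l, g in groups.items() if g != donor_group)
    recipient = recips[int(rng.integers(len(recips)))]
    if with_hgt:
        h2, _ = synthgen.inject_hgt(
            {"fam": hist}, donors, recipient, seed=seed + 30_000, families=["fam"]
        )
        hist = h2["fam"]
    msa = MSA(records=sorted(hist.items()))
    D, labels = distance_matrix(msa)
    events = detect_nested_clades(nj_tree(D, labels), groups, min_foreign=1)
    return events, recipient


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_supports_high_on_clean_signal():
    tree = synthgen.simulate_species_tree(8, 1.0, 2, clade_separation=0.5)
    root = synthgen.random_protein(400, np.random.default_rng(0))
    hist = synthgen.evolve_family(root, tree, 0.15, seed=1)
    msa = MSA(records=sorted(hist.items()))
    boot = phylo.bootstrap_nj(msa, n_replicates=50, seed=3)
    supports = [
        int(n.label) for n in boot.preorder_internal_node_iter()
        if n.label is not None
    ]
    assert supports and np.mean(supports) > 60
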