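from __future__ import annotations

import numpy as np
import pytest

from gudgar import pathcall, profsearch, synthgen

SEARCH_FAMILIES = ("gudD", "garD", "garL", "garR", "gudL")
#: families with an E. coli counterpart; the discovery scenario searches with
#: these only, so the alternative aldolase and transporter stay unannotated
HOMOLOG_FAMILIES = ("gudD", "garD", "garL", "garR")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_601)


def build_profiles(family_histories, families=SEARCH_FAMILIES, n_seeds=8, seed=11):
    profiles = []
    for fam in families:
        history = {k: v for k, v in family_histories[fam].items() if k != "__root__"}
        prof = profsearch.build_pssm(
            synthgen.seed_alignment(history, n_seeds, seed=seed), family_id=fam
        )
        profsearch.calibrate_null(prof, n_shuffles=200, seed=seed + 1)
        profiles.append(prof)
    return profiles


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard planted-pathway study: 50 genomes, 20 complete clusters
    across both layouts, 10 single-deletion decoys, 20 cluster-free genomes."""
    spec = synthgen.SimSpec(n_taxa=50, seed=3)
    tree = synthgen.simulate_species_tree(50, spec.birth_rate, spec.seed)
    genomes, truth, histories = synthgen.plant_genomes(
        tree, spec, n_complete=20, n_decoy=10
    )
    return {"spec": spec, "tree": tree, "genomes": genomes, "truth": truth,
            "histories": histories}


@pytest.fixture(scope="session")
def planted_search(planted_dataset):
    """Profile search plus pathway calls over the planted dataset."""
    profiles = build_profiles(planted_dataset["histories"])
    proteomes = {
        g.genome_id: [(x.locus_tag, x.protein_seq) for x in g.genes]
        for g in planted_dataset["genomes"]
    }
    hits = profsearch.search_proteome(profiles, proteomes, e_cutoff=1e-10)
    grammar = pathcall.PathwayGrammar.from_string()
    calls = pathcall.call_all(hits, grammar, proteomes.keys())
    return {"profiles": profiles, "proteomes": proteomes, "hits": hits,
            "grammar": grammar, "calls": calls}
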