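"""Shared fixtures: a mini taxonomy and simple truths/profiles."""

from __future__ import annotations

import pytest

from dmcbench import (
    GroundTruth,
    GroundTruthEntry,
    SimulationSpec,
    load_taxonomy,
    make_mini_taxonomy,
    make_truth,
)

TRUTH_SPECIES = [
    "Escherichia coli",
    "Bacillus subtilis",
    "Listeria monocytogenes",
    "Salmonella enterica",
    "Pseudomonas aeruginosa",
]


@pytest.fixture(scope="session")
def taxdump_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("taxdump")
    return make_mini_taxonomy(
        TRUTH_SPECIES,
        n_decoys=12,
        n_merged=2,
        n_deleted=1,
        seed=42,
        out_dir=out,
        strains_per_species=2,
    )


@pytest.fixture(scope="session")
def mini_ref(taxdump_paths):
    p = taxdump_paths
    return load_taxonomy(p["nodes"], p["names"], p["merged"], p["delnodes"])


@pytest.fixture(scope="session")
def even_truth(mini_ref):
    """Even five-species truth over the fixture's named species."""
    entries = []
    for name in TRUTH_SPECIES:
        taxid = mini_ref.name_index[name.lower()]
        entries.append(
            GroundTruthEntry(taxid=taxid, name=name, fraction=0.2, genome_length=4_000_000)
        )
    return GroundTruth(dmc_id="even5", entries=entries)


@pytest.fixture(scope="session")
def truth_no_abundances(mini_ref):
    """Truth whose exact relative abundances are unknown."""
    entries = []
    for name in TRUTH_SPECIES[:3]:
        taxid = mini_ref.name_index[name.lower()]
        entries.append(GroundTruthEntry(taxid=taxid, name=name))
    return GroundTruth(dmc_id="noabund3", entries=entries)


@pytest.fixture()
def clean_spec():
    return SimulationSpec(n_species=5, seed=11)


@pytest.fixture()
def sim_truth(mini_ref, clean_spec):
    return make_truth(clean_spec, mini_ref)
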