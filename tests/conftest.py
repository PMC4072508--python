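"""Shared fixtures: one planted complex/database/model set per session."""

import warnings

import numpy as np
import pytest

from bh3scan import pssm, statium, structio, synth


@pytest.fixture(scope="session")
def complex_and_truth():
    return synth.gen_complex(seed=1)


@pytest.fixture(scope="session")
def template(complex_and_truth):
    text, _ = complex_and_truth
    structure = structio.read_structure(text)
    return structio.build_template(structure, "R", "P", anchor=12,
                                   receptor_name="Mcl-1")


@pytest.fixture(scope="session")
def sc_crit():
    return statium.InteractionCriterion.sc()


@pytest.fixture(scope="session")
def sc_pairs(template, sc_crit):
    return statium.detect_pairs(template, sc_crit)


@pytest.fixture(scope="session")
def planted_db(template, sc_pairs):
    texts, expected = synth.gen_structure_db(
        template, sc_pairs, n_structures=150, n_decoys=15, seed=2)
    return [structio.read_structure(t) for t in texts], expected


@pytest.fixture(scope="session")
def sc_model(template, sc_pairs, sc_crit, planted_db):
    db, _ = planted_db
    counts = statium.scan_database(sc_pairs, db, sc_crit)
    bg = statium.background_frequencies(db)
    return statium.derive_potential(counts, sc_pairs, bg,
                                    receptor_name="Mcl-1", variant="SC")


@pytest.fixture(scope="session")
def pssm_model():
    table = pssm.SpotTable.from_tsv(synth.gen_spot_table(seed=4))
    return pssm.build_pssm(table, receptor_name="Mcl-1")


@pytest.fixture(scope="session")
def proteome_and_truth():
    fasta, truth = synth.gen_proteome(seed=9)
    return fasta, truth


@pytest.fixture(autouse=True)
def _quiet_low_count_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message=".*fewer than 100 counts.*")
        yield
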