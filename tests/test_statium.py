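"""Interaction detection, fingerprints, database scanning, potentials."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bh3scan import statium, structio, synth
from bh3scan.statium import (
    InteractionCriterion,
    derive_potential,
    detect_pairs,
    fingerprint_rmsd,
    scan_database,
)
from bh3scan.structio import (
    AA_INDEX,
    AA_ORDER,
    SIDECHAIN_ATOMS,
    Atom,
    Residue,
    StructureModel,
    virtual_cbeta,
)

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation's KD-trees)
# ---------------------------------------------------------------------------

def brute_pairs_sc(template, cutoff=6.0):
    out = set()
    for label, pres in zip(template.register.labels, template.peptide):
        pep = [pres.coords("CA"), virtual_cbeta(pres)]
        for rres in template.receptor:
            names = SIDECHAIN_ATOMS[rres.aa] or ["CA"]
            coords = [rres.coords(n) for n in names
                      if rres.coords(n) is not None]
            if not coords:
                continue
            dmin = min(np.linalg.norm(p - c) for p in pep for c in coords)
            if dmin < cutoff:
                out.add((label, rres.key))
    return out


def brute_pairs_cb(template, cutoff=10.0, angle=True):
    out = set()
    for label, pres in zip(template.register.labels, template.peptide):
        ca_i, cb_i = pres.coords("CA"), virtual_cbeta(pres)
        for rres in template.receptor:
            ca_j, cb_j = rres.coords("CA"), virtual_cbeta(rres)
            if np.linalg.norm(cb_i - cb_j) >= cutoff:
                continue
            if angle:
                if np.dot(cb_i - ca_i, cb_j - cb_i) < 0:
                    continue
                if np.dot(cb_j - ca_j, cb_i - cb_j) < 0:
                    continue
            out.add((label, rres.key))
    return out


def _detected(pairs):
    return {(p.pep_pos, p.rec_key[:2]) for p in pairs}


# ---------------------------------------------------------------------------
# detect_pairs
# ---------------------------------------------------------------------------

def _two_residue_template(gap):
    """One peptide residue and one receptor Ser whose OG sits ``gap`` A from
    the peptide Cbeta."""
    pep = Residue("P", 1, "L", [
        Atom("N", "N", [0.0, 1.4, 0.0]),
        Atom("CA", "C", [0.0, 0.0, 0.0]),
        Atom("C", "C", [1.0, -1.0, 0.0]),
        Atom("CB", "C", [0.0, 0.0, 1.52]),
    ])
    rec = Residue("R", 1, "S", [
        Atom("N", "N", [40.0, 1.4, 0.0]),
        Atom("CA", "C", [40.0, 0.0, 0.0]),
        Atom("C", "C", [41.0, -1.0, 0.0]),
        Atom("CB", "C", [40.0, 0.0, 1.0]),
        Atom("OG", "O", [0.0, gap, 1.52]),
    ])
    register = structio.HeptadRegister(["3a"])
    return structio.TemplateComplex(receptor=[rec], peptide=[pep],
                                    register=register)


def test_sc_pair_detected_just_inside_cutoff():
    tc = _two_residue_template(gap=5.9)
    pairs = detect_pairs(tc, InteractionCriterion.sc())
    assert _detected(pairs) == {("3a", ("R", 1))}


def test_sc_pair_missed_just_outside_cutoff():
    tc = _two_residue_template(gap=6.1)
    assert detect_pairs(tc, InteractionCriterion.sc()) == []


def test_detect_pairs_matches_brute_force_on_planted_complex(template):
    sc = detect_pairs(template, InteractionCriterion.sc())
    assert _detected(sc) == brute_pairs_sc(template)
    cb = detect_pairs(template, InteractionCriterion.cb())
    assert _detected(cb) == brute_pairs_cb(template)


@pytest.mark.parametrize("seed,offset,scale", [
    (11, 4.0, 1.0), (12, 4.8, 1.0), (13, 5.4, 1.0), (14, 4.2, 2.0),
])
def test_detect_pairs_matches_brute_force_on_varied_geometries(
        seed, offset, scale):
    rng = np.random.default_rng(seed)
    labels = sorted(rng.choice(structio.EXTENDED_REGISTER,
                               size=rng.integers(3, 9), replace=False),
                    key=structio.heptad_index)
    text, _ = synth.gen_complex(seed=seed, planted_labels=tuple(labels),
                                contact_offset=offset, spacing_scale=scale)
    structure = structio.read_structure(text)
    tc = structio.build_template(structure, "R", "P", anchor=12)
    for crit, oracle in ((InteractionCriterion.sc(), brute_pairs_sc),
                         (InteractionCriterion.cb(), brute_pairs_cb)):
        assert _detected(detect_pairs(tc, crit)) == oracle(tc)


def test_planted_contacts_are_exactly_recovered(complex_and_truth, template,
                                                sc_pairs):
    _, truth = complex_and_truth
    assert sorted((p.pep_pos, p.rec_key[1]) for p in sc_pairs) == sorted(truth)


# ---------------------------------------------------------------------------
# fingerprint_rmsd
# ---------------------------------------------------------------------------

def test_fingerprint_rmsd_examples():
    assert fingerprint_rmsd([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0
    # one of four distances differing by 0.8 -> sqrt(0.64/4) = 0.4, which is
    # NOT strictly below the 0.4 matching cutoff
    r = fingerprint_rmsd([1.0, 1.0, 1.0, 1.0], [1.8, 1.0, 1.0, 1.0])
    assert r == pytest.approx(0.4, abs=1e-12)
    assert not r < 0.4
    with pytest.raises(ValueError):
        fingerprint_rmsd([1, 2, 3, 4], [1, 2, 3, 4, 5, 6])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 50), min_size=4, max_size=4),
       st.lists(st.floats(0, 50), min_size=4, max_size=4),
       st.lists(st.floats(0, 50), min_size=4, max_size=4))
def test_fingerprint_rmsd_is_a_metric(a, b, c):
    dab = fingerprint_rmsd(a, b)
    assert dab >= 0
    assert dab == fingerprint_rmsd(b, a)
    if a == b:
        assert dab == 0.0
    assert dab <= fingerprint_rmsd(a, c) + fingerprint_rmsd(c, b) + 1e-9


# ---------------------------------------------------------------------------
# scan_database
# ---------------------------------------------------------------------------

def test_database_self_copy_matches_and_counts_are_exact(
        template, sc_pairs, sc_crit, planted_db):
    db, expected = planted_db
    counts = scan_database(sc_pairs, db, sc_crit)
    for tp, vec in zip(sc_pairs, counts):
        got = {AA_ORDER[i]: int(n) for i, n in enumerate(vec) if n}
        assert got == expected[tp.pep_pos]


def test_receptor_identity_mismatch_contributes_nothing(
        template, sc_pairs, sc_crit, planted_db):
    db, _ = planted_db
    # relabel every template pair's receptor to an aa absent from the db
    fake = [statium.TemplatePair(tp.pep_pos,
                                 (tp.rec_key[0], tp.rec_key[1], "C"),
                                 statium.SIDECHAIN_ATOMS["C"],
                                 tp.fingerprint[:4])
            for tp in sc_pairs]
    counts = scan_database(fake, db, sc_crit)
    assert all(int(v.sum()) == 0 for v in counts)


def test_empty_database_warns_and_returns_zero_counts(sc_pairs, sc_crit):
    with pytest.warns(UserWarning, match="empty"):
        counts = scan_database(sc_pairs, [], sc_crit)
    assert all(int(v.sum()) == 0 for v in counts)


def test_decreasing_rmsd_cutoff_never_increases_counts(
        template, sc_pairs, planted_db):
    db, _ = planted_db
    prev = None
    for cutoff in (1.0, 0.7, 0.4, 0.1):
        crit = InteractionCriterion.sc(fingerprint_rmsd_cutoff=cutoff)
        counts = np.array(scan_database(sc_pairs, db[:40], crit))
        if prev is not None:
            assert np.all(counts <= prev)
        prev = counts


# ---------------------------------------------------------------------------
# derive_potential / scoring
# ---------------------------------------------------------------------------

def _single_pair(pep_pos="3a"):
    return [statium.TemplatePair(pep_pos, ("R", 1, "S"), ["CB", "OG"],
                                 np.array([1.0, 2.0, 3.0, 4.0]))]


def test_energy_zero_when_frequencies_match_background():
    pairs = _single_pair()
    bg = np.full(20, 0.05)
    counts = [np.full(20, 5)]  # uniform -> P_aa == bg after pseudocounts
    model = derive_potential(counts, pairs, bg, pseudocount_mass=20.0)
    np.testing.assert_allclose(model.energies, 0.0, atol=1e-12)


def test_energy_hand_computation_and_pseudocount_behaviour():
    pairs = _single_pair()
    bg = np.full(20, 0.05)
    counts = [np.zeros(20, dtype=int)]
    counts[0][AA_INDEX["L"]] = 20  # P_L = 0.20 with 80 spread over others
    for aa in "ACDE":
        counts[0][AA_INDEX[aa]] = 20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = derive_potential(counts, pairs, bg, pseudocount_mass=0.0)
    # P = 0.20 vs bg 0.05 -> E = -ln 4
    assert model.energies[0, AA_INDEX["L"]] == pytest.approx(-math.log(4.0))
    # zero-count aa with pseudocounts -> finite positive energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model20 = derive_potential(counts, pairs, bg, pseudocount_mass=20.0)
    e = model20.energies[0, AA_INDEX["W"]]
    assert np.isfinite(e) and e > 0
    # per-pair frequencies sum to one after pseudocounts
    p = np.exp(-model20.energies[0]) * bg
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_zero_counts_without_pseudocounts_is_an_error():
    with pytest.raises(ValueError):
        derive_potential([np.zeros(20, dtype=int)], _single_pair(),
                         np.full(20, 0.05), pseudocount_mass=0.0)


def test_planted_ratio_recovery(template, sc_pairs, sc_crit):
    """Energy differences recover -ln of the planted preference ratio."""
    prefs = {"3a": {"L": 0.8, "G": 0.2}}
    texts, _ = synth.gen_structure_db(template, sc_pairs, preferences=prefs,
                                      n_structures=200, n_decoys=10, seed=21)
    db = [structio.read_structure(t) for t in texts]
    sub = [tp for tp in sc_pairs if tp.pep_pos == "3a"]
    counts = scan_database(sub, db, sc_crit)
    bg = np.full(20, 0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = derive_potential(counts, sub, bg, pseudocount_mass=0.0)
    diff = model.energies[0, AA_INDEX["L"]] - model.energies[0, AA_INDEX["G"]]
    assert diff == pytest.approx(-math.log(0.8 / 0.2), abs=1e-9)


def test_score_is_additive_and_argmin_matches_planting(sc_model):
    seq = synth.CONSENSUS_26
    labels = structio.EXTENDED_REGISTER
    total = sc_model.score(seq, labels)
    # additivity: sum of per-position contributions queried individually
    by_pos = sc_model.position_matrix()
    manual = sum(by_pos[lab][AA_INDEX[seq[i]]]
                 for i, lab in enumerate(labels) if lab in by_pos)
    assert total == pytest.approx(manual)
    assert total >= sc_model.min_score() - 1e-9
    # the planted Asp preference at 3f makes Asp the top amino acid there
    assert AA_ORDER[int(np.argmin(by_pos["3f"]))] == "D"
    with pytest.raises(ValueError):
        sc_model.score(seq[:10], labels[:10])


def test_model_json_round_trip(sc_model):
    again = statium.StatiumModel.from_json(sc_model.to_json())
    np.testing.assert_allclose(again.energies, sc_model.energies)
    assert [p.pep_pos for p in again.pairs] == \
        [p.pep_pos for p in sc_model.pairs]
    seq = synth.CONSENSUS_26
    assert again.score(seq, structio.EXTENDED_REGISTER) == \
        pytest.approx(sc_model.score(seq, structio.EXTENDED_REGISTER))
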