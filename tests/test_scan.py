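"""Window enumeration, composition filters, Z-scores and selection."""

import math

import numpy as np
import pandas as pd
import pytest

from bh3scan import scan, structio, synth
from bh3scan.scan import (
    BackgroundDistribution,
    CandidateWindow,
    FilterConfig,
    combine_z,
    composition_filter,
    enumerate_windows,
    fit_background,
    identity_fraction,
    redundancy_filter,
    select_candidates,
    zscore,
)
from bh3scan.structio import EXTENDED_REGISTER

LBL = {lab: i for i, lab in enumerate(EXTENDED_REGISTER)}


def _window(seq):
    return CandidateWindow("p", 0, seq)


def _make_seq(**overrides):
    seq = list(synth.CONSENSUS_26)
    for label, aa in overrides.items():
        seq[LBL[label]] = aa
    return "".join(seq)


# ---------------------------------------------------------------------------
# enumerate_windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,expected", [(26, 1), (30, 5), (25, 0)])
def test_window_counts(length, expected):
    windows = list(enumerate_windows({"p": "A" * length}))
    assert len(windows) == expected
    if windows:
        assert all(len(w.sequence) == 26 for w in windows)
        assert windows[0].start == 0


def test_windows_with_bad_characters_skipped():
    seq = "A" * 26 + "X" + "A" * 26
    with pytest.warns(UserWarning):
        windows = list(enumerate_windows({"p": seq}))
    # every window spanning the X is dropped: 53-26+1=28 minus 26 spanning
    assert len(windows) == 2
    assert {w.start for w in windows} == {0, 27}


def test_core_is_suffix_of_window():
    w = _window(synth.CONSENSUS_26)
    assert w.core == w.sequence[3:]
    assert len(w.core) == 23


# ---------------------------------------------------------------------------
# composition_filter
# ---------------------------------------------------------------------------

def test_filter_accepts_bh3_like_window():
    seq = _make_seq()
    polar = sum(c in "DEHKNQRST" for c in seq)
    assert polar / 26 >= 0.35
    assert composition_filter(_window(seq))


def test_filter_rejects_two_core_prolines():
    assert not composition_filter(_window(_make_seq(**{"2f": "P", "3c": "P"})))
    # one core proline is allowed
    assert composition_filter(_window(_make_seq(**{"3c": "P"})))


def test_filter_rejects_polar_residue_at_3a():
    assert not composition_filter(_window(_make_seq(**{"3a": "D"})))


def test_filter_rejects_large_residue_at_3e():
    assert not composition_filter(_window(_make_seq(**{"3e": "W"})))


def test_filter_rejects_low_polar_fraction():
    seq = _make_seq()
    seq = "L" * 14 + seq[14:]  # wipe out the polar N-terminal half
    assert sum(c in "DEHKNQRST" for c in seq) / 26 < 0.35
    assert not composition_filter(_window(seq))


def test_filter_counts_match_brute_force_reimplementation(proteome_and_truth):
    fasta, _ = proteome_and_truth
    prot = scan.read_proteome(fasta)
    windows = list(enumerate_windows(prot))
    got = sum(composition_filter(w) for w in windows)

    def brute(seq):
        return (sum(c in "DEHKNQRST" for c in seq) / 26 >= 0.35
                and seq[7:19].count("P") <= 1
                and seq[11] in "FILVYWM"
                and seq[15] in "ACGS")

    assert got == sum(brute(w.sequence) for w in windows)
    assert got > 0


# ---------------------------------------------------------------------------
# background / zscore / combine
# ---------------------------------------------------------------------------

def test_fit_background_hand_example_and_errors():
    bg = fit_background([0.0, 2.0])
    assert bg.mean == 1.0
    assert bg.sd == pytest.approx(math.sqrt(2.0))
    with pytest.raises(ValueError):
        fit_background([1.0])
    with pytest.raises(ValueError):
        fit_background([3.0, 3.0, 3.0])


def test_fit_background_recovers_normal_parameters():
    rng = np.random.default_rng(5)
    bg = fit_background(rng.normal(-4.0, 2.5, size=100_000))
    assert bg.mean == pytest.approx(-4.0, abs=0.04)
    assert bg.sd == pytest.approx(2.5, rel=0.01)


def test_zscore_orientation():
    bg = BackgroundDistribution(mean=10.0, sd=2.0, n=100)
    assert zscore(10.0, bg) == 0.0
    assert zscore(10.0 - 2 * 2.0, bg) == 2.0   # lower energy -> better
    assert zscore(12.0, bg) == -1.0
    # strictly decreasing in raw energy
    assert zscore(9.0, bg) > zscore(9.5, bg)


def test_combine_z_examples():
    assert combine_z(2.0, 4.0) == 3.0
    assert combine_z(1.5, 1.5) == 1.5
    assert combine_z(-1.0, 3.0) == 1.0
    assert min(-1.0, 3.0) <= combine_z(-1.0, 3.0) <= max(-1.0, 3.0)
    with pytest.raises(ValueError):
        combine_z(None, 1.0)


# ---------------------------------------------------------------------------
# redundancy filter / selection
# ---------------------------------------------------------------------------

def test_redundancy_filter_greedy_chain():
    base = synth.CONSENSUS_26

    def mutate(seq, positions, aa="K"):
        s = list(seq)
        for p in positions:
            s[p] = aa if s[p] != aa else "N"
        return "".join(s)

    a = base
    b = mutate(base, range(0, 6))          # ~77% identical to a
    c = mutate(base, range(0, 12))         # ~77% to b, ~54% to a
    assert identity_fraction(a, b) > 0.75
    assert identity_fraction(b, c) > 0.75
    assert identity_fraction(a, c) <= 0.75
    kept = redundancy_filter([a, b, c], scores=[3.0, 2.0, 1.0])
    assert kept == [a, c]


def test_redundancy_filter_identical_sequences_keep_best():
    w1 = CandidateWindow("p1", 0, synth.CONSENSUS_26)
    w2 = CandidateWindow("p2", 5, synth.CONSENSUS_26)
    kept = redundancy_filter([w1, w2], scores=[1.0, 2.0])
    assert kept == [w2]


def test_redundancy_filter_unrelated_sequences_both_kept():
    a = "A" * 26
    b = "K" * 26
    assert redundancy_filter([a, b], scores=[1.0, 0.5]) == [a, b]


def _selection_frame(n, z_pssm, z_sc, raw_sc):
    return pd.DataFrame({
        "sequence": [f"w{i}" for i in range(n)],
        "z_pssm": z_pssm, "z_sc": z_sc, "raw_sc": raw_sc,
    })


def test_select_candidates_top_k_ordering():
    n = 30
    df = _selection_frame(n, z_pssm=[3.0] * n,
                          z_sc=list(np.linspace(5, 1, n)),
                          raw_sc=[-1.0] * n)
    out = select_candidates(df, "z_pssm", "z_sc", "raw_sc",
                            pssm_z_cutoff=2.0, top_k=20)
    assert len(out) == 20
    assert list(out["z_sc"]) == sorted(out["z_sc"], reverse=True)
    assert out["z_sc"].iloc[0] == 5.0


def test_select_candidates_cutoffs():
    df = _selection_frame(3, z_pssm=[1.0, 1.5, 1.9], z_sc=[5, 5, 5],
                          raw_sc=[-1, -1, -1])
    assert len(select_candidates(df, "z_pssm", "z_sc", "raw_sc", 2.0)) == 0
    df2 = _selection_frame(2, z_pssm=[3.0, 3.0], z_sc=[4.0, 5.0],
                           raw_sc=[0.5, -0.5])
    out = select_candidates(df2, "z_pssm", "z_sc", "raw_sc", 2.0,
                            require_raw_sc_negative=True)
    assert list(out["raw_sc"]) == [-0.5]


# ---------------------------------------------------------------------------
# end-to-end scan properties
# ---------------------------------------------------------------------------

def test_scan_background_z_has_mean_zero_sd_one(proteome_and_truth, sc_model,
                                                pssm_model):
    fasta, _ = proteome_and_truth
    prot = scan.read_proteome(fasta)
    df, bgs = scan.scan_proteome(prot, {"sc": sc_model, "pssm": pssm_model})
    for name in ("sc", "pssm"):
        z = df[f"z_{name}"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert bgs[name].n == len(df)


def test_planted_motifs_rank_in_top_percent(proteome_and_truth, sc_model,
                                            pssm_model):
    fasta, truth = proteome_and_truth
    prot = scan.read_proteome(fasta)
    df, _ = scan.scan_proteome(prot, {"sc": sc_model, "pssm": pssm_model})
    df["combined"] = 0.5 * (df["z_sc"] + df["z_pssm"])
    ranked = df.sort_values("combined", ascending=False).reset_index(drop=True)
    planted = set(zip(truth.protein_id, truth.start))
    ranks = [i for i, (p, s) in enumerate(zip(ranked.protein_id, ranked.start))
             if (p, s) in planted]
    assert len(ranks) == len(planted)   # all planted windows pass the filters
    cutoff = max(1, len(df) // 100)
    assert max(ranks) < cutoff
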