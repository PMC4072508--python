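"""Proteome window enumeration, compositional filters, Z-scores, selection.

Proteins are scanned in sliding 26-residue windows aligned to the extended
heptad register 1d-5a (the 23-mer 1g-5a core is the scored span).  Windows
are kept only if they resemble known BH3 motifs compositionally:

* at least 35% polar/charged residues (DEHKNQRST) over the 26-mer;
* at most one proline between positions 2d and 4a;
* a nonpolar residue (FILVYWM) at position 3a;
* a small residue (ACGS) at position 3e.

Raw model scores are energies (lower = stronger).  To compare models they
are standardized against the distribution of scores over the filtered
genomic background, with the sign flipped so that a higher Z-score means
better predicted binding:  Z = (mean - raw) / sd.  The combined score of the
array-selection protocol is the mean of the PSSM and all-atom potential
Z-scores for the same receptor.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .structio import AA_INDEX, AA_ORDER, EXTENDED_REGISTER

__all__ = [
    "WINDOW_LENGTH", "FilterConfig", "CandidateWindow",
    "BackgroundDistribution", "read_proteome", "enumerate_windows",
    "composition_filter", "fit_background", "zscore", "combine_z",
    "identity_fraction", "redundancy_filter", "select_candidates",
    "score_windows", "scan_proteome", "RECEPTOR_PRIORITY",
]

WINDOW_LENGTH = len(EXTENDED_REGISTER)          # 26
_LABEL_POS = {lab: i for i, lab in enumerate(EXTENDED_REGISTER)}
_CORE_SLICE = slice(_LABEL_POS["2d"], _LABEL_POS["4a"] + 1)
_POS_3A = _LABEL_POS["3a"]
_POS_3E = _LABEL_POS["3e"]

#: Order in which receptors claim candidate peptides for array selection.
RECEPTOR_PRIORITY = ("Bcl-xL", "Mcl-1", "Bfl-1")


@dataclass
class FilterConfig:
    polar_set: frozenset = frozenset("DEHKNQRST")
    polar_min_fraction: float = 0.35
    max_proline_core: int = 1
    pos3a_set: frozenset = frozenset("FILVYWM")
    pos3e_set: frozenset = frozenset("ACGS")

    def __post_init__(self):
        if not 0.0 <= self.polar_min_fraction <= 1.0:
            raise ValueError("polar_min_fraction must be in [0, 1]")


@dataclass
class CandidateWindow:
    protein_id: str
    start: int                  # 0-based offset of the 26-mer in the protein
    sequence: str               # 26-mer on register 1d-5a

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError("window must be a 26-mer")

    @property
    def core(self) -> str:
        """The 23-mer 1g-5a scoring core (suffix of the 26-mer)."""
        return self.sequence[3:]

    @property
    def labels(self):
        return EXTENDED_REGISTER


@dataclass
class BackgroundDistribution:
    mean: float
    sd: float
    n: int
    model: str = ""
    receptor: str = ""


def read_proteome(source) -> dict:
    """FASTA -> ordered {protein_id: sequence} mapping."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = io.StringIO(source)
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(source, "fasta")}


def enumerate_windows(proteome: dict):
    """Yield every contiguous 26-mer of every protein (step 1).

    Windows containing non-amino-acid characters are skipped; one warning is
    emitted per offending protein.
    """
    for pid, seq in proteome.items():
        valid = np.fromiter((c in AA_INDEX for c in seq), dtype=bool,
                            count=len(seq))
        if not valid.all():
            warnings.warn(f"protein {pid} contains non-standard characters; "
                          "affected windows skipped")
        for start in range(0, len(seq) - WINDOW_LENGTH + 1):
            if valid[start:start + WINDOW_LENGTH].all():
                yield CandidateWindow(pid, start, seq[start:start + WINDOW_LENGTH])


def composition_filter(window, cfg: FilterConfig = FilterConfig()) -> bool:
    """Apply the four compositional rules to a window (26-mer)."""
    seq = window.sequence if isinstance(window, CandidateWindow) else window
    if len(seq) != WINDOW_LENGTH:
        raise ValueError("composition filter expects a 26-mer")
    polar = sum(c in cfg.polar_set for c in seq) / len(seq)
    if polar < cfg.polar_min_fraction:
        return False
    if seq[_CORE_SLICE].count("P") > cfg.max_proline_core:
        return False
    if seq[_POS_3A] not in cfg.pos3a_set:
        return False
    if seq[_POS_3E] not in cfg.pos3e_set:
        return False
    return True


def fit_background(scores, model: str = "", receptor: str = "") -> BackgroundDistribution:
    """Sample mean/sd of raw scores over the genomic background."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 background scores")
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: all scores identical")
    return BackgroundDistribution(mean=float(scores.mean()), sd=sd,
                                  n=int(scores.size), model=model,
                                  receptor=receptor)


def zscore(raw_energy: float, bg: BackgroundDistribution) -> float:
    """Standardized score, sign-flipped so higher = better predicted binding."""
    return (bg.mean - raw_energy) / bg.sd


def combine_z(z_pssm, z_statium_sc) -> float:
    """Mean of the two model Z-scores for the same receptor."""
    if z_pssm is None or z_statium_sc is None or \
            np.isnan(z_pssm) or np.isnan(z_statium_sc):
        raise ValueError("both Z-scores are required to combine")
    return 0.5 * (float(z_pssm) + float(z_statium_sc))


def identity_fraction(seq1: str, seq2: str) -> float:
    """Ungapped fractional identity at aligned register positions."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must share the register length")
    return sum(a == b for a, b in zip(seq1, seq2)) / len(seq1)


def redundancy_filter(candidates, scores, identity_threshold: float = 0.75):
    """Greedy non-redundant selection: keep best scorers, drop near-copies.

    Candidates are visited in order of decreasing score (higher = better);
    one is dropped when more than ``identity_threshold`` identical to an
    already-kept sequence.  Returns kept candidates in score order.
    """
    order = sorted(range(len(candidates)), key=lambda i: -scores[i])
    kept = []
    for i in order:
        seq = candidates[i].sequence if isinstance(candidates[i], CandidateWindow) \
            else candidates[i]
        if any(identity_fraction(seq, k) > identity_threshold
               for k in (w.sequence if isinstance(w, CandidateWindow) else w
                         for w in kept)):
            continue
        kept.append(candidates[i])
    return kept


def select_candidates(df: pd.DataFrame, pssm_z_col: str, sc_z_col: str,
                      sc_raw_col: str, pssm_z_cutoff: float,
                      top_k: int = 20,
                      require_raw_sc_negative: bool = True) -> pd.DataFrame:
    """Array-style candidate selection for one receptor.

    Keep windows whose PSSM Z-score meets the cutoff (and, optionally, whose
    raw all-atom potential energy is < 0), rank by the all-atom potential
    Z-score, and truncate to the top ``top_k``.
    """
    mask = df[pssm_z_col] >= pssm_z_cutoff
    if require_raw_sc_negative:
        mask &= df[sc_raw_col] < 0.0
    return (df[mask]
            .sort_values(sc_z_col, ascending=False, kind="mergesort")
            .head(top_k)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Vectorized scoring of many windows
# ---------------------------------------------------------------------------

def _model_matrix(model) -> np.ndarray:
    """26 x 20 score matrix on the extended register; uncovered positions 0."""
    mat = np.zeros((WINDOW_LENGTH, len(AA_ORDER)))
    for label, vec in model.position_matrix().items():
        if label in _LABEL_POS:
            mat[_LABEL_POS[label]] = vec
    return mat


def score_windows(windows, models: dict) -> pd.DataFrame:
    """Raw scores for a list of windows under each model.

    ``models`` maps a column-name stem (e.g. ``"statium_sc/Bcl-xL"``) to a
    model exposing ``position_matrix()``.  All models are position-additive,
    so scoring reduces to a table lookup summed over the 26 positions.
    """
    windows = list(windows)
    seq_idx = np.array([[AA_INDEX[c] for c in w.sequence] for w in windows],
                       dtype=np.intp) if windows else \
        np.empty((0, WINDOW_LENGTH), dtype=np.intp)
    data = {
        "protein_id": [w.protein_id for w in windows],
        "start": [w.start for w in windows],
        "sequence": [w.sequence for w in windows],
    }
    cols = np.arange(WINDOW_LENGTH)
    for name, model in models.items():
        mat = _model_matrix(model)
        if np.isnan(mat).any():
            raise ValueError(f"model {name} has unmeasured entries")
        data[f"raw_{name}"] = mat[cols, seq_idx].sum(axis=1) if windows else []
    return pd.DataFrame(data)


def scan_proteome(proteome: dict, models: dict,
                  cfg: FilterConfig = FilterConfig()):
    """Enumerate, filter and score a proteome; attach genomic Z-scores.

    Returns ``(df, backgrounds)`` where ``df`` has one row per filtered
    window with ``raw_<model>`` and ``z_<model>`` columns, and
    ``backgrounds`` maps model names to the fitted
    :class:`BackgroundDistribution` (computed over the filtered window set,
    per model).
    """
    windows = [w for w in enumerate_windows(proteome)
               if composition_filter(w, cfg)]
    df = score_windows(windows, models)
    backgrounds = {}
    for name in models:
        bg = fit_background(df[f"raw_{name}"], model=name)
        backgrounds[name] = bg
        df[f"z_{name}"] = (bg.mean - df[f"raw_{name}"]) / bg.sd
    return df, backgrounds
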