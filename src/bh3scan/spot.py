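"""Negative-control design and classification of SPOT-array measurements.

Two point mutations abolish binding of genuine BH3 helices: the buried,
strongly conserved Leu at register position 3a is mutated to Asp, and the
small residue at 3e that packs tightly against the receptor is mutated to
Leu.  An array interaction is called a *candidate interaction* when both
control mutants lose at least 30% of the wild-type spot signal.  Signals are
also expressed as fractions of the wild-type Bim BH3 spot, the strong-binding
reference present on every membrane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["SpotMeasurement", "ControlTriple", "make_negative_controls",
           "bim_fraction", "classify_candidate", "signal_bin_counts",
           "classify_table"]

REDUCTION_THRESHOLD = 0.30


@dataclass
class SpotMeasurement:
    peptide_id: str
    receptor: str
    intensity: float
    bim_intensity: float

    def __post_init__(self):
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError("intensity must be finite and >= 0")
        if not math.isfinite(self.bim_intensity) or self.bim_intensity <= 0:
            raise ValueError("Bim reference intensity must be > 0")


@dataclass
class ControlTriple:
    wildtype: SpotMeasurement
    mut_3aD: SpotMeasurement
    mut_3eL: SpotMeasurement

    def __post_init__(self):
        ms = (self.wildtype, self.mut_3aD, self.mut_3eL)
        if len({m.peptide_id for m in ms}) != 1 or \
                len({m.receptor for m in ms}) != 1:
            raise ValueError("control triple must share peptide and receptor")


def make_negative_controls(sequence: str, labels) -> tuple:
    """Return the (3a->Asp, 3e->Leu) control sequences for a window."""
    labels = list(labels)
    if len(labels) != len(sequence):
        raise ValueError("sequence and register labels differ in length")
    try:
        i3a = labels.index("3a")
        i3e = labels.index("3e")
    except ValueError:
        raise ValueError("register must cover positions 3a and 3e") from None
    if sequence[i3a] == "D":
        raise ValueError("3a is already Asp; control is indistinguishable")
    if sequence[i3e] == "L":
        raise ValueError("3e is already Leu; control is indistinguishable")
    ctl_3aD = sequence[:i3a] + "D" + sequence[i3a + 1:]
    ctl_3eL = sequence[:i3e] + "L" + sequence[i3e + 1:]
    return ctl_3aD, ctl_3eL


def bim_fraction(m: SpotMeasurement) -> float:
    """Spot signal as a fraction of the wild-type Bim BH3 signal."""
    return m.intensity / m.bim_intensity


def classify_candidate(t: ControlTriple,
                       reduction_threshold: float = REDUCTION_THRESHOLD) -> bool:
    """True iff both control mutations reduce the signal by >= the threshold.

    Reductions are computed on raw intensities; the Bim normalization cancels.
    """
    wt = t.wildtype.intensity
    if wt <= 0:
        warnings.warn(f"wild-type intensity is 0 for "
                      f"{t.wildtype.peptide_id}/{t.wildtype.receptor}")
        return False
    for ctl in (t.mut_3aD, t.mut_3eL):
        if (wt - ctl.intensity) / wt < reduction_threshold:
            return False
    return True


def signal_bin_counts(measurements, thresholds=(0.05, 0.10, 0.25)) -> dict:
    """Number of measurements with Bim fraction >= each threshold."""
    fracs = [bim_fraction(m) for m in measurements]
    return {thr: sum(f >= thr for f in fracs) for thr in thresholds}


def classify_table(df: pd.DataFrame,
                   reduction_threshold: float = REDUCTION_THRESHOLD) -> pd.DataFrame:
    """Classify a measurement table with columns
    peptide_id, receptor, variant (wt|3aD|3eL), intensity, bim_intensity.

    Returns one row per (peptide_id, receptor) with the wild-type Bim
    fraction and the candidate-interaction call; groups missing either
    control are skipped with a warning.
    """
    rows = []
    for (pid, rec), grp in df.groupby(["peptide_id", "receptor"], sort=True):
        by_var = {v: g.iloc[0] for v, g in grp.groupby("variant")}
        if not {"wt", "3aD", "3eL"} <= set(by_var):
            warnings.warn(f"incomplete control set for {pid}/{rec}; skipped")
            continue
        triple = ControlTriple(*(
            SpotMeasurement(pid, rec, float(by_var[v]["intensity"]),
                            float(by_var[v]["bim_intensity"]))
            for v in ("wt", "3aD", "3eL")))
        rows.append({
            "peptide_id": pid,
            "receptor": rec,
            "bim_fraction": bim_fraction(triple.wildtype),
            "candidate": classify_candidate(triple, reduction_threshold),
        })
    return pd.DataFrame(rows,
                        columns=["peptide_id", "receptor", "bim_fraction",
                                 "candidate"])
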