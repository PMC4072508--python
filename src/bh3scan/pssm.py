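"""Position-specific scoring model derived from peptide-array intensities.

The model is built from SPOT-array measurements of single-residue mutants of
the Bim BH3 peptide binding a prosurvival receptor.  The score of amino acid
``aa`` at register position ``p`` is

    S(p, aa) = -( ln I(p, aa) - ln I_ref(p) ),

where ``I`` is the spot intensity and ``I_ref`` the intensity of the
wild-type (Bim) residue at that position.  Scores are energy-like: the
reference sequence scores exactly 0 and weaker-binding substitutions score
positive.  Only ten core positions carry experimental data (2d, 2e, 2g, 3a,
3b, 3d, 3e, 3f, 3g, 4a); peptide scores are summed over those positions.
Intensities below a floor fraction of the reference are clipped before the
logarithm so that dead spots yield a large but finite penalty.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import AA_INDEX, AA_ORDER

__all__ = ["PSSM_POSITIONS", "SpotTable", "PssmModel", "build_pssm",
           "score_pssm"]

#: Register positions with experimental SPOT data.
PSSM_POSITIONS = ("2d", "2e", "2g", "3a", "3b", "3d", "3e", "3f", "3g", "4a")


@dataclass
class SpotTable:
    """Normalized spot intensities: (position, aa) -> intensity.

    ``reference`` maps each position to ``(wild-type aa, reference intensity)``.
    """

    intensities: dict
    reference: dict

    def __post_init__(self):
        for (pos, aa), v in self.intensities.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"bad intensity for ({pos},{aa}): {v}")
        for pos, (aa, ref) in self.reference.items():
            if ref <= 0:
                raise ValueError(f"reference intensity at {pos} must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotTable":
        """Build from a table with columns position, aa, intensity[, reference].

        Rows with ``reference`` truthy mark the wild-type residue whose
        intensity normalizes the position.
        """
        intensities, reference = {}, {}
        has_ref = "reference" in df.columns
        for row in df.itertuples(index=False):
            pos, aa = str(row.position), str(row.aa)
            intensities[(pos, aa)] = float(row.intensity)
            if has_ref and getattr(row, "reference"):
                reference[pos] = (aa, float(row.intensity))
        if not reference:
            raise ValueError("no reference (wild-type) rows in SPOT table")
        return cls(intensities, reference)

    @classmethod
    def from_tsv(cls, source) -> "SpotTable":
        if isinstance(source, str) and "\t" in source:
            source = io.StringIO(source)
        return cls.from_frame(pd.read_csv(source, sep="\t"))


@dataclass
class PssmModel:
    """10-position x 20-amino-acid score table; lower = stronger binding."""

    scores: np.ndarray                       # (10, 20)
    positions: tuple = PSSM_POSITIONS
    receptor_name: str = ""
    wildtype: dict = field(default_factory=dict)   # position -> wt aa

    def position_matrix(self) -> dict:
        return {pos: self.scores[i] for i, pos in enumerate(self.positions)}

    def score(self, sequence: str, labels) -> float:
        return score_pssm(self, sequence, labels)

    def to_dict(self) -> dict:
        return {"receptor_name": self.receptor_name,
                "positions": list(self.positions),
                "aa_order": AA_ORDER,
                "wildtype": self.wildtype,
                "scores": self.scores.tolist()}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PssmModel":
        return cls(scores=np.array(d["scores"]),
                   positions=tuple(d["positions"]),
                   receptor_name=d.get("receptor_name", ""),
                   wildtype=d.get("wildtype", {}))

    @classmethod
    def from_json(cls, text: str) -> "PssmModel":
        return cls.from_dict(json.loads(text))


def build_pssm(table: SpotTable, floor_fraction: float = 0.01,
               receptor_name: str = "") -> PssmModel:
    """Convert a spot-intensity table into a :class:`PssmModel`.

    Intensities below ``floor_fraction`` of the position's reference are
    clipped to the floor, capping the score at ``-ln(floor_fraction)``.
    Positions or amino acids with no measurement are left NaN and raise at
    scoring time.
    """
    if floor_fraction <= 0:
        raise ValueError("floor_fraction must be > 0")
    scores = np.full((len(PSSM_POSITIONS), len(AA_ORDER)), np.nan)
    wildtype = {}
    for i, pos in enumerate(PSSM_POSITIONS):
        if pos not in table.reference:
            raise ValueError(f"missing reference intensity at position {pos}")
        wt_aa, ref = table.reference[pos]
        wildtype[pos] = wt_aa
        for aa in AA_ORDER:
            inten = table.intensities.get((pos, aa))
            if inten is None:
                continue
            inten = max(inten, floor_fraction * ref)
            scores[i, AA_INDEX[aa]] = -(math.log(inten) - math.log(ref))
        scores[i, AA_INDEX[wt_aa]] = 0.0
    return PssmModel(scores=scores, receptor_name=receptor_name,
                     wildtype=wildtype)


def score_pssm(model: PssmModel, sequence: str, labels) -> float:
    """Sum of position scores over the ten modeled positions.

    ``labels`` gives the register label of each residue in ``sequence``;
    positions outside the modeled ten contribute nothing.
    """
    at = dict(zip(labels, sequence))
    total = 0.0
    for i, pos in enumerate(model.positions):
        if pos not in at:
            raise ValueError(f"window does not cover scored position {pos}")
        aa = at[pos]
        if aa not in AA_INDEX:
            raise ValueError(f"non-standard residue {aa!r} at {pos}")
        s = model.scores[i, AA_INDEX[aa]]
        if np.isnan(s):
            raise ValueError(f"no SPOT measurement for {aa} at {pos}")
        total += float(s)
    return total
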