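"""Protein structure parsing and receptor-peptide template assembly.

BH3 peptides dock as amphipathic helices into a groove on prosurvival Bcl-2
receptors.  Positions along the peptide are labelled on the heptad register
``[abcdefg]_n`` that captures the hydrophobic/polar periodicity of the helix:
``2d``, ``2e``, ... ``4a`` form the 12-residue core, with the strictly
conserved leucine at ``3a`` and aspartate at ``3f`` as landmarks.  This module
reads PDB-format coordinates (via :mod:`gemmi`), normalises them into light
residue/atom containers, and assigns heptad labels to a peptide chain anchored
at its ``3a`` residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AA_ORDER",
    "AA_INDEX",
    "SIDECHAIN_ATOMS",
    "Atom",
    "Residue",
    "StructureModel",
    "HeptadRegister",
    "TemplateComplex",
    "read_structure",
    "write_structure",
    "build_template",
    "virtual_cbeta",
    "heptad_index",
    "heptad_label",
    "register_labels",
    "EXTENDED_REGISTER",
    "CORE_REGISTER",
    "SCORED_CORE",
]

#: Canonical one-letter amino-acid alphabet used for all count/energy vectors.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Modified residues with an unambiguous standard parent are mapped rather than
# dropped; anything else is skipped with a warning.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "MLY": "LYS", "HYP": "PRO",
    "PYL": "LYS", "FME": "MET",
}

#: Heavy side-chain atoms per residue type, in canonical PDB atom-name order.
SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "C": ["CB", "SG"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "G": [],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "M": ["CB", "CG", "SD", "CE"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["CB", "CG", "CD"],
    "S": ["CB", "OG"],
    "T": ["CB", "OG1", "CG2"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "V": ["CB", "CG1", "CG2"],
}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)) or self.coords.shape != (3,):
            raise ValueError("atom coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    aa: str
    atoms: list = field(default_factory=list)

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, name: str):
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def key(self):
        return (self.chain_id, self.seq_num)


@dataclass
class StructureModel:
    id: str
    residues: list = field(default_factory=list)

    def chain(self, chain_id: str) -> list:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_ids(self) -> list:
        seen = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen


# ---------------------------------------------------------------------------
# Heptad register arithmetic
# ---------------------------------------------------------------------------

_HEPTAD_LETTERS = "abcdefg"


def heptad_index(label: str) -> int:
    """Absolute heptad position, e.g. ``3a`` -> 21 (``7*n + letter``)."""
    n, letter = int(label[:-1]), label[-1]
    if letter not in _HEPTAD_LETTERS:
        raise ValueError(f"bad heptad label {label!r}")
    return 7 * n + _HEPTAD_LETTERS.index(letter)


def heptad_label(index: int) -> str:
    return f"{index // 7}{_HEPTAD_LETTERS[index % 7]}"


def register_labels(start: str, end: str) -> list:
    i, j = heptad_index(start), heptad_index(end)
    if j < i:
        raise ValueError("register end precedes start")
    return [heptad_label(k) for k in range(i, j + 1)]


#: 26-residue register used for filtering and reporting.
EXTENDED_REGISTER = tuple(register_labels("1d", "5a"))
#: 23-residue register used for scoring windows.
CORE_REGISTER = tuple(register_labels("1g", "5a"))
#: 12-residue conserved core 2d-4a.
SCORED_CORE = tuple(register_labels("2d", "4a"))

_ANCHOR = heptad_index("3a")
_EXT_LO, _EXT_HI = heptad_index("1d"), heptad_index("5a")


@dataclass
class HeptadRegister:
    labels: list

    def __post_init__(self):
        idx = [heptad_index(l) for l in self.labels]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("register labels must be consecutive heptad positions")

    @property
    def anchor(self) -> int:
        """Index of the ``3a`` label within the register."""
        try:
            return self.labels.index("3a")
        except ValueError:
            raise ValueError("register does not cover position 3a") from None

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self):
        return len(self.labels)


@dataclass
class TemplateComplex:
    receptor: list
    peptide: list
    register: HeptadRegister
    receptor_name: str = ""

    def __post_init__(self):
        if len(self.peptide) != len(self.register):
            raise ValueError("every peptide residue needs a register label")
        rec_keys = {r.key for r in self.receptor}
        if rec_keys & {r.key for r in self.peptide}:
            raise ValueError("receptor and peptide residue sets overlap")

    def peptide_residue(self, label: str) -> Residue:
        return self.peptide[self.register.index_of(label)]


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, model_id: str = "model") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Hydrogens are dropped.  Alternate locations are resolved by keeping, per
    atom name, the conformer with the highest occupancy (first encountered on
    ties).  Non-standard residues are mapped to their parent amino acid when a
    standard mapping exists, otherwise skipped with a warning.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no ATOM records in input")
    residues = []
    seen = set()
    for chain in st[0]:
        for res in chain:
            name = res.name.strip().upper()
            if name in ("HOH", "WAT", "DOD"):
                continue
            if name in NONSTANDARD_PARENT:
                name = NONSTANDARD_PARENT[name]
            if name not in THREE_TO_ONE:
                warnings.warn(f"skipping non-standard residue {res.name} "
                              f"{chain.name}{res.seqid.num}")
                continue
            key = (chain.name, res.seqid.num)
            if key in seen:
                continue
            seen.add(key)
            best = {}
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [Atom(a.name, a.element.name,
                          np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in best.values()]
            if atoms:
                residues.append(Residue(chain.name, res.seqid.num,
                                        THREE_TO_ONE[name], atoms))
    if not residues:
        raise ValueError("no standard residues with atoms parsed")
    return StructureModel(model_id, residues)


def write_structure(model: StructureModel) -> str:
    """Serialize a model back to PDB text (through gemmi's writer)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    chains = {}
    for res in model.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gr = gemmi.Residue()
        gr.name = ONE_TO_THREE[res.aa]
        gr.seqid = gemmi.SeqId(res.seq_num, " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = 1.0
            gr.add_atom(ga)
        chains[res.chain_id].add_residue(gr)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# Template assembly
# ---------------------------------------------------------------------------

def build_template(structure: StructureModel, receptor_chain: str,
                   peptide_chain: str, anchor: int,
                   receptor_name: str = "") -> TemplateComplex:
    """Assemble a receptor-peptide template with heptad labels on the peptide.

    ``anchor`` is the PDB seq_num of the peptide residue at heptad position
    ``3a``.  Labels are assigned outward from the anchor in heptad order;
    peptide residues falling outside the extended 1d-5a register are excluded
    from the template.
    """
    receptor = structure.chain(receptor_chain)
    peptide = structure.chain(peptide_chain)
    if not receptor:
        raise ValueError(f"receptor chain {receptor_chain!r} not found")
    if not peptide:
        raise ValueError(f"peptide chain {peptide_chain!r} not found")
    peptide = sorted(peptide, key=lambda r: r.seq_num)
    anchor_pos = [i for i, r in enumerate(peptide) if r.seq_num == anchor]
    if not anchor_pos:
        raise ValueError(f"anchor seq_num {anchor} not in peptide chain")
    ai = anchor_pos[0]
    kept, labels = [], []
    for i, res in enumerate(peptide):
        hidx = _ANCHOR + (i - ai)
        if _EXT_LO <= hidx <= _EXT_HI:
            kept.append(res)
            labels.append(heptad_label(hidx))
    return TemplateComplex(receptor=receptor, peptide=kept,
                           register=HeptadRegister(labels),
                           receptor_name=receptor_name)


_CB_LENGTH = 1.52  # Angstrom, ideal Calpha-Cbeta bond


def virtual_cbeta(residue: Residue) -> np.ndarray:
    """Coordinates of the (real or ideally constructed) Cbeta atom.

    Glycine lacks a Cbeta but the interaction criteria are defined in terms of
    Cbeta positions, so for residues without one we construct an
    ideal-geometry Cbeta from the N/Calpha/C backbone (tetrahedral, 1.52 A).
    """
    cb = residue.coords("CB")
    if cb is not None:
        return cb.copy()
    n, ca, c = (residue.coords(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(
            f"residue {residue.chain_id}{residue.seq_num} lacks backbone "
            "atoms needed to construct a virtual Cbeta")
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec
    norm = np.linalg.norm(direction)
    if norm < 1e-8:
        raise ValueError("degenerate backbone geometry (collinear N, CA, C)")
    return ca + _CB_LENGTH * direction / norm
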