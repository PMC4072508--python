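"""Interface statistical potentials for receptor-peptide templates.

Two variants of the potential are supported.  The classic variant (``CB``)
declares a peptide/receptor residue pair "interacting" when their Cbeta atoms
lie within 10 A and the Calpha-Cbeta vectors are not pointed away from each
other.  The all-heavy-atom variant (``SC``) instead asks whether any receptor
side-chain heavy atom comes within 6 A of a peptide side-chain atom, where the
peptide side is always represented by its {Calpha, Cbeta} pair.

For every interacting template pair, a geometric fingerprint is stored: the
ordered list of distances between the peptide {Calpha, Cbeta} atoms and the
receptor atoms of the pair (all heavy side-chain atoms for SC, {Calpha,
Cbeta} for CB).  A database of single-chain structures is then scanned for
residue pairs whose receptor-side amino acid matches the template pair and
whose fingerprint agrees to within an RMSD cutoff (0.4 A by default; matches
require strictly smaller RMSD).  The amino-acid identities observed on the
peptide side of matching database pairs form a count matrix per template
pair, which is converted with background frequencies P_bg into energies

    E_pair(aa) = -ln( P_aa / P_bg(aa) ),

so that the score of a peptide sequence, summed over positions and pairs, is
energy-like: lower means stronger predicted binding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import (
    AA_INDEX,
    AA_ORDER,
    SIDECHAIN_ATOMS,
    Residue,
    StructureModel,
    TemplateComplex,
    virtual_cbeta,
)

__all__ = [
    "InteractionCriterion",
    "TemplatePair",
    "StatiumModel",
    "detect_pairs",
    "fingerprint_rmsd",
    "interacting_db_pairs",
    "scan_database",
    "background_frequencies",
    "derive_potential",
]

LOW_COUNT_THRESHOLD = 100  # pairs with fewer matches than this are flagged


@dataclass
class InteractionCriterion:
    """Geometric definition of an interacting residue pair."""

    variant: str = "SC"  # "CB" or "SC"
    distance_cutoff: float = None
    angle_rule_enabled: bool = True  # CB variant only
    fingerprint_rmsd_cutoff: float = 0.4

    def __post_init__(self):
        if self.variant not in ("CB", "SC"):
            raise ValueError("variant must be 'CB' or 'SC'")
        if self.distance_cutoff is None:
            self.distance_cutoff = 10.0 if self.variant == "CB" else 6.0
        if self.distance_cutoff <= 0 or self.fingerprint_rmsd_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def cb(cls, **kw):
        return cls(variant="CB", **kw)

    @classmethod
    def sc(cls, **kw):
        return cls(variant="SC", **kw)


@dataclass
class TemplatePair:
    pep_pos: str                 # register label of the peptide residue
    rec_key: tuple               # (chain_id, seq_num, aa)
    rec_atom_names: list         # receptor atom names, canonical order
    fingerprint: np.ndarray      # distances, peptide-atom-major order

    @property
    def rec_aa(self) -> str:
        return self.rec_key[2]


def _sidechain_atom_coords(res: Residue, require_all: bool = False):
    """Heavy side-chain atom names/coords in canonical order (Gly -> [CA])."""
    names = SIDECHAIN_ATOMS[res.aa] or ["CA"]
    out_names, coords = [], []
    for name in names:
        c = res.coords(name)
        if c is None:
            if require_all:
                return None, None
            continue
        out_names.append(name)
        coords.append(c)
    if not coords:
        return None, None
    return out_names, np.array(coords)


def _peptide_probe(res: Residue):
    """{Calpha, Cbeta} representation of the peptide side (virtual CB ok)."""
    ca = res.coords("CA")
    if ca is None:
        raise ValueError(f"residue {res.chain_id}{res.seq_num} lacks CA")
    return np.array([ca, virtual_cbeta(res)])


def _cb_vectors(res: Residue):
    ca = res.coords("CA")
    if ca is None:
        raise ValueError(f"residue {res.chain_id}{res.seq_num} lacks CA")
    cb = virtual_cbeta(res)
    return ca, cb


def _angle_rule(ca_i, cb_i, ca_j, cb_j) -> bool:
    """Calpha-Cbeta vectors "not pointed away from each other"."""
    return (np.dot(cb_i - ca_i, cb_j - cb_i) >= 0.0
            and np.dot(cb_j - ca_j, cb_i - cb_j) >= 0.0)


def _pair_fingerprint(pep_atoms: np.ndarray, rec_atoms: np.ndarray) -> np.ndarray:
    # peptide-atom-major ordering: d(pep_0, rec_0..k), d(pep_1, rec_0..k), ...
    diffs = pep_atoms[:, None, :] - rec_atoms[None, :, :]
    return np.sqrt((diffs ** 2).sum(axis=2)).ravel()


def detect_pairs(template: TemplateComplex,
                 crit: InteractionCriterion) -> list:
    """Find all interacting peptide/receptor residue pairs in a template."""
    if not template.peptide or not template.receptor:
        raise ValueError("template has an empty chain")
    pairs = []
    for label, pres in zip(template.register.labels, template.peptide):
        try:
            pep_atoms = _peptide_probe(pres)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        for rres in template.receptor:
            try:
                if crit.variant == "SC":
                    _, sc = _sidechain_atom_coords(rres)
                    if sc is None:
                        warnings.warn(
                            f"receptor residue {rres.chain_id}{rres.seq_num} "
                            "has no usable side-chain atoms; skipped")
                        continue
                    d = np.linalg.norm(
                        pep_atoms[:, None, :] - sc[None, :, :], axis=2)
                    if d.min() >= crit.distance_cutoff:
                        continue
                    rec_names, _ = _sidechain_atom_coords(rres)
                    fp = _pair_fingerprint(pep_atoms, sc)
                else:
                    ca_i, cb_i = pep_atoms[0], pep_atoms[1]
                    ca_j, cb_j = _cb_vectors(rres)
                    if np.linalg.norm(cb_i - cb_j) >= crit.distance_cutoff:
                        continue
                    if crit.angle_rule_enabled and not _angle_rule(
                            ca_i, cb_i, ca_j, cb_j):
                        continue
                    rec_names = ["CA", "CB"]
                    fp = _pair_fingerprint(pep_atoms, np.array([ca_j, cb_j]))
            except ValueError as exc:
                warnings.warn(f"pair {label}/{rres.seq_num} skipped: {exc}")
                continue
            pairs.append(TemplatePair(
                pep_pos=label,
                rec_key=(rres.chain_id, rres.seq_num, rres.aa),
                rec_atom_names=rec_names,
                fingerprint=fp,
            ))
    return pairs


def fingerprint_rmsd(fp1, fp2) -> float:
    """Root-mean-squared difference between two distance fingerprints."""
    fp1 = np.asarray(fp1, dtype=float)
    fp2 = np.asarray(fp2, dtype=float)
    if fp1.shape != fp2.shape or fp1.ndim != 1 or fp1.size == 0:
        raise ValueError("fingerprints must be non-empty and of equal length")
    return float(np.sqrt(np.mean((fp1 - fp2) ** 2)))


# ---------------------------------------------------------------------------
# Database scanning
# ---------------------------------------------------------------------------

def interacting_db_pairs(structure: StructureModel,
                         crit: InteractionCriterion) -> list:
    """Unordered interacting residue pairs within a single-chain structure.

    Uses the same geometric criterion as the template.  In a database chain
    neither member is designated peptide or receptor, so for the SC variant
    the side chains of both residues are used (Gly side chain = {CA}).
    """
    residues = structure.residues
    pairs = set()
    if crit.variant == "SC":
        coords, owner = [], []
        for i, res in enumerate(residues):
            _, sc = _sidechain_atom_coords(res)
            if sc is None:
                continue
            coords.append(sc)
            owner.extend([i] * len(sc))
        if not coords:
            return []
        coords = np.vstack(coords)
        owner = np.array(owner)
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(crit.distance_cutoff):
            ia, ib = owner[a], owner[b]
            if ia != ib:
                pairs.add((min(ia, ib), max(ia, ib)))
    else:
        cas, cbs, idx = [], [], []
        for i, res in enumerate(residues):
            try:
                ca, cb = _cb_vectors(res)
            except ValueError:
                continue
            cas.append(ca)
            cbs.append(cb)
            idx.append(i)
        if not cbs:
            return []
        cbs_arr = np.array(cbs)
        tree = cKDTree(cbs_arr)
        for a, b in tree.query_pairs(crit.distance_cutoff):
            if crit.angle_rule_enabled and not _angle_rule(
                    cas[a], cbs_arr[a], cas[b], cbs_arr[b]):
                continue
            pairs.add((min(idx[a], idx[b]), max(idx[a], idx[b])))
    return [(residues[i], residues[j]) for i, j in sorted(pairs)]


def scan_database(pairs: list, db: list, crit: InteractionCriterion) -> list:
    """Accumulate per-template-pair amino-acid count matrices from a database.

    Every database residue pair is tested in both orientations (either member
    may play the receptor role).  When the receptor-role amino acid matches
    the template pair's receptor residue and the fingerprint RMSD is strictly
    below the cutoff, the peptide-role amino acid is counted.
    """
    counts = [np.zeros(len(AA_ORDER), dtype=np.int64) for _ in pairs]
    if not db:
        warnings.warn("empty structure database: all counts are zero")
        return counts
    by_rec_aa = {}
    for idx, tp in enumerate(pairs):
        by_rec_aa.setdefault(tp.rec_aa, []).append(idx)
    for structure in db:
        for res_a, res_b in interacting_db_pairs(structure, crit):
            for rec_role, pep_role in ((res_a, res_b), (res_b, res_a)):
                for idx in by_rec_aa.get(rec_role.aa, ()):
                    tp = pairs[idx]
                    _, rec_coords = _sidechain_atom_coords(
                        rec_role, require_all=True) if crit.variant == "SC" \
                        else (None, None)
                    if crit.variant == "SC":
                        if rec_coords is None:
                            continue
                        names = SIDECHAIN_ATOMS[rec_role.aa] or ["CA"]
                        if names != tp.rec_atom_names:
                            continue
                    else:
                        try:
                            ca_j, cb_j = _cb_vectors(rec_role)
                        except ValueError:
                            continue
                        rec_coords = np.array([ca_j, cb_j])
                    try:
                        pep_atoms = _peptide_probe(pep_role)
                    except ValueError:
                        continue
                    fp = _pair_fingerprint(pep_atoms, rec_coords)
                    if fp.size != tp.fingerprint.size:
                        continue
                    if fingerprint_rmsd(fp, tp.fingerprint) < \
                            crit.fingerprint_rmsd_cutoff:
                        counts[idx][AA_INDEX[pep_role.aa]] += 1
    return counts


def background_frequencies(db: list, pseudocount: float = 1.0) -> np.ndarray:
    """Amino-acid frequencies over all database residues (counted uniformly).

    A small Laplace pseudocount keeps every frequency strictly positive even
    when an amino acid is absent from the database.
    """
    counts = np.full(len(AA_ORDER), float(pseudocount))
    for structure in db:
        for res in structure.residues:
            counts[AA_INDEX[res.aa]] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Potential derivation and scoring
# ---------------------------------------------------------------------------

@dataclass
class StatiumModel:
    """Per-pair, per-amino-acid energies derived from database counts."""

    receptor_name: str
    variant: str
    pairs: list                       # list of TemplatePair
    energies: np.ndarray              # (n_pairs, 20)
    counts: np.ndarray                # (n_pairs, 20) raw counts
    background: np.ndarray            # (20,)
    pseudocount_mass: float
    low_count_pairs: list = field(default_factory=list)

    @property
    def position_index(self) -> dict:
        idx = {}
        for i, tp in enumerate(self.pairs):
            idx.setdefault(tp.pep_pos, []).append(i)
        return idx

    def position_matrix(self) -> dict:
        """Summed 20-vector of energies per register label."""
        out = {}
        for label, pair_ids in self.position_index.items():
            out[label] = self.energies[pair_ids].sum(axis=0)
        return out

    def score(self, sequence: str, labels) -> float:
        """Energy of a peptide window aligned to the register (lower=better)."""
        labels = list(labels)
        if len(sequence) != len(labels):
            raise ValueError("sequence and register labels differ in length")
        at = dict(zip(labels, sequence))
        total = 0.0
        for label, pair_ids in self.position_index.items():
            if label not in at:
                raise ValueError(f"window does not cover position {label}")
            aa = at[label]
            if aa not in AA_INDEX:
                raise ValueError(f"non-standard residue {aa!r}")
            total += float(self.energies[pair_ids, AA_INDEX[aa]].sum())
        return total

    def min_score(self) -> float:
        """Lowest achievable score (per-pair argmin; additive bound)."""
        return float(self.energies.min(axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "receptor_name": self.receptor_name,
            "variant": self.variant,
            "pseudocount_mass": self.pseudocount_mass,
            "background": self.background.tolist(),
            "low_count_pairs": self.low_count_pairs,
            "aa_order": AA_ORDER,
            "pairs": [
                {
                    "pep_pos": tp.pep_pos,
                    "rec_key": list(tp.rec_key),
                    "rec_atom_names": tp.rec_atom_names,
                    "fingerprint": tp.fingerprint.tolist(),
                    "energies": self.energies[i].tolist(),
                    "counts": self.counts[i].tolist(),
                }
                for i, tp in enumerate(self.pairs)
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "StatiumModel":
        pairs = [
            TemplatePair(p["pep_pos"], tuple(p["rec_key"]),
                         p["rec_atom_names"], np.array(p["fingerprint"]))
            for p in d["pairs"]
        ]
        return cls(
            receptor_name=d["receptor_name"],
            variant=d["variant"],
            pairs=pairs,
            energies=np.array([p["energies"] for p in d["pairs"]]),
            counts=np.array([p["counts"] for p in d["pairs"]]),
            background=np.array(d["background"]),
            pseudocount_mass=d["pseudocount_mass"],
            low_count_pairs=d.get("low_count_pairs", []),
        )

    @classmethod
    def from_json(cls, text: str) -> "StatiumModel":
        return cls.from_dict(json.loads(text))


def derive_potential(counts: list, pairs: list, bg: np.ndarray,
                     pseudocount_mass: float = 20.0,
                     receptor_name: str = "", variant: str = "SC") -> StatiumModel:
    """Convert count matrices into a :class:`StatiumModel`.

    Frequencies are smoothed with a background-distributed pseudocount mass:
    ``P_aa = (count_aa + m * bg_aa) / (total + m)``.  Pairs with fewer than
    100 raw counts are flagged as statistically unreliable.
    """
    if pseudocount_mass < 0:
        raise ValueError("pseudocount_mass must be >= 0")
    bg = np.asarray(bg, dtype=float)
    if bg.shape != (len(AA_ORDER),) or np.any(bg <= 0) or \
            abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 20 positive probabilities summing to 1")
    count_mat = np.array(counts, dtype=float)
    if count_mat.shape != (len(pairs), len(AA_ORDER)):
        raise ValueError("counts not aligned with pairs")
    energies = np.empty_like(count_mat)
    low = []
    for i in range(len(pairs)):
        total = count_mat[i].sum()
        if total == 0 and pseudocount_mass == 0:
            raise ValueError(
                f"pair {i} has zero counts and no pseudocount mass")
        p = (count_mat[i] + pseudocount_mass * bg) / (total + pseudocount_mass)
        with np.errstate(divide="ignore"):  # -ln 0 = +inf without pseudocounts
            energies[i] = -np.log(p / bg)
        if total < LOW_COUNT_THRESHOLD:
            low.append(i)
    if low:
        warnings.warn(f"{len(low)} pair(s) have fewer than "
                      f"{LOW_COUNT_THRESHOLD} counts; energies are unreliable")
    return StatiumModel(receptor_name=receptor_name, variant=variant,
                        pairs=list(pairs), energies=energies,
                        counts=count_mat.astype(np.int64), background=bg,
                        pseudocount_mass=pseudocount_mass,
                        low_count_pairs=low)
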