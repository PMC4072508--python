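"""Deterministic synthetic fixtures for every stage of the pipeline.

Nothing here aims at physical realism: the generators produce idealized
helical complexes, miniature structure databases, proteomes, spot-intensity
tables, K_D tables and alignments whose *ground truth is known by
construction*, so that the geometric and statistical contracts of the other
modules can be exercised without any external data.

The planted complex is an idealized helix (2.3 A radius, 1.5 A rise, 100
degrees per residue) carrying backbone N/CA/C/O atoms, a Cbeta placed at the
ideal-geometry position, and compact side-chain pseudo-atom clusters.  For
each planted contact position a receptor residue is placed radially outward
from the peptide Cbeta so that exactly that peptide position falls within
the side-chain interaction cutoff; all receptor side-chain pseudo-atoms are
kept on the far side of the receptor Cbeta, which makes "is this pair within
the cutoff" equivalent to a single center-to-center distance and lets the
generator assert its own contact guarantees at build time.

Structure-database entries copy the template pair geometry exactly (matching
fingerprints at RMSD 0) while re-labeling the peptide-side amino acid
according to a planted preference distribution; counts are allocated
deterministically (largest remainder), so derived potentials can be checked
against exact log-ratios.  Decoy entries displace the receptor copy by 1 A,
which breaks fingerprint matching but not interaction detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pssm import PSSM_POSITIONS
from .scan import FilterConfig, composition_filter
from .structio import (
    AA_ORDER,
    EXTENDED_REGISTER,
    SIDECHAIN_ATOMS,
    Atom,
    Residue,
    StructureModel,
    virtual_cbeta,
    write_structure,
)

__all__ = [
    "DEFAULT_PREFERENCES", "CONSENSUS_26", "FixtureSpec",
    "gen_complex", "gen_structure_db", "gen_proteome",
    "gen_spot_table", "gen_kd_table", "gen_msa", "gen_benchmark_scores",
    "allocate_counts",
]

SC_CUTOFF = 6.0

#: Planted amino-acid preferences at the ten experimentally scored positions.
DEFAULT_PREFERENCES = {
    "2d": {"R": 0.6, "K": 0.2, "Q": 0.2},
    "2e": {"E": 0.6, "D": 0.2, "Q": 0.2},
    "2g": {"R": 0.6, "K": 0.2, "N": 0.2},
    "3a": {"L": 0.6, "I": 0.2, "F": 0.2},
    "3b": {"R": 0.6, "K": 0.2, "E": 0.2},
    "3d": {"I": 0.6, "L": 0.2, "V": 0.2},
    "3e": {"A": 0.6, "G": 0.2, "S": 0.2},
    "3f": {"D": 0.7, "E": 0.2, "N": 0.1},
    "3g": {"E": 0.6, "D": 0.2, "R": 0.2},
    "4a": {"F": 0.6, "Y": 0.2, "N": 0.2},
}

_FILLER = {
    "1d": "E", "1e": "T", "1f": "Q", "1g": "A", "2a": "L", "2b": "S",
    "2c": "R", "2f": "E", "3c": "Q", "4b": "N", "4c": "A", "4d": "Y",
    "4e": "S", "4f": "R", "4g": "K", "5a": "L",
}


def _consensus_26(preferences=DEFAULT_PREFERENCES) -> str:
    seq = []
    for label in EXTENDED_REGISTER:
        if label in preferences:
            seq.append(max(preferences[label], key=preferences[label].get))
        else:
            seq.append(_FILLER[label])
    return "".join(seq)


#: The planted consensus window; passes all four composition rules.
CONSENSUS_26 = _consensus_26()

# Receptor-role residue types for planted contacts.  Ala and Gly are excluded
# so that the reversed orientation of a planted database pair can never
# masquerade as a receptor-side match (see module docstring).
_RECEPTOR_AA_CYCLE = "RKDEQNHFYWMLT"


@dataclass
class FixtureSpec:
    """Bundle of generator knobs; a fixed seed gives byte-identical output."""

    seed: int = 0
    n_db_structures: int = 500
    n_proteins: int = 100
    protein_length: int = 400
    n_planted_motifs: int = 5
    planted_preferences: dict = field(default_factory=lambda: dict(DEFAULT_PREFERENCES))
    kd_effect: float = 1.19  # binder/nonbinder score separation (-> AUC ~0.8)

    def __post_init__(self):
        for label, dist in self.planted_preferences.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"preference at {label} does not sum to 1")
        if self.n_planted_motifs > self.n_proteins:
            raise ValueError("cannot plant more motifs than proteins")


# ---------------------------------------------------------------------------
# Helical complex
# ---------------------------------------------------------------------------

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)


def _helix_frames(n: int):
    """Backbone atoms and local frames for an idealized helix along x."""
    frames = []
    for i in range(n):
        th = i * _HELIX_TWIST
        ca = np.array([_HELIX_RISE * i,
                       _HELIX_RADIUS * math.cos(th),
                       _HELIX_RADIUS * math.sin(th)])
        t = np.array([_HELIX_RISE,
                      -_HELIX_RADIUS * math.sin(th) * _HELIX_TWIST,
                      _HELIX_RADIUS * math.cos(th) * _HELIX_TWIST])
        t /= np.linalg.norm(t)
        u = np.array([0.0, math.cos(th), math.sin(th)])
        w = np.cross(t, u)
        w /= np.linalg.norm(w)
        n_at = ca - 1.46 * _unit(t - 0.45 * w)
        c_at = ca + 1.52 * _unit(t + 0.45 * w)
        o_at = c_at + 1.23 * _unit(u + w)
        frames.append({"N": n_at, "CA": ca, "C": c_at, "O": o_at,
                       "t": t, "u": u, "w": w})
    return frames


def _unit(v):
    return v / np.linalg.norm(v)


def _backbone_residue(chain, seq, aa, frame) -> Residue:
    atoms = [Atom("N", "N", frame["N"]), Atom("CA", "C", frame["CA"]),
             Atom("C", "C", frame["C"]), Atom("O", "O", frame["O"])]
    return Residue(chain, seq, aa, atoms)


def _element_of(atom_name: str) -> str:
    return atom_name[0] if atom_name[0] in "NOSC" else "C"


def _sidechain_cluster(aa: str, cb: np.ndarray, away: np.ndarray,
                       lat1: np.ndarray, lat2: np.ndarray, rng) -> list:
    """Pseudo side-chain atoms past CB: only on the far side of ``cb``.

    Every atom sits at ``cb + a*away + b*lat1 + c*lat2`` with ``a >= 0`` and
    lateral spread <= 1.2 A, so the closest cluster atom to anything on the
    near side is CB itself.
    """
    atoms = [Atom("CB", "C", cb)]
    for name in SIDECHAIN_ATOMS[aa][1:]:
        a = rng.uniform(0.2, 1.2)
        b, c = rng.uniform(-1.2, 1.2, size=2)
        atoms.append(Atom(name, _element_of(name),
                          cb + a * away + b * lat1 + c * lat2))
    return atoms


def gen_complex(seed: int = 0,
                peptide_sequence: str = CONSENSUS_26,
                planted_labels=PSSM_POSITIONS,
                contact_offset: float = 4.2,
                spacing_scale: float = 1.0,
                n_far_residues: int = 4,
                receptor_aa=None):
    """Generate a two-chain PDB text with known interacting pairs.

    Returns ``(pdb_text, truth)`` where ``truth`` is the list of
    ``(peptide register label, receptor seq_num)`` contacts that satisfy the
    side-chain criterion by construction (empty when ``spacing_scale`` pushes
    the contacts beyond the cutoff).  Raises when the requested geometry
    cannot guarantee the planted contact set.
    """
    if len(peptide_sequence) != len(EXTENDED_REGISTER):
        raise ValueError("peptide sequence must be a 26-mer on 1d-5a")
    rng = np.random.default_rng(seed)
    frames = _helix_frames(len(peptide_sequence))
    label_pos = {lab: i for i, lab in enumerate(EXTENDED_REGISTER)}
    if receptor_aa is None:
        receptor_aa = [_RECEPTOR_AA_CYCLE[k % len(_RECEPTOR_AA_CYCLE)]
                       for k in range(len(planted_labels))]

    peptide = []
    cbs = []
    for i, aa in enumerate(peptide_sequence):
        res = _backbone_residue("P", i + 1, aa, frames[i])
        cb = virtual_cbeta(res)
        cbs.append(cb)
        if aa != "G":
            away = _unit(cb - frames[i]["CA"])
            res.atoms.extend(_sidechain_cluster(
                aa, cb, away, frames[i]["w"], frames[i]["t"], rng))
        peptide.append(res)

    off = contact_offset * spacing_scale
    receptor, truth = [], []
    planted_idx = []
    for k, label in enumerate(planted_labels):
        i = label_pos[label]
        u = frames[i]["u"]  # pure radial: keeps the cluster off other residues
        cb_rec = cbs[i] + off * u
        ca_rec = cb_rec + 1.52 * u
        n_rec = ca_rec - 1.46 * _unit(frames[i]["t"] - 0.45 * frames[i]["w"])
        c_rec = ca_rec + 1.52 * _unit(frames[i]["t"] + 0.45 * frames[i]["w"])
        aa = receptor_aa[k]
        res = Residue("R", k + 1, aa,
                      [Atom("N", "N", n_rec), Atom("CA", "C", ca_rec),
                       Atom("C", "C", c_rec)])
        res.atoms.extend(_sidechain_cluster(aa, cb_rec, u, frames[i]["w"],
                                            frames[i]["t"], rng))
        receptor.append(res)
        planted_idx.append(i)
        if off < SC_CUTOFF:
            truth.append((label, k + 1))
    for m in range(n_far_residues):
        i = rng.integers(0, len(peptide_sequence))
        u = frames[i]["u"]
        cb_rec = cbs[i] + 30.0 * u
        aa = _RECEPTOR_AA_CYCLE[m % len(_RECEPTOR_AA_CYCLE)]
        res = Residue("R", len(planted_labels) + m + 1, aa,
                      [Atom("N", "N", cb_rec + np.array([1.4, 0, 0])),
                       Atom("CA", "C", cb_rec + 1.52 * u),
                       Atom("C", "C", cb_rec + np.array([-1.4, 0.5, 0]))])
        res.atoms.extend(_sidechain_cluster(aa, cb_rec, u, frames[i]["w"],
                                            frames[i]["t"], rng))
        receptor.append(res)

    _validate_contacts(peptide, cbs, receptor, planted_idx, off)
    model = StructureModel("synthetic-complex", peptide + receptor)
    return write_structure(model), truth


def _validate_contacts(peptide, cbs, receptor, planted_idx, off):
    """Check by brute distance that realized SC contacts equal the plan."""
    probes = np.array([[p.coords("CA"), cb] for p, cb in zip(peptide, cbs)])
    for k, res in enumerate(receptor):
        sc_names = SIDECHAIN_ATOMS[res.aa] or ["CA"]
        sc = np.array([res.coords(n) for n in sc_names])
        d = np.linalg.norm(probes[:, :, None, :] - sc[None, None, :, :],
                           axis=3).min(axis=(1, 2))
        hit = set(np.flatnonzero(d < SC_CUTOFF))
        if k < len(planted_idx):
            want = {planted_idx[k]} if off < SC_CUTOFF else set()
        else:
            want = set()
        if hit != want:
            raise ValueError(
                f"geometrically infeasible spec: receptor residue {k + 1} "
                f"contacts peptide indices {sorted(hit)}, wanted {sorted(want)}")


# ---------------------------------------------------------------------------
# Structure database with planted amino-acid preferences
# ---------------------------------------------------------------------------

def allocate_counts(dist: dict, n: int) -> dict:
    """Deterministic largest-remainder allocation of ``n`` draws to ``dist``."""
    items = sorted(dist.items())
    raw = [(aa, n * p) for aa, p in items]
    counts = {aa: int(math.floor(x)) for aa, x in raw}
    short = n - sum(counts.values())
    for aa, x in sorted(raw, key=lambda t: (-(t[1] - math.floor(t[1])), t[0])):
        if short == 0:
            break
        counts[aa] += 1
        short -= 1
    return {aa: c for aa, c in counts.items() if c > 0}


def _copy_atoms(res: Residue, shift: np.ndarray, names=None) -> list:
    out = []
    for a in res.atoms:
        if names is not None and a.name not in names:
            continue
        out.append(Atom(a.name, a.element, a.coords + shift))
    return out


def gen_structure_db(template, pairs, preferences=None,
                     n_structures: int = 500, n_decoys: int = 50,
                     seed: int = 0):
    """Single-chain structures planting amino-acid preferences at pairs.

    Each of the ``n_structures`` entries contains, for every template pair
    whose peptide position appears in ``preferences``, an exact geometric
    copy of that pair: the receptor residue keeps its identity and all atoms,
    while the peptide-role residue keeps only its backbone and Cbeta (plus at
    most one extra pseudo-atom, so the reversed orientation is skipped for
    missing atoms) and takes an amino-acid identity from the deterministic
    allocation of the planted distribution.  ``n_decoys`` additional entries
    displace the receptor copy by 1 A, breaking fingerprint matching.

    Returns ``(pdb_texts, expected_counts)`` with ``expected_counts`` a dict
    ``{register label: {aa: count}}`` of matches the scan must recover.
    """
    if preferences is None:
        preferences = DEFAULT_PREFERENCES
    rng = np.random.default_rng(seed)
    rec_by_key = {r.key: r for r in template.receptor}
    used = [(tp, rec_by_key[tp.rec_key[:2]]) for tp in pairs
            if tp.pep_pos in preferences]
    if not used:
        raise ValueError("no template pairs overlap the planted preferences")

    # Per pair: sequence of peptide-role amino acids across structures.
    assignments = {}
    expected = {}
    for tp, rec in used:
        counts = allocate_counts(preferences[tp.pep_pos], n_structures)
        expected[tp.pep_pos] = dict(counts)
        seq = [aa for aa, c in sorted(counts.items()) for _ in range(c)]
        assignments[tp.pep_pos] = list(rng.permutation(seq))
        # A glycine peptide role is only detectable through its CA; check
        # that the CA actually reaches the receptor cluster.
        if "G" in counts:
            pres = template.peptide_residue(tp.pep_pos)
            sc_names = SIDECHAIN_ATOMS[rec.aa] or ["CA"]
            d = min(np.linalg.norm(pres.coords("CA") - rec.coords(n))
                    for n in sc_names)
            if d >= SC_CUTOFF:
                raise ValueError(
                    f"glycine undetectable at pair {tp.pep_pos}: CA is "
                    f"{d:.2f} A from the receptor side chain")

    texts = []
    for s in range(n_structures + n_decoys):
        residues = []
        for q, (tp, rec) in enumerate(used):
            shift = np.array([150.0 * q, 0.0, 0.0])
            pres = template.peptide_residue(tp.pep_pos)
            cb = virtual_cbeta(pres)
            if s < n_structures:
                aa = assignments[tp.pep_pos][s]
                rec_shift = shift
            else:
                aa = rng.choice(sorted(preferences[tp.pep_pos]))
                away = _unit(rec.coords("CB") - cb)  # along the separation
                rec_shift = shift + 1.0 * away
            rec_atoms = _copy_atoms(rec, rec_shift)
            residues.append(Residue("A", 10 * q + 1, rec.aa, rec_atoms))
            pep_atoms = _copy_atoms(pres, shift, names={"N", "CA", "C", "O"})
            sc_names = SIDECHAIN_ATOMS[aa]
            if sc_names:  # real CB at the template position
                pep_atoms.append(Atom("CB", "C", cb + shift))
            if len(sc_names) >= 2:  # one pseudo-atom; the rest stay missing
                lat = _unit(np.cross(cb - pres.coords("CA"),
                                     np.array([1.0, 0.0, 0.0])))
                pep_atoms.append(Atom(sc_names[1], _element_of(sc_names[1]),
                                      cb + shift + 0.5 * lat))
            residues.append(Residue("A", 10 * q + 2, aa, pep_atoms))
        texts.append(write_structure(StructureModel(f"db-{s}", residues)))
    return texts, expected


# ---------------------------------------------------------------------------
# Proteome, SPOT table, K_D table, MSA
# ---------------------------------------------------------------------------

def gen_proteome(seed: int = 0, n_proteins: int = 100,
                 protein_length: int = 400, n_planted: int = 5,
                 planted_sequence: str = CONSENSUS_26,
                 cfg: FilterConfig = FilterConfig()):
    """Random proteome with planted motif windows; returns (fasta, truth_df)."""
    if n_planted > n_proteins:
        raise ValueError("cannot plant more motifs than proteins")
    if not composition_filter(planted_sequence, cfg):
        raise ValueError("planted sequence fails the composition filter")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA_ORDER))
    records, truth = [], []
    width = len(planted_sequence)
    for p in range(n_proteins):
        pid = f"prot{p:04d}"
        seq = "".join(rng.choice(aas, size=protein_length))
        if p < n_planted:
            start = int(rng.integers(0, protein_length - width + 1))
            seq = seq[:start] + planted_sequence + seq[start + width:]
            truth.append({"protein_id": pid, "start": start,
                          "sequence": planted_sequence})
        records.append((pid, seq))
    fasta = "".join(f">{pid}\n{seq}\n" for pid, seq in records)
    return fasta, pd.DataFrame(truth, columns=["protein_id", "start", "sequence"])


def gen_spot_table(seed: int = 0, preferences=None,
                   alt_intensity: float = 0.5,
                   background_range=(0.01, 0.2)) -> str:
    """TSV spot table whose wild type is the planted consensus.

    The wild-type residue at each of the ten scored positions has intensity
    1.0 (the reference); planted alternates get ``alt_intensity``; every
    other amino acid gets a weak random signal.
    """
    if preferences is None:
        preferences = DEFAULT_PREFERENCES
    rng = np.random.default_rng(seed)
    lines = ["position\taa\tintensity\treference"]
    for pos in PSSM_POSITIONS:
        dist = preferences.get(pos)
        wt = max(dist, key=dist.get) if dist else _FILLER[pos]
        for aa in AA_ORDER:
            if aa == wt:
                inten, ref = 1.0, 1
            elif dist and aa in dist:
                inten, ref = alt_intensity, 0
            else:
                inten, ref = float(rng.uniform(*background_range)), 0
            lines.append(f"{pos}\t{aa}\t{inten:.6f}\t{ref}")
    return "\n".join(lines) + "\n"


def gen_kd_table(seed: int = 0, n_peptides: int = 40,
                 n_intermediate: int = 5,
                 receptor_pairs=(("Mcl-1", "Bcl-xL"), ("Bcl-xL", "Mcl-1"),
                                 ("Bfl-1", "Bcl-2"))) -> str:
    """TSV of (peptide, receptor, K_D) with known binder/nonbinder structure.

    Each peptide binds one receptor tightly (K_D lognormal around ~100 nM)
    and fails to bind a second (either ">10000" censored or 20-100 uM);
    ``n_intermediate`` extra measurements fall between the cutoffs and must
    be excluded by the labeling rules.
    """
    rng = np.random.default_rng(seed)
    lines = ["peptide_id\treceptor\tkd_nm"]
    for i in range(n_peptides):
        bound, unbound = receptor_pairs[i % len(receptor_pairs)]
        kd_b = float(np.exp(rng.normal(np.log(100.0), 0.8)))
        kd_b = min(kd_b, 950.0)
        lines.append(f"pep{i:03d}\t{bound}\t{kd_b:.1f}")
        if rng.random() < 0.5:
            lines.append(f"pep{i:03d}\t{unbound}\t>10000")
        else:
            kd_u = float(rng.uniform(20000, 100000))
            lines.append(f"pep{i:03d}\t{unbound}\t{kd_u:.0f}")
    for j in range(n_intermediate):
        rec = ("Bcl-w", "Bcl-2")[j % 2]
        kd = float(rng.uniform(1500, 9000))
        lines.append(f"mid{j:02d}\t{rec}\t{kd:.0f}")
    return "\n".join(lines) + "\n"


def gen_benchmark_scores(examples, auc_target: float = 0.8, seed: int = 0) -> dict:
    """Scores for labeled examples with a chosen expected separability.

    Binders score N(d, 1) and non-binders N(0, 1) with d chosen so the
    population AUC equals ``auc_target`` (AUC = Phi(d / sqrt(2))).
    """
    rng = np.random.default_rng(seed)
    d = math.sqrt(2.0) * float(norm.ppf(auc_target))
    return {(e.peptide_id, e.receptor):
            float(rng.normal(d if e.label == 1 else 0.0, 1.0))
            for e in examples}


def gen_msa(seed: int = 0, n_rows: int = 12, n_cols: int = 60,
            core_start: int = 24, core_width: int = 12,
            core_entropy: float = 0.0, gap_fraction: float = 0.05) -> str:
    """Aligned FASTA with a conserved core of configurable entropy.

    ``core_entropy`` 0 makes the core columns invariant; larger values mix
    in a second residue (per-column two-state entropy grows with the mixing
    probability up to ln 2).
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA_ORDER))
    consensus = rng.choice(aas, size=n_cols)
    swap_p = 0.0
    if core_entropy > 0:  # invert two-state entropy numerically
        grid = np.linspace(0.001, 0.5, 500)
        ent = -(grid * np.log(grid) + (1 - grid) * np.log(1 - grid))
        swap_p = float(grid[np.argmin(np.abs(ent - core_entropy))])
    rows = []
    for r in range(n_rows):
        chars = []
        for j in range(n_cols):
            if core_start <= j < core_start + core_width:
                aa = consensus[j]
                if swap_p and rng.random() < swap_p:
                    aa = aas[(np.where(aas == aa)[0][0] + 1) % len(aas)]
                chars.append(aa)
            elif rng.random() < gap_fraction:
                chars.append("-")
            else:
                chars.append(rng.choice(aas))
        rows.append("".join(chars))
    return "".join(f">seq{r}\n{row}\n" for r, row in enumerate(rows))
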