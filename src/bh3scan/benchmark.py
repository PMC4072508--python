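"""Affinity and specificity benchmarks with ROC/AUC and bootstrap CIs.

Interactions between a peptide and a prosurvival receptor are labeled from
measured dissociation constants: K_D < 1 uM counts as a binder, K_D > 10 uM
as a non-binder, and intermediate affinities are excluded.  Censored values
(e.g. ">10000" nM) are usable when the bound itself settles the label.

Two tests are supported.  The *affinity* test asks whether a model's score
separates binders from non-binders; ROC curves use TPR = TP/(TP+FN) and
FPR = FP/(FP+TN) swept over score cutoffs, with the AUC equal to the
Mann-Whitney rank statistic (ties credited 0.5).  The *specificity* test
collects peptides that bind one receptor (K_D < 1 uM) but not another
(K_D > 10 uM) and asks whether the Z-score difference predicts the
preference; each comparison contributes its delta as a positive example and
the reversed delta as the matched negative, making the test symmetric.
Confidence intervals come from a percentile bootstrap over examples.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RECEPTORS", "InteractionRecord", "LabeledExample",
    "SpecificityComparison", "RocResult", "read_kd_table", "label_affinity",
    "build_specificity", "roc_auc", "bootstrap_auc_ci", "specificity_roc",
]

RECEPTORS = ("Bcl-xL", "Bcl-w", "Bcl-2", "Mcl-1", "Bfl-1")

STRONG_CUTOFF_NM = 1000.0     # binder: K_D below 1 uM
NON_CUTOFF_NM = 10000.0       # non-binder: K_D above 10 uM


@dataclass
class InteractionRecord:
    peptide_id: str
    receptor: str
    kd_nm: float
    censor: str = ""          # "", ">" (lower bound) or "<" (upper bound)

    def __post_init__(self):
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not self.kd_nm > 0:
            raise ValueError("K_D must be positive")
        if self.censor not in ("", ">", "<"):
            raise ValueError("censor flag must be '', '>' or '<'")


@dataclass
class LabeledExample:
    peptide_id: str
    receptor: str
    label: int                # 1 = binder, 0 = nonbinder
    score: float = np.nan


@dataclass
class SpecificityComparison:
    peptide_id: str
    receptor_bound: str
    receptor_unbound: str
    delta_z: float = np.nan


@dataclass
class RocResult:
    points: np.ndarray        # (n, 2) columns FPR, TPR
    auc: float
    n_pos: int
    n_neg: int
    ci90: tuple = None


def _parse_kd(value) -> tuple:
    """Parse a K_D cell like ``250``, ``">10000"`` or ``"<1"``."""
    s = str(value).strip()
    censor = ""
    if s and s[0] in "<>":
        censor, s = s[0], s[1:]
    return float(s), censor


def read_kd_table(source) -> list:
    """TSV with columns peptide_id, receptor, kd_nm -> interaction records."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        kd, censor = _parse_kd(row.kd_nm)
        records.append(InteractionRecord(str(row.peptide_id),
                                         str(row.receptor), kd, censor))
    return records


def _affinity_label(rec: InteractionRecord,
                    strong_cutoff_nm: float,
                    non_cutoff_nm: float):
    """1/0 label or None when the measurement cannot settle it."""
    if rec.censor == "<":
        return 1 if rec.kd_nm <= strong_cutoff_nm else None
    if rec.censor == ">":
        return 0 if rec.kd_nm >= non_cutoff_nm else None
    if rec.kd_nm < strong_cutoff_nm:
        return 1
    if rec.kd_nm > non_cutoff_nm:
        return 0
    return None


def label_affinity(records,
                   strong_cutoff_nm: float = STRONG_CUTOFF_NM,
                   non_cutoff_nm: float = NON_CUTOFF_NM) -> list:
    """Label interactions as binder/nonbinder; intermediate K_D excluded."""
    out = []
    for rec in records:
        label = _affinity_label(rec, strong_cutoff_nm, non_cutoff_nm)
        if label is not None:
            out.append(LabeledExample(rec.peptide_id, rec.receptor, label))
    return out


def build_specificity(records,
                      strong_cutoff_nm: float = STRONG_CUTOFF_NM,
                      non_cutoff_nm: float = NON_CUTOFF_NM) -> list:
    """One comparison per (bound, unbound) receptor pair of each peptide."""
    by_peptide = {}
    for rec in records:
        by_peptide.setdefault(rec.peptide_id, []).append(rec)
    comparisons = []
    for pid in sorted(by_peptide):
        bound, unbound = [], []
        for rec in by_peptide[pid]:
            label = _affinity_label(rec, strong_cutoff_nm, non_cutoff_nm)
            if label == 1:
                bound.append(rec.receptor)
            elif label == 0:
                unbound.append(rec.receptor)
        for rb in bound:
            for ru in unbound:
                comparisons.append(SpecificityComparison(pid, rb, ru))
    return comparisons


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for binder/nonbinder examples (higher score=binder)."""
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(points=np.column_stack([fpr, tpr]), auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def bootstrap_auc_ci(scores, labels, n_resamples: int = 2000,
                     level: float = 0.90, seed=None) -> tuple:
    """Percentile bootstrap interval for the AUC.

    Examples are resampled with replacement ``n_resamples`` times; resamples
    that end up with a single class are redrawn.  Returns the (lower, upper)
    limits of the central ``level`` interval, e.g. the 5th and 95th
    percentiles for the default 90% level.
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("need both classes to bootstrap")
    rng = np.random.default_rng(seed)
    n = labels.size
    aucs = np.empty(n_resamples)
    for b in range(n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            ls = labels[idx]
            if 0 < ls.sum() < n:
                break
        aucs[b] = roc_auc_score(ls, scores[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def specificity_roc(comparisons, z_scores: dict) -> RocResult:
    """ROC/AUC for predicting receptor preference from Z-score differences.

    ``z_scores`` maps ``(peptide_id, receptor)`` to a model Z-score.  Each
    comparison contributes ``delta = Z(bound) - Z(unbound)`` as a positive
    example; the reversed delta forms the matched negative class.
    Comparisons with a missing score are dropped with a warning.
    """
    deltas = []
    for cmp_ in comparisons:
        zb = z_scores.get((cmp_.peptide_id, cmp_.receptor_bound))
        zu = z_scores.get((cmp_.peptide_id, cmp_.receptor_unbound))
        if zb is None or zu is None:
            warnings.warn(f"missing Z-score for {cmp_.peptide_id}; "
                          "comparison dropped")
            continue
        cmp_.delta_z = float(zb) - float(zu)
        deltas.append(cmp_.delta_z)
    if not deltas:
        raise ValueError("no usable specificity comparisons")
    deltas = np.asarray(deltas)
    scores = np.concatenate([deltas, -deltas])
    labels = np.concatenate([np.ones(deltas.size, dtype=int),
                             np.zeros(deltas.size, dtype=int)])
    return roc_auc(scores, labels)
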