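# Methods

This note documents the models implemented in `bh3scan`, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the problem sizes used by the test suite and
`scripts/acceptance.py`.

## Heptad register and window geometry

BH3 motifs are treated as amphipathic helices labeled on the heptad register
`[abcdefg]_n`.  Two window definitions coexist in the field's practice: a
23-residue scoring window and a 26-residue reporting/filtering window.  We
reconcile them by defining the core register 1g–5a (exactly 23 positions)
contained within the extended register 1d–5a (exactly 26 positions); the
23-mer is the suffix of the 26-mer.  Composition filters are applied to the
26-mer; models score whatever positions they cover.  The anchor used to place
a peptide on the register is the residue at 3a, supplied by the user when
building a template (templates bind non-canonical peptides often enough that
guessing the anchor from sequence would be fragile).  Internally indices are
0-based; PDB residue numbers are preserved for reporting.

## Structure I/O

PDB parsing and writing go through `gemmi`.  Hydrogens are dropped.
Alternate locations are resolved per atom name by highest occupancy, first
conformer on ties, which makes parsing deterministic.  Modified residues with
an unambiguous parent (MSE→Met, SEP→Ser, …) are mapped to the parent so that
database chains containing them remain usable; anything else is skipped with
a warning.  Coordinates are ångströms throughout.

Glycine lacks a Cβ but both interaction criteria are stated in terms of Cβ
positions, so a virtual Cβ is constructed from the N/Cα/C backbone with ideal
tetrahedral geometry and renormalized to a 1.52 Å bond.  `virtual_cbeta`
returns the real Cβ unchanged whenever one exists.

## Interface statistical potential

Two interaction criteria are supported:

* `CB`: Cβ atoms closer than 10 Å with Cα–Cβ vectors "not pointed away from
  each other".  The literature does not give the angular rule in closed form;
  we implement it as `dot(Cβi−Cαi, Cβj−Cβi) ≥ 0` **and**
  `dot(Cβj−Cαj, Cβi−Cβj) ≥ 0`, i.e. each side chain points at least weakly
  toward the other residue's Cβ.  The rule is configurable off.
* `SC`: any receptor side-chain heavy atom within 6 Å of a peptide side-chain
  atom, where the peptide side is always represented by {Cα, Cβ} (the peptide
  sequence is the unknown being scored, so only its backbone-anchored atoms
  are meaningful).  A receptor glycine's "side chain" is its Cα, so the
  criterion is evaluable for all residues.

Template pair fingerprints are the ordered distances between the peptide
{Cα, Cβ} and the receptor atoms of the pair (all heavy side-chain atoms for
SC, {Cα, Cβ} for CB), with receptor atoms in canonical PDB atom-name order so
that the correspondence for the RMSD is deterministic.  Database pairs match
a template pair when the receptor-side amino acid is identical and the
fingerprint RMSD is **strictly below** 0.4 Å; both orientations of a database
pair are tested, since within a single chain neither member is intrinsically
the "receptor".  Database pairs with missing canonical atoms are skipped.

Counts are converted to energies with natural logarithms (any base is a
monotone rescaling; ln is conventional for statistical potentials):

    P_aa = (count_aa + m·bg_aa) / (total + m),   E_pair(aa) = −ln(P_aa / bg_aa)

with a background-distributed pseudocount mass `m = 20` by default.  The
pseudocounts keep energies finite for unobserved amino acids; with `m = 0`
the energies are the exact empirical log-ratios (and −ln 0 = +∞ for
unobserved amino acids).  Pairs with fewer than 100 raw counts are flagged in
the model metadata as statistically unreliable.  Background amino-acid
frequencies are counted uniformly over database residues with a Laplace
pseudocount of 1 to keep them strictly positive.  Scores are additive over
pairs and positions; lower is stronger.

## Peptide-array PSSM

Position scores are `S = −(ln I − ln I_ref)` with `I_ref` the wild-type
(Bim-role) intensity at that position, so the reference sequence scores
exactly 0.  Intensities below 1% of the reference are clipped to that floor
before the logarithm — spot backgrounds are noisy near zero and an infinite
penalty would be spurious — capping scores at ln 100 ≈ 4.6.  Only the ten
positions with experimental data (2d, 2e, 2g, 3a, 3b, 3d, 3e, 3f, 3g, 4a)
are scored; other positions contribute nothing.  Missing (position, aa)
measurements are stored as NaN and raise at scoring time rather than being
silently imputed.

## Proteome scanning

Every protein is scanned in 26-residue windows at step 1; proteins shorter
than 26 yield none, and windows containing non-standard characters are
skipped with one warning per protein.  The four compositional rules (≥35%
DEHKNQRST over the 26-mer; at most one proline between 2d and 4a inclusive;
3a ∈ FILVYWM; 3e ∈ ACGS) are applied before scoring; the polar fraction is
computed over the full 26-mer since the filters are defined on the extended
window.

Raw energies are standardized per (model, receptor) against the sample
mean/sd of the **filtered** window set, with the sign flipped:
`Z = (mean − raw)/sd`, so "Z better than 2.0" reads as ≥ 2.0 while raw
energies remain lower-is-better.  The combined score is the arithmetic mean
of the PSSM and SC-potential Z-scores for the same receptor.  Redundancy
removal is greedy by descending score, dropping any window more than 75%
identical (ungapped, over the aligned 26-mer — windows share a register, so
no alignment is needed) to an already-kept one.  Array-style candidate
selection keeps windows whose PSSM Z meets a receptor-specific cutoff and
whose raw SC energy is negative, ranks by SC Z, and truncates to the top 20;
when several receptors are screened, candidates are assigned in the priority
order Bcl-x_L → Mcl-1 → Bfl-1.  Heuristics for hydrophobic or like-charge
runs are not implemented: the published procedure was visual inspection with
no stated thresholds, so we expose nothing rather than guess.

## Conservation filter

Column Shannon entropies `−Σ p ln p` exclude gaps from the frequencies
(counting gaps would conflate alignment length artifacts with variability);
an all-gap column is defined as 0 with a warning.  Window entropy sums 12
consecutive columns — 12 because the 2d–4a core is where known motifs are
most conserved.  A core is conserved when its window entropy is strictly
lower than the mean over all other sliding 12-column windows (step 1, core
excluded); ties fail.  Rows are counted uniformly, without sequence
weighting or deduplication.

## Array classification

Negative controls are the 3a→Asp and 3e→Leu point mutants; construction
errors out if the window already carries the control residue (the filters
guarantee this cannot happen for filtered candidates).  A candidate array
interaction requires a relative signal reduction of at least 30% — inclusive,
matching "at least" — for **both** controls, computed on raw intensities (the
Bim normalization cancels), so the call is scale-invariant.  Signal bins at
5/10/25% of the Bim reference are nested by construction.

## Benchmarks

Affinity labels: binder K_D < 1000 nM, non-binder K_D > 10000 nM,
intermediate excluded.  Censored values are used only when the bound itself
settles the label (">10000" → non-binder; "<1" → binder; ">5000" → excluded).
ROC curves and AUC are computed with scikit-learn (`roc_curve`,
`roc_auc_score`; TPR = TP/(TP+FN), FPR = FP/(FP+TN), ties credited 0.5); the
test suite checks them against an independent Mann–Whitney pair-counting
oracle.  Confidence intervals are percentile bootstrap — 2000 resamples with
replacement, 5th/95th percentiles for the 90% level — with single-class
resamples redrawn; BCa correction is deliberately not applied, keeping the
interval the plain percentile construction.

Specificity comparisons pair each peptide's bound receptor (K_D < 1 µM) with
each unbound receptor (K_D > 10 µM) and score the Z difference
`Z(bound) − Z(unbound)`.  The negative class for the specificity ROC is not
uniquely determined by how such plots are usually described; we use the
reversed deltas as matched negatives, which makes the test symmetric (an AUC
of 0.5 means the sign of the difference carries no information).  This is
one defensible reading, and it is applied uniformly to all models being
compared.

## Synthetic data: what it does and does not emulate

The generators are deterministic under their seed and produce:

* **Complexes**: an idealized helix (2.3 Å radius, 1.5 Å rise, 100°/residue)
  with backbone, ideal-geometry Cβ and compact side-chain pseudo-atom
  clusters, plus receptor residues placed 4.2 Å radially out from chosen
  peptide Cβ atoms.  Receptor side-chain atoms stay on the far side of the
  receptor Cβ, so contact membership reduces to one center distance and the
  generator can verify at build time that the realized contact set equals
  the plan (raising otherwise).  Doubling the spacing pushes every contact
  outside the 6 Å cutoff.
* **Structure databases**: exact geometric copies of template pairs
  (fingerprint RMSD 0) with the peptide-side identity drawn from planted
  preference distributions via deterministic largest-remainder allocation,
  so expected counts are exact integers; decoys displace the receptor copy
  by 1 Å, which keeps the pair interacting but breaks matching.  Peptide-role
  residues carry deliberately incomplete side chains so the reversed
  orientation is skipped for missing atoms and bookkeeping stays exact.
  Receptor-role residues avoid Ala and Gly for the same reason.
* **Proteomes**: uniform-composition random proteins (uniform amino-acid
  frequencies give ~45% polar content, so a realistic fraction of windows
  survives the filters) with a consensus motif window planted at recorded
  locations; the consensus is the argmax of the planted preferences at
  modeled positions and a fixed polar-rich filler elsewhere, constructed to
  pass all four filters.
* **Spot tables / K_D tables / alignments**: complete 10×20 intensity tables
  with the consensus as wild type; K_D tables with known binder/non-binder/
  intermediate structure and censored entries; alignments with a conserved
  core of configurable entropy.
* **Benchmark scores**: binder scores N(d, 1) vs non-binder N(0, 1) with
  `d = √2·Φ⁻¹(AUC)` for a chosen population AUC.

What passing these tests shows is that the geometric criteria, count
bookkeeping, energy algebra, filters, ranking and benchmark statistics are
implemented correctly.  What it does **not** show is predictive performance
on real structures and proteomes: the fixtures have no side-chain rotamers,
no packing constraints, no homologous redundancy, no correlated positions
and no assay noise structure.  Headline numbers from real-data studies
(genome-wide window counts near 6×10⁵, binder Z-scores near 2–3, AUCs near
0.67–0.85) require the real structure database, proteome and array data and
are out of reach of these fixtures by design.

## Problem sizes and tolerances

The test suite and acceptance script use sizes chosen to exercise every
contract while keeping a desk-scale footprint: 50 randomized complexes for
the detection-vs-brute-force equivalence; 500 planted matching pairs (plus
25 decoys) for potential recovery, with the pseudocount-free log-ratio exact
to 1e-9 and the pseudocount-20 recovery within 0.1 of −ln(ratio); a
100-protein, 400-residue proteome (37,500 windows, ~1,800 filtered) with 5
planted motifs required to rank in the top 1% of combined Z; and bootstrap
calibration with n = 200 examples at true AUC 0.8, 500 resamples, 100
repeats, requiring the 90% interval to contain the point estimate at least
85 times.  Background-distribution recovery on 10⁵ normal deviates is
required within 1%.  Boundary semantics are pinned: fingerprint RMSD exactly
0.4 Å is not a match, a control reduction of exactly 30% is a candidate, a
K_D exactly between the affinity cutoffs is excluded.

## Known limitations

* The SC criterion's peptide side uses {Cα, Cβ} rather than full side
  chains; this is faithful to the scanning use case (peptide sequence
  unknown) but means detection in database chains — where both members have
  full side chains — is asymmetric with template detection.
* One structural template per receptor; receptor flexibility, side-chain
  repacking and homology modeling are out of scope.
* The conservation filter assumes a user-supplied alignment; no weighting of
  redundant rows.
* `min_score` is the additive per-pair bound; with multiple pairs per
  position it can be slightly below the best achievable single-sequence
  score when pairs at one position disagree on the argmin amino acid (they
  cannot disagree in the planted fixtures, which have one pair per
  position).
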