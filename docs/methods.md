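# Methods

## Binding-site definition and ligand qualification

A hetero entity of a complex is treated as a candidate ligand. It is
**qualified** unless it (a) is water (HOH/WAT/DOD/H2O), (b) makes no
protein contact within the contact cutoff, or (c) has any atom closer than
the covalent cutoff to a protein atom (a covalently attached group is a
modification, not a ligand). Checks are applied in that order, so a
covalent clash takes precedence over the contact test it would otherwise
also satisfy. An optional molecular-weight window (off by default, since
no universally accepted bounds exist for "small molecule") can reject
entities outside a user-chosen mass range.

A polymer residue is a **binding site** for a qualified ligand iff the
minimum Euclidean distance over all (residue atom, ligand atom) pairs is
≤ 6.5 Å. The comparison is inclusive: a pair at exactly 6.5 Å counts as a
contact. All atoms participate, hydrogens included when present — the
definition is over atoms, not element subsets. When several ligands
qualify, per-ligand labels are OR-merged. Solvent-exposure filtering is
operationalised entirely by the ≥ 1-atom-pair contact rule; no
solvent-accessible-surface-area computation is performed.

Parsing uses gemmi (PDB and mmCIF). Only the first model of a multi-model
file is used. Alternate locations resolve to the highest-occupancy
conformer, ties to the earliest altloc letter. Nucleic-acid polymer
residues are excluded from both the protein residue list and the ligand
candidates; a DNA chain can therefore never be labelled. Because the
underlying reader tolerates malformed coordinate fields, PDB coordinate
records are re-validated before parsing and a malformed field raises an
error naming the file line.

## Residue interaction network

Nodes are polymer residues; an undirected, unweighted edge joins two
residues whose representative distance is within the contact cutoff.
The default rule is Cα–Cα ≤ 7.0 Å with minimum sequence separation 1
(sequence-adjacent residues allowed) — a common convention for
residue-contact networks; an any-atom mode with a 5.0 Å default is also
provided, and residues on different chains are never excluded by the
separation filter. A residue without a Cα under Cα mode is kept as an
edge-less node with a warning (configurable to a hard error).

The seven descriptors are computed from scratch on this graph:

- **Betweenness**: Σ over unordered pairs {s,t} (both ≠ u) of
  σ_st(u)/σ_st, via Brandes' accumulation; raw counts, not normalised.
  Pairs in different components contribute nothing.
- **Closeness**: (n_c − 1)/Σ dist within the node's connected component
  (n_c = component size). Component-local computation avoids the infinite
  distances a disconnected graph would otherwise inject while agreeing
  with the plain definition on connected graphs. Isolated node → 0.
- **Eigenvector centrality**: nonnegative, L2-normalised principal
  eigenvector of the adjacency matrix. Power iteration runs on A + I —
  the shift leaves eigenvectors unchanged but guarantees convergence on
  bipartite components, where iterating on A itself oscillates. On a
  disconnected graph the component with the largest spectral radius
  carries all mass; exact ties go to the earliest component in node
  order. Tolerance 1e-10, at most 1000 iterations (non-convergence is an
  error); an edgeless graph yields the zero vector with a warning.
- **Eccentricity**: max BFS distance to any reachable node; 0 for an
  isolated node.
- **Degree**, **local clustering coefficient** (0 when degree < 2), and
  **average nearest-neighbour degree** (0 when degree 0) by direct
  adjacency arithmetic.

Descriptors are emitted raw; min–max normalisation is applied only in the
distribution analyses, never before training.

## PSSM features

The evolutionary feature of residue i is row i of the L×20 log-odds block
of a PSI-BLAST ASCII PSSM (the weighted-percentage block and footer are
ignored). Values default to raw integer log-odds; an optional elementwise
sigmoid 1/(1+e^(−P)) maps them into (0,1). One row per residue, no
windowing — the feature is 20-dimensional by construction.

Sequence/structure numbering rarely coincides, so PSSM rows are mapped to
residues positionally when the sequences match exactly and otherwise by
local alignment (match +2, mismatch −1, gap open −5, extend −1). The
mapping is rejected when aligned-region identity falls below 95% or when
the alignment covers less than half the chain; the coverage floor keeps a
short accidental perfect match from masquerading as agreement.

## Dataset assembly, split, under-sampling

The design matrix inner-joins labels, topology and PSSM rows on
(structure, chain, residue number, insertion code); residues missing any
source are dropped with a logged count. Column order is fixed: 20 PSSM
columns in alphabetical amino-acid order, then B, Cl, EC, E, D, CC, AN.
Feature groups (PSSM-only, RIN-only, both) are selectable for ablation.

Complexes are split at the complex level by uniform sampling without
replacement (the reference protocol holds out 20 of 120 complexes), and
under-sampling draws round(ratio × n_pos) negatives uniformly without
replacement, keeping every positive; the default ratio 1 balances the
classes. Under-sampling is meant for the training table only — the
independent test set keeps its natural imbalance. All randomness flows
from explicit integer seeds.

## Classifiers and evaluation

Defaults (no canonical settings exist for this task, so these are ordinary
library defaults adjusted for a 27-feature tabular problem): XGBoost with
500 trees, depth 6, learning rate 0.1, histogram method, single thread;
SVM with RBF kernel, C = 1, gamma = 'scale'; CART with Gini impurity and
unlimited depth. All are overridable per run. Scores are positive-class
probabilities where the learner provides them; for the SVM the decision
margin is passed through a logistic map, which is deterministic and keeps
the 0.5 score threshold at margin 0 (Platt scaling via `probability=True`
would be slower and resampling-dependent). Hard labels use threshold 0.5
with ties classified positive.

Metrics are computed directly from the confusion counts: ACC, SEN,
SPE = TN/(TN+FP), PRE, and MCC. A `spe_fn_variant` flag computes
SPE = TN/(TN+FN) instead for comparability with sources that print that
variant. Any zero denominator yields NaN with a warning — never a silent
0. AUC is the trapezoidal area under the ROC of the scores and is omitted
(not fabricated) when scores are unavailable.

Cross-validation pools out-of-fold predictions and computes one metric set
on the pooled vector. k-fold uses class-stratified, seed-deterministic
folds; if a training fold loses a class the folds are re-drawn once with
a shifted seed before erroring. Jackknife is leave-one-row-out, and
k = n k-fold degenerates to the same leave-one-out folds, so the two
protocols coincide for a deterministic learner. Folds are residue-level
by default (matching cross-validation of a balanced residue table);
complex-level grouping is available by subsetting with the split utility
when leakage across folds is a concern.

## Distribution and property analyses

Per-feature normalisation for class comparison is min–max over the pooled
(both-class) values — bounded, order-preserving, and independent of any
distributional assumption; a constant feature normalises to zeros with a
warning. The class comparison reports the mean difference and a
two-sided Mann–Whitney U test with tie-corrected asymptotics (all-tied
input returns the null expectation U = n1·n2/2 with p = 1). No
multiple-testing correction is applied by default; callers scanning many
features should apply one. Frequency histograms use equal-width bins over
the pooled range, normalised per class.

Amino-acid property indices (e.g. the eight high-quality AAindex-derived
scales) are supplied as a TSV input — 20 rows, one column per index —
because no specific values are baked in. A binding-site residue is HIGH
for an index iff its value is ≥ the unweighted mean of that index over
the 20 standard amino acids; ties count HIGH, so a constant index makes
every residue HIGH. Non-standard residues are excluded and counted.
Per-ligand amino-acid preference is plain counting of residue types among
label-1 residues per structure group; no radial diagrams are rendered.

## Synthetic study conditions

The fixture generator emulates the inputs the pipeline consumes, not their
physics:

- **Complexes**: Cα-trace chains on ideal geometry (helix: 1.5 Å rise,
  100° twist, 2.3 Å radius; extended: 3.8 Å spacing; random coil:
  self-avoiding 3.8 Å walk), with optional dummy side-chain atoms. Ligand
  atoms are placed radially outward at cutoff − slack (default slack
  1.0 Å) from each requested contact residue, and every file is verified
  internally against a brute-force distance scan: contacts within the
  cutoff, all other residues beyond cutoff + 0.5 Å. Contact sets that
  cannot satisfy both margins — e.g. an extended chain at the default
  slack, where a flanking residue lands ~6.7 Å from the contact atom —
  raise an error rather than emit a mislabelled fixture (extended-chain
  fixtures use a 0.4 Å slack). Files are byte-deterministic per spec.
- **PSSMs**: integer log-odds uniform on [−10, 12] in a valid PSI-BLAST
  ASCII file; no phylogenetic structure.
- **Classification sets**: negatives i.i.d. N(0, σ²) in all 27 columns;
  positives shifted by (effect size)·σ in chosen columns (default: the 7
  network columns, effect 3, σ = 1, 500 rows per class — a strong,
  cleanly learnable signal; the null control uses effect 0). Gaussian,
  independent columns — real residue features are correlated,
  non-Gaussian, and complex-clustered, so these fixtures validate the
  pipeline's mechanics and protocol correctness, not field performance.

Passing tests on these conditions show that labelling, featurisation,
resampling, training and evaluation do exactly what they claim on inputs
with known truth. They do not estimate accuracy on real DNA-binding
protein–drug complexes, which requires a curated structure set and real
PSSMs.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small
problems: graphs of ≤ 50 nodes for oracle equivalence (100 graphs),
50 synthetic complexes of 15–60 residues for extraction checks, 1,000-row
tables for the classification study, and a 50-tree/depth-3 booster on
120-row tables for the 50-seed null control (a null AUC needs no model
capacity). Distance ties are tested at exactly 6.5 Å, which is exactly
representable in binary floating point, so the inclusive comparison is
exact. Equality tolerances: 1e-8 against brute-force graph oracles (the
power-iteration tolerance 1e-10 dominates), 1e-12 for metric arithmetic.

## Known limitations

- Binding-site labelling treats all qualified hetero entities alike; no
  chemical classification of the ligand (drug vs. cofactor vs. buffer
  component) beyond the water/covalent/contact rules.
- The RIN is unweighted; no interaction-energy or atom-contact-count
  weighting.
- PSSM generation (PSI-BLAST against a sequence database) is out of
  scope; files are consumed as given.
- The synthetic generator produces Cα traces with idealized geometry;
  any-atom contact behaviour on real side chains is exercised only via
  the dummy side-chain option.
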