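# drugsite

Residue-level prediction of drug-binding sites on DNA-binding proteins,
from protein–ligand complex structures.

DNA-binding proteins are targeted by many small-molecule drugs, but
residue-level annotation of where a drug binds is scarce. `drugsite`
implements a complete pipeline for building such a predictor from
protein–drug complexes:

1. **Geometric site labelling.** In a complex structure, a hetero entity
   qualifies as a ligand if it is not water, lies within 6.5 Å of the
   protein, and is not covalently bonded (no atom pair < 2.0 Å). A residue
   is a *binding site* (label 1) iff any of its atoms is within 6.5 Å
   (inclusive) of any qualified-ligand atom; all remaining residues are
   negatives.
2. **Residue interaction network (RIN) features.** The protein is abstracted
   as a graph with residues as nodes and spatial contacts (Cα–Cα ≤ 7.0 Å by
   default) as edges. Seven per-residue topology descriptors are computed:
   betweenness C_b(u) = Σ_{s≠u≠t} σ_st(u)/σ_st, closeness
   C_cl(u) = (n−1)/Σ_v dist(u,v), eigenvector centrality
   x = principal eigenvector of the adjacency matrix A, eccentricity
   C_e(u) = max_v dist(u,v), degree C_d(u) = Σ_v A_uv, local clustering
   coefficient, and average nearest-neighbour degree.
3. **PSSM features.** The 20-dimensional per-residue log-odds row of a
   position-specific scoring matrix (PSI-BLAST `-out_ascii_pssm` format),
   aligned to the structure's chain.
4. **Classification.** The 27-dimensional residue vectors (20 PSSM + 7 RIN)
   train an XGBoost classifier (SVM and CART baselines included) on a 1:1
   randomly under-sampled table; evaluation reports ACC, SEN, SPE, PRE,
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) and ROC AUC under
   jackknife, k-fold or independent-set protocols.
5. **Property analysis.** Min–max-normalised feature distributions per
   class, rank-sum class comparisons, frequency histograms, HIGH/LOW
   proportions of amino-acid property indices (AAindex-style scales) at
   binding sites, and per-ligand amino-acid preference counts.

A synthetic-fixture module generates complexes with known ground-truth
sites, valid PSSM files, and feature tables with planted class signal, so
the whole pipeline is testable without any database access.

## Worked example

```python
import drugsite as ds

# a 50-residue helix whose ligand touches residues 10-12
spec = ds.FixtureSpec(n_residues=50, geometry="helix",
                      ligand_contacts=frozenset({10, 11, 12}), seed=7)
path, truth = ds.make_complex(spec, "helix50.pdb")

s = ds.read_structure(path)
labels = ds.label_structure(s)          # qualify ligands + 6.5 Å labelling
print("binding-site residues:",
      sorted(k.residue_number for k in labels.positive_keys))

g = ds.build_rin(s, ds.ContactRule("c_alpha", 7.0, 1))
topo = ds.compute_all_topology(g)       # 7 descriptors per residue
print(topo[["resnum", "B", "Cl", "D"]].head(3).round(3).to_string(index=False))

# planted-signal study: effect only in the 7 network columns
t = ds.make_classification_set(ds.ClassSignalSpec(
    n_pos=500, n_neg=500, effect_size=3.0, seed=11))
report = ds.cross_validate(t, ds.ModelConfig("xgboost", seed=11),
                           "kfold", k=10, seed=11)
print(report.summary())
```

prints

```
binding-site residues: [10, 11, 12]
 resnum     B    Cl   D
      1 0.000 0.151 4.0
      2 0.486 0.157 5.0
      3 2.444 0.162 6.0
protocol: kfold(k=10)
counts:   TP=499 TN=500 FP=0 FN=1
ACC=0.9990  SEN=0.9980  SPE=1.0000  PRE=1.0000  MCC=0.9980  AUC=1.0000
```

The extractor recovers exactly the residues the generator placed in
contact; the first rows of the topology table show the raw betweenness,
closeness and degree of the helix ends; and a 3-SD planted shift in the
seven network columns is, as expected, almost perfectly learnable by the
gradient-boosted classifier under 10-fold cross-validation.

The same stages are available from the shell:

```sh
drugsite simulate complex --n-residues 50 --contacts 10,11,12 --out c.pdb
drugsite extract-sites --structure c.pdb --cutoff 6.5 --out labels.tsv
drugsite build-rin --structure c.pdb --mode c-alpha --cutoff 7.0 --out rin.tsv
drugsite cv --features table.tsv --algorithm xgboost --k 10
```

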