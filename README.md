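# psfmkit

Sequence-based identification of DNA-binding proteins from evolutionary
profiles.

DNA-binding proteins drive replication, repair and transcriptional
regulation, and recognising them from sequence alone is a long-standing
prediction task. The strongest sequence-only predictors work not on the raw
residue string but on its **position specific frequency matrix (PSFM)** —
the L×20 row-stochastic profile produced by PSI-BLAST, whose entry P_{i,j}
is the occurrence probability of amino acid j at position i across the
protein's homologs. Because profiles have variable length L while
classifiers need fixed-length inputs, the heart of the method is a family of
transformations from the PSFM to a fixed-length feature vector ψ₁…ψ_Ω:

* **RPT** (residue probing, Ω = 420): rows grouped by query residue,
  columns summed per group, e_{k,j}/L, plus the 20 amino-acid-composition
  values (column means).
* **EDT** (evolutionary difference, Ω = 400·D):
  f(A_x, A_y | d) = (1/(L−d)) Σᵢ (P_{i,x} − P_{i+d,y})², d = 1…D.
* **DBT** (distance bigram, Ω = 400·(D+1)):
  f(A_x, A_y | d) = (1/(L−d)) Σᵢ P_{i,x}·P_{i+d,y}, d = 0…D — the expected
  frequency of residue pair (x, y) at separation d under the profile; the
  d = 0 block carries the amino-acid composition on its diagonal.
* **TT** (trigram, Ω = 8000): f(A_x, A_y, A_z) = Σᵢ P_{i,x}P_{i+1,y}P_{i+2,z},
  unnormalized.

The vectors feed a soft-margin SVM with an RBF kernel; cost c and kernel
width g are chosen by stratified 5-fold cross-validated grid search over
powers of two. Evaluation uses the field's standard protocol — jackknife
(leave-one-out), k-fold, and independent-test schemes scored by SN, SP,
ACC, the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN))

and the area under the ROC curve. For interpretation, the per-sample dual
weights A = [a₁…a_N] of the trained machine give per-feature discriminant
weights **W = A·M** (M the training feature matrix); summing W per ordered
residue pair over separations d ≥ 1 yields a 20×20 bigram-importance table
in which, on real DNA-binding data, the (R,R), (T,T), (K,K), (R,K) and
(K,R) bigrams dominate — matching the known role of positively charged and
polar residues in DNA contact.

The package also ships a synthetic-profile generator (Dirichlet rows with
class-dependent enrichment of chosen residue columns) so the entire
pipeline is testable without PSI-BLAST runs or database downloads.

## Worked example

```python
from psfmkit import ProfileSVM, jackknife
from psfmkit.synthetic import SyntheticConfig, generate

# 20+20 synthetic profiles; positive class enriched in K, R, T columns
ds = generate(SyntheticConfig(n_pos=20, n_neg=20, length_range=(50, 90), seed=4))

model = ProfileSVM.from_dataset(ds, "dbt", D=4)          # 2000 features
gs = model.grid_search(c_grid=(0.125, 1.0, 8.0),
                       g_grid=(1e-4, 1e-3, 1e-2), folds=5, seed=4)
print("chosen c =", gs.c, " g =", gs.g, " CV accuracy =", gs.best_accuracy)

res = model.fit(c=gs.c, g=gs.g)
print(res.summary())

dw = res.discriminant_weights()
print("aggregated weight (K,K):", round(dw.bigram_weight("K", "K"), 3))
print("aggregated weight (D,D):", round(dw.bigram_weight("D", "D"), 3))

print(jackknife(ds, "dbt", 4, c=gs.c, g=gs.g).summary())
```

Output:

```
chosen c = 0.125  g = 0.001  CV accuracy = 1.0
Profile RBF-SVM results
========================================
Feature method:     dbt (D=4)
Features:           2000
Training samples:   40
Support vectors:    30
Cost c:             0.125
RBF gamma g:        0.001
Bias:               -0.306263
Sum of dual weights: 0.000e+00
Training accuracy:  1.0000
aggregated weight (K,K): 11.106
aggregated weight (D,D): -5.616
[jackknife] N=40 TP=20 TN=20 FP=0 FN=0  SN=1.0000 SP=1.0000 ACC=1.0000 MCC=1.0000 AUC=1.0000
```

The grid search settles on a smooth, strongly regularised machine (CV
accuracy 1.0 — the synthetic signal is deliberately strong); the positive
aggregated weight for the enriched (K,K) bigram and the negative weight for
the unenriched (D,D) bigram show the discriminant analysis recovering the
planted signal, and the leave-one-out run confirms perfect held-out
separation.

## Command line

```bash
psfmkit synth --out fx --n-pos 30 --n-neg 30 --seed 1
psfmkit extract --profiles fx --method dbt -D 4 --out features.tsv
psfmkit train --features features.tsv --labels fx/labels.tsv \
              --method dbt -D 4 --grid-search --seed 1 --out model.json
psfmkit predict --model model.json --features features.tsv
psfmkit evaluate --profiles fx --labels fx/labels.tsv --method dbt -D 4 \
                 --c 1 --g 0.001 --scheme kfold --k 5 --seed 1 \
                 --out report.json --roc-out roc.tsv
psfmkit analyze --model model.json --features features.tsv --out weights.json
```

`extract` also accepts PSI-BLAST ascii PSSM files (`*.pssm`, the weighted
observed percentages block is used) or a FASTA file with `--fasta`
(one-hot profiles, for profile-free experimentation).

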