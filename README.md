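# fragminer

Imbalance-aware binary classification of kinase-inhibitor fingerprints and
mining of the pharmacophoric fragments that drive the classification.

Small structure–activity datasets are typically imbalanced: far more potent
than non-potent compounds. Classifiers trained naively on such data learn to
predict "potent" for everything — sensitivity looks excellent while
specificity collapses. `fragminer` packages the standard workflow for this
setting, at desk scale and fully seeded:

1. **Potency labeling.** Compounds with pIC50 = −log10 IC50[M] ≥ 6.0
   (IC50 ≤ 1 μM) are labeled potent (P), the rest non-potent (N); the
   boundary counts potent.
2. **Training-set balancing** by SMOTE + Tomek links, implemented from
   scratch: the minority class is oversampled to parity with synthetic rows
   x_new = x_i + u·(x_nn − x_i), u ~ U(0,1), x_nn one of the k = 5 minority
   nearest neighbors (binarized at 0.5 so rows stay valid fingerprints);
   then every cross-class mutual-nearest-neighbor pair (Tomek link) is
   removed, cleaning the class boundary. Test sets are never balanced.
3. **A seven-algorithm grid** (SVM, LR, kNN, ANN, NB, RF with 20 trees and
   depth 15, DT) evaluated by pooled stratified 5-fold cross-validation —
   every compound predicted once, out of fold, into a single confusion
   table — and on a held-out 3:1 split, ranked by AUC then CA.
4. **The metric suite** computed exactly from confusion counts:
   SE = TP/(TP+FN), SP = TN/(TN+FP), CA = (TP+TN)/N,
   MCC = (TP·TN − FP·FN)/√((TN+FN)(TN+FP)(TP+FN)(TP+FP)),
   BA = (SE+SP)/2, and AUC as the Mann–Whitney concordance probability
   (ties ½). Degenerate margins yield an explicit undefined marker,
   rendered `-`.
5. **Fragment mining.** Each fingerprint bit is scored by base-2 information
   gain, IG = H(class) − H(class | bit), and by the class-frequency ratio
   freq_I = (N_fragment,I · N_total)/(N_fragment,total · N_I); freq_P > 1
   flags a privileged substructure of the potent class.

A synthetic-data module generates datasets with the statistical structure
the analysis assumes (exact class counts, class-conditionally enriched bits,
constant bits, correlated bit pairs, truncated-normal pIC50 values), so the
whole pipeline runs and is tested without any external download.

## Worked example

Run the end-to-end pipeline on the default simulated dataset
(117 compounds, 89 P / 28 N, 881 bits):

```bash
fragminer run --seed 1 --out demo_run
```

Top of `demo_run/ranked_models.csv` (imbalanced training):

```
Split,Model,AUC,CA,MCC,TP,TN,FP,FN,SE,SP,BA
test,SimFP-LR,0.890,0.759,-,22,0,7,0,1.000,0.000,0.500
test,SimFP-SVM,0.857,0.759,-,22,0,7,0,1.000,0.000,0.500
```

Every non-potent test compound is misclassified (SP = 0.000, MCC
undefined): the majority class has swallowed the decision rule. Rerunning
with `balance: true` in the config applies SMOTE + Tomek to the training
set first:

```
Split,Model,AUC,CA,MCC,TP,TN,FP,FN,SE,SP,BA
cv_train,SimFP-RF,0.945,0.917,0.833,60,61,5,6,0.909,0.924,0.917
cv_train,SimFP-SVM,0.941,0.962,0.927,66,61,5,0,1.000,0.924,0.962
```

Training-set specificity recovers from 0.000 to ≈ 0.92 at essentially
unchanged sensitivity — the signature benefit of hybrid balancing (see
`docs/methods.md` for why the default balance-before-CV protocol also
inflates these CV numbers, and for the sounder `balance_within_folds`
alternative).

The fragment table (`demo_run/fragments.csv`) ranks the planted enriched
bits first and prints frequencies in `value (count)` style:

```
Fingerprint,IG,FP,FN,Polarity
PubchemFP691,0.134,1.248 (38),0.210 (2),positive
PubchemFP703,0.127,1.246 (37),0.215 (2),positive
```

IG = 0.134 bits means knowing this substructure's presence removes 0.134
bits of uncertainty about the potency class; freq_P = 1.248 > 1 means the
fragment occurs 1.25× more often among potent compounds than its overall
rate — a privileged substructure candidate.

Each stage is also available separately: `fragminer simulate | label |
split | balance | train-eval | mine | chemspace | report` (see `--help`).

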