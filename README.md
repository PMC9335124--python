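# pepbinder

Machine-learning discovery of target-binding peptides from phage-display
deep sequencing.

Random peptide libraries (e.g. 12-mer M13 display libraries) panned
against a protein target and read out by deep sequencing yield thousands
of candidate sequences, most of which are selection artifacts. `pepbinder`
implements the full computational path from raw selection reads to a
trained binder classifier:

1. **Enrichment calling** — per-sample read counts are normalized to
   parts-per-million (ppm); a peptide is called target-enriched when its
   target/control abundance ratio is `R >= 2` with a one-tailed
   unequal-variance (Welch) t-test `p <= 0.05` against *every* control
   selection arm (naive library R0, round-1 pool R1, bead-only and
   unrelated-antibody round-2 controls). Hits can be clustered on a
   BLOSUM62-profile embedding.
2. **Dataset preparation** — CD-HIT-style greedy redundancy removal at
   0.8 identity, screening against a local table of target-unrelated
   peptides (flagged when recovered by >= 4 entirely different targets),
   and balanced pairing of the positives with ten disjoint equal-size
   negative samples.
3. **Sequence encoding** — each peptide becomes a 519-dimensional vector:
   amino-acid composition AAC (20) | dipeptide composition DPC (400) |
   Chou's pseudo amino-acid composition PseAAC with λ = 4, ω = 0.4 (24) |
   composition of k-spaced amino-acid group pairs CKSAAGP, k = 0,1,2 (75).
4. **Feature selection** — filter scoring (Pearson |r| by default; also
   chi-square, information gain, F-score, mutual information), top-160
   selection, MinMax scaling to [0, 1].
5. **Ensemble classification** — one RBF-kernel SVM per balanced
   sub-dataset with grid-searched (c, γ) over the canonical LIBSVM grid
   and Platt-scaled probabilities; the ensemble averages the ten submodel
   probabilities and calls a binder when the mean is at or above the
   threshold `tp` (default 0.5; 0.55 is the recommended operating point).

The estimators follow scikit-learn conventions (`fit` / `transform` /
`predict_proba`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn pipelines and model selection.

## Worked example

```python
import numpy as np
from pepbinder.synthetic import gen_benchmark
from pepbinder.datasets import build_sub_datasets
from pepbinder.ensemble import train_ensemble, predict_peptides
from pepbinder.metrics import mean_report

# a motif-positive vs background benchmark in the canonical 80/800 shape
peps = gen_benchmark(n_pos=80, n_neg=800, separation=1.0, seed=1)
pos = [p for p in peps if p.label == "positive"]
neg = [p for p in peps if p.label == "negative"]

subs = build_sub_datasets(pos, neg, n_pairs=10, seed=1)   # ten 80+80 pairings
ens = train_ensemble(subs, seed=1)                        # ten RBF-SVM submodels
print({k: round(v, 4) for k, v in mean_report(ens.cv_report()).items()})

preds = predict_peptides(ens, pos[:3], tp=0.55)
for p in preds:
    print(p.seq, round(p.prob, 3), p.votes, p.label)
```

Output:

```
{'Sn': 0.9975, 'Sp': 0.9662, 'Pr': 0.9689, 'F1': 0.9825, 'Acc': 0.9819, 'MCC': 0.9651, 'AUROC': 0.9984, 'AUPRC': 0.998}
WDHCYRPTDFFM 0.994 10 binder
WTHTYHPPDDFE 0.998 10 binder
WCHGYFPDDSFD 0.996 10 binder
```

The first line is the fold-averaged fivefold cross-validation report over
the ten submodels (sensitivity, specificity, precision, F1, accuracy,
Matthews correlation, AUROC, AUPRC). Each prediction line shows the mean
ensemble probability, the number of submodels voting "binder" at the
threshold, and the final call.

The same workflow is available from the shell:

```bash
pepbinder simulate --out sim --seed 1
pepbinder enrich   --counts sim/counts.tsv --samples sim/samples.tsv --out enr
pepbinder prep     --positives pos.tsv --negatives neg.tsv --out prep
pepbinder train    --sub-datasets prep/sub_datasets.tsv --out model
pepbinder predict  --model model/model.bundle --in peptides.fasta --out pred.tsv --tp 0.55
pepbinder eval     --pred pred.tsv --truth truth.tsv
```

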