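# hazardcp

Conformal prediction of CLP/GHS hazard-statement (H-statement) classes from
SMILES strings, with class-wise error control.

Under the EU CLP regulation every marketed substance must carry hazard
statements (H301 "toxic if swallowed", H400 "very toxic to aquatic life",
...). For novel chemicals without adequate test data, in-silico models can
propose these classifications — but a regulatory setting needs predictions
with a stated, controlled error rate, not bare point estimates. `hazardcp`
implements a pipeline for exactly that use case: binary classification of
one H-statement group at a time (hazard-labelled vs conclusively
not-labelled), wrapped in Mondrian inductive conformal prediction so the
per-class error rate is bounded by a user-chosen significance level.

The package is aimed at computational toxicologists and cheminformaticians
who want calibrated hazard classifiers, and at method developers who want a
fully synthetic, reproducible test bed for conformal pipelines on
SMILES-like data.

## The method

**Featurization.** SMILES strings are mapped to fixed-length count vectors
by dictionary-based N-gram hashing: each character has a 3-digit code
(`'a'`→101 ... `'|'`→177); a window of *n* consecutive characters is
concatenated into one decimal integer and reduced modulo the hash length
*h*. For the string `abcdag` with *n* = 4, the windows `abcd`, `bcda`,
`cdag` encode to 101102103104, 102103104101, 103104101107 and (mod 1024)
increment positions 576, 613, 755. Because every SMILES symbol is covered,
salts, counter-ions and metals featurize without any structure stripping.
Variants apply the same k-merization to pair-encoded token streams, to a
parenthesis-free (DeepSMILES-style) rewriting, and to a bracket-token
(SELFIES-style) encoding; Morgan count fingerprints and binary SMILES
extended-connectivity fingerprints complete the descriptor set.

**Conformal prediction.** A random forest is trained on a proper training
set; a held-out calibration set (20% of each fold's training portion) is
scored with the nonconformity function α = 1 − P̂(true class), kept
separately per class (Mondrian). For a test compound the p-value of class
*c* is

    p_c = ( #{ α_i in cal_c : α_i ≥ α } + 1 ) / ( |cal_c| + 1 )

and the prediction set at significance ε is {c : p_c > ε} — one of
{active}, {inactive}, {both}, {empty}. Under exchangeability the per-class
error rate (sets missing the true class) is at most ε. *Validity* is the
fraction of sets containing the true class; *efficiency* the fraction of
single-label sets.

**Consensus.** Per-descriptor models are combined either by the median
p-value per compound and class (`consensus_pvals_*`) or by majority vote on
the prediction sets (`consensus_cls_*`), ties resolved in the fixed order
single-active > single-inactive > both > empty.

**Synthetic data.** Regulatory datasets cannot be redistributed, so the
package ships a generator: molecules assembled from a fragment grammar,
labels driven by planted toxicophore motifs (nitro, acyl chloride, nitrile,
epoxide) plus label noise, optional counter-ion fragments, and class
imbalance profiles mirroring the ten H-statement groups (≈3% to ≈49%
actives).

## Worked example

```python
import numpy as np
from hazardcp import (SyntheticConfig, generate_dataset,
                      run_cv_experiment, encode_ngram_counts)
from hazardcp.consensus import ConsensusConfig

# the N-gram worked example: three windows of 'abcdag' land at 576/613/755
vec = encode_ngram_counts("abcdag", n=4, hash_len=1024)
print(np.flatnonzero(vec))          # -> [576 613 755]

records, truth = generate_dataset(SyntheticConfig(n_compounds=2000, seed=7))
cv = run_cv_experiment(
    records,
    ["ngram_4_hashed_1024", "ngram_6_hashed_64", "ngramsPE"],
    epsilons=(0.1, 0.2, 0.3),
    consensus_configs=[ConsensusConfig(mode="cls", model_set="all")],
    k=10, seed=7,
)
print(cv.summary(0.2))
```

prints

```
10-fold CV conformal prediction report (epsilon=0.2)
==============================================================================
model                        val_act val_ina eff_act eff_ina      BA     MCC
------------------------------------------------------------------------------
ngram_4_hashed_1024            0.806   0.811   0.829   0.625   0.732   0.463
ngram_6_hashed_64              0.805   0.826   0.736   0.533   0.704   0.408
ngramsPE                       0.795   0.815   0.823   0.604   0.722   0.443
consensus_cls_all              0.812   0.812   0.819   0.601   0.729   0.457
```

Read it as: at significance ε = 0.2 every model's validity is ≈ 0.8 for
both classes — the conformal guarantee (error ≤ 20% per class) holds; the
4-gram/1024 model gives a single-label answer for 83% of true actives and
63% of true inactives; balanced accuracy on those single-label calls is
0.73 under the generator's 20% label noise. The consensus vote matches or
slightly improves the best single descriptor.

The same pipeline is available from the shell:

```
hazardcp synth --n 2000 --seed 7 --out data.csv
hazardcp featurize --spec ngram_4_hashed_1024 --in data.csv --out X.csv
hazardcp train --features X.csv --seed 7 --out model.joblib
hazardcp predict --model model.joblib --features X.csv --significance 0.2 --out preds.csv
hazardcp evaluate --config experiment.yaml --out report/
```

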