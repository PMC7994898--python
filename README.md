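# hlrr — classification from block-wise missing multimodal data

`hlrr` implements a hypergraph-Laplacian regularized low-rank representation
pipeline for classifying subjects from multimodal feature tables in which
whole modality blocks are missing — the situation typical of multimodal
dementia cohorts, where every subject may have structural MRI features but
only about half have PET or CSF measurements, and a modality is either
present in full or absent entirely for a given subject.

Instead of discarding incomplete subjects or imputing the missing blocks,
the pipeline:

1. **Groups** subjects by their exact modality-availability pattern (three
   modalities give up to seven groups), so every group has a complete data
   matrix `X_m` (features × subjects);
2. **Learns a denoised representation** per group by solving

   ```
   min_{Z,E}  ||Z||_* + λ||Z||_1 + β tr(Z L Z^T) + γ||E||_1
   s.t.       X = X Z + E,   Z ≥ 0
   ```

   where `||Z||_*` (nuclear norm) drives `Z` toward a low-rank
   representation of each subject in terms of the others, `E` collects
   sparse gross errors, and `L` is the normalized Laplacian of a
   *hypergraph* over the group's subjects built from their mutual sparse
   codes — its quadratic form ties together the representations of
   subjects that co-occur in a hyperedge, capturing higher-order (beyond
   pairwise) relations.  The program is solved by linearized ADM with an
   adaptive penalty: singular value thresholding for the `Z`-step,
   elementwise shrinkage for `E` and the nonnegative sparse copy `J`,
   multiplier updates and geometric penalty growth;
3. **Classifies** with one linear SVM per group, trained on the columns of
   the learned representation, and combines members by majority vote —
   a test subject is scored by every member whose modality pattern it
   covers, `f(x) = sign(mean of member votes)`.

A synthetic-data generator reproduces the assumed data regime (class-wise
low-rank subspaces with latent factors partially shared across modalities,
dense noise, sparse gross corruption, seven-pattern block-wise
missingness) so that every stage is testable without any cohort download,
and an evaluation module supplies the seven classification metrics (ACC,
SEN, SPE, BAC, PPV, NPV, rank-based AUC), nested stratified
cross-validation with grid search, zero/KNN imputation baselines and
Friedman/Nemenyi comparison statistics.

## Worked example

```python
import numpy as np
from hlrr import HLRR
from hlrr.synthetic import scaled_down_config, generate

cfg = scaled_down_config(seed=0)          # 80 subjects, dims (20, 20, 3)
ds, truth = generate(cfg)

rng = np.random.default_rng(0)
idx = rng.permutation(ds.n_subjects)
train, test = idx[:64], idx[64:]

model = HLRR(ds.subset(train), positive_label="case", negative_label="control")
results = model.fit()
print(results.summary())

labels, scores, n_votes = results.predict(ds.subset(test))
acc = np.mean(labels == ds.labels[test])
print(f"\nheld-out accuracy: {acc:.3f} on {len(test)} subjects")
```

prints

```
Hypergraph-regularized low-rank representation ensemble
========================================================
Task: case (+1) vs control (-1)
Subjects: 64   Groups: 4   Ensemble members: 4
Penalties: lam=0.05  beta=2.0  gamma=5.0
Mode: transductive   All groups converged: False

    pattern  n_subjects  dim  iterations  converged  residual_rel  rank_Z  nnz_frac_J
MRI+PET+CSF          13   43         278       True  1.869063e-07      13    0.786982
    MRI+PET          18   40         500      False  0.000000e+00      18    0.996914
    MRI+CSF          12   23         500      False  6.101488e-08      12    0.888889
        MRI          21   20         500      False  1.131648e-08      21    0.979592

held-out accuracy: 0.750 on 16 subjects
```

The diagnostics table shows one row per modality-availability group: its
sample count, concatenated feature dimension, solver iterations, whether
both stopping tests passed, the final relative reconstruction residual
`||X - XZ - E||_F / ||X||_F`, the numerical rank of the learned `Z` and
the density of the nonnegative copy `J`.  `converged=False` here means the
conservative iterate-change test was still above tolerance at the
iteration cap — the feasibility residuals (1e-8 to 1e-16) show the
representations themselves are essentially exact.  Each test subject was
scored by the ensemble members whose modality patterns it covers and
labelled by their majority vote.

A `hlrr` command-line tool wraps the same functionality
(`hlrr simulate`, `hlrr fit`, `hlrr predict`, `hlrr evaluate`).

## Layout

```
src/hlrr/
  datamodel.py    feature tables, availability masks, group partition
  hypergraph.py   sparse codes, incidence, degrees, hyper-Laplacian
  solver.py       proximal operators and the linearized-ADM solver
  classifier.py   per-group SVMs, majority vote, transductive prediction
  synthetic.py    block-wise missing multimodal data generator
  evaluation.py   metrics, nested CV, imputation baselines, Friedman/Nemenyi
  model.py        HLRR / HLRRResults facade
  cli.py          command-line entry points
```
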