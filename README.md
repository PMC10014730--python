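# atacml

Cell-type classification and marker discovery from **binary single-cell
chromatin-accessibility matrices**.

Single-cell ATAC-seq atlases represent each cell by the *existence status*
of every gene — 1 if at least one accessible chromatin segment maps to the
gene in that cell, 0 otherwise — giving a sparse binary cells × genes
matrix with tens of cell types and strong class imbalance. `atacml` is a
reusable, tested implementation of a two-pass machine-learning protocol
for such data, aimed at computational biologists who want both an accurate
cell-type classifier and *interpretable* per-type accessibility signatures:

1. **Boruta screening** — all-relevant feature selection: every gene
   competes against a permuted "shadow" copy of itself across repeated
   random-forest fits; a binomial test on hit counts confirms or rejects it.
2. **Monte Carlo feature selection (MCFS)** — genes are ranked by relative
   importance accumulated over *s·t* decision trees grown on random
   *m*-feature projections:
   `RI_g = Σ_τ (wAcc_τ)^u · Σ_{nodes n of τ splitting on g} IG(n) · (samples(n)/samples(root))^v`.
3. **Incremental feature selection (IFS)** — nested prefix subsets of the
   ranking (step 5) are each evaluated by stratified 10-fold
   cross-validation (optionally SMOTE-balanced inside training folds) with
   decision-tree and random-forest classifiers; performance is the
   multiclass Matthews correlation coefficient
   `MCC = cov(X,Y) / √(cov(X,X)·cov(Y,Y))` over one-hot prediction/truth
   matrices (Gorodkin's R_K).
4. **Rule extraction** — the optimal decision tree is unrolled into
   if–then rules (one per leaf, with support and purity); on binary
   features every threshold is 0.5, so rules read "gene accessible /
   inaccessible".
5. **Autoencoder + T-split re-ranking (pass 2)** — the optimal RF features
   are reconstructed by a tied-weight autoencoder
   (`y = f(Wx + b)`, `z = g(Wᵀy + b′)`, trained by SGD on the
   reconstruction loss), the reconstructed features are re-ranked by
   LightGBM split counts (`T-Split = Σ_i Split_i` over all boosted trees),
   and a step-1 IFS pass yields the final, smaller and usually better
   classifier.

A synthetic-data module generates imbalanced multiclass binary matrices
with planted class-specific marker genes, providing ground truth for every
stage.

## Worked example

Run the full two-pass protocol on the built-in 8-class benchmark
(150 cells per class, 500 genes, 5 disjoint marker genes per class,
marker accessibility 0.9 vs background 0.1):

```python
from atacml import benchmark_config, report, run_all

manifest = run_all(benchmark_config(seed=1, out_dir="scratch/demo"))
print(report(manifest).to_string(index=False))
```

```
       classifier  n_features      acc      mcc
       optimal DT          30 0.858333 0.838198
pass-1 optimal RF          40 0.993333 0.992390
pass-2 optimal RF          39 0.989167 0.987625
```

Reading the table: Boruta screens the 500 genes down to the confirmed set
(essentially the 40 planted markers), MCFS ranks them, and the pass-1 IFS
curve peaks at 40 features with a cross-validated MCC of 0.992 for the
random forest; the single decision tree is weaker (MCC 0.838 at 30
features) but yields human-readable rules
(`rules/rules.tsv`, e.g. `IF g0005 > 0.5 AND g0012 <= 0.5 THEN class01`).
The pass-2 autoencoder/LightGBM re-ranking reaches comparable accuracy
with no more features. Every stage writes its artifacts (TSV/JSON, with
content hashes in `manifest.json`) under the output directory, and
rerunning the same config reproduces the hashes bit-for-bit.

The same protocol is scriptable from the shell:

```bash
atacml simulate --config syn.yaml --out data/
atacml boruta --data data/ --out boruta/ --seed 1
atacml mcfs --data data/ --out ranking.tsv --seed 1
atacml ifs --data data/ --ranking ranking.tsv --classifier rf --step 5 --out curve.tsv
atacml run-all --config pipeline.yaml
```

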