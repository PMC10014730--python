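# Methods

## Data model

The unit of analysis is a cells × genes matrix of gene *existence status*:
entry (i, j) is 1 when at least one accessible chromatin segment maps to
gene j in cell i, else 0, together with a per-cell type label. The package
takes this gene-level binary matrix as given; collapsing segments to genes
and all upstream read processing are out of scope. Three matrix kinds are
distinguished by `AccessibilityDataset.kind`: `binary` (raw stage inputs,
strictly {0,1}; the reader rejects anything else in strict mode),
`fractional` (SMOTE-interpolated rows, values in [0,1]) and `real`
(autoencoder reconstructions, unbounded). On-disk representation is Matrix
Market coordinate format (1-based indices per the MTX standard, converted
to 0-based internally), a headered TSV of cell metadata and a plain gene
list; a transpose flag accepts gene-row matrices.

## Synthetic generator

The generator plants disjoint marker-gene sets: cell i of class c draws
its class's `markers_per_class` genes Bernoulli(`p_on`) and every other
gene Bernoulli(`p_bg`), after which each bit is flipped independently with
probability `flip_rate`. Symmetric bit-flip noise is the natural noise
model for binary features: it preserves the Bernoulli structure with
shifted means p(1−f) + (1−p)f. Class sizes can be supplied directly or
drawn log-uniformly between a maximum and maximum/ratio
(`imbalanced_sizes`), mimicking the long-tailed per-type counts of real
cell atlases, where up to a 70-fold spread between the largest and
smallest type occurs.

The reference benchmark used throughout tests and the acceptance script
is 8 classes × 150 cells, 500 genes, 5 markers/class, `p_on` 0.9, `p_bg`
0.1, no flips. These sizes keep every stage to seconds or a few minutes on
one CPU while leaving the marker-recovery problem non-trivial (markers are
noisy, 460 genes are pure background). What the generator does **not**
emulate: correlated genes, overlapping marker sets, batch effects, or
fragment-count structure. Passing tests therefore demonstrate that the
machinery recovers planted independent signals under Bernoulli noise — not
performance on real atlases, where feature correlation and label noise are
substantial.

## Boruta screening

Per iteration: every still-active column is copied and row-permuted (a
"shadow" whose label association is destroyed but whose marginal
distribution is preserved), a random forest is fitted on
[originals | shadows], and each original scoring above the *maximum*
shadow importance records a hit. Hits follow Binomial(iterations, 1/2)
under the null; a two-sided binomial test with Bonferroni correction over
the currently undecided features confirms (significantly many hits) or
rejects (significantly few). Rejected columns leave the design matrix;
confirmed ones stay so importances remain comparable. After `max_iter`
(default 100) survivors are tentative and are excluded downstream unless
`keep_tentative` is set. Importance is the backend's impurity-based
feature importance; forest size defaults to 100 trees. The z-score
formulation sometimes described for this family of methods is treated as
descriptive; the hit-count binomial test is the implemented decision rule.

## Monte Carlo feature selection

`s` random projections of `m` features are drawn (default
m = max(⌈0.05·d⌉, 2)); per projection `t` CART trees are grown on fresh
`train_fraction` = 0.66 splits. A tree contributes
(wAcc)^u · IG(node) · (n_node/n_root)^v for every internal node, where IG
is the Gini impurity decrease and wAcc the unweighted mean of per-class
recall on the tree's held-out samples — held-out rather than training so
overfit trees are not rewarded, unweighted so rare classes count equally.
Defaults u = v = 1, t = 5, s = 200 follow the conventional defaults of the
reference MCFS program; all are configurable. Ranking ties break
lexicographically by feature id, making rankings reproducible.

## Incremental feature selection

Prefix subsets of sizes step, 2·step, …, ⌊d/step⌋·step (floor convention —
a trailing remainder shorter than one step is dropped; 3,897 features at
step 5 give exactly 779 subsets) are each scored by stratified k-fold CV
(default 10). Fold assignment is deterministic per-class round-robin after
a seeded shuffle, so classes smaller than the fold count simply appear in
fewer folds; one partition is shared across all subset sizes of a curve so
the curve reflects feature-set changes only. Predictions are pooled across
folds before computing MCC/ACC/per-class accuracy. The optimal subset
maximizes MCC, ties broken toward fewer features (parsimony). Backends:
CART with Gini for the tree, 100-tree bagged CART for the forest.

## Class balancing

SMOTE builds each synthetic minority row as x + u·(x_nbr − x), u ~ U[0,1],
with x_nbr one of the k = 5 nearest same-class neighbours under Euclidean
distance (the standard SMOTE choice, meaningful on binary/fractional
features). Every class is raised to the largest class's count; originals
are never modified; a singleton class is an error, and k is clipped to
class_size − 1 with a warning for very small classes. By default
balancing is applied *inside training folds only*, so no synthetic sample
leaks into a test fold; a global mode (balance once, before CV) is
available for comparison with protocols that describe balancing the whole
dataset. The benchmark classes are balanced, so the pipeline defaults run
without SMOTE; its contract is exercised directly by dedicated tests.

## Performance measures

Multiclass MCC is computed from the one-hot covariance definition and
equals Gorodkin's R_K; when a variance term vanishes (constant prediction
or single-class truth) the score is defined as 0, the "no better than
random" reading that also avoids division by zero. ACC is the plain
fraction correct and equals the class-size-weighted mean of per-class
accuracies; per-class accuracy (recall) is reported only for classes
present in the truth.

## Rule extraction

One rule per leaf, conditions read root-to-leaf. Conditions repeating a
feature are merged to the tightest interval for display; the raw path is
retained and is what rule application evaluates, so the rules of one tree
are mutually exclusive and exhaustive and reproduce the tree's predictions
exactly. Leaf-majority ties resolve by the backend's argmax convention
(first class in the fitted class order); any other choice would break the
rules ≡ tree equivalence that the module is built around. On binary inputs
CART always splits at 0.5, so rules read as accessible (> 0.5) versus
inaccessible (≤ 0.5).

## Autoencoder and T-split re-ranking

The autoencoder is tied-weight: encoder y = f(Wx + b), decoder
z = g(Wᵀy + b′); defaults are a logistic encoder, identity decoder,
embedding width 64 (clipped to the input width when fewer pass-1 features
exist), squared-error loss (absolute error available — the loss family is
configurable because either is conventional), minibatch SGD with momentum
0.9, learning rate 0.05, 200 epochs. With linear activations and
embedding width ≥ the data rank the model can reach the PCA residual,
which the tests use as a closed-form convergence oracle. The
*reconstruction* z — same dimensionality as the input, so columns map
one-to-one back to genes — is what is re-ranked; ranking the embedding
columns y instead is possible in principle but would break the gene-level
interpretation of the final feature list, which is the point of the
protocol. T-split ranking fits a LightGBM multiclass ensemble
(100 rounds × one tree per class, ≤31 leaves, learning rate 0.1,
`min_child_samples` lowered to 5 so small datasets still grow trees,
deterministic single-threaded mode) and scores each feature by its total
split count across all trees. Pass-2 IFS runs at step 1 over the
re-ranked reconstructed features; the final bundle stores the autoencoder
so new cells are transformed before prediction.

## Orchestration and reproducibility

`run_all` executes data → Boruta → MCFS → IFS (DT and RF) → rules (from
the optimal DT) → re-ranking pass (from the optimal RF features) →
report. Each stage's seed is the first 4 bytes of
SHA-256("global_seed:stage") reduced mod 2³¹, so stages never share
random streams. Artifacts are plain TSV/JSON; the manifest records a
SHA-256 per artifact, and rerunning a config reproduces every hash (the
resolved config is persisted without the output path so runs in different
directories compare equal). All stochastic components — generator, shadow
permutations, forests, projections, fold shuffles, SMOTE, SGD, LightGBM —
consume explicit seeds; LightGBM runs in deterministic single-thread mode.

## Numerical and degenerate-input choices

Fractional matrices are written with 17 significant digits so round trips
are exact to ≤1e-12. Gini gain is computed as
impurity(node) − weighted mean of child impurities from the fitted tree's
arrays. Zero-variance MCC → 0 (above). Empty trees yield empty
contribution maps; an all-constant feature can never beat its shadow and
is rejected by screening. `build_subsets` requires a non-empty ranking and
step ≥ 1.

## Known limitations

Boruta with the plain Bonferroni correction is conservative; on small
noisy datasets informative features can end tentative rather than
confirmed. The MCFS wAcc estimate is noisy for classes with very few
held-out samples. The SMOTE neighbour search is O(n²) per class, fine for
desk-scale class sizes but not for atlas-scale ones. The autoencoder is a
single hidden layer by design (the tied-weight formulation); it is not a
general deep AE. Runtime of a full benchmark run is about three minutes
on one CPU; the dominant cost is cross-validated forest fitting in the
two IFS passes.
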