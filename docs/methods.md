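# Methods

## Model

The classifier is a redundant structured higher-order factorization machine
(RHOFM): an order-`m` factorization machine on the concatenation of an item
and a user feature vector in which (i) all interaction orders share one
latent dimension `d` and one scalar weight per order, and (ii) every latent
row is generated from the corresponding entity's features by a shared
structure function `s_W`. Only the linear structure `s_W(x) = xW` is
trainable here (non-linear structures are supported at scoring time through
a user-supplied callable). Two algebraic forms are implemented:

* the **factored** form — linear term on the two entity embeddings,
  interaction terms as degree-`t` ANOVA kernels over value-weighted feature
  embeddings, computed per latent dimension by the elementary-symmetric-
  polynomial recursion in `O(q·t)`. This is the differentiable form used in
  training and prediction;
* the **exact** definitional form, in which the weights are first
  re-estimated from the pair at hand by a ridge least-squares fit of
  `s_W` on the 2×F design matrix of the two feature vectors (pseudo-inverse,
  so ridge 0 is legal). It is kept for validation: with a linear structure
  and ridge 0 the linear terms of the two forms agree exactly (projection
  identity), and the interaction terms agree whenever the rows of `W` lie in
  the span of the two inputs. The printed shape of that design matrix in the
  source description is F×2, which makes the least-squares problem ill-posed;
  we use the 2×F reading, the only one under which the estimator is defined.

Interpretable mode fixes the mixing weights at one (`ω¹ = 1_d`,
`ω^{2:m} = 1`), under which the intrinsic importance of feature `f` is the
row sum `Σ_k W_{f,k}` and the attribution for an entity is that row sum
scaled by its feature value. Free mixing weights are available behind a
flag, with the caveat that the importance read-out then loses its premise
(a warning is raised).

Missing feature values are represented as NaN end to end and zero-imputed
at every scoring boundary ("padding with zeroes"), never in storage.

## Joint training

The recommendation problem is reduced to knowledge-graph completion on a
nine-relation graph over items, users, features and optional prior-only
nodes: `prior` edges, signed association edges taken from the nonzero cells
of `A`, `item-sim`/`user-sim` edges for cosine similarity strictly above
`τ` (computed on zero-imputed columns; stored once per unordered pair, no
self-loops — duplicates would only double-count in the loss), and signed
entity–feature edges from the signs of the feature tables (missing entries
produce no edge). Cosine similarity is the default `sim`; it is scale-free
and lands in [-1, 1] as required.

Signed edges are scored by ±RHOFM; all other relations by MuRE with
embeddings `s_W(x)` (features map to indicator vectors, so their embeddings
are rows of `W`). The loss is the soft margin ranking loss with margin 1
against one uniform head corruption per positive, resampled each epoch,
rejected while the corruption exists in the graph, and drawn within the
head's partition. As printed, the loss orientation would *penalise*
high-scoring true triplets, contradicting the accompanying text ("edge
score to be maximized for present triplets"); the standard orientation
(margin − true + corrupted) is implemented, the printed one kept behind
`strict_paper_sign=True`.

Optimisation is minibatch Adam with fully analytic gradients (closed-form
for both score families; the general-order interaction gradient uses a
prefix/suffix elementary-symmetric-polynomial table; both are verified
against finite differences in the tests). Defaults: learning rate 5e-3,
40 epochs, batch 512, parameters initialised i.i.d. N(0, 0.1²), relation
matrices at the identity, biases at zero. These settings are free design
choices (the reference training configuration is not public); they were
chosen so the loss visibly plateaus on the package's own convergence and
separability checks at the default problem sizes, and every one of them is
a keyword argument. The train/test protocol splits the *nonzero* cells of
`A` uniformly (default 80/20) per seed; the graph is built from training
cells only. Given a seed, fitting and prediction are bit-reproducible.

The parameter count of the RHOFM follows the component shapes of its
definition: `1 + d + (m−1) + F·d = m + (F+1)d` scalars. A sometimes-quoted
closed form adds one more (it matches only if the ridge level is counted as
a parameter); the structural count is authoritative here.

## Synthetic data

The generator emulates the reference study conditions: item and user
features i.i.d. standard normal (`F=10`, `n_i=n_u=173` by default), a
ground-truth `W* ∈ R^{F×d}` (`d=2`), also standard normal — the
distribution of `W*` is not specified by the source; any continuous choice
works for the rank-based importance evaluation. Pair scores come from a
logistic generating model: first-order `σ(Σ_k((x^i+x^u)W*)_k)`, or
second-order — the interpretable-mode RHOFM with intercept 1 and `m=2`,
in its factored form (the same form the model trains). Labels are obtained
by symmetric quantile thresholding: the top `(1−s)/2` fraction of scores
becomes +1, the bottom the same fraction −1, the rest 0, hitting the target
sparsity `s` exactly up to one cell's rounding.

Missingness is Gaussian self-masking: an entry is hidden with probability
`K_f · exp(−(x−μ_f)²/(2σ_f²))` with per-row empirical moments and `K_f`
calibrated so the expected missing fraction equals the target rate (closed
form when the amplitude stays below 1, bisection with clipping otherwise;
constant rows fall back to uniform Bernoulli masking). The default rate is
0.1 (~10% missing). Scores are computed on the *complete* tables and the
masking is applied afterwards to the observed tables only: the hidden
values then act as irreducible noise, which is what makes the study's
reported spreads (NS-AUC well below 1 at AUC ≈ 0.99, high variance of the
importance correlation) attainable at all — masking before scoring leaves a
noise-free problem.

What the generator does *not* emulate: correlated or heavy-tailed features,
entity-specific missingness rates, label noise unrelated to the features,
and cold-start entity splits (splits are over cells, so every entity has
training signal). Passing tests on this data therefore demonstrate correct
mechanics and recoverability under the stated model, not performance on
real pharmacological data.

## Evaluation

Four metrics: Spearman's ρ between fitted and generating importance scores
(average ranks on ties; undefined-on-constant reported as NaN with a
warning); AUC on labelled cells (half credit on ties), computed on the
held-out nonzero cells — zeros are unknown, not negatives; NS-AUC — the
user-averaged fraction of strictly correctly ordered item pairs among pairs
whose ground-truth labels differ (ties earn nothing); and NDCG at the list
length with raw ±1 gains (so negative values are possible and meaningful).
The printed TPR/FPR normalisations accompanying the source's AUC definition
do not define the standard ROC rates; the standard ROC area is used.

The two ranking metrics are evaluated per user over every cell *outside
the training set*: held-out positives compete with the unknown cells,
which carry the middle label. This leave-out candidate list is the
standard recommender protocol; including training cells would reward pure
memorisation (free-embedding baselines reach NS-AUC ≈ 0.95 there), while
restricting to held-out labelled cells only degenerates to separating +1
from −1, which every competent model does perfectly.

## Ablations

`FM2` and `CrossFM2` are unstructured second-order FMs on the concatenated
2F input (CrossFM2 keeps only item×user interaction pairs), trained by
full-batch Adam on the logistic loss. The SELT arms learn embeddings
separately and freeze them: `SELT-PCAf` takes each feature's leading
principal-component coordinates (features as samples over entity columns);
`SELT-PCAiu` transforms entity vectors with a PCA fitted on entities as
samples — the features-as-samples transform cannot typecheck on length-F
entity vectors, so this is the only consistent reading; `SELT-KGE` trains
free (unstructured) MuRE embeddings on the same graph with an empty prior.
PCA signs are canonicalised (largest-|loading| positive).

The frozen embeddings enter an interpretable-mode RHOFM head: they
contribute a *fixed* offset `Σ_k(e_i+e_u)_k`, and only the intercept (plus
the single interaction weight, when feature embeddings make the order-2
kernel available) is fitted, by a binomial GLM with offset. A frozen
embedding whose orientation disagrees with the labels therefore cannot be
repaired — the failure mode that separates SELT from joint training.

The free-KGE arm is trained with plain SGD rather than Adam: the MuRE score
is invariant under a global rotation of all embeddings
(`e → Qe`, `e_r → Qe_r`, `R_r → QR_rQᵀ`), the Gaussian initialisation is
rotation-symmetric, and SGD commutes with this gauge, so the orientation in
which the embeddings come to rest is genuinely arbitrary. An adaptive
per-coordinate optimiser breaks the equivariance and was observed to park
the dominant (popularity) axis systematically along the all-ones direction,
which the fixed unit readout then silently exploits. Known limitation: under
the arbitrary gauge our SELT-KGE averages near chance on the ranking
metrics with large run-to-run spread, above the considerably lower value
the reference reports for its own pipeline; the qualitative ordering
(joint model above every SELT arm) is robust.

## Problem sizes and numerical choices

The repeated-split studies in the tests and the acceptance script use the
reference data scale (`F=10`, `d=2`, `n_i=n_u=173`) with 10 datasets × 10
splits per arm and ≥10 runs per robustness/ablation cell — the package's
scaled-down protocol; the reference runs 100 splits per dataset. Seeds for
datasets and splits derive from one base seed through `SeedSequence`, so
every table is reproducible from a single integer. Tolerances: kernel DP
vs. enumeration and gradient checks at 1e−12/1e−6; quantile label ties are
broken by stable sort order; degenerate inputs (constant rows, zero
vectors, single-class cells, exhausted corruption partitions) are either
handled by a documented fallback or rejected with a specific error, as
listed per function.
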