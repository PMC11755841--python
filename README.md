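# jeli

Interpretable collaborative filtering by jointly training a structured
factorization machine with knowledge-graph embeddings.

## The problem

Recommendation problems in drug repurposing ask for new item–user (drug–disease)
associations given a sparse association matrix `A ∈ {-1, 0, +1}^{n_i × n_u}`
(zeros are *unknown*, not negative) plus item and user feature tables
`S, P ∈ R^{F × n}` over a shared feature set (e.g. gene signatures), possibly
with missing values. In healthcare settings a prediction is only useful if it
comes with *feature attribution*: a per-feature score saying which genes drove
the call.

## The model

**RHOFM.** A redundant structured higher-order factorization machine of order
`m` and dimension `d` assumes every entity embedding is produced from its
feature vector by one shared structure function `s_W` (linear case
`s_W(x) = xW`, `W ∈ R^{F×d}`; the embedding of feature `f` itself is row
`W_f`). For `m = 2`:

```
score(x^i, x^u) = ω⁰ + ω¹ᵀ(s_W(x^i) + s_W(x^u))
                + ω² Σ_{f<f'} ⟨ x'_f s_W(x^{f%F}), x'_{f'} s_W(x^{f'%F}) ⟩
```

with `x'` the concatenation of the two feature vectors. Interaction terms are
degree-`t` ANOVA kernels, evaluated with the `O(q·t)` dynamic-programming
recursion. Sharing `W` across items, users, features and orders leaves only
`m + (F+1)d` scalars. In interpretable mode (`ω¹ = 1_d`, `ω² = 1`) the
intrinsic importance of feature `f` is the row sum `Σ_k W_{f,k}`, and the
attribution for an entity `x` is `x_f Σ_k W_{f,k}`.

**Joint training.** A nine-relation knowledge graph is built from the data:
signed association edges from `A`, cosine-similarity edges between items and
between users (threshold `τ`), signed entity–feature edges from the signs of
`S` and `P`, plus an optional prior edge list. Signed edges are scored by
±RHOFM; every other relation `r` by the MuRE interaction model

```
MuRE(e_h, e_r, e_t) = -‖R_r e_h − (e_t + e_r)‖² + b_h + b_t,   e = s_W(x)
```

All parameters — `θ = (ω⁰, ω¹, ω^{2:m}, W)`, per-relation `(R_r, e_r)`, and
per-entity biases — are fitted together by minimising the soft margin ranking
loss `Σ log(1 + exp(λ⁰ − score(true) + score(corrupted)))` (margin `λ⁰ = 1`,
one uniform head corruption per positive) with minibatch Adam and analytic
gradients. Prediction for any pair, including unseen entities (zero-padded
features), is `+1` iff `σ(RHOFM(x^i, x^u)) > 0.5`.

## Worked example

```python
from jeli import JELIModel, make_synthetic_dataset

ds = make_synthetic_dataset(F=10, d=2, n_i=173, n_u=173,
                            kind="first_order", sparsity=0.5, seed=7)
model = JELIModel.from_dataset(ds, dim=2, order=2)
res = model.fit(seed=1)
print(res.summary())
print(res.evaluate("test", s_true=ds.true_importance).to_dict())
```

prints (abridged):

```
              Joint embedding-classifier (JELI) results
========================================================================
items:    173   users:    173   features:    10   dim: 2
graph: 16780 triplets over 356 entities
train cells: 11971   test cells: 2993
epochs: 40   final mean pair loss: 0.8094
------------------------------------------------------------------------
feature importance (row sums of fitted W):
    f10      -0.8384
    f3       +0.3923
    f1       +0.3909
    ...
{'auc': 0.999, 'ns_auc': 0.941, 'ndcg': 0.821, 'spearman_rho': 0.952, ...}
```

The dataset generator drew a ground-truth `W*` whose row sums are the true
importance scores (here `f10` is the strongest, negative driver: true value
−1.909); the fitted row sums recover their ranking with Spearman ρ = 0.95,
while the held-out AUC (0.999) and the per-user leave-out ranking quality
(NS-AUC 0.941) measure predictive performance.

A command-line surface wraps the same pipeline:

```
jeli simulate -F 10 -d 2 --sparsity 0.5 --seed 0 --out run/data
jeli train run/data --dimension 2 --epochs 40 --seed 0 --out run/model
jeli importance run/model/model.npz
jeli evaluate run/data run/model/model.npz --test-cells run/model/test_cells.tsv
```

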