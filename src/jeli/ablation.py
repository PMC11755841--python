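"""Ablation baselines: unstructured FMs and separate embedding learning.

The within-family comparison arms are:

* ``FM2`` — plain second-order factorization machine on the concatenated
  item/user feature vector, logistic loss;
* ``CrossFM2`` — as FM2 but keeping only item-by-user interaction pairs;
* ``SELT-PCAf`` — feature embeddings from a PCA over features (samples =
  features, coordinates = entities), frozen, then the structured FM head
  is fitted on top;
* ``SELT-PCAiu`` — item/user embeddings from a PCA over entities, frozen,
  then a linear-in-embedding logistic head;
* ``SELT-KGE`` — free (unstructured) MuRE embeddings trained on the
  similarity knowledge graph, frozen, then a linear-in-embedding head;
* ``JELI`` — the jointly trained reference arm.

SELT = separate embedding learning and training: the embeddings never see
the classification loss, which is exactly the coupling the joint model is
meant to supply.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .datasets import make_synthetic_dataset
from .kg import build_knowledge_graph
from .metrics import evaluate_predictions
from .model import (
    JELIModel,
    _Adam,
    _EncodedGraph,
    _mure_backward,
    _mure_forward,
    train_test_split_cells,
)
from .rhofm import sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "AblationSpec",
    "selt_embeddings",
    "FixedEmbeddingClassifier",
    "train_fixed_embedding_classifier",
    "run_ablation_suite",
    "run_jeli_study",
]

VARIANTS = ("FM2", "CrossFM2", "SELT-PCAf", "SELT-PCAiu", "SELT-KGE", "JELI")


@dataclass
class AblationSpec:
    variants: tuple[str, ...] = VARIANTS
    dim: int = 2
    sparsities: tuple[float, ...] = (0.5, 0.65, 0.8)
    n_datasets: int = 5
    n_seeds: int = 10
    F: int = 10
    n_i: int = 173
    n_u: int = 173
    kind: str = "first_order"
    mask_rate: float = 0.1
    tau: float = 0.5
    base_seed: int = 0
    jeli_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown ablation variants: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# embedding learners


def _canonical_signs(coords: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Flip each principal component so its largest-|.| loading is positive."""
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return coords * flip[None, :]


def _train_free_kge(A, S, P, d, seed, tau=0.5, epochs=40, lr=5e-2,
                    batch_size=1024, margin=1.0, init_scale=0.1):
    """Unstructured MuRE embedding training on the similarity graph.

    Every entity gets a free d-dimensional embedding and every relation —
    including the signed association edges, since no classifier is
    attached here — its own (R_r, e_r). Margin ranking loss with one head
    corruption per positive, minimised by plain SGD: the MuRE score is
    invariant under a global rotation of all embeddings (e -> Qe,
    e_r -> Qe_r, R_r -> Q R_r Q^T), the Gaussian init is
    rotation-symmetric and SGD commutes with the gauge, so the
    orientation in which the embeddings come to rest is genuinely
    arbitrary — a property an adaptive per-coordinate optimiser would
    silently break.
    """
    kg = build_knowledge_graph(A, S, P, prior=None, tau=tau)
    enc = _EncodedGraph(kg, np.asarray(S, float), np.asarray(P, float))
    rng = np.random.default_rng(seed)
    rels = sorted({r for _, r, _ in kg.triplets})
    rel_id = {r: i for i, r in enumerate(rels)}
    params = {"E": rng.normal(0.0, init_scale, size=(enc.n_ent, d)),
              "b": np.zeros(enc.n_ent)}
    for r in rels:
        params[f"R:{r}"] = np.eye(d)
        params[f"e:{r}"] = rng.normal(0.0, init_scale, size=d)
    rel_of_triplet = np.array([rel_id[r] for _, r, _ in kg.triplets])
    for _ in range(epochs):
        perm = rng.permutation(len(enc.H))
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            neg, ok = enc.corrupt_heads(idx, rng)
            idx, neg = idx[ok], neg[ok]
            if len(idx) == 0:
                continue
            B = len(idx)
            H = np.concatenate([enc.H[idx], neg])
            T = np.concatenate([enc.T[idx], enc.T[idx]])
            Rids = np.concatenate([rel_of_triplet[idx], rel_of_triplet[idx]])
            scores = np.empty(2 * B)
            caches = {}
            for r in rels:
                sel = np.where(Rids == rel_id[r])[0]
                if not len(sel):
                    continue
                s, u = _mure_forward(params["E"][H[sel]], params["E"][T[sel]],
                                     params[f"R:{r}"], params[f"e:{r}"],
                                     params["b"][H[sel]], params["b"][T[sel]])
                scores[sel] = s
                caches[r] = (sel, u)
            g = sigmoid(margin - scores[:B] + scores[B:])
            w_pair = np.concatenate([-g, g])
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for r, (sel, u) in caches.items():
                w = w_pair[sel]
                dEh, dEt, der, dR = _mure_backward(w, u, params["E"][H[sel]],
                                                   params[f"R:{r}"])
                np.add.at(grads["E"], H[sel], dEh)
                np.add.at(grads["E"], T[sel], dEt)
                grads[f"e:{r}"] += der
                grads[f"R:{r}"] += dR
                np.add.at(grads["b"], H[sel], w)
                np.add.at(grads["b"], T[sel], w)
            scale = lr / max(len(idx), 1)
            for k, g in grads.items():
                params[k] -= scale * g
    n_i, n_u = A.shape
    return params["E"][:n_i], params["E"][n_i:n_i + n_u]


def selt_embeddings(S, P, A, variant: str, d: int, seed: int = 0,
                    tau: float = 0.5, **kge_kwargs) -> dict[str, np.ndarray]:
    """Learn frozen embeddings for one SELT variant.

    Returns ``{"features": (F, d)}`` for PCAf or ``{"items": (n_i, d),
    "users": (n_u, d)}`` for PCAiu/KGE.
    """
    S0 = np.nan_to_num(np.asarray(S, dtype=float))
    P0 = np.nan_to_num(np.asarray(P, dtype=float))
    if variant in ("PCAf", "SELT-PCAf"):
        data = np.hstack([S0, P0])  # (F, n_i + n_u), features as samples
        if d > min(data.shape):
            raise ValueError(f"d={d} exceeds the rank bound {min(data.shape)}")
        pca = PCA(n_components=d, svd_solver="full")
        coords = pca.fit_transform(data)
        return {"features": _canonical_signs(coords, pca.components_)}
    if variant in ("PCAiu", "SELT-PCAiu"):
        data = np.hstack([S0, P0]).T  # entities as samples of dimension F
        if d > min(data.shape):
            raise ValueError(f"d={d} exceeds the rank bound {min(data.shape)}")
        pca = PCA(n_components=d, svd_solver="full")
        pca.fit(data)
        items = _canonical_signs(pca.transform(S0.T), pca.components_)
        users = _canonical_signs(pca.transform(P0.T), pca.components_)
        return {"items": items, "users": users}
    if variant in ("KGE", "SELT-KGE"):
        items, users = _train_free_kge(np.asarray(A), S0, P0, d, seed,
                                       tau=tau, **kge_kwargs)
        return {"items": items, "users": users}
    raise ValueError(f"unknown SELT variant {variant!r}")


# ---------------------------------------------------------------------------
# classifier heads on frozen embeddings


class FixedEmbeddingClassifier:
    """Interpretable-mode RHOFM head over frozen embeddings.

    In interpretable mode the mixing weights are fixed at one (omega1 =
    1_d, omega2m = 1), so the frozen embeddings enter the score as a fixed
    offset ``sum_k (e_i + e_u)_k``; the head only fits the intercept
    omega0 and, when feature embeddings are available (PCAf) so the
    order-2 interaction kernel can be formed, one interaction weight. With
    entity-only embeddings (PCAiu, KGE) the interaction term is omitted
    entirely. If the frozen embeddings' orientation disagrees with the
    labels, the head cannot repair it — which is precisely what separates
    these ablations from the joint model.
    """

    def __init__(self, embeddings: dict[str, np.ndarray], S=None, P=None):
        self.embeddings = embeddings
        if "features" in embeddings:
            if S is None or P is None:
                raise ValueError("feature embeddings need the S and P tables")
            W = embeddings["features"]
            S0, P0 = np.nan_to_num(np.asarray(S, float)), np.nan_to_num(np.asarray(P, float))
            self._Zi, self._Zu = S0.T @ W, P0.T @ W
            self._Qi = ((S0.T**2) @ (W**2)).sum(axis=1)
            self._Qu = ((P0.T**2) @ (W**2)).sum(axis=1)
        else:
            self._Zi, self._Zu = embeddings["items"], embeddings["users"]
            self._Qi = self._Qu = None

    def _offset_and_k2(self, cells: np.ndarray):
        zi, zu = self._Zi[cells[:, 0]], self._Zu[cells[:, 1]]
        offset = (zi + zu).sum(axis=1)  # 1_d^T (e_i + e_u), fixed weights
        if self._Qi is None:
            return offset, None
        k2 = 0.5 * (((zi + zu) ** 2).sum(1) - self._Qi[cells[:, 0]] - self._Qu[cells[:, 1]])
        return offset, k2

    def fit(self, A, train_cells: np.ndarray) -> "FixedEmbeddingClassifier":
        y = np.asarray(A)[train_cells[:, 0], train_cells[:, 1]]
        if len(np.unique(y)) < 2:
            raise ValueError("training cells hold a single class")
        offset, k2 = self._offset_and_k2(np.asarray(train_cells))
        n = len(y)
        X = np.ones((n, 1)) if k2 is None else np.column_stack([np.ones(n), k2])
        glm = sm.GLM(y == 1, X, family=sm.families.Binomial(), offset=offset)
        self._coef = np.asarray(glm.fit().params, dtype=float)
        return self

    def predict_matrix(self) -> np.ndarray:
        """Raw decision scores for every (item, user) pair."""
        raw = (self._coef[0]
               + self._Zi.sum(1)[:, None] + self._Zu.sum(1)[None, :])
        if self._Qi is not None:
            w2 = self._coef[1]
            sq = ((self._Zi**2).sum(1)[:, None] + 2.0 * self._Zi @ self._Zu.T
                  + (self._Zu**2).sum(1)[None, :])
            raw = raw + 0.5 * w2 * (sq - self._Qi[:, None] - self._Qu[None, :])
        return raw


def train_fixed_embedding_classifier(embeddings, A, train_cells,
                                     S=None, P=None) -> FixedEmbeddingClassifier:
    """Fit the logistic head on frozen embeddings over the training cells."""
    return FixedEmbeddingClassifier(embeddings, S=S, P=P).fit(A, train_cells)


# ---------------------------------------------------------------------------
# unstructured factorization-machine baselines


def _fit_fm_adam(X_parts, y, d, seed, cross: bool, iters=300, lr=5e-2,
                 init_scale=0.1):
    """Full-batch Adam on the logistic loss for FM2 / CrossFM2.

    ``X_parts`` is (Xi, Xu) of per-cell feature rows. Returns the fitted
    parameter dict.
    """
    Xi, Xu = X_parts
    X = np.hstack([Xi, Xu])
    n, q = X.shape
    rng = np.random.default_rng(seed)
    params = {"w0": np.zeros(()), "w1": np.zeros(q),
              "V": rng.normal(0.0, init_scale, size=(q, d))}
    opt = _Adam(params, lr)
    F = Xi.shape[1]
    X2 = X**2
    for _ in range(iters):
        V = params["V"]
        if cross:
            z1, z2 = Xi @ V[:F], Xu @ V[F:]
            inter = (z1 * z2).sum(axis=1)
        else:
            Z = X @ V
            inter = 0.5 * ((Z**2).sum(axis=1) - (X2 @ V**2).sum(axis=1))
        s = params["w0"] + X @ params["w1"] + inter
        g = -y * sigmoid(-y * s) / n
        grads = {"w0": np.asarray(g.sum()), "w1": X.T @ g}
        if cross:
            gV = np.vstack([Xi.T @ (g[:, None] * z2), Xu.T @ (g[:, None] * z1)])
        else:
            gV = X.T @ (g[:, None] * Z) - (X2.T @ g)[:, None] * V
        grads["V"] = gV
        opt.step(grads)
    return params


def _fm_matrix(params, S0, P0, cross: bool) -> np.ndarray:
    """Raw FM2/CrossFM2 scores for all pairs from fitted parameters."""
    F = S0.shape[0]
    V = params["V"]
    li = S0.T @ params["w1"][:F]
    lu = P0.T @ params["w1"][F:]
    if cross:
        inter = (S0.T @ V[:F]) @ (P0.T @ V[F:]).T
    else:
        Zi, Zu = S0.T @ V[:F], P0.T @ V[F:]
        Qi = ((S0.T**2) @ (V[:F] ** 2)).sum(axis=1)
        Qu = ((P0.T**2) @ (V[F:] ** 2)).sum(axis=1)
        sq = (Zi**2).sum(1)[:, None] + 2.0 * Zi @ Zu.T + (Zu**2).sum(1)[None, :]
        inter = 0.5 * (sq - Qi[:, None] - Qu[None, :])
    return float(params["w0"]) + li[:, None] + lu[None, :] + inter


# ---------------------------------------------------------------------------
# the experiment harness


def run_jeli_study(kind: str = "first_order", sparsity: float = 0.5,
                   n_datasets: int = 10, n_seeds: int = 10, F: int = 10,
                   d: int = 2, n_i: int = 173, n_u: int = 173,
                   mask_rate: float = 0.1, base_seed: int = 0,
                   jeli_kwargs: dict | None = None) -> pd.DataFrame:
    """Repeated-split evaluation of the joint model on synthetic data.

    Generates ``n_datasets`` datasets of the given kind and sparsity, fits
    the joint model on ``n_seeds`` random 80/20 splits of each, and
    returns one row per run with held-out AUC, the leave-out ranking
    metrics and the Spearman correlation between fitted and generating
    importance scores. Dataset and split seeds are derived from
    ``base_seed`` so the whole table is reproducible.
    """
    kind_id = 0 if kind == "first_order" else 1
    rows = []
    for i in range(n_datasets):
        ds_seed = int(np.random.SeedSequence(
            [base_seed, kind_id, int(round(sparsity * 100)), i]
        ).generate_state(1)[0] % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dataset = make_synthetic_dataset(F=F, d=d, n_i=n_i, n_u=n_u,
                                             kind=kind, sparsity=sparsity,
                                             mask_rate=mask_rate, seed=ds_seed)
        model = JELIModel.from_dataset(dataset, dim=d)
        for s in range(n_seeds):
            fit_seed = int(np.random.SeedSequence(
                [base_seed, kind_id, int(round(sparsity * 100)), i, s]
            ).generate_state(1)[0] % (2**31))
            res = model.fit(seed=fit_seed, **(jeli_kwargs or {}))
            rep = res.evaluate("test", s_true=dataset.true_importance)
            rows.append({"dataset": i, "seed": s, "auc": rep.auc,
                         "ns_auc": rep.ns_auc, "ndcg": rep.ndcg,
                         "spearman_rho": rep.spearman_rho})
    return pd.DataFrame(rows)


def _run_one(variant, dataset, seed, spec: AblationSpec):
    A = dataset.associations
    S0 = np.nan_to_num(dataset.item_features)
    P0 = np.nan_to_num(dataset.user_features)
    train_cells, test_cells = train_test_split_cells(A, 0.2, seed)
    mask = np.zeros(A.shape, dtype=bool)
    mask[test_cells[:, 0], test_cells[:, 1]] = True
    A_train = np.zeros_like(A)
    A_train[train_cells[:, 0], train_cells[:, 1]] = A[train_cells[:, 0], train_cells[:, 1]]

    if variant == "JELI":
        model = JELIModel(A, dataset.item_features, dataset.user_features,
                          tau=spec.tau, dim=spec.dim)
        res = model.fit(seed=seed, train_cells=train_cells,
                        test_cells=test_cells, **spec.jeli_kwargs)
        scores = res.raw_scores()
    elif variant in ("FM2", "CrossFM2"):
        cross = variant == "CrossFM2"
        Xi, Xu = S0.T[train_cells[:, 0]], P0.T[train_cells[:, 1]]
        y = A[train_cells[:, 0], train_cells[:, 1]].astype(float)
        params = _fit_fm_adam((Xi, Xu), y, spec.dim, seed, cross)
        scores = _fm_matrix(params, S0, P0, cross)
    else:
        emb = selt_embeddings(dataset.item_features, dataset.user_features,
                              A_train, variant, spec.dim, seed, tau=spec.tau)
        clf = train_fixed_embedding_classifier(
            emb, A, train_cells, S=dataset.item_features, P=dataset.user_features
        )
        scores = clf.predict_matrix()
    rank_mask = np.ones(A.shape, dtype=bool)
    rank_mask[train_cells[:, 0], train_cells[:, 1]] = False
    report = evaluate_predictions(A, scores, mask=mask, rank_mask=rank_mask)
    return report.auc, report.ns_auc, report.ndcg


def run_ablation_suite(spec: AblationSpec, out: str | Path | None = None):
    """Run every variant x sparsity x dataset x seed cell of the study.

    Returns ``(runs, summary)``: a tidy per-run table and the mean +/- sd
    aggregate per (variant, sparsity). Single-run failures are recorded as
    NaN rows and the suite continues.
    """
    rows = []
    for sparsity in spec.sparsities:
        for ds_idx in range(spec.n_datasets):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dataset = make_synthetic_dataset(
                    F=spec.F, d=spec.dim, n_i=spec.n_i, n_u=spec.n_u,
                    kind=spec.kind, sparsity=sparsity, mask_rate=spec.mask_rate,
                    seed=spec.base_seed + 1000 * ds_idx + int(round(sparsity * 100)),
                )
            for seed in range(spec.n_seeds):
                for variant in spec.variants:
                    try:
                        auc_v, ns_v, ndcg_v = _run_one(variant, dataset,
                                                       spec.base_seed + seed, spec)
                    except Exception as exc:  # single-run failure: record, go on
                        logger.warning("run failed (%s, sparsity=%s, ds=%d, seed=%d): %s",
                                       variant, sparsity, ds_idx, seed, exc)
                        auc_v = ns_v = ndcg_v = float("nan")
                    rows.append({"variant": variant, "sparsity": sparsity,
                                 "dataset": ds_idx, "seed": seed, "auc": auc_v,
                                 "ns_auc": ns_v, "ndcg": ndcg_v})
    runs = pd.DataFrame(rows)
    summary = (runs.groupby(["variant", "sparsity"])[["auc", "ns_auc", "ndcg"]]
               .agg(["mean", "std"]).reset_index())
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        runs.to_csv(out, sep="\t", index=False)
        summary.to_csv(out.with_suffix(".summary.tsv"), sep="\t")
    return runs, summary
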