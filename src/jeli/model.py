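"""Joint training of the RHOFM classifier and knowledge-graph embeddings.

The association problem is cast as knowledge-graph completion: every
relation except the signed association edges is scored by the MuRE
interaction model on embeddings produced by the shared structure function
``s_W``, while ``+`` edges are scored by the RHOFM itself and ``-`` edges
by its negation. All parameters — the RHOFM's, one (R_r, e_r) pair per
non-signed relation and one bias per entity — are fitted together by
minimising a soft margin ranking loss against sampled head-corrupted
negative triplets, with minibatch Adam. Gradients are analytic (the scores
are closed-form in every parameter).

The public surface follows the Model/Results convention: build a
:class:`JELIModel` from the data matrices, call :meth:`~JELIModel.fit`, and
read estimates, diagnostics and predictions off the returned
:class:`JELIResults`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .kg import RELATIONS, KnowledgeGraph, build_knowledge_graph
from .rhofm import (
    LINEAR_STRUCTURE,
    RHOFMParams,
    rhofm_score,
    rhofm_score_matrix,
    feature_importance,
    sigmoid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "JELIParams",
    "TrainConfig",
    "JELIModel",
    "JELIResults",
    "mure_score",
    "edge_score",
    "margin_ranking_loss",
    "sample_negatives",
    "train_test_split_cells",
    "fit_jeli",
    "predict_scores",
]

SIGNED = ("+", "-")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class JELIParams:
    """All fitted parameters: theta plus relation and bias terms.

    The signed relations carry no MuRE parameters — they are scored by the
    RHOFM; every other relation present in the graph has a (d, d) matrix
    and a length-d embedding, and every entity has a scalar bias.
    """

    rhofm: RHOFMParams
    rel_matrices: dict[str, np.ndarray]
    rel_embeddings: dict[str, np.ndarray]
    entity_biases: dict[str, float]

    def __post_init__(self) -> None:
        for r in self.rel_matrices:
            if r in SIGNED:
                raise ValueError(f"relation {r!r} is scored by the RHOFM, not MuRE")


@dataclass
class TrainConfig:
    margin: float = 1.0
    negatives_per_positive: int = 1
    epochs: int = 40
    batch_size: int = 512
    learning_rate: float = 5e-3
    seed: int = 0
    test_fraction: float = 0.2
    interpretable_mode: bool = True
    init_scale: float = 0.1
    strict_paper_sign: bool = False


# ---------------------------------------------------------------------------
# elementary scores


def mure_score(e_h, e_r, e_t, R_r, b_h: float = 0.0, b_t: float = 0.0) -> float:
    """Multi-relational Euclidean score -||R_r e_h - (e_t + e_r)||^2 + b_h + b_t."""
    e_h, e_r, e_t = (np.asarray(v, dtype=float) for v in (e_h, e_r, e_t))
    R_r = np.asarray(R_r, dtype=float)
    if not (e_h.shape == e_r.shape == e_t.shape) or R_r.shape != (e_h.size, e_h.size):
        raise ValueError("inconsistent embedding dimensions")
    u = R_r @ e_h - (e_t + e_r)
    return float(-(u @ u) + b_h + b_t)


def edge_score(
    params: JELIParams,
    h: str,
    r: str,
    t: str,
    features: dict[str, np.ndarray],
) -> float:
    """Score one triplet: MuRE for plain relations, +/-RHOFM for signed ones.

    ``features`` maps entity names to their length-F feature vectors
    (feature entities should map to indicator vectors).
    """
    if r not in RELATIONS:
        raise ValueError(f"unknown relation label {r!r}")
    xh, xt = features[h], features[t]
    if r == "+":
        return rhofm_score(params.rhofm, xh, xt)
    if r == "-":
        return -rhofm_score(params.rhofm, xh, xt)
    W = params.rhofm.W
    spec = params.rhofm.structure
    eh = spec.apply(W, np.nan_to_num(np.asarray(xh, dtype=float)))
    et = spec.apply(W, np.nan_to_num(np.asarray(xt, dtype=float)))
    return mure_score(
        eh, params.rel_embeddings[r], et, params.rel_matrices[r],
        params.entity_biases.get(h, 0.0), params.entity_biases.get(t, 0.0),
    )


def margin_ranking_loss(
    pos_scores, neg_scores, margin: float = 1.0, strict_paper_sign: bool = False
) -> float:
    """Soft margin ranking loss over paired true/corrupted triplet scores.

    ``sum log(1 + exp(margin - s_true + s_corrupted))``: non-negative and
    decreasing in the score gap, so minimising it pushes true triplets
    above corrupted ones. ``strict_paper_sign`` flips the orientation of
    the gap inside the exponential.
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.shape != neg.shape:
        raise ValueError("positive and corrupted scores must be paired")
    if pos.size == 0:
        return 0.0
    gap = pos - neg
    if strict_paper_sign:
        gap = -gap
    return float(np.logaddexp(0.0, margin - gap).sum())


# ---------------------------------------------------------------------------
# triplet encoding and negative sampling


def _encode(h, r, t, n_ent):
    return (np.asarray(r, dtype=np.int64) * n_ent + h) * n_ent + t


class _EncodedGraph:
    """Integer view of a knowledge graph for vectorised training."""

    def __init__(self, kg: KnowledgeGraph, S: np.ndarray, P: np.ndarray):
        self.kg = kg
        names = kg.entities
        self.index = {name: i for i, name in enumerate(names)}
        self.names = names
        self.n_ent = len(names)
        F = S.shape[0]
        n_i, n_u = len(kg.items), len(kg.users)
        X = np.zeros((self.n_ent, F))
        X[:n_i] = np.nan_to_num(S.T)
        X[n_i:n_i + n_u] = np.nan_to_num(P.T)
        X[n_i + n_u:n_i + n_u + F] = np.eye(F)
        self.X = X  # prior-only nodes keep all-zero features
        part = np.empty(self.n_ent, dtype=np.int64)
        part[:n_i] = 0
        part[n_i:n_i + n_u] = 1
        part[n_i + n_u:n_i + n_u + F] = 2
        part[n_i + n_u + F:] = 3
        self.part = part
        self.members = [np.where(part == p)[0] for p in range(4)]
        self.H = np.array([self.index[h] for h, _, _ in kg.triplets], dtype=np.int64)
        self.R = np.array([RELATIONS.index(r) for _, r, _ in kg.triplets], dtype=np.int64)
        self.T = np.array([self.index[t] for _, _, t in kg.triplets], dtype=np.int64)
        self.keys = np.sort(_encode(self.H, self.R, self.T, self.n_ent))

    def contains(self, h, r, t) -> np.ndarray:
        key = _encode(h, r, t, self.n_ent)
        pos = np.searchsorted(self.keys, key)
        pos = np.minimum(pos, len(self.keys) - 1)
        return self.keys[pos] == key

    def corrupt_heads(self, idx, rng, max_tries: int = 50):
        """Uniform head corruptions within each head's partition.

        Returns (neg_heads, ok_mask); a triplet whose partition offers no
        valid corruption after ``max_tries`` rounds is flagged out.
        """
        H, R, T = self.H[idx], self.R[idx], self.T[idx]
        parts = self.part[H]
        neg = np.empty_like(H)
        for p in range(4):
            sel = parts == p
            if sel.any():
                pool = self.members[p]
                neg[sel] = pool[rng.integers(0, len(pool), size=int(sel.sum()))]
        bad = self.contains(neg, R, T)
        tries = 0
        while bad.any() and tries < max_tries:
            for p in range(4):
                sel = bad & (parts == p)
                if sel.any():
                    pool = self.members[p]
                    neg[sel] = pool[rng.integers(0, len(pool), size=int(sel.sum()))]
            bad = self.contains(neg, R, T)
            tries += 1
        if bad.any():
            logger.info("%d triplets had no valid head corruption; skipped", int(bad.sum()))
        return neg, ~bad


def sample_negatives(
    kg: KnowledgeGraph,
    S: np.ndarray,
    P: np.ndarray,
    k: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str, str]]:
    """Draw k head-corrupted triplets per positive, absent from the graph.

    Corruptions are uniform over the head's partition (item/user/feature/
    prior) and rejected while they collide with an existing triplet;
    positives whose partition is exhausted are skipped (logged).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    enc = _EncodedGraph(kg, np.asarray(S, dtype=float), np.asarray(P, dtype=float))
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, str]] = []
    all_idx = np.arange(len(enc.H))
    for _ in range(k):
        neg, ok = enc.corrupt_heads(all_idx, rng)
        for i in np.where(ok)[0]:
            out.append((enc.names[neg[i]], RELATIONS[enc.R[i]], enc.names[enc.T[i]]))
    return out


def train_test_split_cells(A: np.ndarray, test_fraction: float, seed) -> tuple:
    """Uniformly split the nonzero cells of A into train and test sets."""
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = np.argwhere(np.asarray(A) != 0)
    if len(cells) == 0:
        raise ValueError("association matrix has no nonzero cells")
    perm = rng.permutation(len(cells))
    n_test = int(round(test_fraction * len(cells)))
    return cells[perm[n_test:]], cells[perm[:n_test]]


# ---------------------------------------------------------------------------
# batched scores and analytic gradients


def _mure_forward(Eh, Et, R, er, bh, bt):
    u = Eh @ R.T - Et - er
    return -(u**2).sum(axis=1) + bh + bt, u


def _mure_backward(w, u, Eh, R):
    """Gradients of sum_b w_b * score_b for a MuRE batch."""
    wu = w[:, None] * u
    dEh = -2.0 * wu @ R
    dEt = 2.0 * wu
    der = 2.0 * wu.sum(axis=0)
    dR = -2.0 * wu.T @ Eh
    return dEh, dEt, der, dR


def _rhofm_pair_forward(W, omega0, omega1, omega2m, order, Xi, Xu):
    """Factored RHOFM scores for a batch of (item, user) feature rows.

    Returns (scores, cache) where cache carries the intermediates the
    backward pass needs. The order-2 case uses the closed-form kernel; the
    general case runs the elementary-symmetric-polynomial recursion with a
    prefix/suffix table for the gradient.
    """
    zi, zu = Xi @ W, Xu @ W
    z = zi + zu
    lin = z @ omega1
    if order == 2:
        W2 = W**2
        s2 = Xi**2 + Xu**2
        q = (s2 @ W2).sum(axis=1)
        K2 = 0.5 * ((z**2).sum(axis=1) - q)
        scores = omega0 + lin + omega2m[0] * K2
        return scores, ("fast", z, s2, K2)
    B, F = Xi.shape
    d = W.shape[1]
    Wstack = np.vstack([W, W])
    P = np.concatenate([Xi, Xu], axis=1)[:, :, None] * Wstack[None]
    q2 = 2 * F
    pre = np.zeros((B, q2 + 1, order + 1, d))
    pre[:, :, 0, :] = 1.0
    for f in range(q2):
        pre[:, f + 1, 1:, :] = pre[:, f, 1:, :] + P[:, f, None, :] * pre[:, f, :-1, :]
    suf = np.zeros((B, q2 + 1, order + 1, d))
    suf[:, :, 0, :] = 1.0
    for f in range(q2 - 1, -1, -1):
        suf[:, f, 1:, :] = suf[:, f + 1, 1:, :] + P[:, f, None, :] * suf[:, f + 1, :-1, :]
    K = pre[:, q2, :, :].sum(axis=2)  # (B, order+1); K[:, t] = kernel of degree t
    scores = omega0 + lin + sum(
        omega2m[t - 2] * K[:, t] for t in range(2, order + 1)
    )
    return scores, ("dp", z, P, pre, suf, K)


def _rhofm_pair_backward(w, cache, W, omega1, omega2m, order, Xi, Xu):
    """Gradients of sum_b w_b * score_b; returns (dW, domega0, domega1, domega2m)."""
    kind = cache[0]
    domega0 = float(w.sum())
    if kind == "fast":
        _, z, s2, K2 = cache
        dW = np.outer((Xi + Xu).T @ w, omega1)
        dW += omega2m[0] * ((Xi + Xu).T @ (w[:, None] * z) - (s2.T @ w)[:, None] * W)
        domega1 = (w[:, None] * z).sum(axis=0)
        domega2m = np.array([float(w @ K2)])
        return dW, domega0, domega1, domega2m
    _, z, P, pre, suf, K = cache
    B, F = Xi.shape
    q2 = 2 * F
    G = np.zeros_like(P)  # dscore/dP weighted by w
    for t in range(2, order + 1):
        coef = (w * omega2m[t - 2])[:, None, None]
        acc = np.zeros((B, q2, W.shape[1]))
        for s in range(t):
            acc += pre[:, :q2, s, :] * suf[:, 1:, t - 1 - s, :]
        G += coef * acc
    dW = np.outer((Xi + Xu).T @ w, omega1)
    dW += np.einsum("bf,bfk->fk", Xi, G[:, :F, :])
    dW += np.einsum("bf,bfk->fk", Xu, G[:, F:, :])
    domega1 = (w[:, None] * z).sum(axis=0)
    domega2m = np.array([float(w @ K[:, t]) for t in range(2, order + 1)])
    return dW, domega0, domega1, domega2m


class _Adam:
    """Adaptive-moment SGD on a dict of named arrays (in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            self.params[k] -= self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps
            )


# ---------------------------------------------------------------------------
# the model / results pair


class JELIModel:
    """Joint embedding-classifier model for an association matrix.

    Parameters
    ----------
    A : (n_i, n_u) array over {-1, 0, +1}; zeros are unknown associations.
    S, P : (F, n_i) and (F, n_u) feature tables; NaN marks missing values.
    prior : optional list of (head, tail) edges distilled into the graph.
    tau : cosine-similarity threshold for the similarity edges.
    dim, order, ridge : RHOFM hyperparameters (d, m, lambda).
    interpretable : fix the mixing weights omega1 = 1_d, omega2m = 1 so the
        row sums of W are directly the feature importance scores.
    """

    def __init__(self, A, S, P, prior=None, tau: float = 0.5, dim: int = 2,
                 order: int = 2, ridge: float = 0.0, interpretable: bool = True):
        self.A = np.asarray(A)
        self.S = np.asarray(S, dtype=float)
        self.P = np.asarray(P, dtype=float)
        bad = np.argwhere(~np.isin(self.A, (-1, 0, 1)))
        if len(bad):
            i, u = bad[0]
            raise ValueError(
                f"association matrix holds {self.A[i, u]!r} at cell ({i}, {u}); "
                "values must be in {-1, 0, +1}"
            )
        self.prior = list(prior) if prior is not None else []
        self.tau = tau
        self.dim = dim
        self.order = order
        self.ridge = ridge
        self.interpretable = interpretable

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "JELIModel":
        """Build the model from a :class:`~jeli.datasets.SyntheticDataset`."""
        return cls(dataset.associations, dataset.item_features,
                   dataset.user_features, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, epochs: int = 40, learning_rate: float = 5e-3,
            batch_size: int = 512, negatives: int = 1, margin: float = 1.0,
            seed: int = 0, test_fraction: float = 0.2,
            init_scale: float = 0.1, strict_paper_sign: bool = False,
            train_cells=None, test_cells=None) -> "JELIResults":
        """Fit all parameters by minibatch Adam on the margin ranking loss.

        The nonzero cells of A are split train/test with ``test_fraction``
        (unless explicit cell arrays are given); the knowledge graph is
        built from the training cells only. Deterministic given ``seed``.
        """
        config = TrainConfig(
            margin=margin, negatives_per_positive=negatives, epochs=epochs,
            batch_size=batch_size, learning_rate=learning_rate, seed=seed,
            test_fraction=test_fraction, interpretable_mode=self.interpretable,
            init_scale=init_scale, strict_paper_sign=strict_paper_sign,
        )
        rng = np.random.default_rng(seed)
        if train_cells is None:
            train_cells, test_cells = train_test_split_cells(
                self.A, test_fraction, rng
            )
        if len(train_cells) == 0:
            raise ValueError("no nonzero training cells")
        A_train = np.zeros_like(self.A)
        A_train[train_cells[:, 0], train_cells[:, 1]] = self.A[
            train_cells[:, 0], train_cells[:, 1]
        ]
        kg = build_knowledge_graph(A_train, self.S, self.P, self.prior, self.tau)
        enc = _EncodedGraph(kg, self.S, self.P)
        F, d, m = self.S.shape[0], self.dim, self.order

        mure_rels = sorted(
            {r for _, r, _ in kg.triplets if r not in SIGNED}, key=RELATIONS.index
        )
        params: dict[str, np.ndarray] = {
            "W": rng.normal(0.0, init_scale, size=(F, d)),
            "omega0": np.zeros(()),
            "b": np.zeros(enc.n_ent),
        }
        for r in mure_rels:
            params[f"R:{r}"] = np.eye(d)
            params[f"e:{r}"] = rng.normal(0.0, init_scale, size=d)
        omega1 = np.ones(d)
        omega2m = np.ones(m - 1)
        if not self.interpretable:
            params["omega1"] = rng.normal(0.0, init_scale, size=d)
            params["omega2m"] = rng.normal(0.0, init_scale, size=m - 1)

        opt = _Adam(params, learning_rate)
        n_pos = len(enc.H)
        loss_history: list[float] = []
        tic = time.perf_counter()
        rel_ids = {r: RELATIONS.index(r) for r in RELATIONS}
        plus_id, minus_id = rel_ids["+"], rel_ids["-"]

        for _epoch in range(epochs):
            perm = rng.permutation(np.repeat(np.arange(n_pos), negatives))
            epoch_loss, epoch_pairs = 0.0, 0
            for start in range(0, len(perm), batch_size):
                idx = perm[start:start + batch_size]
                neg_heads, ok = enc.corrupt_heads(idx, rng)
                idx, neg_heads = idx[ok], neg_heads[ok]
                if len(idx) == 0:
                    continue
                B = len(idx)
                H = np.concatenate([enc.H[idx], neg_heads])
                R = np.concatenate([enc.R[idx], enc.R[idx]])
                T = np.concatenate([enc.T[idx], enc.T[idx]])
                w1 = params.get("omega1", omega1)
                w2m = params.get("omega2m", omega2m)

                scores = np.empty(2 * B)
                caches = {}
                signed_mask = (R == plus_id) | (R == minus_id)
                if signed_mask.any():
                    sel = np.where(signed_mask)[0]
                    Xi, Xu = enc.X[H[sel]], enc.X[T[sel]]
                    s, cache = _rhofm_pair_forward(
                        params["W"], float(params["omega0"]), w1, w2m, m, Xi, Xu
                    )
                    sign = np.where(R[sel] == plus_id, 1.0, -1.0)
                    scores[sel] = sign * s
                    caches["signed"] = (sel, Xi, Xu, sign, cache)
                for r in mure_rels:
                    sel = np.where(R == rel_ids[r])[0]
                    if len(sel) == 0:
                        continue
                    Eh = enc.X[H[sel]] @ params["W"]
                    Et = enc.X[T[sel]] @ params["W"]
                    s, u = _mure_forward(
                        Eh, Et, params[f"R:{r}"], params[f"e:{r}"],
                        params["b"][H[sel]], params["b"][T[sel]],
                    )
                    scores[sel] = s
                    caches[r] = (sel, Eh, Et, u)

                gap = scores[:B] - scores[B:]
                if strict_paper_sign:
                    gap = -gap
                diff = margin - gap
                epoch_loss += float(np.logaddexp(0.0, diff).sum())
                epoch_pairs += B
                g = sigmoid(diff)
                w_pair = np.concatenate([-g, g])
                if strict_paper_sign:
                    w_pair = -w_pair

                grads = {k: np.zeros_like(v) for k, v in params.items()}
                if "signed" in caches:
                    sel, Xi, Xu, sign, cache = caches["signed"]
                    w = w_pair[sel] * sign
                    dW, do0, do1, do2m = _rhofm_pair_backward(
                        w, cache, params["W"], w1, w2m, m, Xi, Xu
                    )
                    grads["W"] += dW
                    grads["omega0"] += do0
                    if not self.interpretable:
                        grads["omega1"] += do1
                        grads["omega2m"] += do2m
                for r in mure_rels:
                    if r not in caches:
                        continue
                    sel, Eh, Et, u = caches[r]
                    w = w_pair[sel]
                    dEh, dEt, der, dR = _mure_backward(w, u, Eh, params[f"R:{r}"])
                    grads["W"] += enc.X[H[sel]].T @ dEh + enc.X[T[sel]].T @ dEt
                    grads[f"e:{r}"] += der
                    grads[f"R:{r}"] += dR
                    np.add.at(grads["b"], H[sel], w)
                    np.add.at(grads["b"], T[sel], w)
                opt.step(grads)
            loss_history.append(epoch_loss / max(epoch_pairs, 1))

        rhofm = RHOFMParams(
            W=params["W"].copy(), omega0=float(params["omega0"]),
            omega1=params.get("omega1", omega1).copy(),
            omega2m=params.get("omega2m", omega2m).copy(),
            order=m, ridge=self.ridge, structure=LINEAR_STRUCTURE,
        )
        fitted = JELIParams(
            rhofm=rhofm,
            rel_matrices={r: params[f"R:{r}"].copy() for r in mure_rels},
            rel_embeddings={r: params[f"e:{r}"].copy() for r in mure_rels},
            entity_biases={name: float(params["b"][i]) for i, name in enumerate(enc.names)},
        )
        return JELIResults(
            model=self, params=fitted, config=config, graph=kg,
            loss_history=np.asarray(loss_history),
            train_cells=np.asarray(train_cells), test_cells=np.asarray(test_cells),
            fit_seconds=time.perf_counter() - tic,
        )


@dataclass
class JELIResults:
    """Fitted parameters, training log and prediction/evaluation helpers."""

    model: JELIModel
    params: JELIParams
    config: TrainConfig
    graph: KnowledgeGraph
    loss_history: np.ndarray
    train_cells: np.ndarray
    test_cells: np.ndarray
    fit_seconds: float = field(default=0.0)

    # -- predictions -------------------------------------------------------

    def raw_scores(self, S=None, P=None) -> np.ndarray:
        """RHOFM scores for every (item, user) pair (logit scale)."""
        S = self.model.S if S is None else np.asarray(S, dtype=float)
        P = self.model.P if P is None else np.asarray(P, dtype=float)
        return rhofm_score_matrix(self.params.rhofm, S, P)

    def predict_scores(self, S=None, P=None):
        """Association probabilities sigmoid(RHOFM) and {-1,+1} labels."""
        raw = self.raw_scores(S, P)
        probs = sigmoid(raw)
        labels = np.where(probs > 0.5, 1, -1).astype(np.int8)
        return probs, labels

    def feature_importance(self, x=None) -> np.ndarray:
        """Intrinsic importance scores (row sums of the fitted W)."""
        return feature_importance(self.params.rhofm, x)

    def evaluate(self, on: str = "test", s_true=None):
        """Metrics report for the fitted model.

        AUC is computed on the held-out (or training) labelled cells;
        NS-AUC and NDCG rank, per user, every cell outside the training
        set — held-out positives compete with the unknown cells.
        Importance recovery is included when the true scores are supplied.
        """
        from .metrics import evaluate_predictions

        cells = self.test_cells if on == "test" else self.train_cells
        mask = np.zeros(self.model.A.shape, dtype=bool)
        mask[cells[:, 0], cells[:, 1]] = True
        rank_mask = np.ones(self.model.A.shape, dtype=bool)
        if on == "test":
            rank_mask[self.train_cells[:, 0], self.train_cells[:, 1]] = False
        scores = self.raw_scores()
        s_pred = self.feature_importance() if s_true is not None else None
        return evaluate_predictions(self.model.A, scores, mask=mask,
                                    rank_mask=rank_mask,
                                    s_true=s_true, s_pred=s_pred)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        kg = self.graph
        rows = [
            "              Joint embedding-classifier (JELI) results",
            "=" * 72,
            f"items: {m.A.shape[0]:>6}   users: {m.A.shape[1]:>6}   "
            f"features: {m.S.shape[0]:>5}   dim: {self.params.rhofm.dim}",
            f"order m: {self.params.rhofm.order}   ridge: {self.params.rhofm.ridge}"
            f"   interpretable: {m.interpretable}   tau: {m.tau}",
            f"graph: {len(kg.triplets)} triplets over {len(kg.entities)} entities",
            f"train cells: {len(self.train_cells)}   test cells: {len(self.test_cells)}",
            f"epochs: {self.config.epochs}   final mean pair loss: "
            f"{self.loss_history[-1]:.4f}   ({self.fit_seconds:.1f} s)",
            "-" * 72,
            "feature importance (row sums of fitted W):",
        ]
        imp = self.feature_importance()
        order = np.argsort(-np.abs(imp))
        for f in order:
            rows.append(f"    f{f + 1:<4d} {imp[f]:+10.4f}")
        rows.append("=" * 72)
        return "\n".join(rows)

    def plot_importance(self, ax=None, true_scores=None):
        """Bar plot of fitted (and optionally true) importance scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        imp = self.feature_importance()
        idx = np.arange(len(imp))
        width = 0.4 if true_scores is not None else 0.8
        ax.bar(idx, imp, width=width, label="fitted")
        if true_scores is not None:
            ax.bar(idx + width, true_scores, width=width, label="true")
            ax.legend()
        ax.set_xlabel("feature")
        ax.set_ylabel("importance")
        return ax

    def save(self, path) -> None:
        from .io import save_model

        save_model(self.params, path)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_jeli(A, S, P, prior=None, config: TrainConfig | None = None,
             tau: float = 0.5, dim: int = 2, order: int = 2):
    """Functional fit: returns (JELIParams, per-epoch mean pair loss)."""
    config = config or TrainConfig()
    model = JELIModel(A, S, P, prior=prior, tau=tau, dim=dim, order=order,
                      interpretable=config.interpretable_mode)
    res = model.fit(
        epochs=config.epochs, learning_rate=config.learning_rate,
        batch_size=config.batch_size, negatives=config.negatives_per_positive,
        margin=config.margin, seed=config.seed,
        test_fraction=config.test_fraction, init_scale=config.init_scale,
        strict_paper_sign=config.strict_paper_sign,
    )
    return res.params, res.loss_history


def predict_scores(params: JELIParams, S, P):
    """Probabilities and labels for every pair under fitted parameters."""
    raw = rhofm_score_matrix(params.rhofm, np.asarray(S, float), np.asarray(P, float))
    probs = sigmoid(raw)
    return probs, np.where(probs > 0.5, 1, -1).astype(np.int8)
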