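"""Redundant structured higher-order factorization machines (RHOFM).

A standard order-m factorization machine (HOFM) on an input vector x keeps
one latent row per input coordinate and scores x as an intercept, a linear
term and sums of ANOVA kernels of degree t = 2..m over the latent rows. The
*redundant structured* variant replaces the free latent rows by embeddings
produced from the entity's feature vector through a shared structure
function ``s_W`` (linear case: ``s_W(x) = x W`` with W of shape (F, d)), and
shares a single scalar mixing weight per interaction order. Item, user and
feature entities thereby live in one embedding space, and the scalar count
drops to ``m + (F+1) d``.

Two evaluation modes are provided:

* ``factored`` — the differentiable O(F d m) form used in training: the
  linear term reads the item/user embeddings directly, and the interaction
  terms combine feature embeddings weighted by the raw feature values;
* ``exact`` — the definitional form in which the shared weights are first
  reconstructed from the pair at hand by a ridge (pseudo-inverse) least
  squares fit of the structure function on the two feature vectors.

With a linear structure and no ridge the two linear terms coincide exactly;
the interaction terms coincide whenever the rows of W lie in the span of
the two input vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np

__all__ = [
    "StructureSpec",
    "LINEAR_STRUCTURE",
    "RHOFMParams",
    "FMParams",
    "parameter_count",
    "structure_apply",
    "ridge_embedding_estimator",
    "anova_kernel",
    "rhofm_score",
    "rhofm_score_matrix",
    "feature_importance",
    "predict_label",
    "fm_score",
    "crossfm_score",
    "hofm_bruteforce",
    "sigmoid",
]


def sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def _impute(x: np.ndarray) -> np.ndarray:
    """Zero-impute missing (NaN) entries; the package-wide convention."""
    return np.nan_to_num(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class StructureSpec:
    """A structure function mapping a length-F feature vector to R^d.

    ``apply(W, x)`` must be differentiable in W for training; the linear
    structure is ``x @ W``, under which the embedding of the indicator
    vector of feature f is exactly row f of W.
    """

    id: str
    apply: Callable[[np.ndarray, np.ndarray], np.ndarray]


LINEAR_STRUCTURE = StructureSpec(id="linear", apply=lambda W, x: x @ W)


def structure_apply(spec: StructureSpec, W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Embed a feature vector; NaNs are imputed to zero first.

    This is also the inference-time embedding of an entity unseen during
    training (zero-padded on unavailable features).
    """
    x = _impute(x)
    if x.shape[-1] != W.shape[0]:
        raise ValueError(f"feature vector length {x.shape[-1]} != {W.shape[0]} rows of W")
    return spec.apply(W, x)


@dataclass
class RHOFMParams:
    """Parameters theta = (omega0, omega1, omega2m, W) of an RHOFM."""

    W: np.ndarray                      # (F, d) structure parameter
    omega0: float = 0.0                # intercept
    omega1: np.ndarray = None          # (d,) linear-term weights
    omega2m: np.ndarray = None         # (m-1,) per-order interaction weights
    order: int = 2                     # m >= 2
    ridge: float = 0.0                 # lambda of the exact-mode estimator
    structure: StructureSpec = LINEAR_STRUCTURE
    interpretable: bool = field(default=None)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.order < 2:
            raise ValueError(f"order must be >= 2, got {self.order}")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        d = self.W.shape[1]
        if self.omega1 is None:
            self.omega1 = np.ones(d)
        self.omega1 = np.asarray(self.omega1, dtype=float)
        if self.omega2m is None:
            self.omega2m = np.ones(self.order - 1)
        self.omega2m = np.asarray(self.omega2m, dtype=float)
        if self.omega1.shape != (d,):
            raise ValueError("omega1 must have length d")
        if self.omega2m.shape != (self.order - 1,):
            raise ValueError("omega2m must have length m-1")
        if self.interpretable is None:
            self.interpretable = bool(
                np.all(self.omega1 == self.omega1[0]) and np.all(self.omega2m == 1.0)
            )

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    @property
    def n_parameters(self) -> int:
        """Number of scalars in (omega0, omega1, omega2m, W)."""
        return 1 + self.omega1.size + self.omega2m.size + self.W.size


def parameter_count(F: int, d: int, m: int) -> int:
    """Scalar count of an RHOFM: 1 + d + (m-1) + F*d = m + (F+1)*d.

    A plain HOFM on the concatenated 2F-dimensional input would need
    1 + 2F + 2Fd(m-1) scalars and its inhomogeneous-kernel variant
    1 + m + 2Fd; sharing the structure removes the multiplicative factor
    on F.
    """
    return m + (F + 1) * d


def ridge_embedding_estimator(
    xi: np.ndarray, xu: np.ndarray, params: RHOFMParams
) -> np.ndarray:
    """Reconstruct the structure weights from one (item, user) pair.

    Solves ``X V = [s_W(x^i); s_W(x^u)]`` for V in the ridge least-squares
    sense, where X is the 2xF design matrix with rows x^i and x^u; the
    pseudo-inverse makes ridge = 0 legal under rank deficiency. With a
    linear structure the reconstruction X @ V equals X @ W exactly.
    """
    xi, xu = _impute(xi), _impute(xu)
    X = np.vstack([xi, xu])  # (2, F)
    Y = np.vstack(
        [structure_apply(params.structure, params.W, xi),
         structure_apply(params.structure, params.W, xu)]
    )  # (2, d)
    F = X.shape[1]
    G = X.T @ X + params.ridge * np.eye(F)
    return np.linalg.pinv(G) @ X.T @ Y  # (F, d)


def _esp_table(P: np.ndarray, t_max: int) -> np.ndarray:
    """Elementary symmetric polynomials e_0..e_t of P along its q axis.

    P has shape (q, d); the returned table has shape (t_max+1, d) with row t
    holding e_t({P[0, k], ..., P[q-1, k]}) for each latent dimension k.
    O(q * t_max) per dimension.
    """
    q, d = P.shape
    E = np.zeros((t_max + 1, d))
    E[0] = 1.0
    for f in range(q):
        for s in range(min(t_max, f + 1), 0, -1):
            E[s] += P[f] * E[s - 1]
    return E


def anova_kernel(V: np.ndarray, xw: np.ndarray, t: int) -> float:
    """Degree-t ANOVA kernel over weighted latent rows.

    Computes ``sum_{f1<...<ft} <V_{f1},...,V_{ft}> xw_{f1} ... xw_{ft}``,
    i.e. per latent dimension the degree-t elementary symmetric polynomial
    of {xw_f * V_{f,k}}, summed over k. Evaluated with the O(q*t) dynamic
    programming recursion. ``t > q`` returns 0 (empty sum).
    """
    if t < 2:
        raise ValueError(f"ANOVA kernel degree must be >= 2, got {t}")
    V = np.atleast_2d(np.asarray(V, dtype=float))
    xw = np.asarray(xw, dtype=float)
    q = V.shape[0]
    if xw.shape != (q,):
        raise ValueError(f"weights must have length {q}, got shape {xw.shape}")
    if t > q:
        return 0.0
    E = _esp_table(xw[:, None] * V, t)
    return float(E[t].sum())


def _interaction_terms(params: RHOFMParams, P: np.ndarray) -> float:
    """sum_t omega2m[t-1] * (degree-t kernel) for t = 2..m, from P (q, d)."""
    t_max = min(params.order, P.shape[0])
    if t_max < 2:
        return 0.0
    E = _esp_table(P, t_max)
    return float(sum(params.omega2m[t - 2] * E[t].sum() for t in range(2, t_max + 1)))


def rhofm_score(
    params: RHOFMParams, xi: np.ndarray, xu: np.ndarray, mode: str = "factored"
) -> float:
    """Score one (item, user) pair of feature vectors.

    ``factored`` evaluates the reordered form (linear term on the two
    entity embeddings, interactions over value-weighted feature
    embeddings); ``exact`` evaluates the definitional form with the
    pair-specific ridge reconstruction of the structure weights.
    """
    xi, xu = _impute(xi), _impute(xu)
    if mode == "factored":
        ei = structure_apply(params.structure, params.W, xi)
        eu = structure_apply(params.structure, params.W, xu)
        linear = float(params.omega1 @ (ei + eu))
        # feature embeddings s_W(x^f) for the indicator vectors x^f
        feat = np.vstack(
            [structure_apply(params.structure, params.W, row) for row in np.eye(params.n_features)]
        ) if params.structure.id != "linear" else params.W
        P = np.concatenate([xi, xu])[:, None] * np.vstack([feat, feat])
    elif mode == "exact":
        W_tilde = ridge_embedding_estimator(xi, xu, params)
        stacked = np.vstack([W_tilde, W_tilde])  # (2F, d)
        xprime = np.concatenate([xi, xu])
        linear = float(params.omega1 @ (xprime @ stacked))
        P = xprime[:, None] * stacked
    else:
        raise ValueError(f"mode must be 'factored' or 'exact', got {mode!r}")
    return params.omega0 + linear + _interaction_terms(params, P)


def rhofm_score_matrix(
    params: RHOFMParams, S: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """Factored-mode scores for every (item, user) pair, vectorized.

    S and P are (F, n_i) and (F, n_u) feature tables (NaN allowed). Only
    the linear structure is vectorized; other structures fall back to the
    pairwise loop.
    """
    S0, P0 = _impute(S), _impute(P)
    if S0.shape[0] != params.n_features or P0.shape[0] != params.n_features:
        raise ValueError(
            f"feature axis mismatch: model has {params.n_features} features, "
            f"inputs have {S0.shape[0]} and {P0.shape[0]}"
        )
    if params.structure.id != "linear" or params.order > 2:
        out = np.empty((S0.shape[1], P0.shape[1]))
        for i in range(S0.shape[1]):
            for u in range(P0.shape[1]):
                out[i, u] = rhofm_score(params, S0[:, i], P0[:, u])
        return out
    W = params.W
    Zi, Zu = S0.T @ W, P0.T @ W
    linear = (Zi * params.omega1).sum(1)[:, None] + (Zu * params.omega1).sum(1)[None, :]
    Qi = ((S0.T**2) @ (W**2)).sum(axis=1)
    Qu = ((P0.T**2) @ (W**2)).sum(axis=1)
    sq = (Zi**2).sum(1)[:, None] + 2.0 * Zi @ Zu.T + (Zu**2).sum(1)[None, :]
    pair = 0.5 * params.omega2m[0] * (sq - Qi[:, None] - Qu[None, :])
    return params.omega0 + linear + pair


def feature_importance(params: RHOFMParams, x: np.ndarray | None = None) -> np.ndarray:
    """Intrinsic importance scores (row sums of W), or the attribution for x.

    Valid as stated only in interpretable mode (constant mixing weights);
    otherwise a warning is raised and the row sums are still returned.
    """
    if not params.interpretable:
        warnings.warn(
            "feature importance assumes constant mixing weights "
            "(omega1 and omega2m); scores may not be attributable as-is",
            stacklevel=2,
        )
    s = params.W.sum(axis=1)
    if x is None:
        return s
    return _impute(x) * s


def predict_label(
    params: RHOFMParams, xi: np.ndarray, xu: np.ndarray, mode: str = "factored"
):
    """Predict the association label: +1 iff sigmoid(score) > 0.5.

    Returns ``(label, probability)``; the boundary sigmoid(0) = 0.5 maps
    to -1 (strict inequality).
    """
    raw = rhofm_score(params, xi, xu, mode=mode)
    prob = sigmoid(raw)
    return (1 if prob > 0.5 else -1), prob


@dataclass
class FMParams:
    """Parameters of an unstructured second-order FM on a length-q input."""

    omega0: float
    omega1: np.ndarray  # (q,)
    omega2: np.ndarray  # (q, d)

    def __post_init__(self) -> None:
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega2 = np.asarray(self.omega2, dtype=float)
        if self.omega2.shape[0] != self.omega1.shape[0]:
            raise ValueError("omega1 and omega2 must agree on the input length")


def fm_score(theta: FMParams, x: np.ndarray) -> float:
    """Second-order factorization machine on the concatenated input.

    Uses the degree-2 kernel identity
    ``sum_{f<f'} <v_f, v_f'> x_f x_f' = 0.5 * (||X v||^2-ish expansion)``.
    """
    x = _impute(x)
    if x.shape != theta.omega1.shape:
        raise ValueError(f"input length {x.shape} != {theta.omega1.shape}")
    z = x @ theta.omega2  # (d,)
    pair = 0.5 * float((z**2).sum() - ((x[:, None] * theta.omega2) ** 2).sum())
    return theta.omega0 + float(theta.omega1 @ x) + pair


def crossfm_score(theta: FMParams, xi: np.ndarray, xu: np.ndarray) -> float:
    """FM variant keeping only item-by-user feature interaction pairs."""
    xi, xu = _impute(xi), _impute(xu)
    F = xi.shape[0]
    if xu.shape[0] != F or theta.omega1.shape[0] != 2 * F:
        raise ValueError("crossfm expects omega over the concatenated 2F input")
    zi = xi @ theta.omega2[:F]
    zu = xu @ theta.omega2[F:]
    return theta.omega0 + float(theta.omega1 @ np.concatenate([xi, xu])) + float(zi @ zu)


def hofm_bruteforce(theta, x: np.ndarray, m: int) -> float:
    """Exhaustive-enumeration HOFM evaluation (test oracle, small inputs).

    ``theta`` is ``(omega0, omega1, [omega_t for t=2..m])`` with omega_t of
    shape (q, d_t). Enumerates every strictly increasing index tuple.
    """
    omega0, omega1, higher = theta
    x = _impute(x)
    q = x.shape[0]
    total_tuples = sum(math.comb(q, t) for t in range(2, m + 1))
    if total_tuples > 200_000:
        raise ValueError(f"instance too large for brute force ({total_tuples} tuples)")
    score = float(omega0) + float(np.asarray(omega1) @ x)
    for t in range(2, m + 1):
        V = np.asarray(higher[t - 2], dtype=float)
        for idx in combinations(range(q), t):
            rows = V[list(idx)]
            score += float(np.prod(rows, axis=0).sum() * np.prod(x[list(idx)]))
    return score
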