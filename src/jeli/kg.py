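"""Similarity-based knowledge graph over items, users and features.

The graph has nine relation labels: an optional ``prior`` edge list,
signed association edges (``+``/``-``) copied from the nonzero cells of
the association matrix, similarity edges between users and between items
whose feature vectors exceed a cosine-similarity threshold tau, and signed
entity-feature edges given by the signs of the feature tables. Missing
feature entries produce no edge. Similarity edges are stored once in a
canonical direction (lower index first) and never as self-loops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["RELATIONS", "KnowledgeGraph", "similarity", "build_knowledge_graph",
           "save_graph", "load_graph", "read_prior_edges"]

RELATIONS = (
    "prior",
    "+",
    "-",
    "user-sim",
    "item-sim",
    "item-feat-pos",
    "item-feat-neg",
    "user-feat-pos",
    "user-feat-neg",
)


@dataclass
class KnowledgeGraph:
    items: list[str]
    users: list[str]
    features: list[str]
    prior_entities: list[str] = field(default_factory=list)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def entities(self) -> list[str]:
        return self.items + self.users + self.features + self.prior_entities

    @property
    def partitions(self) -> dict[str, str]:
        """Map each entity to its partition name."""
        out = {e: "item" for e in self.items}
        out.update({e: "user" for e in self.users})
        out.update({e: "feature" for e in self.features})
        out.update({e: "prior" for e in self.prior_entities})
        return out

    def count(self, relation: str) -> int:
        return sum(1 for _, r, _ in self.triplets if r == relation)


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; zero vectors map to 0, NaN to 0."""
    u = np.nan_to_num(np.asarray(u, dtype=float))
    v = np.nan_to_num(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError(f"length mismatch {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of the columns of X (NaN -> 0)."""
    X = np.nan_to_num(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=0)
    safe = np.where(norms == 0.0, 1.0, norms)
    Xn = X / safe
    C = Xn.T @ Xn
    C[norms == 0.0, :] = 0.0
    C[:, norms == 0.0] = 0.0
    return np.clip(C, -1.0, 1.0)


def build_knowledge_graph(
    A: np.ndarray,
    S: np.ndarray,
    P: np.ndarray,
    prior: list[tuple[str, str]] | None = None,
    tau: float = 0.5,
) -> KnowledgeGraph:
    """Assemble the nine-relation graph from A, S, P and a prior edge list.

    Prior edges may reference item/user/feature names or new entities;
    unknown endpoints are registered as prior-only nodes (and logged).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    A = np.asarray(A)
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    if S.shape[0] != P.shape[0]:
        raise ValueError("S and P must share the feature axis")
    if A.shape != (S.shape[1], P.shape[1]):
        raise ValueError(
            f"A has shape {A.shape}, expected ({S.shape[1]}, {P.shape[1]})"
        )
    n_i, n_u = A.shape
    F = S.shape[0]
    items = [f"i{j + 1}" for j in range(n_i)]
    users = [f"u{j + 1}" for j in range(n_u)]
    features = [f"f{j + 1}" for j in range(F)]
    known = set(items) | set(users) | set(features)

    triplets: list[tuple[str, str, str]] = []
    prior_entities: list[str] = []
    seen_prior: set[tuple[str, str]] = set()
    for s, t in (prior or []):
        if (s, t) in seen_prior:
            continue
        seen_prior.add((s, t))
        for endpoint in (s, t):
            if endpoint not in known and endpoint not in prior_entities:
                prior_entities.append(endpoint)
                logger.info("prior edge endpoint %r registered as a new entity", endpoint)
        triplets.append((s, "prior", t))

    pos = np.argwhere(A == 1)
    neg = np.argwhere(A == -1)
    triplets += [(items[i], "+", users[u]) for i, u in pos]
    triplets += [(items[i], "-", users[u]) for i, u in neg]

    for names, X, rel in ((users, P, "user-sim"), (items, S, "item-sim")):
        C = _cosine_matrix(X)
        j_idx, k_idx = np.where(np.triu(C, k=1) > tau)
        triplets += [(names[j], rel, names[k]) for j, k in zip(j_idx, k_idx)]

    for names, X, rel_pos, rel_neg in (
        (items, S, "item-feat-pos", "item-feat-neg"),
        (users, P, "user-feat-pos", "user-feat-neg"),
    ):
        with np.errstate(invalid="ignore"):
            f_idx, j_idx = np.where(X > 0)
            triplets += [(names[j], rel_pos, features[f]) for f, j in zip(f_idx, j_idx)]
            f_idx, j_idx = np.where(X < 0)
            triplets += [(names[j], rel_neg, features[f]) for f, j in zip(f_idx, j_idx)]

    return KnowledgeGraph(
        items=items, users=users, features=features,
        prior_entities=prior_entities, triplets=triplets,
    )


def save_graph(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the triplets as 3-column TSV with a partition sidecar JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        for h, r, t in graph.triplets:
            fh.write(f"{h}\t{r}\t{t}\n")
    sidecar = {
        "items": graph.items,
        "users": graph.users,
        "features": graph.features,
        "prior_entities": graph.prior_entities,
    }
    path.with_suffix(path.suffix + ".entities.json").write_text(json.dumps(sidecar))


def load_graph(path: str | Path) -> KnowledgeGraph:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".entities.json").read_text())
    triplets = []
    with open(path) as fh:
        for line in fh:
            h, r, t = line.rstrip("\n").split("\t")
            if r not in RELATIONS:
                raise ValueError(f"unknown relation label {r!r}")
            triplets.append((h, r, t))
    return KnowledgeGraph(triplets=triplets, **sidecar)


def read_prior_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read a prior edge list: 2- or 3-column TSV (relation column ignored)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) == 3:
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"malformed prior edge line: {line!r}")
    return edges
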