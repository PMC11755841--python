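"""Dataset loading/validation and model archive round trips."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .datasets import _read_table
from .kg import read_prior_edges
from .model import JELIParams
from .rhofm import LINEAR_STRUCTURE, RHOFMParams, StructureSpec

logger = logging.getLogger(__name__)

__all__ = ["load_dataset", "save_model", "load_model", "MODEL_FORMAT_VERSION"]

MODEL_FORMAT_VERSION = "jeli-model-1"


def load_dataset(a_path, s_path, p_path, prior_path=None):
    """Read and validate (A, S, P, prior) from TSV tables.

    Empty fields become NaN in the feature tables; the association matrix
    must hold only {-1, 0, +1} and match the feature tables' entity
    counts. A missing prior file yields an empty edge list (logged).
    """
    A = _read_table(Path(a_path))
    S = _read_table(Path(s_path))
    P = _read_table(Path(p_path))
    if np.isnan(A).any():
        i, u = np.argwhere(np.isnan(A))[0]
        raise ValueError(f"association matrix has a missing value at cell ({i + 1}, {u + 1})")
    bad = np.argwhere(~np.isin(A, (-1.0, 0.0, 1.0)))
    if len(bad):
        i, u = bad[0]
        raise ValueError(
            f"association value {A[i, u]!r} at row i{i + 1}, column u{u + 1} "
            "is outside {-1, 0, +1}"
        )
    if S.shape[0] != P.shape[0]:
        raise ValueError(
            f"feature-axis mismatch: S has {S.shape[0]} features, P has {P.shape[0]}"
        )
    if A.shape != (S.shape[1], P.shape[1]):
        raise ValueError(
            f"A is {A.shape} but S/P describe ({S.shape[1]}, {P.shape[1]}) entities"
        )
    prior = []
    if prior_path is not None:
        if Path(prior_path).exists():
            prior = read_prior_edges(prior_path)
        else:
            logger.info("prior file %s not found; using an empty prior graph", prior_path)
    logger.info(
        "loaded dataset: %d items x %d users, %d features, sparsity %.3f",
        A.shape[0], A.shape[1], S.shape[0], float(np.mean(A == 0)),
    )
    return A.astype(np.int8), S, P, prior


def save_model(params: JELIParams, path) -> None:
    """Write all parameter arrays plus metadata to one .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rhofm = params.rhofm
    bias_names = list(params.entity_biases)
    meta = {
        "version": MODEL_FORMAT_VERSION,
        "order": rhofm.order,
        "dim": rhofm.dim,
        "n_features": rhofm.n_features,
        "ridge": rhofm.ridge,
        "structure": rhofm.structure.id,
        "interpretable": bool(rhofm.interpretable),
        "relations": list(params.rel_matrices),
        "bias_entities": bias_names,
    }
    arrays = {
        "W": rhofm.W,
        "omega0": np.asarray(rhofm.omega0),
        "omega1": rhofm.omega1,
        "omega2m": rhofm.omega2m,
        "biases": np.array([params.entity_biases[n] for n in bias_names]),
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    for r in params.rel_matrices:
        arrays[f"R_{r}"] = params.rel_matrices[r]
        arrays[f"e_{r}"] = params.rel_embeddings[r]
    np.savez(path, **arrays)


def load_model(path, structure: StructureSpec | None = None) -> JELIParams:
    """Read a model archive; fails cleanly on version mismatch or truncation."""
    try:
        with np.load(Path(path)) as archive:
            data = {k: archive[k] for k in archive.files}
    except Exception as exc:
        raise ValueError(f"unreadable model archive {path}: {exc}") from exc
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {meta.get('version')!r} does not match {MODEL_FORMAT_VERSION!r}"
        )
    if structure is None:
        if meta["structure"] != "linear":
            raise ValueError("non-linear structures need an explicit StructureSpec")
        structure = LINEAR_STRUCTURE
    rhofm = RHOFMParams(
        W=data["W"], omega0=float(data["omega0"]), omega1=data["omega1"],
        omega2m=data["omega2m"], order=int(meta["order"]),
        ridge=float(meta["ridge"]), structure=structure,
    )
    return JELIParams(
        rhofm=rhofm,
        rel_matrices={r: data[f"R_{r}"] for r in meta["relations"]},
        rel_embeddings={r: data[f"e_{r}"] for r in meta["relations"]},
        entity_biases=dict(zip(meta["bias_entities"], data["biases"].tolist())),
    )
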