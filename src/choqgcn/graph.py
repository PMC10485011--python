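"""Patient-similarity graphs from sample-sample Pearson correlation.

Nodes are samples; an edge joins two samples whose correlation across
features reaches a threshold. The propagation matrix used downstream is the
symmetric normalization D^{-1/2} A D^{-1/2} (with self-loops by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleGraph",
    "pearson_matrix",
    "build_adjacency",
    "normalize_adjacency",
    "build_graph",
]


@dataclass
class SampleGraph:
    """Adjacency, degrees and normalized propagation matrix over patient nodes."""

    node_ids: list[str]
    A: np.ndarray
    degree: np.ndarray
    A_norm: np.ndarray
    X: np.ndarray | None = None
    threshold: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def edge_list(self, R: np.ndarray | None = None) -> pd.DataFrame:
        """Upper-triangle edges as (source_id, target_id, correlation)."""
        i, j = np.nonzero(np.triu(self.A, k=1))
        corr = R[i, j] if R is not None else np.ones(i.size)
        return pd.DataFrame(
            {
                "source_id": [self.node_ids[a] for a in i],
                "target_id": [self.node_ids[b] for b in j],
                "correlation": corr,
            }
        )

    def to_edge_tsv(self, path: str | Path, R: np.ndarray | None = None) -> None:
        self.edge_list(R).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        i, j = np.nonzero(np.triu(self.A, k=1))
        g.add_edges_from(
            (self.node_ids[a], self.node_ids[b]) for a, b in zip(i, j)
        )
        nx.write_graphml(g, path)


def adjacency_from_edge_tsv(path: str | Path, node_ids: Sequence[str]) -> np.ndarray:
    """Rebuild a binary adjacency from an edge-list TSV (round-trip of export)."""
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    pos = {s: i for i, s in enumerate(node_ids)}
    A = np.zeros((len(node_ids), len(node_ids)))
    for s, t in zip(df["source_id"], df["target_id"]):
        A[pos[s], pos[t]] = A[pos[t], pos[s]] = 1.0
    return A


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Sample-sample Pearson correlation matrix (rows are samples).

    Zero-variance rows get correlation 0 against everything (with a
    warning); the diagonal is exactly 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if X.shape[1] < 2:
        raise ValueError("correlation ill-defined with a single feature")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows: correlation set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def build_adjacency(
    R: np.ndarray, threshold: float, absolute: bool = False
) -> np.ndarray:
    """Binary adjacency: edge (i, j), i != j, iff R_ij >= threshold.

    With ``absolute=True`` the rule is |R_ij| >= threshold. The diagonal is
    zero (self-loops are added later by :func:`normalize_adjacency`).
    """
    R = np.asarray(R, dtype=float)
    if not -1.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [-1, 1]")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    val = np.abs(R) if absolute else R
    A = (val >= threshold).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def normalize_adjacency(A: np.ndarray, add_self_loops: bool = True) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2}.

    By default self-loops are added first (A~ = A + I), guaranteeing every
    degree >= 1. Without them, isolated nodes yield zero rows (warned).
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(A.shape[0]) if add_self_loops else A
    deg = A_tilde.sum(axis=1)
    if (deg == 0).any():
        warnings.warn(
            f"{int((deg == 0).sum())} isolated nodes: zero rows in A_norm"
        )
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_graph(
    X: np.ndarray,
    node_ids: Sequence[str],
    threshold: float,
    absolute: bool = False,
    add_self_loops: bool = True,
) -> SampleGraph:
    """Correlation-threshold graph plus its normalized propagation matrix."""
    R = pearson_matrix(X)
    A = build_adjacency(R, threshold, absolute=absolute)
    A_norm = normalize_adjacency(A, add_self_loops=add_self_loops)
    return SampleGraph(
        node_ids=list(node_ids),
        A=A,
        degree=A.sum(axis=1),
        A_norm=A_norm,
        X=np.asarray(X, dtype=float),
        threshold=threshold,
    )
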