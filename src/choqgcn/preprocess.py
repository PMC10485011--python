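"""Preprocessing for multi-omics survival cohorts.

Turns raw modality tables into the normalized/discretized, imputed and
mRMR-reduced matrices consumed by the graph and classifier stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "OmicsMatrix",
    "LabelVector",
    "minmax_normalize",
    "discretize_expression",
    "impute_knn_weighted",
    "mrmr_select",
    "search_feature_count",
    "smote_oversample",
]

#: Declared value domains per modality.
ALPHABETS = {
    "GE": frozenset({-1.0, 0.0, 1.0}),
    "CNA": frozenset({-2.0, -1.0, 0.0, 1.0, 2.0}),
    "CLN": "unit_interval",
    "REAL": "real",
}


@dataclass
class OmicsMatrix:
    """One modality's samples x features table with a declared value alphabet.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (no duplicates)
    feature_ids : ordered feature identifiers (no duplicates)
    values : float array of shape (n_samples, n_features)
    modality : one of ``{"GE", "CNA", "CLN"}`` (or ``"REAL"`` for raw input)
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: str = "REAL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample identifiers")
        if len(self.feature_ids) != len(set(self.feature_ids)):
            raise ValueError("duplicate feature identifiers")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.modality not in ALPHABETS:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def check_alphabet(self) -> bool:
        """True iff every (non-missing) value lies in the declared alphabet."""
        vals = self.values[np.isfinite(self.values)]
        alphabet = ALPHABETS[self.modality]
        if alphabet == "real":
            return True
        if alphabet == "unit_interval":
            return bool(np.all((vals >= 0.0) & (vals <= 1.0)))
        return bool(np.all(np.isin(vals, sorted(alphabet))))

    def subset_features(self, index: Sequence[int]) -> "OmicsMatrix":
        index = list(index)
        return OmicsMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in index],
            values=self.values[:, index],
            modality=self.modality,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str = "REAL") -> "OmicsMatrix":
        """Read a TSV whose first column is ``sample_id``; empty/NA cells -> NaN."""
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
        if df.columns[0] != "sample_id":
            raise ValueError(f"{path}: first column must be 'sample_id'")
        values = df.iloc[:, 1:].to_numpy()
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric entry in data matrix") from exc
        return cls(
            sample_ids=df["sample_id"].tolist(),
            feature_ids=df.columns[1:].tolist(),
            values=values,
            modality=modality,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class LabelVector:
    """Binary survival labels: 1 = short-term survivor, 0 = long-term."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample identifiers")
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match sample_ids")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelVector":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if not {"sample_id", "label"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'sample_id' and 'label'")
        return cls(sample_ids=df["sample_id"].tolist(), y=df["label"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "label": self.y}).to_csv(
            path, sep="\t", index=False
        )

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Labels reordered to match ``sample_ids``; raises on mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise ValueError(f"sample id {exc.args[0]!r} has no label") from exc
        return self.y[idx]


def _as_float_matrix(X: np.ndarray) -> np.ndarray:
    try:
        X = np.asarray(X, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric entries in input matrix") from exc
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("input must be a 2-D matrix with at least one row")
    return X


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Column-wise map x -> (x - min) / (max - min) into [0, 1].

    Constant columns map to 0 by convention.
    """
    X = _as_float_matrix(X)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


def discretize_expression(X: np.ndarray, z_cut: float = 1.0) -> np.ndarray:
    """Trichotomize each column by z-score into {-1, 0, +1}.

    Values with z < -z_cut become -1 (under-expression), z > +z_cut become +1
    (over-expression), the rest 0 (baseline). Zero-variance columns map to 0.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    X = _as_float_matrix(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    nz = sd > 0
    z = (X[:, nz] - mu[nz]) / sd[nz]
    out[:, nz] = np.where(z > z_cut, 1.0, np.where(z < -z_cut, -1.0, 0.0))
    return out


def impute_knn_weighted(
    X: np.ndarray, k: int = 5, eps: float = 1e-8
) -> np.ndarray:
    """Fill missing cells with a distance-weighted k-nearest-row average.

    For a missing cell (i, j), candidate donors are the rows observed at
    feature j; distance to row i is the Euclidean distance over features
    co-observed by both rows, weights are 1 / (eps + distance). Observed
    cells are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _as_float_matrix(X)
    missing = ~np.isfinite(X)
    if not missing.any():
        return X.copy()
    if np.all(missing, axis=1).any():
        raise ValueError("every row must have at least one observed value")
    if np.all(missing, axis=0).any():
        j = int(np.flatnonzero(np.all(missing, axis=0))[0])
        raise ValueError(f"feature column {j} is missing in all rows")

    out = X.copy()
    n = X.shape[0]
    for i, j in zip(*np.nonzero(missing)):
        donors = np.flatnonzero(~missing[:, j] & (np.arange(n) != i))
        dists = np.full(donors.shape, np.inf)
        for d, r in enumerate(donors):
            shared = ~missing[i] & ~missing[r]
            if shared.any():
                diff = X[i, shared] - X[r, shared]
                dists[d] = float(np.sqrt(np.sum(diff * diff)))
        order = np.argsort(dists, kind="stable")[: min(k, donors.size)]
        near = donors[order]
        w = 1.0 / (eps + dists[order])
        out[i, j] = float(np.sum(w * X[near, j]) / np.sum(w))
    return out


def _codes(a: np.ndarray) -> tuple[np.ndarray, int]:
    vals, inv = np.unique(a, return_inverse=True)
    return inv.astype(np.int64), len(vals)


def _mi_codes(ca: np.ndarray, na: int, cb: np.ndarray, nb: int) -> float:
    """Plug-in mutual information (nats) from integer-coded columns.

    Equivalent to sklearn's mutual_info_score, but fast enough to call tens
    of thousands of times inside the greedy mRMR loop.
    """
    n = ca.size
    joint = np.bincount(ca * nb + cb, minlength=na * nb).astype(float)
    joint = joint[joint > 0] / n
    pa = np.bincount(ca, minlength=na) / n
    pb = np.bincount(cb, minlength=nb) / n
    outer = np.outer(pa, pb).ravel()
    outer = outer[np.bincount(ca * nb + cb, minlength=na * nb) > 0]
    return float(np.sum(joint * np.log(joint / outer)))


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    # plug-in mutual information on empirical joint frequencies (nats)
    ca, na = _codes(a)
    cb, nb = _codes(b)
    return _mi_codes(ca, na, cb, nb)


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    n_features: int,
    criterion: str = "MID",
) -> list[int]:
    """Greedy forward mRMR on discrete-valued columns.

    MID score of a candidate f given selected set S is
    ``I(f; y) - mean_{s in S} I(f; s)`` (MIQ divides instead). The first
    pick is the argmax of I(f; y); ties break to the lowest column index.
    Returns the ordered list of selected column indices.
    """
    X = _as_float_matrix(X)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y row counts differ")
    if len(np.unique(y)) < 2:
        raise ValueError("relevance undefined: y is constant")
    p = X.shape[1]
    if not 1 <= n_features <= p:
        raise ValueError("n_features must be in [1, n_features_total]")
    if criterion not in {"MID", "MIQ"}:
        raise ValueError("criterion must be 'MID' or 'MIQ'")

    codes = [_codes(X[:, j]) for j in range(p)]
    cy, ny = _codes(y)
    relevance = np.array([_mi_codes(c, nc, cy, ny) for c, nc in codes])

    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(p) if j != selected[0]]
    # redundancy[j] accumulates sum of I(f_j; f_s) over selected s
    redundancy = np.zeros(p)
    while len(selected) < n_features:
        cl, nl = codes[selected[-1]]
        for j in remaining:
            cj, nj = codes[j]
            redundancy[j] += _mi_codes(cj, nj, cl, nl)
        mean_red = redundancy[remaining] / len(selected)
        rel = relevance[remaining]
        if criterion == "MID":
            score = rel - mean_red
        else:
            score = rel / (mean_red + 1e-12)
        best = remaining[int(np.argmax(score))]  # argmax ties -> lowest index
        selected.append(best)
        remaining.remove(best)
    return selected


def search_feature_count(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[int],
    seed: int = 0,
    val_fraction: float = 0.25,
) -> int:
    """Pick the feature count with best validation AUC of a fast linear proxy.

    A single mRMR ranking up to ``max(candidates)`` is computed; for each
    candidate N a logistic-regression proxy is scored by ROC-AUC on a
    stratified held-out split. Ties go to the smaller N.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidates must be nonempty")
    X = _as_float_matrix(X)
    n_max = min(max(candidates), X.shape[1])
    ranking = mrmr_select(X, y, n_max)

    tr, va = train_test_split(
        np.arange(X.shape[0]),
        test_size=val_fraction,
        stratify=y,
        random_state=seed,
    )
    best_n, best_auc = candidates[0], -np.inf
    for n in candidates:
        idx = ranking[: min(n, n_max)]
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(X[np.ix_(tr, idx)], y[tr])
        auc = roc_auc_score(y[va], clf.predict_proba(X[np.ix_(va, idx)])[:, 1])
        if auc > best_auc + 1e-12:
            best_auc, best_n = auc, n
    return best_n


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic point is ``x + u * (x_n - x)`` for a random minority
    sample x, one of its k nearest minority neighbours x_n and
    u ~ Uniform(0, 1). Original rows are preserved verbatim; output class
    counts are equal.
    """
    X = _as_float_matrix(X)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    idx_min = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)

    if idx_min.size == 1:
        warnings.warn("single minority sample: falling back to duplication")
        X_new = np.repeat(X[idx_min], n_needed, axis=0)
    else:
        if idx_min.size <= k:
            k = idx_min.size - 1
            warnings.warn(f"minority class smaller than k+1: reducing k to {k}")
        Xm = X[idx_min]
        d2 = np.sum((Xm[:, None, :] - Xm[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]
        rows = rng.integers(0, idx_min.size, size=n_needed)
        picks = neighbours[rows, rng.integers(0, k, size=n_needed)]
        u = rng.random(n_needed)[:, None]
        X_new = Xm[rows] + u * (Xm[picks] - Xm[rows])

    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    return X_out, y_out
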