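"""Choquet fuzzy-integral fusion of probabilistic classifiers.

A λ-fuzzy (Sugeno) measure on classifier subsets is built from per-classifier
densities g_j derived from validation accuracies; the single interaction
parameter λ > -1 solves 1 + λ = Π_j (1 + g_j λ). Per-sample class
confidences are then aggregated with the Choquet integral
Σ_i (s_i - s_{i-1}) μ(A_i) over the ascending-sorted scores, where A_i is the
suffix set of classifiers at or above rank i.

When the densities are normalized to sum to 1 — the default construction —
the unique admissible λ is 0, the measure is additive, and the fusion
reduces exactly to the density-weighted arithmetic mean of the confidences.
Unnormalized densities (λ != 0) are available via ``normalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FuzzyMeasure",
    "ScoreMatrix",
    "fuzzy_densities",
    "solve_lambda",
    "subset_measure",
    "choquet_integral",
    "ensemble_predict",
]

_SUM_TOL = 1e-12


def fuzzy_densities(validation_scores: Sequence[float]) -> np.ndarray:
    """Normalized densities g_j = score_j / Σ score_j (sum to 1)."""
    s = np.asarray(validation_scores, dtype=float)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("validation_scores must be a nonempty 1-D sequence")
    if (s <= 0).any():
        raise ValueError("validation scores must be strictly positive")
    return s / s.sum()


def _lambda_poly(densities: np.ndarray) -> np.ndarray:
    # ascending coefficients of h(x) = [prod(1 + g_i x) - 1]/x - 1, whose
    # root is the nontrivial solution of the lambda equation
    c = np.array([1.0])
    for g in densities:
        c = np.polynomial.polynomial.polymul(c, [1.0, g])
    h = c[1:].copy()
    h[0] -= 1.0
    return h


def solve_lambda(densities: Sequence[float]) -> float:
    """Root of 1 + λ = Π (1 + g_j λ) with λ > -1.

    Σg = 1 forces the additive case λ = 0 exactly. Otherwise the trivial
    root at 0 is factored out and the unique remaining root is bracketed —
    in (0, ∞) when Σg < 1 and in (-1, 0) when Σg > 1 — and solved to a
    residual below 1e-12.
    """
    g = np.asarray(densities, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two densities")
    if (g <= 0).any() or (g >= 1).any():
        raise ValueError("densities must lie strictly in (0, 1)")
    total = float(g.sum())
    if abs(total - 1.0) <= _SUM_TOL:
        return 0.0

    h = _lambda_poly(g)
    hfun = lambda x: float(np.polynomial.polynomial.polyval(x, h))
    if total < 1.0:
        lo, hi = 0.0, 1.0
        while hfun(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                raise ArithmeticError(
                    f"no admissible lambda root found (densities={g.tolist()})"
                )
    else:
        lo, hi = -1.0, 0.0
    lam = float(brentq(hfun, lo, hi, xtol=1e-15, rtol=8.9e-16))
    residual = abs(np.prod(1.0 + g * lam) - (1.0 + lam))
    if residual > 1e-12:
        raise ArithmeticError(
            f"lambda root residual {residual:.2e} exceeds tolerance "
            f"(lam={lam}, densities={g.tolist()})"
        )
    return lam


def subset_measure(
    subset: Iterable[int], densities: Sequence[float], lam: float
) -> float:
    """λ-measure of a classifier subset, folding the pairwise rule.

    μ(∅) = 0; μ({j}) = g_j; μ(S ∪ {j}) = μ(S) + g_j + λ μ(S) g_j. The fold
    is order-independent for λ-measures; the full set measures 1 (within
    1e-9) by construction of λ.
    """
    g = np.asarray(densities, dtype=float)
    idx = sorted(set(int(i) for i in subset))
    if idx and (idx[0] < 0 or idx[-1] >= g.size):
        raise KeyError(f"unknown classifier index in subset {idx}")
    mu = 0.0
    for i in idx:
        mu = mu + g[i] + lam * mu * g[i]
    if len(idx) == g.size and abs(mu - 1.0) > 1e-9:
        raise ArithmeticError(f"full-set measure {mu} deviates from 1")
    return float(mu)


def choquet_integral(
    sorted_scores: Sequence[float], suffix_measures: Sequence[float]
) -> float:
    """Σ_i (s_i - s_{i-1}) μ(A_i) with s_0 = 0 and scores sorted ascending.

    ``suffix_measures[i]`` is μ({C_i, ..., C_m}) under the caller's sort.
    The result always lies between min and max score when μ(A_1) = 1.
    """
    s = np.asarray(sorted_scores, dtype=float)
    mu = np.asarray(suffix_measures, dtype=float)
    if s.shape != mu.shape:
        raise ValueError("scores and suffix measures must align")
    if np.any(np.diff(s) < 0):
        raise ValueError("scores must be sorted ascending")
    prev = np.concatenate([[0.0], s[:-1]])
    return float(np.sum((s - prev) * mu))


@dataclass
class FuzzyMeasure:
    """Densities, λ and the induced measure over classifier subsets."""

    classifier_ids: list[str]
    densities: np.ndarray
    lam: float = field(init=False)
    _table: dict[frozenset[int], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.classifier_ids) != self.densities.size:
            raise ValueError("one density per classifier required")
        self.lam = solve_lambda(self.densities)
        m = self.densities.size
        self._table = {}
        for r in range(m + 1):
            for combo in combinations(range(m), r):
                self._table[frozenset(combo)] = subset_measure(
                    combo, self.densities, self.lam
                )

    @classmethod
    def from_validation_scores(
        cls,
        classifier_ids: Sequence[str],
        validation_scores: Sequence[float],
        normalize: bool = True,
    ) -> "FuzzyMeasure":
        """Build from positive validation accuracies.

        ``normalize=True`` (the default) uses g_j = score_j / Σ score_j,
        which makes the measure additive (λ = 0); ``normalize=False`` keeps
        the raw accuracies as densities, giving a genuinely non-additive
        measure whenever they do not sum to 1.
        """
        s = np.asarray(validation_scores, dtype=float)
        if (s <= 0).any():
            raise ValueError("validation scores must be strictly positive")
        g = fuzzy_densities(s) if normalize else s
        return cls(classifier_ids=list(classifier_ids), densities=g)

    def measure(self, subset: Iterable[str | int]) -> float:
        idx = []
        for c in subset:
            if isinstance(c, str):
                try:
                    idx.append(self.classifier_ids.index(c))
                except ValueError as exc:
                    raise KeyError(f"unknown classifier id {c!r}") from exc
            else:
                if not 0 <= int(c) < len(self.classifier_ids):
                    raise KeyError(f"unknown classifier index {c}")
                idx.append(int(c))
        return self._table[frozenset(idx)]


@dataclass
class ScoreMatrix:
    """Per-sample, per-classifier, per-class confidences in [0, 1]."""

    sample_ids: list[str]
    classifier_ids: list[str]
    probs: np.ndarray  # (n_samples, n_classifiers, n_classes)
    validation_accuracies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("probs must have shape (samples, classifiers, classes)")
        n, m, _ = self.probs.shape
        if n != len(self.sample_ids) or m != len(self.classifier_ids):
            raise ValueError("probs shape does not match id lists")
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("confidences must lie in [0, 1]")
        rowsum = self.probs.sum(axis=2)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise ValueError("per-classifier class confidences must sum to 1")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "classifier_id": str})
        need = {"sample_id", "classifier_id", "p_class0", "p_class1"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        samples = list(dict.fromkeys(df["sample_id"]))
        clfs = list(dict.fromkeys(df["classifier_id"]))
        probs = np.full((len(samples), len(clfs), 2), np.nan)
        si = {s: i for i, s in enumerate(samples)}
        ci = {c: i for i, c in enumerate(clfs)}
        for _, row in df.iterrows():
            probs[si[row["sample_id"]], ci[row["classifier_id"]]] = (
                row["p_class0"],
                row["p_class1"],
            )
        if np.isnan(probs).any():
            raise ValueError(f"{path}: missing classifier scores for some samples")
        return cls(sample_ids=samples, classifier_ids=clfs, probs=probs)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for j, c in enumerate(self.classifier_ids):
                rows.append((s, c, self.probs[i, j, 0], self.probs[i, j, 1]))
        pd.DataFrame(
            rows, columns=["sample_id", "classifier_id", "p_class0", "p_class1"]
        ).to_csv(path, sep="\t", index=False)


def _fuse_class(scores: np.ndarray, measure: FuzzyMeasure) -> np.ndarray:
    """Choquet-fuse one class's (n_samples, m) confidence columns."""
    n, m = scores.shape
    fused = np.empty(n)
    for i in range(n):
        order = np.argsort(scores[i], kind="stable")  # ties -> classifier index
        s_sorted = scores[i][order]
        suffix = [
            measure._table[frozenset(order[j:].tolist())] for j in range(m)
        ]
        fused[i] = choquet_integral(s_sorted, suffix)
    return fused


def ensemble_predict(
    scores: ScoreMatrix,
    measure: FuzzyMeasure,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-classifier confidences; returns (fused class-1 probs, labels).

    Each class's confidences are fused separately with the Choquet integral,
    then the two fused scores are renormalized to sum to 1 so the 0.5
    threshold acts on a proper probability. Hard label is 1 iff the
    renormalized class-1 score exceeds the threshold.
    """
    if scores.classifier_ids != measure.classifier_ids:
        raise ValueError("score matrix and measure disagree on classifiers")
    fused0 = _fuse_class(scores.probs[:, :, 0], measure)
    fused1 = _fuse_class(scores.probs[:, :, 1], measure)
    total = fused0 + fused1
    total = np.where(total > 0, total, 1.0)
    p1 = fused1 / total
    labels = (p1 > threshold).astype(int)
    return p1, labels
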