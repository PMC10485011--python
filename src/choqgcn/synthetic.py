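"""Synthetic multi-omics cohorts with the structure the pipeline assumes.

A low-dimensional class-conditional Gaussian latent drives the informative
features of every modality, so that (a) informative columns carry
label signal and (b) same-class samples correlate — which is exactly what
the correlation-threshold graph stage needs to exhibit community structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .choquet import ScoreMatrix
from .preprocess import LabelVector, OmicsMatrix, discretize_expression, minmax_normalize

__all__ = ["CohortSpec", "generate_cohort", "generate_score_fixture"]

_CNA_BASE = np.array([0.05, 0.20, 0.50, 0.20, 0.05])  # P(-2..2) null columns


@dataclass
class CohortSpec:
    """Knobs of the generative model; defaults mirror a 1980-sample cohort
    with 491/1489 class imbalance and 400/200/25 feature widths."""

    n_samples: int = 1980
    minority_fraction: float = 491 / 1980
    n_ge: int = 400
    n_cna: int = 200
    n_cln: int = 25
    informative_fraction: float = 0.2
    effect_size: float = 2.0
    within_class_corr: float = 0.5
    latent_dim: int = 4
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minority_fraction < 1:
            raise ValueError("minority_fraction must be in (0, 1)")
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in (0, 1]")
        if min(self.n_samples, self.n_ge, self.n_cna, self.n_cln) < 1:
            raise ValueError("all counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.within_class_corr < 1:
            raise ValueError("within_class_corr must be in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


def _latent(spec: CohortSpec, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # class means +- effect_size/2 apart along the all-ones direction
    direction = np.ones(spec.latent_dim) / np.sqrt(spec.latent_dim)
    mu = np.outer(2.0 * y - 1.0, direction) * (spec.effect_size / 2.0)
    return mu + rng.standard_normal((y.size, spec.latent_dim))


def _ge_block(
    spec: CohortSpec, Z: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_inf = max(1, int(round(spec.informative_fraction * spec.n_ge)))
    raw = rng.standard_normal((spec.n_samples, spec.n_ge))
    w = spec.within_class_corr
    # informative loadings share a common latent direction so that rows of
    # the same class correlate across columns
    loadings = np.ones((n_inf, spec.latent_dim)) / np.sqrt(spec.latent_dim)
    loadings += 0.2 * rng.standard_normal((n_inf, spec.latent_dim))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    signal = Z @ loadings.T
    raw[:, :n_inf] = np.sqrt(w) * signal + np.sqrt(1.0 - w) * raw[:, :n_inf]
    ge = discretize_expression(raw, z_cut=1.0)
    return ge, np.arange(n_inf)


def _cna_block(
    spec: CohortSpec, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_samples
    n_inf = max(1, int(round(spec.informative_fraction * spec.n_cna)))
    values = np.empty((n, spec.n_cna))
    cats = np.arange(-2, 3)
    delta = min(0.15, 0.04 * spec.effect_size)
    # class-shifted categorical probabilities; half the informative columns
    # shift toward amplification for class 1, half toward deletion
    for j in range(spec.n_cna):
        if j < n_inf:
            shift = delta if j % 2 == 0 else -delta
            p1 = _CNA_BASE + shift * np.array([-0.5, -0.5, 0.0, 0.5, 0.5])
            p0 = _CNA_BASE - shift * np.array([-0.5, -0.5, 0.0, 0.5, 0.5])
            p1 = np.clip(p1, 1e-3, None)
            p0 = np.clip(p0, 1e-3, None)
            p1, p0 = p1 / p1.sum(), p0 / p0.sum()
            col = np.where(
                y == 1,
                rng.choice(cats, size=n, p=p1),
                rng.choice(cats, size=n, p=p0),
            )
        else:
            col = rng.choice(cats, size=n, p=_CNA_BASE)
        values[:, j] = col
    return values, np.arange(n_inf)


def _cln_block(
    spec: CohortSpec, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_inf = max(1, int(round(spec.informative_fraction * spec.n_cln)))
    raw = rng.standard_normal((spec.n_samples, spec.n_cln))
    raw[:, :n_inf] += np.outer(2.0 * y - 1.0, np.ones(n_inf)) * (spec.effect_size / 2.0)
    return minmax_normalize(raw), np.arange(n_inf)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, LabelVector, dict]:
    """Draw a fully seeded cohort; returns (GE, CNA, CLN, labels, truth).

    The truth record lists informative column ids per modality plus the
    latent parameters, for test assertions.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_samples) < spec.minority_fraction).astype(int)
    Z = _latent(spec, y, rng)

    ge, ge_inf = _ge_block(spec, Z, rng)
    cna, cna_inf = _cna_block(spec, y, rng)
    cln, cln_inf = _cln_block(spec, y, rng)

    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    ge_ids = [f"GE{j:04d}" for j in range(spec.n_ge)]
    cna_ids = [f"CNA{j:04d}" for j in range(spec.n_cna)]
    cln_ids = [f"CLN{j:03d}" for j in range(spec.n_cln)]

    if spec.missing_fraction > 0:
        for block in (ge, cna):
            holes = rng.random(block.shape) < spec.missing_fraction
            holes[:, 0] = False  # keep every row partially observed
            block[holes] = np.nan

    truth = {
        "informative_ge": [ge_ids[j] for j in ge_inf],
        "informative_cna": [cna_ids[j] for j in cna_inf],
        "informative_cln": [cln_ids[j] for j in cln_inf],
        "latent_dim": spec.latent_dim,
        "effect_size": spec.effect_size,
        "labels": y.copy(),
    }
    return (
        OmicsMatrix(sample_ids, ge_ids, ge, "GE"),
        OmicsMatrix(sample_ids, cna_ids, cna, "CNA"),
        OmicsMatrix(sample_ids, cln_ids, cln, "CLN"),
        LabelVector(sample_ids, y),
        truth,
    )


def write_cohort(
    out_dir: str | Path,
    ge: OmicsMatrix,
    cna: OmicsMatrix,
    cln: OmicsMatrix,
    labels: LabelVector,
    truth: dict | None = None,
) -> None:
    """Emit the TSV dialect the preprocessing/pipeline stages consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ge.to_tsv(out / "ge.tsv")
    cna.to_tsv(out / "cna.tsv")
    cln.to_tsv(out / "cln.tsv")
    labels.to_tsv(out / "labels.tsv")
    if truth is not None:
        rows = [
            (mod, fid)
            for mod, key in (
                ("GE", "informative_ge"),
                ("CNA", "informative_cna"),
                ("CLN", "informative_cln"),
            )
            for fid in truth[key]
        ]
        pd.DataFrame(rows, columns=["modality", "feature_id"]).to_csv(
            out / "truth.tsv", sep="\t", index=False
        )


def generate_score_fixture(
    n_samples: int,
    m_classifiers: int = 3,
    agreement_level: float = 0.5,
    strength: float = 1.5,
    seed: int = 0,
) -> tuple[ScoreMatrix, np.ndarray]:
    """Correlated-classifier confidence fixture for testing the fusion layer.

    Each classifier's class-1 logit is ``strength * (2y - 1)`` plus noise
    that is shared across classifiers with weight ``agreement_level`` —
    at 1 all classifiers emit identical confidences, at 0 their errors are
    independent.
    """
    if not 0 <= agreement_level <= 1:
        raise ValueError("agreement_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_samples)
    shared = rng.standard_normal(n_samples)
    probs = np.empty((n_samples, m_classifiers, 2))
    for j in range(m_classifiers):
        own = rng.standard_normal(n_samples)
        noise = np.sqrt(agreement_level) * shared + np.sqrt(1 - agreement_level) * own
        logit = strength * (2 * y - 1) + noise
        p1 = 1.0 / (1.0 + np.exp(-logit))
        probs[:, j, 0] = 1.0 - p1
        probs[:, j, 1] = p1
    sm = ScoreMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n_samples)],
        classifier_ids=[f"C{j + 1}" for j in range(m_classifiers)],
        probs=probs,
    )
    return sm, y
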