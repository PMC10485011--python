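"""End-to-end orchestration: per-modality selection/graphs/GCN, feature
stacking, base classifiers, Choquet fusion and 10-fold evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .choquet import FuzzyMeasure, ScoreMatrix, ensemble_predict
from .gcn import GCNConfig, extract_embeddings, train_gcn
from .graph import build_graph
from .preprocess import (
    LabelVector,
    OmicsMatrix,
    minmax_normalize,
    mrmr_select,
    search_feature_count,
    smote_oversample,
)

__all__ = [
    "PipelineConfig",
    "FoldResult",
    "stack_features",
    "train_base_classifiers",
    "compute_metrics",
    "run_fold",
    "run_cross_validation",
]

METRIC_NAMES = ["Acc", "Mcc", "Pre", "Sn", "Sp", "Bal_Acc", "F1", "AUC"]
CLASSIFIER_IDS = ["LR", "SVM", "RF"]


@dataclass
class PipelineConfig:
    """Flat configuration mirrored by the YAML config file."""

    modalities: tuple[str, ...] = ("GE", "CNA", "CLN")
    ge_threshold: float = 0.3
    cna_threshold: float = 0.6
    absolute_correlation: bool = False
    add_self_loops: bool = True
    n_folds: int = 10
    validation_fraction: float = 0.20
    seed: int = 0
    mrmr_n_ge: int | None = None
    mrmr_n_cna: int | None = None
    mrmr_candidates: tuple[int, ...] | None = None
    mrmr_per_fold: bool = True
    hidden_sizes: tuple[int, ...] = (200, 150, 100)
    epochs: int = 200
    learning_rate: float = 0.001
    l2_coeff: float = 5e-4
    rf_n_estimators: int = 70
    smote: bool = True
    smote_k: int = 5
    normalize_densities: bool = True
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        if not self.modalities:
            raise ValueError("modality list must be nonempty")
        unknown = set(self.modalities) - {"GE", "CNA", "CLN"}
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        for t in (self.ge_threshold, self.cna_threshold):
            if not -1.0 <= t <= 1.0:
                raise ValueError("correlation thresholds must lie in [-1, 1]")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def gcn_config(self, seed_offset: int = 0) -> GCNConfig:
        return GCNConfig(
            hidden_sizes=self.hidden_sizes,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            l2_coeff=self.l2_coeff,
            seed=self.seed + seed_offset,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("modalities", "hidden_sizes", "mrmr_candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class FoldResult:
    """Everything reported for one cross-validation fold."""

    fold: int
    test_sample_ids: list[str]
    validation_accuracies: dict[str, float]
    fused_scores: np.ndarray
    hard_labels: np.ndarray
    metrics: dict[str, float]
    lam: float = 0.0


def stack_features(
    blocks: Sequence[tuple[Sequence[str], np.ndarray]],
) -> tuple[list[str], np.ndarray]:
    """Column-wise concatenation of (sample_ids, matrix) blocks.

    Rows are aligned by sample id to the first block's order; a missing or
    extra id in any block is an alignment error.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    ref_ids = list(blocks[0][0])
    parts = []
    for ids, mat in blocks:
        mat = np.asarray(mat, dtype=float)
        if set(ids) != set(ref_ids) or len(ids) != len(ref_ids):
            raise ValueError("sample id mismatch across feature blocks")
        pos = {s: i for i, s in enumerate(ids)}
        parts.append(mat[[pos[s] for s in ref_ids]])
    return ref_ids, np.hstack(parts)


def train_base_classifiers(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
    rf_n_estimators: int = 70,
):
    """Fit LR, RBF-SVM and RF; returns (fitted dict, validation accuracies).

    The random forest uses 70 trees; the linear/kernel models sit behind a
    standard scaler. Validation accuracy per classifier feeds the fuzzy
    densities.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    models = {
        "LR": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "SVM": make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=seed),
        ),
        "RF": RandomForestClassifier(
            n_estimators=rf_n_estimators, random_state=seed
        ),
    }
    val_acc = {}
    for name, model in models.items():
        model.fit(X_train, y_train)
        val_acc[name] = float(accuracy_score(y_val, model.predict(X_val)))
    return models, val_acc


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}: reporting 0")
        return 0.0
    return num / den


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray | None = None,
) -> dict[str, float]:
    """Confusion-table metrics plus AUC.

    Acc, Pre, Sn, Sp, Bal_Acc, F1 and Mcc come straight from the 2x2 table
    (class 1 = positive); zero-denominator cells report 0 with a warning.
    AUC uses the trapezoid rule on ``y_score`` and is NaN (warned) when only
    one class is present.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn

    acc = _safe_div(tp + tn, n, "Acc")
    pre = _safe_div(tp, tp + fp, "Pre")
    sn = _safe_div(tp, tp + fn, "Sn")
    sp = _safe_div(tn, tn + fp, "Sp")
    bal = 0.5 * (sn + sp)
    f1 = _safe_div(2 * pre * sn, pre + sn, "F1")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "Mcc")

    if y_score is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, y_score))
    else:
        if y_score is not None:
            warnings.warn("single-class y_true: AUC undefined, reporting NaN")
        auc = float("nan")
    return {
        "Acc": acc,
        "Mcc": mcc,
        "Pre": pre,
        "Sn": sn,
        "Sp": sp,
        "Bal_Acc": bal,
        "F1": f1,
        "AUC": auc,
    }


def _select_features(
    X: np.ndarray,
    y: np.ndarray,
    fit_rows: np.ndarray,
    n_features: int | None,
    candidates: tuple[int, ...] | None,
    seed: int,
) -> list[int]:
    """mRMR ranking fitted on ``fit_rows`` only (labels outside never read)."""
    if n_features is None and candidates is None:
        return list(range(X.shape[1]))
    Xf, yf = X[fit_rows], y[fit_rows]
    if candidates is not None:
        n_features = search_feature_count(Xf, yf, candidates, seed=seed)
    n_features = min(n_features, X.shape[1])
    return mrmr_select(Xf, yf, n_features)


def run_fold(
    data: dict[str, OmicsMatrix],
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    fold: int = 0,
    return_artifacts: bool = False,
):
    """Run one fold given explicit index sets.

    Labels at ``test_idx`` are never read by any training-stage step: mRMR
    fits on train+validation rows, the GCN loss mask is the training rows,
    SMOTE touches the training rows only and validation accuracies come
    from the validation rows. The graph itself is transductive (built over
    all samples' features).
    """
    sample_ids = next(iter(data.values())).sample_ids
    y = np.asarray(y, dtype=int)
    trainval = np.concatenate([train_idx, val_idx])

    blocks: list[tuple[Sequence[str], np.ndarray]] = []
    artifacts: dict[str, object] = {"selected": {}, "gcn_weights": {}}
    for mod in config.modalities:
        if mod not in data:
            raise ValueError(f"modality {mod} requested but not provided")
        om = data[mod]
        if om.sample_ids != sample_ids:
            raise ValueError("sample ids differ across modalities")
        if mod == "CLN":
            blocks.append((om.sample_ids, minmax_normalize(om.values)))
            continue
        threshold = config.ge_threshold if mod == "GE" else config.cna_threshold
        n_sel = config.mrmr_n_ge if mod == "GE" else config.mrmr_n_cna
        selected = _select_features(
            om.values, y, trainval, n_sel, config.mrmr_candidates, config.seed + fold
        )
        artifacts["selected"][mod] = selected
        X_sel = om.values[:, selected]
        graph = build_graph(
            X_sel,
            om.sample_ids,
            threshold,
            absolute=config.absolute_correlation,
            add_self_loops=config.add_self_loops,
        )
        model, _trace = train_gcn(
            graph, y, train_idx, config.gcn_config(seed_offset=fold)
        )
        artifacts["gcn_weights"][mod] = [W.copy() for W in model.weights]
        blocks.append((om.sample_ids, extract_embeddings(graph, model)))

    ids, X_stack = stack_features(blocks)
    X_tr, y_tr = X_stack[train_idx], y[train_idx]
    if config.smote:
        X_tr, y_tr = smote_oversample(
            X_tr, y_tr, k=config.smote_k, seed=config.seed + fold
        )
    models, val_acc = train_base_classifiers(
        X_tr,
        y_tr,
        X_stack[val_idx],
        y[val_idx],
        seed=config.seed + fold,
        rf_n_estimators=config.rf_n_estimators,
    )
    # validation accuracy of 0 would break the density construction
    scores = [max(val_acc[c], 1e-6) for c in CLASSIFIER_IDS]
    measure = FuzzyMeasure.from_validation_scores(
        CLASSIFIER_IDS, scores, normalize=config.normalize_densities
    )
    probs = np.stack(
        [models[c].predict_proba(X_stack[test_idx]) for c in CLASSIFIER_IDS], axis=1
    )
    score_matrix = ScoreMatrix(
        sample_ids=[sample_ids[i] for i in test_idx],
        classifier_ids=CLASSIFIER_IDS,
        probs=probs,
    )
    fused, hard = ensemble_predict(
        score_matrix, measure, threshold=config.decision_threshold
    )
    metrics = compute_metrics(y[test_idx], hard, fused)
    result = FoldResult(
        fold=fold,
        test_sample_ids=[sample_ids[i] for i in test_idx],
        validation_accuracies=val_acc,
        fused_scores=fused,
        hard_labels=hard,
        metrics=metrics,
        lam=measure.lam,
    )
    if return_artifacts:
        return result, artifacts
    return result


def run_cross_validation(
    data: dict[str, OmicsMatrix],
    labels: LabelVector,
    config: PipelineConfig,
) -> tuple[list[FoldResult], dict[str, float], pd.DataFrame]:
    """Stratified k-fold evaluation of the full method.

    Returns (per-fold results, mean metrics over folds, pooled ROC points).
    Fully reproducible from ``config.seed``; a fold whose training data
    collapses to a single class is recorded as failed and skipped.
    """
    missing = set(config.modalities) - set(data)
    if missing:
        raise ValueError(f"modality {sorted(missing)[0]} requested but not provided")
    sample_ids = next(iter(data.values())).sample_ids
    y = labels.aligned_to(sample_ids)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    results: list[FoldResult] = []
    pooled_y, pooled_score = [], []
    for fold, (trainval_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_idx, val_idx = train_test_split(
            trainval_idx,
            test_size=config.validation_fraction,
            stratify=y[trainval_idx],
            random_state=config.seed + fold,
        )
        try:
            res = run_fold(data, y, train_idx, val_idx, test_idx, config, fold=fold)
        except ValueError as exc:
            warnings.warn(f"fold {fold} failed ({exc}); continuing")
            continue
        results.append(res)
        pooled_y.append(y[test_idx])
        pooled_score.append(res.fused_scores)

    if not results:
        raise RuntimeError("every fold failed")
    mean_metrics = {
        m: float(np.nanmean([r.metrics[m] for r in results])) for m in METRIC_NAMES
    }
    fpr, tpr, thr = roc_curve(np.concatenate(pooled_y), np.concatenate(pooled_score))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return results, mean_metrics, roc


def fold_metrics_table(results: list[FoldResult]) -> pd.DataFrame:
    rows = [{"fold": r.fold, **r.metrics} for r in results]
    return pd.DataFrame(rows)


def fused_scores_table(results: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for sid, p1, lab in zip(r.test_sample_ids, r.fused_scores, r.hard_labels):
            rows.append({"sample_id": sid, "fused_p1": p1, "label": int(lab)})
    return pd.DataFrame(rows)
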