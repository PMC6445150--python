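"""Per-drug SVM ranking with repeated stratified cross-validated AUROC.

A soft-margin SVM (RBF kernel by default) is trained on the labelled
positive/negative example functions over the selected feature columns;
unlabelled candidate functions are ranked by the decision-function margin.
Performance is estimated by stratified k-fold cross-validation repeated over
several iterations (default 4 folds × 20 iterations), reporting AUROC per
held-out fold.  Features are standardised with training-fold statistics
only; the same transform is applied to held-out and candidate rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)
    class_weight: str | None = "balanced"


DEFAULT_SVM = SVMConfig()


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney; ties count one half)."""
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class FittedModel:
    """An SVM plus the training standardisation and its column contract."""

    svc: SVC
    columns: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    config: SVMConfig

    def _transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if tuple(X.columns) != self.columns:
                raise ValueError(
                    "candidate matrix columns do not match the trained model"
                )
            X = X.to_numpy(dtype=float)
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} columns, got {X.shape[1]}"
            )
        return (X - self.mean) / self.scale

    def decision_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(X))

    def to_json(self, path: str | Path) -> None:
        """Serialize the fitted model to a documented JSON container.

        Stores the column contract, standardisation statistics, kernel
        configuration and the fitted support-vector expansion
        (support vectors, dual coefficients, intercept, gamma value).
        """
        svc = self.svc
        doc = {
            "format": "funact-svm-1",
            "columns": list(self.columns),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "config": asdict(self.config),
            "gamma_value": float(svc._gamma),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
            "classes": svc.classes_.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SerializedModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format") != "funact-svm-1":
            raise ValueError("not a funact SVM model container")
        return SerializedModel(doc)


class SerializedModel:
    """Decision-scoring view of a JSON-serialized SVM (RBF or linear)."""

    def __init__(self, doc: dict):
        self.columns = tuple(doc["columns"])
        self.mean = np.asarray(doc["mean"], dtype=float)
        self.scale = np.asarray(doc["scale"], dtype=float)
        self.config = SVMConfig(**doc["config"])
        self.gamma_value = float(doc["gamma_value"])
        self.support_vectors = np.asarray(doc["support_vectors"], dtype=float)
        self.dual_coef = np.asarray(doc["dual_coef"], dtype=float)
        self.intercept = np.asarray(doc["intercept"], dtype=float)
        if self.config.kernel not in ("rbf", "linear"):
            raise ValueError(
                f"serialized scoring supports rbf/linear, not {self.config.kernel}"
            )

    def decision_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if tuple(X.columns) != self.columns:
                raise ValueError("columns do not match the serialized model")
            X = X.to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        if self.config.kernel == "rbf":
            d2 = (
                (Z**2).sum(axis=1)[:, None]
                + (self.support_vectors**2).sum(axis=1)[None, :]
                - 2 * Z @ self.support_vectors.T
            )
            K = np.exp(-self.gamma_value * d2)
        else:
            K = Z @ self.support_vectors.T
        return (K @ self.dual_coef.ravel()) + self.intercept[0]


def train_model(
    matrix_selected: pd.DataFrame,
    labels: Mapping[str, int],
    config: SVMConfig = DEFAULT_SVM,
    random_state: int = 0,
) -> FittedModel:
    """Fit a soft-margin SVM on the labelled rows of the selected columns."""
    rows = [f for f in matrix_selected.index if f in labels]
    y = np.asarray([labels[f] for f in rows], dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training needs at least one example per class")
    # fixed memory order keeps reductions bit-identical across input routes
    X = np.ascontiguousarray(matrix_selected.loc[rows].to_numpy(dtype=float))
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=random_state,
    )
    svc.fit((X - mean) / scale, y)
    return FittedModel(
        svc=svc,
        columns=tuple(matrix_selected.columns),
        mean=mean,
        scale=scale,
        config=config,
    )


@dataclass
class CVReport:
    fold_aurocs: list[float]
    folds: int
    iterations: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aurocs))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_aurocs))

    def to_dict(self) -> dict:
        return {
            "mean_auroc": self.mean,
            "sd_auroc": self.sd,
            "fold_aurocs": self.fold_aurocs,
            "folds": self.folds,
            "iterations": self.iterations,
            "seed": self.seed,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )


def cross_validate(
    matrix_selected: pd.DataFrame,
    labels: Mapping[str, int],
    folds: int = 4,
    iterations: int = 20,
    seed: int = 0,
    config: SVMConfig = DEFAULT_SVM,
) -> CVReport:
    """Repeated stratified k-fold CV; AUROC per held-out fold.

    Folds are resampled each iteration from ``seed + iteration``; the mean
    and standard deviation are computed over the pooled folds × iterations
    values.  If a class has fewer members than ``folds`` the fold count is
    reduced (with a warning recorded in the report).
    """
    rows = [f for f in matrix_selected.index if f in labels]
    y = np.asarray([labels[f] for f in rows], dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes")
    warns: list[str] = []
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("cross-validation needs >= 2 examples per class")
    if min_count < folds:
        warns.append(
            f"reduced folds from {folds} to {min_count}: smallest class has "
            f"{min_count} members"
        )
        folds = min_count
    X = matrix_selected.loc[rows]
    fold_aurocs: list[float] = []
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            train_rows = [rows[i] for i in train_idx]
            test_rows = [rows[i] for i in test_idx]
            model = train_model(
                X.loc[train_rows],
                {r: int(labels[r]) for r in train_rows},
                config=config,
                random_state=seed + it,
            )
            scores = model.decision_scores(X.loc[test_rows])
            fold_aurocs.append(auroc(scores, y[test_idx]))
    return CVReport(
        fold_aurocs=fold_aurocs,
        folds=folds,
        iterations=iterations,
        seed=seed,
        warnings=warns,
    )


@dataclass
class RankedCandidates:
    """Candidates ordered by decision score (ties broken by function id)."""

    ranking: list[tuple[str, float]]
    drug_id: str
    selected_columns: tuple[str, ...]
    config: SVMConfig

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.ranking[:n]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tfunction_id\tscore\n")
            for i, (fid, score) in enumerate(self.ranking, start=1):
                fh.write(f"{i}\t{fid}\t{score!r}\n")


def rank_candidates(
    model: FittedModel,
    candidate_matrix: pd.DataFrame,
    drug_id: str = "",
) -> RankedCandidates:
    """Score candidate rows with the fitted model and sort descending."""
    scores = model.decision_scores(candidate_matrix)
    order = sorted(
        zip(candidate_matrix.index, scores), key=lambda t: (-t[1], t[0])
    )
    return RankedCandidates(
        ranking=[(fid, float(s)) for fid, s in order],
        drug_id=drug_id,
        selected_columns=model.columns,
        config=model.config,
    )
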