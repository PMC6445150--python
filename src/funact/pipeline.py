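"""End-to-end orchestration: features -> selection -> CV -> ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .features import (
    FeatureMatrix,
    SelectionResult,
    build_feature_matrix,
    select_features,
)
from .hetnet import FUNCTION, HeteroNetwork, NetworkSchema
from .metapath import DEFAULT_CONVENTIONS, Conventions
from .ontology import DrugCase
from .svm import (
    DEFAULT_SVM,
    CVReport,
    FittedModel,
    RankedCandidates,
    SVMConfig,
    auroc,
    cross_validate,
    rank_candidates,
    train_model,
)


@dataclass
class RunResult:
    matrix: FeatureMatrix
    selection: SelectionResult
    cv_report: CVReport
    model: FittedModel
    ranked: RankedCandidates
    labels: dict[str, int]
    candidates: tuple[str, ...]


def case_labels(case: DrugCase) -> dict[str, int]:
    labels = {f: 1 for f in case.positives}
    labels.update({f: 0 for f in case.negatives})
    return labels


def run_case(
    network: HeteroNetwork,
    schema: NetworkSchema,
    case: DrugCase,
    functions: Iterable[str] | None = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    k: int = 20,
    folds: int = 4,
    iterations: int = 20,
    seed: int = 0,
    svm_config: SVMConfig = DEFAULT_SVM,
    select_in_fold: bool = False,
) -> RunResult:
    """Run the full prioritization pipeline for one drug case.

    ``functions`` defaults to every function node; candidates are the
    evaluated functions that carry no label.  By default feature selection is
    fit once per drug on all labelled examples; ``select_in_fold=True``
    instead refits the selection inside every CV training fold (stricter, no
    information from held-out labels).
    """
    if functions is None:
        functions = network.nodes_of_type(FUNCTION)
    functions = sorted(set(functions))
    labels = case_labels(case)
    missing = [f for f in labels if f not in functions]
    if missing:
        functions = sorted(set(functions) | set(labels))
    matrix = build_feature_matrix(network, schema, case, functions, conventions)
    selection = select_features(matrix, labels, k=k)
    selected_df = matrix.data[selection.selected]
    if select_in_fold:
        cv_report = _cross_validate_in_fold(
            matrix, labels, k, folds, iterations, seed, svm_config
        )
    else:
        cv_report = cross_validate(
            selected_df, labels, folds=folds, iterations=iterations, seed=seed,
            config=svm_config,
        )
    model = train_model(selected_df, labels, config=svm_config, random_state=seed)
    candidates = tuple(f for f in functions if f not in labels)
    ranked = rank_candidates(
        model, selected_df.loc[list(candidates)], drug_id=case.drug_id
    )
    return RunResult(
        matrix=matrix,
        selection=selection,
        cv_report=cv_report,
        model=model,
        ranked=ranked,
        labels=labels,
        candidates=candidates,
    )


def _cross_validate_in_fold(
    matrix: FeatureMatrix,
    labels: Mapping[str, int],
    k: int,
    folds: int,
    iterations: int,
    seed: int,
    svm_config: SVMConfig,
) -> CVReport:
    from sklearn.model_selection import StratifiedKFold

    rows = [f for f in matrix.data.index if f in labels]
    y = np.asarray([labels[f] for f in rows], dtype=int)
    counts = np.bincount(y)
    warns: list[str] = []
    min_count = int(counts[counts > 0].min())
    if min_count < folds:
        warns.append(f"reduced folds from {folds} to {min_count}")
        folds = min_count
    fold_aurocs: list[float] = []
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            train_rows = [rows[i] for i in train_idx]
            test_rows = [rows[i] for i in test_idx]
            fold_labels = {r: int(labels[r]) for r in train_rows}
            sel = select_features(
                matrix.data.loc[train_rows + test_rows], fold_labels, k=k
            )
            model = train_model(
                matrix.data.loc[train_rows, sel.selected],
                fold_labels,
                config=svm_config,
                random_state=seed + it,
            )
            scores = model.decision_scores(matrix.data.loc[test_rows, sel.selected])
            fold_aurocs.append(auroc(scores, y[test_idx]))
    return CVReport(
        fold_aurocs=fold_aurocs,
        folds=folds,
        iterations=iterations,
        seed=seed,
        warnings=warns,
    )


def recall_at(ranked: RankedCandidates, truth: Iterable[str], n: int = 10) -> float:
    """Fraction of the true unlabelled functions found in the top n."""
    truth = set(truth)
    if not truth:
        raise ValueError("empty ground-truth set")
    top = {fid for fid, _ in ranked.top(n)}
    return len(top & truth) / len(truth)
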