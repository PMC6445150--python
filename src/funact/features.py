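"""Per-function feature matrices over observed meta-paths, and selection.

Each candidate function gets, per observed meta-path, the triple
(path count, PDP sum, PDP max); target-side meta-paths are traversed from
the drug's targets to the function, indication-side meta-paths from the
function to the drug's indications (paths to several targets/indications are
pooled before the triple is computed).  Meta-paths with no path instance for
any evaluated function are dropped, so the column set is the drug case's
*observed* meta-paths.

Feature selection ranks columns by the magnitude of the univariate
ordinary-least-squares slope of the label on the z-scored column, computed
on labelled rows only, and keeps the top ``k`` (default 20).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hetnet import FUNCTION, MOLECULE, PHENOTYPE, HeteroNetwork, NetworkSchema
from .metapath import (
    DEFAULT_CONVENTIONS,
    STAT_NAMES,
    Conventions,
    MetaPath,
    enumerate_metapaths,
    find_paths,
    triple_from_paths,
)
from .ontology import DrugCase

TARGET_SIDE = "target"
INDICATION_SIDE = "indication"

COLUMN_SEP = "::"


def column_name(side: str, metapath: MetaPath | str, stat: str) -> str:
    mp = metapath if isinstance(metapath, str) else metapath.canonical_string
    return f"{side}{COLUMN_SEP}{mp}{COLUMN_SEP}{stat}"


def split_column(col: str) -> tuple[str, str, str]:
    side, mp, stat = col.split(COLUMN_SEP)
    return side, mp, stat


@dataclass
class FeatureMatrix:
    """Functions × (meta-path, statistic) feature values.

    ``data`` is indexed by function id; columns are
    ``side::<canonical meta-path>::<statistic>`` strings, target-side columns
    first, statistics in (path_count, pdp_sum, pdp_max) order.
    """

    data: pd.DataFrame

    @property
    def functions(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def metapaths(self) -> list[tuple[str, str]]:
        """Distinct (side, canonical string) pairs, in column order."""
        seen: list[tuple[str, str]] = []
        for col in self.data.columns:
            side, mp, _ = split_column(col)
            if (side, mp) not in seen:
                seen.append((side, mp))
        return seen

    def side_of(self, col: str) -> str:
        return split_column(col)[0]

    def to_long_tsv(self, path: str | Path) -> None:
        """features dump: function_id, side, metapath, path_count, pdp_sum, pdp_max."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("function_id\tside\tmetapath\tpath_count\tpdp_sum\tpdp_max\n")
            for fid in self.data.index:
                for side, mp in self.metapaths:
                    vals = [
                        self.data.at[fid, column_name(side, mp, s)]
                        for s in STAT_NAMES
                    ]
                    fh.write(
                        f"{fid}\t{side}\t{mp}\t{int(vals[0])}"
                        f"\t{float(vals[1])!r}\t{float(vals[2])!r}\n"
                    )

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "FeatureMatrix":
        """Inverse of :meth:`to_long_tsv` (column order preserved)."""
        long = pd.read_csv(
            path, sep="\t", float_precision="round_trip",
            dtype={"function_id": str, "side": str, "metapath": str},
        )
        functions = list(dict.fromkeys(long["function_id"]))
        order: list[str] = []
        for _, row in long.iterrows():
            key = (row["side"], row["metapath"])
            cols = [column_name(*key, s) for s in STAT_NAMES]
            if cols[0] not in order:
                order.extend(cols)
        df = pd.DataFrame(0.0, index=functions, columns=order)
        for _, row in long.iterrows():
            for stat in STAT_NAMES:
                df.at[row["function_id"], column_name(row["side"], row["metapath"], stat)] = float(
                    row[stat]
                )
        return cls(df)


def build_feature_matrix(
    network: HeteroNetwork,
    schema: NetworkSchema,
    case: DrugCase,
    functions: Iterable[str],
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> FeatureMatrix:
    """Assemble the observed-meta-path feature matrix for one drug case."""
    funcs = sorted(set(functions))
    for f in funcs:
        if f not in network.nodes:
            raise KeyError(f"unknown function node {f!r}")
        if network.node_type(f) != FUNCTION:
            raise TypeError(
                f"{f!r} has node type {network.node_type(f)}, expected function"
            )
    target_mps = enumerate_metapaths(
        schema, MOLECULE, FUNCTION, conventions.max_len_target, conventions
    )
    indication_mps = enumerate_metapaths(
        schema, FUNCTION, PHENOTYPE, conventions.max_len_indication, conventions
    )
    targets = sorted(case.targets)
    indications = sorted(case.indications)
    w = conventions.w
    mode = conventions.pdp_degree_mode

    blocks: dict[str, np.ndarray] = {}
    order: list[str] = []
    for side, mps in ((TARGET_SIDE, target_mps), (INDICATION_SIDE, indication_mps)):
        for mp in mps:
            rows = np.zeros((len(funcs), 3))
            for i, f in enumerate(funcs):
                if side == TARGET_SIDE:
                    paths = find_paths(network, targets, f, mp, conventions)
                else:
                    paths = []
                    for ind in indications:
                        paths.extend(find_paths(network, [f], ind, mp, conventions))
                triple = triple_from_paths(network, paths, w, mode)
                rows[i] = triple.as_tuple()
            if not rows.any():
                continue  # unobserved meta-path: no column
            for j, stat in enumerate(STAT_NAMES):
                col = column_name(side, mp, stat)
                blocks[col] = rows[:, j]
                order.append(col)
    df = pd.DataFrame(blocks, index=funcs, columns=order)
    return FeatureMatrix(df)


@dataclass
class SelectionResult:
    """Ranked feature columns with univariate regression coefficients."""

    table: pd.DataFrame  # columns: column, coefficient, rank, selected
    selected: list[str]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["selected"] = out["selected"].astype(int)
        out.to_csv(path, sep="\t", index=False)


def univariate_coefficients(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of y on each z-scored column; constant columns get 0.

    Returns (slopes, nonconstant mask).  With x standardised to unit
    population variance the slope reduces to cov(x, y).
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconstant = sd > 0
    Xz = np.zeros_like(X, dtype=float)
    Xz[:, nonconstant] = (X[:, nonconstant] - mu[nonconstant]) / sd[nonconstant]
    slopes = (Xz * (y - y.mean())[:, None]).mean(axis=0)
    slopes[~nonconstant] = 0.0
    return slopes, nonconstant


def select_features(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: Mapping[str, int],
    k: int = 20,
) -> SelectionResult:
    """Rank columns by |univariate OLS slope| on labelled rows; keep top k.

    Ties break on the column string; constant columns rank last and are
    never selected, so ``len(selected) = min(k, #non-constant columns)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    labelled = [f for f in df.index if f in labels]
    y = np.asarray([labels[f] for f in labelled], dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("feature selection needs both classes among the labels")
    X = np.ascontiguousarray(df.loc[labelled].to_numpy(dtype=float))
    slopes, nonconstant = univariate_coefficients(X, y)
    cols = list(df.columns)
    ranked = sorted(
        range(len(cols)),
        key=lambda j: (-abs(slopes[j]), cols[j]),
    )
    # constant columns always sink below non-constant ones (stable sort)
    ranked = sorted(ranked, key=lambda j: not nonconstant[j])
    selected_idx = [j for j in ranked if nonconstant[j]][:k]
    selected_set = set(selected_idx)
    table = pd.DataFrame(
        {
            "column": [cols[j] for j in ranked],
            "coefficient": [slopes[j] for j in ranked],
            "rank": np.arange(1, len(cols) + 1),
            "selected": [j in selected_set for j in ranked],
        }
    )
    return SelectionResult(table=table, selected=[cols[j] for j in selected_idx])
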