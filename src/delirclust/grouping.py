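"""Stage 1: cluster item@day columns into feature groups and average them.

Each of the (typically 65) columns of the feature matrix is treated as one
point whose coordinates are the scores of all participants for that cell.
K-means with AIC order selection partitions the columns into G groups; the
matrix is then collapsed to one per-participant mean composite per group.
Columns are clustered on raw ordinal scores (all cells share the same 0-3
scale); pass ``standardize=True`` to z-score columns first for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DataError, FeatureMatrix, parse_col_label
from . import kmeans
from .kmeans import SelectionReport


@dataclass
class FeatureGrouping:
    """Map from column label to feature-group index 0..G-1."""

    group_of: dict[str, int]
    G: int
    group_names: list[str] | None = None
    selection: SelectionReport | None = None

    def __post_init__(self) -> None:
        found = sorted(set(self.group_of.values()))
        if found != list(range(self.G)):
            raise DataError(
                f"group indices must be exactly 0..{self.G - 1}, got {found}"
            )
        if self.group_names is not None and len(self.group_names) != self.G:
            raise DataError("group_names length must equal G")

    def members(self, g: int) -> list[str]:
        return [c for c, gg in self.group_of.items() if gg == g]

    def labels_for(self, col_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.group_of[c] for c in col_labels])

    def name_of(self, g: int) -> str:
        if self.group_names is not None:
            return self.group_names[g]
        return f"group{g}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "col_label": list(self.group_of),
                "group": [self.group_of[c] for c in self.group_of],
                "group_name": [self.name_of(self.group_of[c]) for c in self.group_of],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReducedMatrix:
    """Participants x G matrix of within-group mean composites."""

    values: np.ndarray
    row_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.group_labels)):
            raise DataError("reduced matrix shape mismatch")

    @property
    def G(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.group_labels)
        df.insert(0, "participant", self.row_ids)
        return df


def group_features(
    X: FeatureMatrix,
    k_range: Iterable[int] = kmeans.DEFAULT_K_RANGE,
    restarts: int = kmeans.DEFAULT_RESTARTS,
    master_seed: int = 0,
    criterion: str = kmeans.DEFAULT_CRITERION,
    standardize: bool = False,
) -> FeatureGrouping:
    """Partition the columns of ``X`` into AIC-selected feature groups."""
    if X.n_participants < 2:
        raise DataError("need at least 2 participants to group features")
    pts = X.values.T.copy()
    if standardize:
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    report = kmeans.select_k(
        pts, k_range=k_range, restarts=restarts, master_seed=master_seed,
        criterion=criterion,
    )
    assign = report.selected_solution.assignments
    # relabel groups by first occurrence along the column order, so the
    # grouping is invariant to the arbitrary K-means label permutation
    order: dict[int, int] = {}
    for a in assign:
        if int(a) not in order:
            order[int(a)] = len(order)
    group_of = {c: order[int(a)] for c, a in zip(X.col_labels, assign)}
    grouping = FeatureGrouping(group_of=group_of, G=report.selected_K)
    grouping.selection = report
    grouping.group_names = suggest_group_names(grouping)
    return grouping


def reduce(X: FeatureMatrix, grouping: FeatureGrouping) -> ReducedMatrix:
    """Collapse ``X`` to one mean composite per feature group."""
    if set(grouping.group_of) != set(X.col_labels):
        raise DataError("grouping does not cover exactly the matrix columns")
    labels = grouping.labels_for(X.col_labels)
    cols = []
    names = []
    for g in range(grouping.G):
        mask = labels == g
        cols.append(X.values[:, mask].mean(axis=1))
        names.append(grouping.name_of(g))
    return ReducedMatrix(np.stack(cols, axis=1), list(X.row_ids), names)


def suggest_group_names(grouping: FeatureGrouping) -> list[str]:
    """Cosmetic auto-labels from each group's cell composition.

    A group that is >= 80% one item is named after that item
    ("<item>-dominant"); a group that is >= 80% day-1 cells is "day1-acute";
    otherwise "group<g>".  Purely a convenience for readable output.
    """
    names = []
    for g in range(grouping.G):
        members = grouping.members(g)
        items = [parse_col_label(c)[0] for c in members]
        days = [parse_col_label(c)[1] for c in members]
        top_item, top_n = pd.Series(items).value_counts().index[0], pd.Series(
            items
        ).value_counts().iloc[0]
        if top_n / len(members) >= 0.8:
            names.append(f"{top_item}-dominant")
        elif sum(d == 1 for d in days) / len(members) >= 0.8:
            names.append("day1-acute")
        else:
            names.append(f"group{g}")
    return names
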