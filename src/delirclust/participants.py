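"""Stage 2: cluster participants on the reduced matrix and label the clusters.

After stage 1 collapses the 65 item@day cells to G composites, each
participant is a point in R^G.  K-means with AIC order selection yields the
participant clusters; clusters are then ordered by the within-cluster mean
of the participant's maximum daily total severity (rank 1 = most severe) and
labeled delirium / non-delirium by majority of the DSM-5 diagnosis labels of
their members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import DataError
from .grouping import ReducedMatrix
from . import kmeans
from .kmeans import ClusteringSolution, SelectionReport

DELIRIUM = "delirium"
NON_DELIRIUM = "non-delirium"


@dataclass
class ParticipantClustering:
    """A participant K-means solution plus its clinical ordering/labels."""

    solution: ClusteringSolution
    row_ids: list[str]
    severity_rank: np.ndarray | None = None    # rank of raw cluster k, 1 = worst
    delirium_label: list[str] | None = None    # per raw cluster
    selection: SelectionReport | None = None

    @property
    def K(self) -> int:
        return self.solution.K

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant": self.row_ids,
                "raw_cluster": self.solution.assignments,
            }
        )
        if self.severity_rank is not None:
            df["severity_rank"] = self.severity_rank[self.solution.assignments]
        if self.delirium_label is not None:
            df["cluster_label"] = [
                self.delirium_label[a] for a in self.solution.assignments
            ]
        return df


def cluster_participants(
    Xr: ReducedMatrix,
    k_range: Iterable[int] = kmeans.DEFAULT_K_RANGE,
    restarts: int = kmeans.DEFAULT_RESTARTS,
    master_seed: int = 0,
    criterion: str = kmeans.DEFAULT_CRITERION,
    standardize: bool = False,
) -> ParticipantClustering:
    """AIC-selected K-means over the rows of the reduced matrix."""
    if len(Xr.row_ids) < 2:
        raise DataError("need at least 2 participants")
    pts = Xr.values.copy()
    if standardize:
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    report = kmeans.select_k(
        pts, k_range=k_range, restarts=restarts, master_seed=master_seed,
        criterion=criterion,
    )
    pc = ParticipantClustering(
        solution=report.selected_solution, row_ids=list(Xr.row_ids)
    )
    pc.selection = report
    return pc


def rank_by_severity(
    solution: ClusteringSolution, severities: Sequence[float]
) -> np.ndarray:
    """Rank raw clusters 1..K by descending within-cluster mean severity.

    ``severities`` is the per-participant maximum daily total score, aligned
    to the clustered rows.  Ties in the mean go to the smaller raw index.
    Returns an array mapping raw cluster index -> rank (1 = most severe).
    """
    sev = np.asarray(severities, dtype=float)
    if sev.shape[0] != solution.assignments.shape[0]:
        raise DataError("one severity per clustered participant required")
    means = np.array(
        [sev[solution.assignments == k].mean() for k in range(solution.K)]
    )
    order = sorted(range(solution.K), key=lambda k: (-means[k], k))
    rank = np.empty(solution.K, dtype=int)
    for r, k in enumerate(order, start=1):
        rank[k] = r
    return rank


def label_from_counts(n_delirium: int, n_non_delirium: int) -> str:
    """Majority rule on diagnosis counts; a tie labels the cluster delirium.

    The tie rule is the clinically conservative choice (flagging a balanced
    cluster as delirium errs toward attention, not neglect).
    """
    return DELIRIUM if n_delirium >= n_non_delirium else NON_DELIRIUM


def label_delirium(
    solution: ClusteringSolution, dsm5: Sequence[bool | None]
) -> list[str]:
    """Per-cluster majority delirium / non-delirium label.

    ``dsm5`` holds the per-participant DSM-5 diagnosis aligned to the
    clustered rows; ``None`` entries are excluded from the counts.
    """
    if len(dsm5) != solution.assignments.shape[0]:
        raise DataError("one diagnosis label per clustered participant required")
    if all(v is None for v in dsm5):
        raise DataError("no diagnosis labels available for labeling")
    labels = []
    flags = np.array([-1 if v is None else int(v) for v in dsm5])
    for k in range(solution.K):
        in_k = flags[solution.assignments == k]
        labels.append(label_from_counts(int((in_k == 1).sum()), int((in_k == 0).sum())))
    return labels


def cluster_summary(
    clustering: ParticipantClustering,
    severities: Sequence[float],
    dsm5: Sequence[bool | None] | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cluster summary table ordered by severity rank.

    Columns: rank, raw cluster, size, diagnosis counts, cluster label,
    severity mean +/- SE, then mean of any supplied covariates.
    """
    sol = clustering.solution
    sev = np.asarray(severities, dtype=float)
    rank = clustering.severity_rank
    if rank is None:
        rank = rank_by_severity(sol, sev)
    labels = clustering.delirium_label
    rows = []
    for k in range(sol.K):
        mask = sol.assignments == k
        entry = {
            "severity_rank": int(rank[k]),
            "raw_cluster": k,
            "n": int(mask.sum()),
            "drs_max_mean": float(sev[mask].mean()),
            "drs_max_se": float(sev[mask].std(ddof=1) / np.sqrt(mask.sum()))
            if mask.sum() > 1
            else float("nan"),
        }
        if dsm5 is not None:
            flags = np.array([-1 if v is None else int(v) for v in dsm5])[mask]
            entry["n_delirium"] = int((flags == 1).sum())
            entry["n_non_delirium"] = int((flags == 0).sum())
        if labels is not None:
            entry["cluster_label"] = labels[k]
        if covariates is not None:
            for col in covariates.columns:
                vals = pd.to_numeric(covariates[col], errors="coerce")[mask]
                entry[f"{col}_mean"] = float(vals.mean())
        rows.append(entry)
    return pd.DataFrame(rows).sort_values("severity_rank").reset_index(drop=True)
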