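"""Two-dimensional PCA views of features and participants.

View A projects the 65 item@day column vectors (points = features) and
colors them by feature group; view B projects participants in reduced
composite space and colors them by cluster, with separate markers for the
DSM-5 delirium / non-delirium diagnosis.  PCA is computed on centered,
unscaled data (covariance PCA, consistent with clustering on raw scores)
with a deterministic sign convention.  The numeric scatter TSV is the
artifact of record; the image is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataError


@dataclass
class Projection2D:
    points: np.ndarray                    # m x 2 PC scores, zero column mean
    explained_variance_fraction: tuple[float, float]
    axis_labels: tuple[str, str] = ("PC1", "PC2")


def pca_2d(points: np.ndarray) -> Projection2D:
    """Project rows of ``points`` onto the top-2 principal components.

    Columns are centered; scores are the projections onto the top-2 right
    singular vectors.  Sign convention: within each component, the loading
    of largest magnitude is made positive (first such loading on ties).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DataError("pca_2d needs an m x d matrix with m >= 2, d >= 2")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise DataError("rank-0 data: all points identical")
    # deterministic signs
    for i in range(min(2, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    ncomp = min(2, s.shape[0])
    scores = np.zeros((X.shape[0], 2))
    scores[:, :ncomp] = U[:, :ncomp] * s[:ncomp]
    total = float((s**2).sum())
    evf = tuple(
        float(s[i] ** 2 / total) if i < ncomp else 0.0 for i in range(2)
    )
    return Projection2D(points=scores, explained_variance_fraction=evf)


def scatter_frame(
    projection: Projection2D,
    ids: Sequence[str],
    group_or_cluster: Sequence,
    diagnosis: Sequence | None = None,
) -> pd.DataFrame:
    """Scatter table: id, pc1, pc2, group_or_cluster, diagnosis."""
    if len(ids) != projection.points.shape[0]:
        raise DataError("ids length must match projected points")
    if len(group_or_cluster) == 0:
        raise DataError("empty group/cluster list")
    if len(group_or_cluster) != len(ids):
        raise DataError("group/cluster length must match points")
    df = pd.DataFrame(
        {
            "id": list(ids),
            "pc1": projection.points[:, 0],
            "pc2": projection.points[:, 1],
            "group_or_cluster": list(group_or_cluster),
        }
    )
    if diagnosis is not None:
        if len(diagnosis) != len(ids):
            raise DataError("diagnosis length must match points")
        df["diagnosis"] = list(diagnosis)
    else:
        df["diagnosis"] = ""
    return df


def render_views(
    projection: Projection2D,
    ids: Sequence[str],
    group_or_cluster: Sequence,
    out_path: str | Path,
    diagnosis: Sequence | None = None,
    image: bool = False,
) -> pd.DataFrame:
    """Write the scatter TSV (always) and optionally a PNG next to it."""
    df = scatter_frame(projection, ids, group_or_cluster, diagnosis)
    out_path = Path(out_path)
    df.to_csv(out_path, sep="\t", index=False)
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        cats = pd.Categorical(df["group_or_cluster"])
        cmap = plt.get_cmap("tab10")
        for ci, cat in enumerate(cats.categories):
            sub = df[df["group_or_cluster"] == cat]
            # diagnosed participants as crosses, the rest as filled circles
            pos = sub[sub["diagnosis"].astype(str).isin(["True", "delirium", "1"])]
            neg = sub.drop(pos.index)
            ax.scatter(neg["pc1"], neg["pc2"], s=14, marker="o",
                       color=cmap(ci % 10), label=str(cat))
            ax.scatter(pos["pc1"], pos["pc2"], s=18, marker="x",
                       color=cmap(ci % 10))
        evf = projection.explained_variance_fraction
        ax.set_xlabel(f"PC1 ({evf[0]:.1%} var)")
        ax.set_ylabel(f"PC2 ({evf[1]:.1%} var)")
        ax.legend(fontsize=7, markerscale=0.8)
        fig.tight_layout()
        fig.savefig(out_path.with_suffix(".png"), dpi=150)
        plt.close(fig)
    return df
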