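"""End-to-end orchestration: scores -> feature groups -> clusters -> profile.

``run_pipeline`` executes the full two-stage analysis on long-format scores
(real or simulated), writes every artifact of record (grouping TSV, reduced
matrix, per-participant cluster TSV, cluster summary, sign-table profile,
ANOVA screen, PCA scatter TSVs) plus a JSON manifest holding the seeds,
selected K values and per-K best criterion scores needed to replay any
single K-means run.  ``report`` re-renders a human-readable summary from an
existing results directory without recomputation.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, kmeans
from .data import (
    DataError,
    ItemCatalog,
    LongitudinalScores,
    ParticipantMeta,
    max_total_severities,
    read_long,
    read_meta,
    to_wide,
    write_json_results,
    write_wide,
)
from .embedding import pca_2d, render_views
from .grouping import group_features, reduce
from .participants import (
    cluster_participants,
    label_delirium,
    rank_by_severity,
    cluster_summary,
)
from .posthoc import (
    CharacterizationConfig,
    anova_table,
    infer_roles,
    interpret_labels,
    posthoc_profile,
)

log = logging.getLogger("delirclust")


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run (defaults follow the reference protocol)."""

    out_dir: Path = Path("results")
    k_range_features: Sequence[int] = tuple(range(1, 11))
    k_range_participants: Sequence[int] = tuple(range(1, 11))
    restarts_features: int = kmeans.DEFAULT_RESTARTS
    restarts_participants: int = kmeans.DEFAULT_RESTARTS
    master_seed: int = 0
    criterion: str = kmeans.DEFAULT_CRITERION
    alpha_fwer: float = 0.05
    standardize_features: bool = False
    standardize_participants: bool = False
    write_images: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.restarts_features < 1 or self.restarts_participants < 1:
            raise DataError("restarts must be >= 1")


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive independent per-stage seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    kids = ss.spawn(3)
    names = ["features", "participants", "misc"]
    return {n: int(k.generate_state(1)[0] % (2**31)) for n, k in zip(names, kids)}


def run_pipeline(
    scores: LongitudinalScores,
    meta: ParticipantMeta | None,
    config: PipelineConfig,
) -> dict:
    """Run both clustering stages plus characterization; write artifacts.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    t0 = time.time()

    log.info("stage: feature matrix")
    X = to_wide(scores)
    write_wide(X, out / "feature_matrix.csv")

    log.info("stage: feature grouping (restarts=%d)", config.restarts_features)
    grouping = group_features(
        X,
        k_range=config.k_range_features,
        restarts=config.restarts_features,
        master_seed=seeds["features"],
        criterion=config.criterion,
        standardize=config.standardize_features,
    )
    grouping.write_tsv(out / "feature_grouping.tsv")
    Xr = reduce(X, grouping)
    Xr.to_frame().to_csv(out / "reduced_matrix.csv", index=False)

    log.info("stage: participant clustering (restarts=%d)", config.restarts_participants)
    pc = cluster_participants(
        Xr,
        k_range=config.k_range_participants,
        restarts=config.restarts_participants,
        master_seed=seeds["participants"],
        criterion=config.criterion,
        standardize=config.standardize_participants,
    )
    severities = max_total_severities(scores).loc[Xr.row_ids]
    pc.severity_rank = rank_by_severity(pc.solution, severities.to_numpy())
    dsm5 = meta.delirium_labels(Xr.row_ids) if meta is not None else None
    if dsm5 is not None and any(v is not None for v in dsm5):
        pc.delirium_label = label_delirium(pc.solution, dsm5)
    pc.to_frame().to_csv(out / "participant_clusters.tsv", sep="\t", index=False)

    covars = None
    if meta is not None:
        covars = meta.table.drop(columns=["delirium_dsm5"], errors="ignore")
        covars = covars.loc[[pid for pid in Xr.row_ids if pid in covars.index]]
        covars = covars.reindex(Xr.row_ids)
    summary = cluster_summary(pc, severities.to_numpy(), dsm5, covars)
    summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)

    log.info("stage: post-hoc characterization")
    profile = None
    anova = None
    if pc.K >= 2:
        profile = posthoc_profile(
            Xr, pc.solution, CharacterizationConfig(alpha_fwer=config.alpha_fwer)
        )
        roles = None
        if grouping.G == 4:
            comp = {grouping.name_of(g): grouping.members(g) for g in range(4)}
            roles = {name: role for name, role in infer_roles(comp).items()}
        interpret_labels(profile, roles)
        sign = profile.sign_table()
        sign.insert(0, "cluster", range(profile.K))
        sign["interpretation"] = profile.labels
        sign.to_csv(out / "cluster_profile.tsv", sep="\t", index=False)
        if covars is not None and len(covars.columns):
            anova = anova_table(covars, pc.solution)
            anova.to_csv(out / "anova.tsv", sep="\t", index=False)

    log.info("stage: embeddings")
    proj_feat = pca_2d(X.values.T)
    render_views(
        proj_feat,
        X.col_labels,
        [grouping.group_of[c] for c in X.col_labels],
        out / "embedding_features.tsv",
        image=config.write_images,
    )
    proj_part = pca_2d(Xr.values)
    render_views(
        proj_part,
        Xr.row_ids,
        pc.solution.assignments.tolist(),
        out / "embedding_participants.tsv",
        diagnosis=["" if v is None else v for v in dsm5] if dsm5 else None,
        image=config.write_images,
    )

    manifest = {
        "version": __version__,
        "master_seed": int(config.master_seed),
        "stage_seeds": seeds,
        "criterion": config.criterion,
        "selected_K": {
            "features": int(grouping.G),
            "participants": int(pc.K),
        },
        "selection_features": grouping.selection.to_dict(),
        "selection_participants": pc.selection.to_dict(),
        "alpha_fwer": config.alpha_fwer,
        "n_participants": len(Xr.row_ids),
        "n_features": X.n_features,
        "elapsed_s": round(time.time() - t0, 3),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    write_json_results(manifest, out / "manifest.json")
    return manifest


def run_pipeline_files(
    scores_path: str | Path,
    meta_path: str | Path | None,
    config: PipelineConfig,
) -> dict:
    scores = read_long(scores_path)
    meta = read_meta(meta_path) if meta_path else None
    return run_pipeline(scores, meta, config)


REQUIRED_ARTIFACTS = [
    "manifest.json",
    "feature_grouping.tsv",
    "participant_clusters.tsv",
    "cluster_summary.tsv",
]


def report(results_dir: str | Path) -> str:
    """Render a markdown summary from a completed results directory."""
    out = Path(results_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (out / a).exists()]
    if missing:
        raise DataError(f"incomplete results bundle; missing: {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    lines = [
        "# delirclust run summary",
        "",
        f"- package version: {manifest['version']}",
        f"- master seed: {manifest['master_seed']}",
        f"- selection criterion: {manifest['criterion']}",
        f"- participants: {manifest['n_participants']}, "
        f"feature cells: {manifest['n_features']}",
        f"- selected feature groups G = {manifest['selected_K']['features']}",
        f"- selected participant clusters K = {manifest['selected_K']['participants']}",
        "",
        "## Cluster summary (ordered by severity rank)",
        "",
    ]
    summary = pd.read_csv(out / "cluster_summary.tsv", sep="\t")
    lines.append(summary.to_string(index=False))
    prof_path = out / "cluster_profile.tsv"
    if prof_path.exists():
        lines += ["", "## Cluster-by-feature direction profile", ""]
        lines.append(pd.read_csv(prof_path, sep="\t").to_string(index=False))
    anova_path = out / "anova.tsv"
    if anova_path.exists():
        lines += ["", "## Covariate ANOVA across clusters", ""]
        lines.append(pd.read_csv(anova_path, sep="\t").to_string(index=False))
    return "\n".join(lines) + "\n"
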