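"""2-D PCA views of the two clustering stages.

View A embeds the 65 item@day column vectors and colors them by feature
group; columns grouped together sit close in PC space.  View B embeds
participants in composite space colored by cluster, with the DSM-5
diagnosis as the marker distinction.
"""

from pathlib import Path

import delirclust as dc

cohort = dc.simulate(dc.default_design(), seed=17)
X = dc.to_wide(cohort.scores)
grouping = dc.group_features(X, restarts=200, master_seed=1)
Xr = dc.reduce(X, grouping)
pc = dc.cluster_participants(Xr, restarts=200, master_seed=2)

out = Path("scratch") / "embeddings"
out.mkdir(parents=True, exist_ok=True)

proj_a = dc.pca_2d(X.values.T)
dc.render_views(proj_a, X.col_labels,
                [grouping.group_of[c] for c in X.col_labels],
                out / "features.tsv")
print("view A (features):  PC1 %.1f%%, PC2 %.1f%% of variance"
      % tuple(100 * f for f in proj_a.explained_variance_fraction))

proj_b = dc.pca_2d(Xr.values)
dc.render_views(proj_b, Xr.row_ids, pc.solution.assignments.tolist(),
                out / "participants.tsv",
                diagnosis=cohort.meta.delirium_labels(Xr.row_ids))
print("view B (participants): PC1 %.1f%%, PC2 %.1f%% of variance"
      % tuple(100 * f for f in proj_b.explained_variance_fraction))
print(f"scatter TSVs written under {out}/")
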