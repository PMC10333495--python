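"""Post-hoc statistical characterization of participant clusters.

For every (cluster, grouped feature) pair a one-sample t-test asks whether
the cluster's mean composite differs from the cohort-wide mean of that
composite (the baseline includes the tested cluster's own members, which
makes the tests mildly conservative under the null).  The family of all
K x G tests is controlled at a family-wise error rate alpha by Bonferroni
division, and each significant pair is graded +/++/+++ (or -/--/---) by
binning its Bonferroni-corrected p-value.  One-way ANOVA across clusters
screens per-participant covariates for any between-cluster differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError
from .grouping import ReducedMatrix
from .kmeans import ClusteringSolution

ELEVATED = "elevated"
DEPRESSED = "depressed"
NS = "N.S."


@dataclass(frozen=True)
class CharacterizationConfig:
    alpha_fwer: float = 0.05
    #: corrected-p cutoffs mapping to grades 1, 2, 3 (+ / ++ / +++)
    grading_cutoffs: tuple[float, ...] = (0.05, 0.01, 0.001)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fwer < 1:
            raise DataError("alpha_fwer must be in (0,1)")
        if list(self.grading_cutoffs) != sorted(self.grading_cutoffs, reverse=True):
            raise DataError("grading cutoffs must be strictly decreasing")


@dataclass
class ClusterProfile:
    """Per-(cluster, grouped feature) test results and grades."""

    t: pd.DataFrame          # clusters x groups
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame
    direction: pd.DataFrame  # entries in {elevated, depressed, N.S.}
    grade: pd.DataFrame      # entries in {0,1,2,3}
    m_tests: int
    config: CharacterizationConfig
    baseline: pd.Series
    labels: list[str] | None = None

    @property
    def K(self) -> int:
        return self.t.shape[0]

    def sign_table(self) -> pd.DataFrame:
        """Table-style view with cells in {- - -, - -, -, N.S., +, + +, + + +}."""

        def cell(direction: str, grade: int) -> str:
            if direction == NS or grade == 0:
                return NS
            mark = "+" if direction == ELEVATED else "−"
            return " ".join([mark] * grade)

        out = self.direction.copy()
        for i in out.index:
            for c in out.columns:
                out.loc[i, c] = cell(self.direction.loc[i, c], int(self.grade.loc[i, c]))
        return out


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean(values) against ``mu0``.

    Returns (t, p) with df = n - 1.  A zero-variance sample is degenerate:
    if its mean equals ``mu0`` the test is (0, 1); otherwise the difference
    is exact and reported as (signed inf, 0).
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise DataError("one_sample_t needs a sample of size >= 2")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        if mean == mu0:
            return 0.0, 1.0
        warnings.warn("zero-variance sample with nonzero shift; t is infinite")
        return math.copysign(math.inf, mean - mu0), 0.0
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def posthoc_profile(
    Xr: ReducedMatrix,
    clustering: ClusteringSolution,
    config: CharacterizationConfig | None = None,
) -> ClusterProfile:
    """Bonferroni-controlled battery of cluster-vs-baseline t-tests."""
    config = config or CharacterizationConfig()
    if clustering.assignments.shape[0] != len(Xr.row_ids):
        raise DataError("clustering does not cover the reduced matrix rows")
    if clustering.K < 2:
        raise DataError("post-hoc characterization needs K >= 2")
    K, G = clustering.K, Xr.G
    m = K * G
    baseline = pd.Series(Xr.values.mean(axis=0), index=Xr.group_labels)
    t = pd.DataFrame(np.zeros((K, G)), columns=Xr.group_labels)
    p_raw = pd.DataFrame(np.ones((K, G)), columns=Xr.group_labels)
    for k in range(K):
        mask = clustering.assignments == k
        if not mask.any():
            raise DataError(f"cluster {k} is empty")
        for j, g in enumerate(Xr.group_labels):
            tv, pv = one_sample_t(Xr.values[mask, j], baseline[g])
            t.iloc[k, j] = tv
            p_raw.iloc[k, j] = pv
    p_corr = (p_raw * m).clip(upper=1.0)
    direction = p_raw.copy().astype(object)
    grade = p_raw.copy()
    for k in range(K):
        for j in range(G):
            significant = p_raw.iloc[k, j] <= config.alpha_fwer / m
            if not significant:
                direction.iloc[k, j] = NS
                grade.iloc[k, j] = 0
            else:
                direction.iloc[k, j] = ELEVATED if t.iloc[k, j] > 0 else DEPRESSED
                gr = 0
                for cut in config.grading_cutoffs:
                    if p_corr.iloc[k, j] <= cut:
                        gr += 1
                grade.iloc[k, j] = gr
    return ClusterProfile(
        t=t,
        p_raw=p_raw,
        p_corrected=p_corr,
        direction=direction,
        grade=grade.astype(int),
        m_tests=m,
        config=config,
        baseline=baseline,
    )


def anova_across_clusters(
    covariate: Sequence[float], clustering: ClusteringSolution
) -> tuple[float, float, int, int]:
    """One-way fixed-effects ANOVA of a covariate across clusters.

    Clusters with fewer than 2 non-missing values are excluded with a
    warning.  Returns (F, p, df_between, df_within).
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != clustering.assignments.shape[0]:
        raise DataError("one covariate value per clustered participant required")
    groups = []
    for k in range(clustering.K):
        vals = x[clustering.assignments == k]
        vals = vals[np.isfinite(vals)]
        if vals.shape[0] < 2:
            warnings.warn(f"cluster {k} has <2 covariate values; excluded from ANOVA")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise DataError("ANOVA needs at least 2 clusters with >= 2 members")
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        raise DataError("zero total variance in covariate")
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = allv.shape[0] - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), p, dfb, dfw


def anova_table(
    covariates: pd.DataFrame, clustering: ClusteringSolution
) -> pd.DataFrame:
    """ANOVA screen of every numeric covariate column (complete-case)."""
    rows = []
    for col in covariates.columns:
        vals = pd.to_numeric(covariates[col], errors="coerce").to_numpy()
        try:
            F, p, dfb, dfw = anova_across_clusters(vals, clustering)
            rows.append({"covariate": col, "F": F, "df_between": dfb,
                         "df_within": dfw, "p": p})
        except DataError as exc:
            rows.append({"covariate": col, "F": np.nan, "df_between": np.nan,
                         "df_within": np.nan, "p": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical-style interpretation of direction patterns

#: roles a grouped feature can play in the interpretation rules
ROLES = ("motor", "cognitive", "acute", "sleep")

_LABEL_RULES: list[tuple[dict[str, str], str]] = [
    ({"motor": NS, "cognitive": ELEVATED, "acute": NS, "sleep": NS},
     "cognitive and higher-order thinking domain dominant delirium"),
    ({"motor": ELEVATED, "cognitive": ELEVATED, "acute": ELEVATED, "sleep": NS},
     "prolonged delirium"),
    ({"motor": NS, "cognitive": NS, "acute": ELEVATED, "sleep": NS},
     "acute and brief delirium"),
    ({"motor": ELEVATED, "cognitive": ELEVATED, "acute": NS, "sleep": NS},
     "subsyndromal delirium-enriched"),
    ({"motor": NS, "cognitive": ELEVATED, "acute": NS, "sleep": ELEVATED},
     "subsyndromal delirium-enriched with insomnia"),
    ({"motor": DEPRESSED, "cognitive": DEPRESSED, "acute": DEPRESSED,
      "sleep": ELEVATED}, "insomnia"),
    ({"motor": DEPRESSED, "cognitive": DEPRESSED, "acute": DEPRESSED,
      "sleep": DEPRESSED}, "fit"),
]

UNCLASSIFIED = "unclassified pattern"


def interpret_labels(
    profile: ClusterProfile, roles: Mapping[str, str] | None = None
) -> list[str]:
    """Map each cluster's direction pattern to a clinical-style label.

    ``roles`` maps each grouped-feature column name of the profile to one of
    ``motor / cognitive / acute / sleep``; when omitted, column names that
    already are role names are used.  Patterns outside the seven recognized
    archetypes fall back to "unclassified pattern".  Stored on the profile
    and returned.
    """
    cols = list(profile.direction.columns)
    if roles is None:
        roles = {c: c for c in cols}
    unknown = [c for c in cols if roles.get(c) not in ROLES]
    if len(cols) != len(ROLES) or unknown:
        # pattern rules are only defined for the four canonical roles
        profile.labels = [UNCLASSIFIED] * profile.K
        return profile.labels
    labels = []
    for k in range(profile.K):
        pattern = {roles[c]: profile.direction.iloc[k][c] for c in cols}
        for rule, name in _LABEL_RULES:
            if pattern == rule:
                labels.append(name)
                break
        else:
            labels.append(UNCLASSIFIED)
    profile.labels = labels
    return labels


def null_fwer(
    n_replicates: int = 500,
    cluster_sizes: Sequence[int] = (6, 8, 13, 28, 26, 80, 125),
    n_groups: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical family-wise error rate of the battery under a global null.

    Each replicate draws every participant's composites i.i.d. from a
    standard normal (no cluster structure), assigns participants to clusters
    of the given sizes uniformly at random, runs the Bonferroni-corrected
    battery, and records whether any (cluster, feature) test rejected.
    Returns (fraction of replicates with >= 1 rejection, Monte-Carlo SE of
    that fraction).  With Bonferroni control the fraction should not exceed
    ``alpha`` beyond Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(cluster_sizes, dtype=int)
    n = int(sizes.sum())
    config = CharacterizationConfig(alpha_fwer=alpha)
    base_assign = np.repeat(np.arange(len(sizes)), sizes)
    labels = [f"g{j}" for j in range(n_groups)]
    hits = 0
    for _ in range(n_replicates):
        values = rng.normal(size=(n, n_groups))
        assign = rng.permutation(base_assign)
        Xr = ReducedMatrix(values, [f"p{i}" for i in range(n)], labels)
        sol = ClusteringSolution(
            K=len(sizes),
            assignments=assign,
            centroids=np.zeros((len(sizes), n_groups)),
            wcss=0.0,
        )
        profile = posthoc_profile(Xr, sol, config)
        if (profile.direction != NS).any().any():
            hits += 1
    rate = hits / n_replicates
    se = float(np.sqrt(max(rate, 1.0 / n_replicates) * (1 - rate) / n_replicates))
    return rate, se


def infer_roles(group_composition: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Heuristic role assignment from each group's member cells.

    ``group_composition`` maps group name -> list of ``item@d<day>`` member
    labels.  The sleep role goes to the group dominated by the sleep item,
    the acute role to the group dominated by day-1 cells, the cognitive role
    to the group with the largest share of cognitive/higher-order items, and
    the motor role to the remainder.  Mirrors the visual-inspection step a
    human performs on the grouped-feature table; only usable when G = 4.
    """
    from .data import parse_col_label

    names = list(group_composition)
    if len(names) != 4:
        raise DataError("role inference is defined for exactly 4 groups")
    cognitive_items = {
        "orientation", "attention", "short_term_memory", "long_term_memory",
        "visuospatial_ability", "language", "thought_process",
        "perceptual_disturbance", "delusion",
    }

    def frac(name, pred):
        cells = [parse_col_label(c) for c in group_composition[name]]
        return sum(1 for it, d in cells if pred(it, d)) / len(cells)

    roles: dict[str, str] = {}
    remaining = set(names)
    sleep = max(remaining, key=lambda n: frac(n, lambda it, d: it == "sleep_wake_cycle"))
    roles[sleep] = "sleep"
    remaining.discard(sleep)
    acute = max(remaining, key=lambda n: frac(n, lambda it, d: d == 1))
    roles[acute] = "acute"
    remaining.discard(acute)
    cog = max(remaining, key=lambda n: frac(n, lambda it, d: it in cognitive_items))
    roles[cog] = "cognitive"
    remaining.discard(cog)
    roles[remaining.pop()] = "motor"
    return roles
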