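"""Synthetic cohort generator with planted feature groups and archetypes.

The study cohort behind this pipeline is not publicly released, so every
stage is exercised on a simulated stand-in: 286 participants, 13 ordinal
0-3 severity items over 5 postoperative days, built from

* a planted partition of the 65 item@day cells into 4 feature groups
  (sleep-only, day-1 acute, cognitive/higher-order, mixed motor) — an
  explicit approximation of the reference grouped-feature table, stored as
  configuration, and
* 7 participant archetypes whose per-group mean severities realize the
  reference elevated/depressed/neutral direction patterns, with sizes
  (6, 8, 13, 28, 26, 80, 125) and per-archetype delirium-label
  probabilities taken from the reference cluster table.

Scores are discretized Gaussians: ``round(clip(mean + N(0, noise_sd)))``
(numpy round-half-even), clipped to the ordinal range.  An optional AR(1)
latent correlates an item's noise across days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data import (
    DataError,
    FeatureMatrix,
    ItemCatalog,
    LongitudinalScores,
    ParticipantMeta,
    col_label,
    from_wide,
    parse_col_label,
    wide_column_order,
    write_long,
    write_meta,
)

GROUP_NAMES = ("motor", "cognitive", "acute", "sleep")

#: items treated as cognitive / higher-order / perception-content domain
COGNITIVE_ITEMS = (
    "orientation",
    "attention",
    "short_term_memory",
    "long_term_memory",
    "visuospatial_ability",
    "language",
    "thought_process",
    "perceptual_disturbance",
    "delusion",
)

DEFAULT_NOISE_SD = 0.4

# per-group mean item scores realizing the direction patterns
ELEV, NEUT, DEPR = 2.0, 0.5, 0.2

#: (name, size, (motor, cognitive, acute, sleep) means, delirium prob numerator/denominator)
_DEFAULT_ARCHETYPES = (
    ("cognitive-dominant delirium", 6, (NEUT, ELEV, NEUT, NEUT), (6, 6)),
    ("prolonged delirium", 8, (ELEV, ELEV, ELEV, NEUT), (8, 8)),
    ("acute and brief delirium", 13, (NEUT, NEUT, ELEV, NEUT), (13, 13)),
    ("subsyndromal delirium-enriched", 28, (ELEV, ELEV, NEUT, NEUT), (27, 28)),
    ("subsyndromal delirium-enriched with insomnia", 26, (NEUT, ELEV, NEUT, ELEV), (20, 26)),
    ("insomnia", 80, (DEPR, DEPR, DEPR, ELEV), (12, 80)),
    ("fit", 125, (DEPR, DEPR, DEPR, DEPR), (5, 125)),
)


@dataclass
class Archetype:
    """One planted participant cluster."""

    name: str
    size: int
    #: mean item score per planted group; either a length-G vector shared by
    #: all days or a G x D matrix of per-day means
    means: np.ndarray
    delirium_probability: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.size < 1:
            raise DataError("archetype size must be >= 1")
        if not 0 <= self.delirium_probability <= 1:
            raise DataError("delirium_probability must be in [0,1]")

    def mean_for(self, group: int, day: int) -> float:
        if self.means.ndim == 1:
            return float(self.means[group])
        return float(self.means[group, day - 1])


@dataclass
class PlantedDesign:
    """Full specification of a synthetic cohort."""

    feature_partition: dict[str, int]     # col_label -> group index
    archetypes: list[Archetype]
    group_names: tuple[str, ...] = GROUP_NAMES
    noise_sd: float = DEFAULT_NOISE_SD
    ar1_rho: float = 0.0                  # optional day-to-day noise correlation
    catalog: ItemCatalog = field(default_factory=ItemCatalog)
    n_days: int = 5

    def __post_init__(self) -> None:
        expected = set(wide_column_order(self.catalog, self.n_days))
        if set(self.feature_partition) != expected:
            raise DataError("feature partition must cover every item@day cell exactly once")
        G = len(self.group_names)
        if set(self.feature_partition.values()) - set(range(G)):
            raise DataError("partition group indices out of range")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not -1 < self.ar1_rho < 1:
            raise DataError("ar1_rho must be in (-1, 1)")
        for a in self.archetypes:
            if a.means.shape not in {(G,), (G, self.n_days)}:
                raise DataError(
                    f"archetype {a.name!r} means must be length {G} or {G} x {self.n_days}"
                )

    @property
    def n_participants(self) -> int:
        return sum(a.size for a in self.archetypes)

    @property
    def G(self) -> int:
        return len(self.group_names)

    def partition_labels(self, col_labels: Sequence[str]) -> np.ndarray:
        return np.array([self.feature_partition[c] for c in col_labels])

    # -- serialization (documented design-file schema) ---------------------
    def to_dict(self) -> dict:
        return {
            "group_names": list(self.group_names),
            "noise_sd": self.noise_sd,
            "ar1_rho": self.ar1_rho,
            "n_days": self.n_days,
            "items": list(self.catalog.items),
            "score_min": self.catalog.score_min,
            "score_max": self.catalog.score_max,
            "feature_partition": self.feature_partition,
            "archetypes": [
                {
                    "name": a.name,
                    "size": a.size,
                    "means": a.means.tolist(),
                    "delirium_probability": a.delirium_probability,
                }
                for a in self.archetypes
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlantedDesign":
        catalog = ItemCatalog(
            items=tuple(d.get("items", ItemCatalog().items)),
            score_min=int(d.get("score_min", 0)),
            score_max=int(d.get("score_max", 3)),
        )
        return cls(
            feature_partition={k: int(v) for k, v in d["feature_partition"].items()},
            archetypes=[
                Archetype(
                    name=a["name"],
                    size=int(a["size"]),
                    means=np.asarray(a["means"], dtype=float),
                    delirium_probability=float(a["delirium_probability"]),
                )
                for a in d["archetypes"]
            ],
            group_names=tuple(d.get("group_names", GROUP_NAMES)),
            noise_sd=float(d.get("noise_sd", DEFAULT_NOISE_SD)),
            ar1_rho=float(d.get("ar1_rho", 0.0)),
            catalog=catalog,
            n_days=int(d.get("n_days", 5)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PlantedDesign":
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def default_partition(catalog: ItemCatalog | None = None, n_days: int = 5) -> dict[str, int]:
    """The default planted 4-group partition of the 65 cells.

    sleep: the sleep-wake item on all days; acute: every other item on
    day 1; cognitive: cognitive/higher-order plus perception/content items
    on days 2+; motor: the remaining (motor/affect) cells on days 2+.
    """
    catalog = catalog or ItemCatalog()
    part: dict[str, int] = {}
    for d in range(1, n_days + 1):
        for it in catalog.items:
            if it == "sleep_wake_cycle":
                g = 3
            elif d == 1:
                g = 2
            elif it in COGNITIVE_ITEMS:
                g = 1
            else:
                g = 0
            part[col_label(it, d)] = g
    return part


def default_design(noise_sd: float = DEFAULT_NOISE_SD) -> PlantedDesign:
    """The reference 286-participant design: 7 archetypes, 4 planted groups."""
    archetypes = [
        Archetype(name=n, size=s, means=np.asarray(m), delirium_probability=num / den)
        for n, s, m, (num, den) in _DEFAULT_ARCHETYPES
    ]
    return PlantedDesign(
        feature_partition=default_partition(),
        archetypes=archetypes,
        noise_sd=noise_sd,
    )


@dataclass
class SyntheticCohort:
    """Simulated scores, metadata, and the generating ground truth."""

    scores: LongitudinalScores
    meta: ParticipantMeta
    truth_archetype: np.ndarray          # per-participant archetype index
    design: PlantedDesign
    seed: int

    @property
    def participants(self) -> list[str]:
        return self.scores.participants

    def truth_feature_labels(self, col_labels: Sequence[str]) -> np.ndarray:
        return self.design.partition_labels(col_labels)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write long CSV + metadata CSV + truth JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": out / "scores_long.csv",
            "meta": out / "meta.csv",
            "truth": out / "truth.json",
        }
        write_long(self.scores, paths["scores"])
        write_meta(self.meta, paths["meta"])
        paths["truth"].write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "archetype_of": {
                        pid: int(a)
                        for pid, a in zip(self.participants, self.truth_archetype)
                    },
                    "archetype_names": [a.name for a in self.design.archetypes],
                    "feature_partition": self.design.feature_partition,
                    "group_names": list(self.design.group_names),
                },
                indent=2,
            )
            + "\n"
        )
        return paths


def simulate(design: PlantedDesign, seed: int = 0) -> SyntheticCohort:
    """Draw one cohort from a planted design, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    catalog, D = design.catalog, design.n_days
    cols = wide_column_order(catalog, D)
    groups = design.partition_labels(cols)
    days = np.array([parse_col_label(c)[1] for c in cols])
    items = [parse_col_label(c)[0] for c in cols]

    n = design.n_participants
    arch_idx = np.repeat(np.arange(len(design.archetypes)),
                         [a.size for a in design.archetypes])
    ids = [f"P{i + 1:04d}" for i in range(n)]

    mu = np.empty((n, len(cols)))
    for j in range(len(cols)):
        for ai, a in enumerate(design.archetypes):
            mu[arch_idx == ai, j] = a.mean_for(int(groups[j]), int(days[j]))

    if design.ar1_rho:
        # correlate an item's noise across its days with an AR(1) latent
        noise = np.empty((n, len(cols)))
        rho = design.ar1_rho
        for it in catalog.items:
            idx = [j for j in range(len(cols)) if items[j] == it]
            idx.sort(key=lambda j: days[j])
            e = rng.normal(0.0, design.noise_sd, size=(n, len(idx)))
            z = np.empty_like(e)
            z[:, 0] = e[:, 0]
            for t in range(1, len(idx)):
                z[:, t] = rho * z[:, t - 1] + np.sqrt(1 - rho**2) * e[:, t]
            for t, j in enumerate(idx):
                noise[:, j] = z[:, t]
    else:
        noise = rng.normal(0.0, design.noise_sd, size=mu.shape)

    raw = np.round(np.clip(mu + noise, catalog.score_min, catalog.score_max))
    matrix = FeatureMatrix(raw, ids, cols)
    scores = from_wide(matrix, catalog=catalog, n_days=D)

    probs = np.array([design.archetypes[a].delirium_probability for a in arch_idx])
    labels = rng.random(n) < probs
    # null covariates (no planted cluster signal) for ANOVA exercises
    age = np.clip(rng.normal(66.0, 10.0, n), 20, 95).round(1)
    mmse = np.clip(rng.normal(28.5, 1.5, n), 0, 30).round(0)
    meta = ParticipantMeta(
        pd.DataFrame(
            {
                "participant": ids,
                "delirium_dsm5": labels,
                "age": age,
                "mmse": mmse,
            }
        )
    )
    return SyntheticCohort(
        scores=scores, meta=meta, truth_archetype=arch_idx, design=design,
        seed=int(seed),
    )


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions (ARI in [-1, 1])."""
    if len(labels_a) != len(labels_b):
        raise DataError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
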