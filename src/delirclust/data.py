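"""Data model and tabular I/O for longitudinal ordinal symptom scores.

The raw input is a set of severity ratings: one ordinal score per
(participant, postoperative day, questionnaire item) cell.  The default
catalog is the 13-item DRS-R-98 severity subscale, each item scored 0-3,
assessed on 5 consecutive postoperative days, giving a complete participant
65 cells.  Analysis operates on the wide "feature matrix" whose columns are
``<item>@d<day>`` cells in day-major order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical DRS-R-98 severity items.  The instrument does not impose a
#: single published ordering of all 13 items in one list, so this order is a
#: package convention (documented in docs/methods.md); the catalog is
#: configuration, not logic.
DEFAULT_ITEMS: tuple[str, ...] = (
    "sleep_wake_cycle",
    "perceptual_disturbance",
    "delusion",
    "affective_lability",
    "language",
    "thought_process",
    "motor_agitation",
    "motor_retardation",
    "orientation",
    "attention",
    "short_term_memory",
    "long_term_memory",
    "visuospatial_ability",
)

DEFAULT_DAYS = 5


class DataError(ValueError):
    """Malformed, duplicate, incomplete or out-of-range score data."""


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered list of item names plus the shared ordinal score range."""

    items: tuple[str, ...] = DEFAULT_ITEMS
    score_min: int = 0
    score_max: int = 3

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise DataError("catalog needs at least one item")
        if len(set(self.items)) != len(self.items):
            raise DataError("item names must be unique")
        if any(not name for name in self.items):
            raise DataError("item names must be non-empty")
        if not self.score_min < self.score_max:
            raise DataError("score_min must be < score_max")

    def index_of(self, item: str) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise DataError(f"unknown item {item!r}") from None


def col_label(item: str, day: int) -> str:
    return f"{item}@d{day}"


def parse_col_label(label: str) -> tuple[str, int]:
    """Split ``<item>@d<day>`` back into its parts."""
    item, sep, daypart = label.rpartition("@d")
    if not sep or not daypart.isdigit():
        raise DataError(f"malformed column label {label!r}")
    return item, int(daypart)


@dataclass
class LongitudinalScores:
    """Tidy per-cell score records.

    ``records`` is a DataFrame with columns participant, day, item, score;
    at most one row per (participant, day, item).  A participant is
    "complete" when all ``n_days * len(catalog.items)`` cells are present.
    """

    records: pd.DataFrame
    n_days: int = DEFAULT_DAYS
    catalog: ItemCatalog = field(default_factory=ItemCatalog)

    def __post_init__(self) -> None:
        req = ["participant", "day", "item", "score"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise DataError(f"records missing columns {missing}")
        rec = self.records[req].copy()
        rec["participant"] = rec["participant"].astype(str)
        rec["day"] = rec["day"].astype(int)
        rec["score"] = rec["score"].astype(int)
        bad_day = rec[(rec["day"] < 1) | (rec["day"] > self.n_days)]
        if len(bad_day):
            raise DataError(
                f"day out of range 1..{self.n_days}: "
                f"{sorted(bad_day['day'].unique().tolist())}"
            )
        unknown = set(rec["item"]) - set(self.catalog.items)
        if unknown:
            raise DataError(f"unknown items: {sorted(unknown)}")
        lo, hi = self.catalog.score_min, self.catalog.score_max
        bad = rec[(rec["score"] < lo) | (rec["score"] > hi)]
        if len(bad):
            raise DataError(f"score out of range [{lo},{hi}]")
        dup = rec.duplicated(subset=["participant", "day", "item"])
        if dup.any():
            first = rec[dup].iloc[0]
            raise DataError(
                "duplicate record for "
                f"({first['participant']}, day {first['day']}, {first['item']})"
            )
        self.records = rec.reset_index(drop=True)

    @property
    def participants(self) -> list[str]:
        """Participant ids in first-appearance order."""
        return list(dict.fromkeys(self.records["participant"]))

    def missing_cells(self, participant: str) -> list[tuple[int, str]]:
        sub = self.records[self.records["participant"] == participant]
        have = set(zip(sub["day"], sub["item"]))
        return [
            (d, it)
            for d in range(1, self.n_days + 1)
            for it in self.catalog.items
            if (d, it) not in have
        ]

    def is_complete(self, participant: str) -> bool:
        return not self.missing_cells(participant)


@dataclass
class ParticipantMeta:
    """Per-participant metadata: binary diagnosis label plus covariates.

    ``table`` is indexed by participant id; the diagnosis column
    ``delirium_dsm5`` is boolean (NA allowed); remaining columns are free
    numeric/boolean covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "participant":
            if "participant" in self.table.columns:
                self.table = self.table.set_index("participant")
            else:
                raise DataError("metadata needs a participant column/index")
        self.table.index = self.table.index.astype(str)
        if self.table.index.duplicated().any():
            raise DataError("duplicate participant ids in metadata")

    def delirium_labels(self, ids: Sequence[str]) -> list[bool | None]:
        """DSM-5 labels aligned to ``ids``; missing/NA -> None."""
        out: list[bool | None] = []
        col = self.table.get("delirium_dsm5")
        for pid in ids:
            if col is None or pid not in self.table.index or pd.isna(col.loc[pid]):
                out.append(None)
            else:
                out.append(bool(col.loc[pid]))
        return out


@dataclass
class FeatureMatrix:
    """Participants x (item@day) wide matrix of scores."""

    values: np.ndarray
    row_ids: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_labels)):
            raise DataError("matrix shape does not match row/col labels")
        if not np.isfinite(self.values).all():
            raise DataError("feature matrix contains missing/non-finite entries")
        for lab in self.col_labels:
            parse_col_label(lab)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.col_labels)
        df.insert(0, "participant", self.row_ids)
        return df


def wide_column_order(catalog: ItemCatalog, n_days: int) -> list[str]:
    """Day-major column order: all items of day 1, then day 2, ..."""
    return [
        col_label(it, d) for d in range(1, n_days + 1) for it in catalog.items
    ]


def to_wide(scores: LongitudinalScores) -> FeatureMatrix:
    """Pivot complete long records to the participants x cells matrix."""
    ids = scores.participants
    for pid in ids:
        miss = scores.missing_cells(pid)
        if miss:
            shown = ", ".join(f"d{d}:{it}" for d, it in miss[:5])
            more = "" if len(miss) <= 5 else f" (+{len(miss) - 5} more)"
            raise DataError(f"participant {pid} incomplete: missing {shown}{more}")
    cols = wide_column_order(scores.catalog, scores.n_days)
    rec = scores.records
    piv = rec.pivot(index="participant", columns=["day", "item"], values="score")
    piv.columns = [col_label(it, d) for d, it in piv.columns]
    piv = piv.loc[ids, cols]
    return FeatureMatrix(piv.to_numpy(dtype=float), ids, cols)


def from_wide(matrix: FeatureMatrix, catalog: ItemCatalog | None = None,
              n_days: int | None = None) -> LongitudinalScores:
    """Inverse of :func:`to_wide` (used for round-trip checks and file input)."""
    catalog = catalog or ItemCatalog()
    days = [parse_col_label(c)[1] for c in matrix.col_labels]
    n_days = n_days or max(days)
    rows = []
    for i, pid in enumerate(matrix.row_ids):
        for j, lab in enumerate(matrix.col_labels):
            item, day = parse_col_label(lab)
            rows.append((pid, day, item, int(matrix.values[i, j])))
    rec = pd.DataFrame(rows, columns=["participant", "day", "item", "score"])
    return LongitudinalScores(rec, n_days=n_days, catalog=catalog)


def max_total_severity(scores: LongitudinalScores, participant: str) -> float:
    """Max over days of the participant's total (all-item) score that day.

    This is the "maximum total severity over the assessment window" summary
    used to order participant clusters from most to least severe.
    """
    if participant not in set(scores.records["participant"]):
        raise DataError(f"unknown participant {participant!r}")
    if not scores.is_complete(participant):
        raise DataError(f"participant {participant!r} incomplete")
    sub = scores.records[scores.records["participant"] == participant]
    return float(sub.groupby("day")["score"].sum().max())


def max_total_severities(scores: LongitudinalScores) -> pd.Series:
    """Per-participant max daily total, aligned to participant order."""
    ids = scores.participants
    return pd.Series(
        [max_total_severity(scores, pid) for pid in ids], index=ids, name="drs_max"
    )


# ---------------------------------------------------------------------------
# file I/O (delimiter-separated text; delimiter inferred from extension)

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_long(path: str | Path, catalog: ItemCatalog | None = None,
              n_days: int = DEFAULT_DAYS) -> LongitudinalScores:
    """Read long-format scores (header: participant,day,item,score)."""
    path = Path(path)
    catalog = catalog or ItemCatalog()
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc
    for col in ("day", "score"):
        if col in df.columns:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise DataError(
                    f"malformed row at line {int(bad.index[0]) + 2} of {path}: "
                    f"non-numeric {col!r}"
                )
    return LongitudinalScores(df, n_days=n_days, catalog=catalog)


def write_long(scores: LongitudinalScores, path: str | Path) -> None:
    path = Path(path)
    rec = scores.records.sort_values(
        ["participant", "day", "item"],
        key=lambda s: s.map(scores.catalog.index_of) if s.name == "item" else s,
    )
    rec.to_csv(path, sep=_sep_for(path), index=False)


def read_wide(path: str | Path, catalog: ItemCatalog | None = None) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "participant" not in df.columns:
        raise DataError(f"{path} lacks a participant column")
    ids = df["participant"].astype(str).tolist()
    cols = [c for c in df.columns if c != "participant"]
    return FeatureMatrix(df[cols].to_numpy(dtype=float), ids, cols)


def write_wide(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_meta(path: str | Path) -> ParticipantMeta:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return ParticipantMeta(df)


def write_meta(meta: ParticipantMeta, path: str | Path) -> None:
    path = Path(path)
    meta.table.reset_index().to_csv(path, sep=_sep_for(path), index=False)


def write_json_results(results: Mapping, path: str | Path) -> None:
    """Dump a results/manifest mapping to JSON (numpy types coerced)."""

    def coerce(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=coerce) + "\n")
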