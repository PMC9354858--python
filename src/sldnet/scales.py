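"""Composite symptom-scale scoring from multi-instrument item ratings.

Weekly depression ratings arrive as long-format item records from up to three
instruments (a clinician-rated HRSD-like scale and two self-report scales with
BDI-like and IDS-like structure). Items carry different maximum scores, so each
raw score is first rescaled to [0, 1] by dividing by its maximum possible
score; the rescaled items mapped to the same core depressive symptom are then
averaged into one of nine composite symptom scales per week. The result is a
per-patient 13-week x 9-symptom matrix of scale scores with a missingness
mask, the input to the linkage-density estimator.

The item -> symptom mapping is configuration (see
:func:`default_scale_map`); scale reliability is summarized by average
inter-item correlations computed across patients at a given week.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateRecordError,
    InvalidItemError,
    MappingError,
    ReliabilityUndefinedError,
)

#: The nine core depressive symptom labels, in the canonical (lexicographic)
#: order used throughout the package.
SYMPTOMS: tuple[str, ...] = (
    "appetite",
    "concentration",
    "energy",
    "guilt",
    "interest",
    "mood",
    "psychomotor",
    "sleep",
    "suicidality",
)

#: Number of weekly assessments: treatment weeks 1-12 plus one post-treatment
#: assessment as week 13.
N_WEEKS: int = 13

ITEM_COLUMNS = ("patient_id", "week", "instrument", "item_id", "score", "max_score")


@dataclass(frozen=True)
class ItemRecord:
    """One raw instrument item response at one week for one patient."""

    patient_id: str
    week: int
    instrument: str
    item_id: str
    score: int
    max_score: int

    def __post_init__(self):
        if self.max_score <= 0:
            raise InvalidItemError(f"max_score must be positive, got {self.max_score}")
        if not (0 <= self.score <= self.max_score):
            raise InvalidItemError(
                f"score {self.score} outside [0, {self.max_score}] for item "
                f"{self.instrument}/{self.item_id}"
            )
        if not (1 <= self.week <= N_WEEKS):
            raise InvalidItemError(f"week must be in 1..{N_WEEKS}, got {self.week}")


class ScaleMap:
    """Mapping from (instrument, item_id) to one of the nine symptom labels.

    Each item maps to at most one symptom; items not present in the map are
    ignored by the scorer. Entries may optionally carry the item's maximum
    score, which the synthetic generator uses for emission and the scorer
    uses to cross-check incoming records.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], str],
        max_scores: Mapping[tuple[str, str], int] | None = None,
    ):
        bad = sorted(set(entries.values()) - set(SYMPTOMS))
        if bad:
            raise MappingError(f"unknown symptom labels in scale map: {bad}")
        self._entries = dict(entries)
        self._max_scores = dict(max_scores or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def symptom_for(self, instrument: str, item_id: str) -> str | None:
        return self._entries.get((instrument, item_id))

    def max_score_for(self, instrument: str, item_id: str) -> int | None:
        return self._max_scores.get((instrument, item_id))

    def items_for(self, symptom: str) -> list[tuple[str, str]]:
        return sorted(k for k, v in self._entries.items() if v == symptom)

    @property
    def symptoms(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._entries.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "instrument": inst,
                "item_id": item,
                "symptom": sym,
                "max_score": self._max_scores.get((inst, item)),
            }
            for (inst, item), sym in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleMap":
        """Build from a nested ``{"symptoms": {label: [{instrument, item_id,
        max_score?}, ...]}}`` mapping (the YAML layout)."""
        entries: dict[tuple[str, str], str] = {}
        max_scores: dict[tuple[str, str], int] = {}
        for symptom, items in d["symptoms"].items():
            for spec in items:
                key = (spec["instrument"], spec["item_id"])
                if key in entries:
                    raise MappingError(f"item {key} mapped to more than one symptom")
                entries[key] = symptom
                if "max_score" in spec and spec["max_score"] is not None:
                    max_scores[key] = int(spec["max_score"])
        return cls(entries, max_scores)

    @classmethod
    def from_yaml(cls, path_or_buffer) -> "ScaleMap":
        if isinstance(path_or_buffer, (str, bytes)) or hasattr(path_or_buffer, "__fspath__"):
            with open(path_or_buffer) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(path_or_buffer))

    def to_yaml(self, path) -> None:
        d: dict = {"symptoms": {}}
        for (inst, item), sym in sorted(self._entries.items()):
            spec = {"instrument": inst, "item_id": item}
            if (inst, item) in self._max_scores:
                spec["max_score"] = self._max_scores[(inst, item)]
            d["symptoms"].setdefault(sym, []).append(spec)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def default_scale_map() -> ScaleMap:
    """The packaged default mapping (47 items across three instruments)."""
    text = resources.files("sldnet.data").joinpath("default_scale_map.yaml").read_text()
    return ScaleMap.from_yaml(io.StringIO(text))


@dataclass
class SymptomSeries:
    """Per-patient 13-week x 9-symptom matrix of [0, 1] scale scores.

    ``values[w, s]`` is the score at week ``w + 1`` for ``symptoms[s]``;
    missing entries are NaN. ``observed_weeks`` counts weeks with any
    instrument data.
    """

    patient_id: str
    values: np.ndarray
    observed_weeks: int
    symptoms: tuple[str, ...] = SYMPTOMS
    n_weeks: int = N_WEEKS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_weeks, len(self.symptoms)):
            raise ValueError(
                f"values must be {self.n_weeks}x{len(self.symptoms)}, got {self.values.shape}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("non-missing scale values must lie in [0, 1]")

    def to_long(self) -> pd.DataFrame:
        weeks = np.repeat(np.arange(1, self.n_weeks + 1), len(self.symptoms))
        syms = np.tile(np.array(self.symptoms, dtype=object), self.n_weeks)
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "week": weeks,
                "symptom": syms,
                "value": self.values.ravel(),
            }
        )


def rescale_item(score: float, max_score: float) -> float:
    """Rescale one raw item score to [0, 1] by its maximum possible score."""
    if max_score <= 0:
        raise InvalidItemError(f"max_score must be positive, got {max_score}")
    if not (0 <= score <= max_score):
        raise InvalidItemError(f"score {score} outside [0, {max_score}]")
    return score / max_score


def _validate_items(items: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise InvalidItemError(f"item table missing columns: {missing}")
    items = items.copy()
    if (items["max_score"] <= 0).any():
        raise InvalidItemError("non-positive max_score in item table")
    bad = (items["score"] < 0) | (items["score"] > items["max_score"])
    if bad.any():
        row = items[bad].iloc[0]
        raise InvalidItemError(
            f"score {row['score']} outside [0, {row['max_score']}] "
            f"(patient {row['patient_id']}, week {row['week']}, item {row['item_id']})"
        )
    if ((items["week"] < 1) | (items["week"] > N_WEEKS)).any():
        raise InvalidItemError(f"weeks must lie in 1..{N_WEEKS}")
    dup = items.duplicated(subset=["patient_id", "week", "instrument", "item_id"])
    if dup.any():
        row = items[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record for patient {row['patient_id']}, week {row['week']}, "
            f"item {row['instrument']}/{row['item_id']}"
        )
    return items


def score_symptom(
    records: pd.DataFrame | Iterable[ItemRecord],
    scale_map: ScaleMap,
    symptom: str | None = None,
    min_items: int = 1,
) -> float:
    """Score one patient-week-symptom as the mean of its rescaled items.

    Returns NaN if fewer than ``min_items`` mapped items are present (the
    all-available-items rule: partially missing instruments still contribute).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records], columns=ITEM_COLUMNS)
    if records.empty:
        return float("nan")
    records = _validate_items(records)
    if records["patient_id"].nunique() > 1 or records["week"].nunique() > 1:
        raise MappingError("records span more than one patient-week")
    mapped = records.apply(
        lambda r: scale_map.symptom_for(r["instrument"], r["item_id"]), axis=1
    )
    if mapped.isna().any():
        raise MappingError("record not present in the scale map")
    if symptom is None:
        symptom = mapped.iloc[0]
    if (mapped != symptom).any():
        raise MappingError(f"records map to symptoms other than {symptom!r}")
    if len(records) < min_items:
        return float("nan")
    return float((records["score"] / records["max_score"]).mean())


def score_cohort(
    items: pd.DataFrame, scale_map: ScaleMap | None = None, min_items: int = 1
) -> pd.DataFrame:
    """Score a whole cohort of item records into tidy symptom-scale values.

    Parameters
    ----------
    items
        Long-format table with columns
        ``patient_id, week, instrument, item_id, score, max_score``.
    scale_map
        Item -> symptom mapping; defaults to the packaged map.
    min_items
        Minimum number of available mapped items for a symptom-week score.

    Returns
    -------
    Tidy frame ``patient_id, week, symptom, value`` on the full
    13-week x 9-symptom grid per patient, NaN where missing. Weeks with no
    instrument data at all are fully missing.
    """
    scale_map = scale_map or default_scale_map()
    items = _validate_items(items)

    map_df = scale_map.to_frame()[["instrument", "item_id", "symptom"]]
    merged = items.merge(map_df, on=["instrument", "item_id"], how="inner")
    merged["rescaled"] = merged["score"] / merged["max_score"]

    grp = (
        merged.groupby(["patient_id", "week", "symptom"], sort=True)["rescaled"]
        .agg(["mean", "count"])
        .reset_index()
    )
    grp["value"] = np.where(grp["count"] >= min_items, grp["mean"], np.nan)

    patients = sorted(items["patient_id"].unique())
    grid = pd.MultiIndex.from_product(
        [patients, range(1, N_WEEKS + 1), SYMPTOMS],
        names=["patient_id", "week", "symptom"],
    )
    out = (
        grp.set_index(["patient_id", "week", "symptom"])["value"]
        .reindex(grid)
        .reset_index()
    )
    return out


def build_symptom_series(
    records: pd.DataFrame,
    scale_map: ScaleMap | None = None,
    min_items: int = 1,
    patient_id: str | None = None,
) -> SymptomSeries:
    """Build one patient's 13x9 symptom series from their item records."""
    scale_map = scale_map or default_scale_map()
    records = _validate_items(records)
    if patient_id is None:
        ids = records["patient_id"].unique()
        if len(ids) != 1:
            raise MappingError(f"expected records for one patient, got {len(ids)}")
        patient_id = ids[0]
    observed_weeks = int(records["week"].nunique())
    tidy = score_cohort(records, scale_map, min_items=min_items)
    values = (
        tidy.pivot(index="week", columns="symptom", values="value")
        .reindex(index=range(1, N_WEEKS + 1), columns=list(SYMPTOMS))
        .to_numpy()
    )
    return SymptomSeries(patient_id=str(patient_id), values=values, observed_weeks=observed_weeks)


def series_from_long(tidy: pd.DataFrame) -> list[SymptomSeries]:
    """Split a tidy ``patient_id, week, symptom, value`` frame into per-patient series."""
    out = []
    for pid, sub in tidy.groupby("patient_id", sort=True):
        values = (
            sub.pivot(index="week", columns="symptom", values="value")
            .reindex(index=range(1, N_WEEKS + 1), columns=list(SYMPTOMS))
            .to_numpy()
        )
        observed = int(np.isfinite(values).any(axis=1).sum())
        out.append(SymptomSeries(patient_id=str(pid), values=values, observed_weeks=observed))
    return out


def average_interitem_correlation(
    items: pd.DataFrame,
    scale_map: ScaleMap,
    symptom: str,
    week: int,
    min_patients: int = 3,
) -> float:
    """Average pairwise Pearson correlation among a scale's rescaled items.

    Correlations are computed across patients at the given week; items with
    zero variance are excluded from pairing. Raises
    :class:`ReliabilityUndefinedError` when no valid item pair remains.
    """
    keys = scale_map.items_for(symptom)
    if len(keys) < 2:
        raise ReliabilityUndefinedError(f"scale {symptom!r} has fewer than 2 mapped items")
    sub = _validate_items(items)
    sub = sub[sub["week"] == week]
    sub = sub[[tuple(k) in set(keys) for k in zip(sub["instrument"], sub["item_id"])]]
    if sub.empty:
        raise ReliabilityUndefinedError(f"no items for {symptom!r} at week {week}")
    sub = sub.assign(rescaled=sub["score"] / sub["max_score"])
    wide = sub.pivot_table(
        index="patient_id", columns=["instrument", "item_id"], values="rescaled"
    )
    rs = []
    for a, b in combinations(wide.columns, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < min_patients:
            continue
        xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
        if xa.std(ddof=1) == 0 or xb.std(ddof=1) == 0:
            continue  # zero-variance item: flagged out of the pair set
        rs.append(float(np.corrcoef(xa, xb)[0, 1]))
    if not rs:
        raise ReliabilityUndefinedError(
            f"no valid item pair for {symptom!r} at week {week}"
        )
    return float(np.mean(rs))


def reliability_summary(
    items: pd.DataFrame, scale_map: ScaleMap, week: int = N_WEEKS
) -> pd.DataFrame:
    """Average inter-item correlation per symptom scale at one week."""
    rows = []
    for symptom in SYMPTOMS:
        try:
            r = average_interitem_correlation(items, scale_map, symptom, week)
        except ReliabilityUndefinedError:
            r = float("nan")
        rows.append(
            {"symptom": symptom, "n_items": len(scale_map.items_for(symptom)), "avg_r": r}
        )
    return pd.DataFrame(rows)


def read_items_csv(path) -> pd.DataFrame:
    items = pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "week": int,
            "instrument": str,
            "item_id": str,
            "score": int,
            "max_score": int,
        },
    )
    return _validate_items(items)


def write_symptom_series_csv(tidy: pd.DataFrame, path) -> None:
    """Write a tidy symptom table; missing values become empty fields."""
    tidy.to_csv(path, index=False)


def read_symptom_series_csv(path) -> pd.DataFrame:
    tidy = pd.read_csv(path, dtype={"patient_id": str, "week": int, "symptom": str})
    return tidy
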