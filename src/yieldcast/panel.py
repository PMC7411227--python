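"""Long-format spatio-temporal panel container.

A :class:`PanelDataset` holds one row per (location, year) with a continuous
response (yield, kg/ha), a harvested-area aggregation weight, administrative
labels (state, agricultural district) and an arbitrary set of feature columns.
Every feature column carries metadata: the group it belongs to (``weather``,
``soil``, ``management`` or ``trend``) and, for weekly-resolved features, its
week-of-year tag.  The metadata is load-bearing: expert filtering, trend
protection during feature selection and in-season weather cutoffs all key off
it, so the panel travels as (DataFrame, metadata) rather than a bare table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: columns every panel must carry besides its features
INDEX_COLUMNS = (
    "location_id",
    "year",
    "state",
    "district",
    "response",
    "harvested_area",
)

VALID_GROUPS = frozenset({"weather", "soil", "management", "trend"})

#: groups whose columns must carry a week-of-year tag
WEEKLY_GROUPS = frozenset({"weather"})
#: groups whose columns must NOT carry a week tag
STATIC_GROUPS = frozenset({"soil", "trend"})
# management columns may be weekly (planting progress) or static (plant
# population), so they appear in neither set.


@dataclass(frozen=True)
class FeatureInfo:
    """Metadata attached to one feature column."""

    group: str
    week: int | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"unknown feature group {self.group!r}; expected one of {sorted(VALID_GROUPS)}"
            )
        if self.group in WEEKLY_GROUPS and self.week is None:
            raise ValueError(f"{self.group} features require a week tag")
        if self.group in STATIC_GROUPS and self.week is not None:
            raise ValueError(f"{self.group} features must not carry a week tag")


class PanelDataset:
    """One row per (location, year) plus per-feature metadata.

    Parameters
    ----------
    frame
        Long-format table containing all :data:`INDEX_COLUMNS` and one column
        per feature named in ``feature_meta``.
    feature_meta
        Mapping feature name -> :class:`FeatureInfo`.  Iteration order defines
        the canonical feature order used everywhere downstream (tie-breaking
        in selection, learner input order).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        feature_meta: Mapping[str, FeatureInfo],
        validate: bool = True,
    ) -> None:
        self.frame = frame.reset_index(drop=True)
        self.feature_meta: dict[str, FeatureInfo] = dict(feature_meta)
        if validate:
            self._validate()

    def _validate(self) -> None:
        missing = [c for c in INDEX_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"panel is missing required columns: {missing}")
        keys = self.frame[["location_id", "year"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (location, year) key: ({dup['location_id']}, {dup['year']})"
            )
        if (self.frame["harvested_area"] < 0).any():
            raise ValueError("harvested_area must be nonnegative")
        for name in self.feature_meta:
            if name not in self.frame.columns:
                raise ValueError(f"feature {name!r} declared in metadata but absent from table")
            if not pd.api.types.is_numeric_dtype(self.frame[name]):
                raise ValueError(f"feature {name!r} is not numeric")

    # -- accessors ---------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.feature_meta)

    @property
    def X(self) -> pd.DataFrame:
        """Feature matrix in canonical feature order."""
        return self.frame[self.features]

    @property
    def y(self) -> pd.Series:
        return self.frame["response"]

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.frame["year"].unique())

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features_in_group(self, group: str) -> list[str]:
        return [f for f, m in self.feature_meta.items() if m.group == group]

    def rows_in_years(self, years: Iterable[int]) -> "PanelDataset":
        years = set(years)
        mask = self.frame["year"].isin(years)
        return PanelDataset(self.frame[mask], self.feature_meta, validate=False)

    def select_features(self, names: Iterable[str]) -> "PanelDataset":
        """Return a panel keeping only ``names`` (canonical order preserved)."""
        keep = [n for n in self.feature_meta if n in set(names)]
        frame = self.frame[list(INDEX_COLUMNS) + keep]
        meta = {n: self.feature_meta[n] for n in keep}
        return PanelDataset(frame, meta, validate=False)

    def with_feature(self, name: str, values, info: FeatureInfo) -> "PanelDataset":
        frame = self.frame.copy()
        frame[name] = np.asarray(values)
        meta = dict(self.feature_meta)
        meta[name] = info
        return PanelDataset(frame, meta, validate=False)

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.frame.copy(), dict(self.feature_meta), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PanelDataset({self.n_rows} rows, {len(self.feature_meta)} features, "
            f"years {self.frame['year'].min()}-{self.frame['year'].max()})"
        )

    # -- persistence -------------------------------------------------------

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the table as CSV with a JSON sidecar for feature metadata."""
        path = Path(path)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        self.frame.to_csv(path, index=False)
        payload = {
            name: {"group": info.group, "week": info.week}
            for name, info in self.feature_meta.items()
        }
        meta_path.write_text(json.dumps(payload, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "PanelDataset":
        path = Path(path)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        frame = pd.read_csv(path)
        raw = json.loads(Path(meta_path).read_text())
        meta = {name: FeatureInfo(group=v["group"], week=v["week"]) for name, v in raw.items()}
        return cls(frame, meta)


def split_by_year(
    data: PanelDataset, first_test_year: int
) -> tuple[PanelDataset, PanelDataset]:
    """Chronological train/test split: test = all rows with year >= cutoff.

    ``first_test_year`` must lie strictly inside the panel's year range so
    that both sides are non-empty.
    """
    years = data.years
    if first_test_year <= years.min() or first_test_year > years.max():
        raise ValueError(
            f"first_test_year={first_test_year} must lie strictly inside "
            f"the panel years [{years.min()}, {years.max()}]"
        )
    train_mask = data.frame["year"] < first_test_year
    train = PanelDataset(data.frame[train_mask], data.feature_meta, validate=False)
    test = PanelDataset(data.frame[~train_mask], data.feature_meta, validate=False)
    return train, test
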