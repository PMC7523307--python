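"""Panel containers: long-format EMA records and per-person gridded series."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ItemCatalog, default_catalog

GROUPS = ("comorbid", "depression_only", "anxiety_only")

PANEL_ID_COLS = ["person_id", "group", "t_min", "answered"]


@dataclass
class EmaPanel:
    """Long-format momentary-assessment panel.

    ``data`` holds one row per person per scheduled prompt with columns
    ``person_id, group, t_min, answered`` followed by the seven item columns
    (NaN when the prompt went unanswered).  ``t_min`` counts minutes since the
    person's first scheduled prompt and is strictly increasing within person.

    ``coded`` records whether reverse coding has been applied: the raw
    questionnaire emits "cheerful"/"relaxed" scores (high = good mood), the
    analysis scale flips those so high always means symptomatic.
    """

    data: pd.DataFrame
    catalog: ItemCatalog = field(default_factory=default_catalog)
    metadata: pd.DataFrame | None = None  # per-person: severity, recency_class
    coded: bool = False
    likert: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_ID_COLS + self.catalog.codes if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        bad_groups = set(self.data["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        for pid, sub in self.data.groupby("person_id", sort=False):
            t = sub["t_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"t_min not strictly increasing for person {pid!r}")
            if sub["group"].nunique() != 1:
                raise ValueError(f"person {pid!r} has multiple group labels")
        unanswered = ~self.data["answered"].astype(bool)
        if unanswered.any() and self.data.loc[unanswered, self.catalog.codes].notna().any().any():
            raise ValueError("unanswered rows must carry no scores")

    @property
    def item_codes(self) -> list:
        return self.catalog.codes

    @property
    def person_ids(self) -> list:
        return list(self.data["person_id"].unique())

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    def group_of(self, person_id) -> str:
        return self.data.loc[self.data["person_id"] == person_id, "group"].iloc[0]

    def answered_data(self) -> pd.DataFrame:
        return self.data[self.data["answered"].astype(bool)]

    def subset_persons(self, person_ids) -> "EmaPanel":
        keep = set(person_ids)
        data = self.data[self.data["person_id"].isin(keep)].reset_index(drop=True)
        meta = None
        if self.metadata is not None:
            meta = self.metadata[self.metadata["person_id"].isin(keep)].reset_index(drop=True)
        return EmaPanel(data=data, catalog=self.catalog, metadata=meta,
                        coded=self.coded, likert=self.likert)

    # ------------------------------------------------------------------ I/O

    def write_csv(self, path, sidecar: dict | None = None) -> None:
        """Write the long CSV; optional JSON sidecar (config, seed, flags)."""
        path = Path(path)
        cols = PANEL_ID_COLS + self.catalog.codes
        self.data[cols].to_csv(path, index=False)
        side = {"coded": self.coded, "likert": self.likert}
        if sidecar:
            side.update(sidecar)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2, default=str))
        if self.metadata is not None:
            self.metadata.to_csv(path.with_name(path.stem + "_metadata.csv"), index=False)

    @classmethod
    def read_csv(cls, path, catalog: ItemCatalog | None = None) -> "EmaPanel":
        path = Path(path)
        catalog = catalog or default_catalog()
        data = pd.read_csv(path)
        data["answered"] = data["answered"].astype(bool)
        coded, likert = False, True
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            coded = bool(side.get("coded", False))
            likert = bool(side.get("likert", True))
        meta_path = path.with_name(path.stem + "_metadata.csv")
        metadata = pd.read_csv(meta_path) if meta_path.exists() else None
        return cls(data=data, catalog=catalog, metadata=metadata, coded=coded, likert=likert)


@dataclass
class PersonGrid:
    """One person's series on the equally spaced lattice (NaN = missing)."""

    person_id: object
    group: str
    values: np.ndarray          # T_i x n_items, NaN where missing
    delta_min: float
    t0_min: float
    n_collisions: int = 0

    @property
    def n_slots(self) -> int:
        return self.values.shape[0]

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.values).all(axis=1).sum())

    @property
    def observed_mask(self) -> np.ndarray:
        """Per-slot flag: True where the slot holds an observed record."""
        return np.isfinite(self.values).any(axis=1)


@dataclass
class GriddedPanel:
    """Collection of per-person lattices sharing one spacing and item order."""

    persons: list
    delta_min: float
    item_codes: list
    catalog: ItemCatalog = field(default_factory=default_catalog)

    def __post_init__(self) -> None:
        for pg in self.persons:
            if pg.values.shape[1] != len(self.item_codes):
                raise ValueError(f"person {pg.person_id!r}: item dimension mismatch")
            if pg.delta_min != self.delta_min:
                raise ValueError(f"person {pg.person_id!r}: spacing mismatch")

    def __len__(self) -> int:
        return len(self.persons)

    def __iter__(self):
        return iter(self.persons)

    @property
    def groups(self) -> list:
        seen = []
        for pg in self.persons:
            if pg.group not in seen:
                seen.append(pg.group)
        return seen

    def n_observed_cells(self) -> int:
        return int(sum(np.isfinite(pg.values).sum() for pg in self.persons))

    def write_csv(self, path) -> None:
        """Wide CSV, one row per person-slot, explicit NA cells."""
        rows = []
        for pg in self.persons:
            for t in range(pg.n_slots):
                rows.append({"person_id": pg.person_id, "group": pg.group, "slot": t,
                             "t_min": pg.t0_min + t * pg.delta_min,
                             **{c: pg.values[t, j] for j, c in enumerate(self.item_codes)}})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, delta_min: float, catalog: ItemCatalog | None = None) -> "GriddedPanel":
        catalog = catalog or default_catalog()
        df = pd.read_csv(path)
        persons = []
        for pid, sub in df.groupby("person_id", sort=False):
            sub = sub.sort_values("slot")
            persons.append(PersonGrid(
                person_id=pid, group=sub["group"].iloc[0],
                values=sub[catalog.codes].to_numpy(dtype=float),
                delta_min=delta_min, t0_min=float(sub["t_min"].iloc[0])))
        return cls(persons=persons, delta_min=delta_min,
                   item_codes=catalog.codes, catalog=catalog)
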