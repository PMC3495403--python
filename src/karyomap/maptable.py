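"""Ordered marker tables with sex-specific centimorgan positions.

The layout mirrors a standard supplementary linkage-map table with eight
columns: marker id, linkage group, 1-based order within the group, female cM,
male cM, number of informative meioses, a free-text accession and a
population-specific flag (serialized as a literal ``x`` or an empty field).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "LinkageMapTable", "MapValidationError", "map_summary"]

COLUMNS = [
    "marker",
    "group",
    "order",
    "female_cM",
    "male_cM",
    "n_meioses",
    "accession",
    "population_specific",
]

_POSITION_TOL = 1e-9


class MapValidationError(ValueError):
    """A marker table violates the ordered-map invariants."""


class LinkageMapTable:
    """Validated, ordered linkage-map table.

    Within each linkage group the order column must be a permutation of
    ``1..k`` and both cM columns must be non-decreasing along it with the
    first marker at 0 cM (a non-zero origin is tolerated with a warning so
    that externally produced files can still be summarized).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise MapValidationError(f"missing columns: {missing}")
        df = df[COLUMNS]
        df["marker"] = df["marker"].astype(str)
        df["group"] = df["group"].astype(str)
        df["order"] = df["order"].astype(int)
        df["female_cM"] = df["female_cM"].astype(float)
        df["male_cM"] = df["male_cM"].astype(float)
        df["n_meioses"] = df["n_meioses"].astype(int)
        df["accession"] = df["accession"].fillna("").astype(str)
        df["population_specific"] = df["population_specific"].astype(bool)
        # canonical row order: groups in first-appearance order, markers by order index
        group_rank = {g: i for i, g in enumerate(df["group"].drop_duplicates())}
        df = df.sort_values(
            ["group", "order"], key=lambda s: s.map(group_rank) if s.name == "group" else s
        ).reset_index(drop=True)
        self.df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        dup = self.df["marker"][self.df["marker"].duplicated()]
        if len(dup):
            raise MapValidationError(f"duplicate marker ids: {sorted(set(dup))[:5]}")
        for group, rows in self.df.groupby("group", sort=False):
            order = rows["order"].to_numpy()
            if sorted(order) != list(range(1, len(rows) + 1)):
                raise MapValidationError(
                    f"group {group!r}: order must be a permutation of 1..{len(rows)}"
                )
            for col in ("female_cM", "male_cM"):
                pos = rows[col].to_numpy()
                if np.any(np.diff(pos) < -_POSITION_TOL):
                    i = int(np.argmax(np.diff(pos) < -_POSITION_TOL))
                    raise MapValidationError(
                        f"group {group!r}: {col} decreases at order {i + 2}"
                    )
            if abs(rows["female_cM"].iloc[0]) > 1e-6 or abs(rows["male_cM"].iloc[0]) > 1e-6:
                warnings.warn(
                    f"group {group!r}: first marker not at 0 cM", stacklevel=2
                )

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkageMapTable):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return bool(
            (a["marker"] == b["marker"]).all()
            and (a["group"] == b["group"]).all()
            and (a["order"] == b["order"]).all()
            and np.allclose(a["female_cM"], b["female_cM"], atol=5e-4)
            and np.allclose(a["male_cM"], b["male_cM"], atol=5e-4)
            and (a["n_meioses"] == b["n_meioses"]).all()
            and (a["accession"] == b["accession"]).all()
            and (a["population_specific"] == b["population_specific"]).all()
        )

    @property
    def markers(self) -> list[str]:
        return self.df["marker"].tolist()

    @property
    def groups(self) -> list[str]:
        return self.df["group"].drop_duplicates().tolist()

    def group_rows(self, group: str) -> pd.DataFrame:
        rows = self.df[self.df["group"] == group]
        if rows.empty:
            raise KeyError(f"no such linkage group: {group!r}")
        return rows.sort_values("order").reset_index(drop=True)

    def marker_positions(self, sex: str = "female") -> dict[str, float]:
        col = "female_cM" if sex == "female" else "male_cM"
        return dict(zip(self.df["marker"], self.df[col]))

    def marker_groups(self) -> dict[str, str]:
        return dict(zip(self.df["marker"], self.df["group"]))

    def summary(self) -> dict:
        return map_summary(self)


def map_summary(table: LinkageMapTable) -> dict:
    """Totals for a map table.

    Total lengths are sums over linkage groups of the maximum position per
    sex.  An empty table yields zeros throughout.
    """
    df = table.df
    if df.empty:
        return {
            "n_markers": 0,
            "n_groups": 0,
            "female_length_cM": 0.0,
            "male_length_cM": 0.0,
            "n_population_specific": 0,
            "n_shared": 0,
        }
    per_group = df.groupby("group", sort=False)
    return {
        "n_markers": int(len(df)),
        "n_groups": int(df["group"].nunique()),
        "female_length_cM": float(per_group["female_cM"].max().sum()),
        "male_length_cM": float(per_group["male_cM"].max().sum()),
        "n_population_specific": int(df["population_specific"].sum()),
        "n_shared": int((~df["population_specific"]).sum()),
    }
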