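"""Binary-fission genealogies.

A lineage records one chamber's family tree: a single founder divides
synchronously (up to jitter) into 2, 4, 8, ... cells, so a lineage with G
completed generations holds 2**(G+1) - 1 cells.  Frames are integers on the
recording grid; lifetimes are half-open intervals [birth_frame, end_frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LineageTable"]

_COLUMNS = ["cell_id", "parent_id", "generation", "birth_frame", "division_frame", "end_frame"]


@dataclass
class LineageTable:
    """Genealogy of one recording series.

    Wraps a DataFrame with one row per cell and columns ``cell_id``,
    ``parent_id`` (NaN for the founder), ``generation``, ``birth_frame``,
    ``division_frame`` (NaN for terminal cells) and ``end_frame`` (division
    frame, or end of observation for terminal cells).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"lineage table missing columns {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        df["cell_id"] = df["cell_id"].astype(int)
        self.table = df
        self.validate()

    # -- access ---------------------------------------------------------

    @property
    def cell_ids(self) -> list[int]:
        return self.table["cell_id"].tolist()

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def generations(self) -> int:
        """Index of the last generation present."""
        return int(self.table["generation"].max())

    def row(self, cell_id: int) -> pd.Series:
        sel = self.table[self.table["cell_id"] == cell_id]
        if sel.empty:
            raise KeyError(f"no cell {cell_id} in lineage")
        return sel.iloc[0]

    def parent_of(self, cell_id: int) -> int | None:
        p = self.row(cell_id)["parent_id"]
        return None if pd.isna(p) else int(p)

    def daughters_of(self, cell_id: int) -> list[int]:
        sel = self.table[self.table["parent_id"] == cell_id]
        return sel["cell_id"].astype(int).tolist()

    def generation_of(self, cell_id: int) -> int:
        return int(self.row(cell_id)["generation"])

    def lifespan(self, cell_id: int) -> tuple[int, int]:
        """Half-open frame interval [birth, end) of a cell."""
        r = self.row(cell_id)
        return int(r["birth_frame"]), int(r["end_frame"])

    def contemporaries(self, cell_id: int, frame: int) -> list[int]:
        """Cells other than ``cell_id`` whose lifespan contains ``frame``."""
        df = self.table
        alive = df[(df["birth_frame"] <= frame) & (frame < df["end_frame"])]
        return [int(c) for c in alive["cell_id"] if int(c) != cell_id]

    def parent_daughter_pairs(self) -> list[tuple[int, int]]:
        """(parent_id, daughter_id) for every non-founder cell."""
        out = []
        for _, r in self.table.iterrows():
            if not pd.isna(r["parent_id"]):
                out.append((int(r["parent_id"]), int(r["cell_id"])))
        return out

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        df = self.table
        if df["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids")
        founders = df[df["parent_id"].isna()]
        if len(founders) != 1:
            raise ValueError(f"expected exactly one founder, got {len(founders)}")
        ids = set(df["cell_id"])
        for _, r in df.iterrows():
            if not pd.isna(r["parent_id"]) and int(r["parent_id"]) not in ids:
                raise ValueError(f"cell {int(r['cell_id'])} has unknown parent")
            if r["birth_frame"] >= r["end_frame"]:
                raise ValueError(f"cell {int(r['cell_id'])} has empty lifespan")
        for _, r in df.iterrows():
            if pd.isna(r["division_frame"]):
                continue
            daughters = self.daughters_of(int(r["cell_id"]))
            if len(daughters) != 2:
                raise ValueError(
                    f"dividing cell {int(r['cell_id'])} has {len(daughters)} daughters"
                )
            for d in daughters:
                if self.row(d)["birth_frame"] != r["division_frame"]:
                    raise ValueError(
                        f"daughter {d} not born at parent division frame"
                    )

    # -- IO -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LineageTable":
        df = pd.read_csv(path)
        if "end_frame" not in df.columns:
            # legacy tables: terminal cells get no observation end; use the
            # largest division frame as a fallback horizon
            horizon = df["division_frame"].max()
            df["end_frame"] = df["division_frame"].fillna(horizon)
        return cls(df)

    @classmethod
    def from_records(cls, records) -> "LineageTable":
        df = pd.DataFrame.from_records(records)
        if "end_frame" not in df.columns:
            df["end_frame"] = df["division_frame"]
        return cls(df)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineageTable):
            return NotImplemented
        return self.table.equals(other.table)


def full_tree_size(generations: int) -> int:
    """Cell count of a complete binary-fission tree with generations 0..G."""
    return 2 ** (generations + 1) - 1


def expand_binary_tree(generations: int) -> list[tuple[int, int | None, int]]:
    """(cell_id, parent_id, generation) triples in breadth-first id order.

    The founder is cell 0; generation g occupies ids 2**g - 1 .. 2**(g+1) - 2,
    and cell i's daughters are 2i+1 and 2i+2 (heap layout).
    """
    out: list[tuple[int, int | None, int]] = []
    for g in range(generations + 1):
        for i in range(2**g - 1, 2 ** (g + 1) - 1):
            parent = None if i == 0 else (i - 1) // 2
            out.append((i, parent, g))
    return out
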