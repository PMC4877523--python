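"""Individual plant records stored as flat arrays with a parcel index.

Each plant carries a unique integer id, continuous coordinates (m), age
(days), biomass B (g) and the running maximum biomass Bmax (g) that the
water-stress death rule compares against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["Population"]


class Population:
    """Flat structure-of-arrays collection of living plants."""

    __slots__ = ("ids", "x", "y", "age", "B", "Bmax", "next_id")

    def __init__(self, ids, x, y, age, B, Bmax, next_id=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.age = np.asarray(age, dtype=np.float64)
        self.B = np.asarray(B, dtype=np.float64)
        self.Bmax = np.asarray(Bmax, dtype=np.float64)
        if next_id is None:
            next_id = int(self.ids.max()) + 1 if self.ids.size else 0
        self.next_id = int(next_id)

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls) -> "Population":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, next_id=0)

    def __len__(self) -> int:
        return self.ids.size

    def copy(self) -> "Population":
        return Population(self.ids.copy(), self.x.copy(), self.y.copy(),
                          self.age.copy(), self.B.copy(), self.Bmax.copy(),
                          next_id=self.next_id)

    # ------------------------------------------------------------------
    def parcel_index(self, dx: float, nx: int) -> np.ndarray:
        """Flat (row-major) parcel index of every plant.

        Parcels are indexed iy * nx + ix with ix = floor(x / dx); the
        origin sits at the lower-left corner of the plot.
        """
        ix = np.floor(self.x / dx).astype(np.int64)
        iy = np.floor(self.y / dx).astype(np.int64)
        return iy * nx + ix

    def biomass_per_parcel(self, dx: float, nx: int, ny: int) -> np.ndarray:
        """Total biomass per parcel as an (ny, nx) array (g)."""
        idx = self.parcel_index(dx, nx)
        out = np.bincount(idx, weights=self.B, minlength=nx * ny)
        return out.reshape(ny, nx)

    # ------------------------------------------------------------------
    def add(self, x, y, age, B) -> None:
        """Append new plants (Bmax initialised to B); ids assigned in order."""
        n = len(np.atleast_1d(x))
        if n == 0:
            return
        new_ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.ids = np.concatenate([self.ids, new_ids])
        self.x = np.concatenate([self.x, np.atleast_1d(np.float64(x))])
        self.y = np.concatenate([self.y, np.atleast_1d(np.float64(y))])
        self.age = np.concatenate([self.age, np.atleast_1d(np.float64(age))])
        B = np.atleast_1d(np.float64(B))
        self.B = np.concatenate([self.B, B])
        self.Bmax = np.concatenate([self.Bmax, B.copy()])
        self.next_id += n

    def remove(self, mask: np.ndarray) -> None:
        """Drop plants where mask is True."""
        keep = ~np.asarray(mask, dtype=bool)
        self.ids = self.ids[keep]
        self.x = self.x[keep]
        self.y = self.y[keep]
        self.age = self.age[keep]
        self.B = self.B[keep]
        self.Bmax = self.Bmax[keep]

    # ------------------------------------------------------------------
    @property
    def total_biomass(self) -> float:
        return float(self.B.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "x": self.x, "y": self.y,
            "age": self.age, "biomass": self.B, "bmax": self.Bmax,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Population":
        """Build a population from a plant table.

        Requires columns x, y, biomass, age; id and bmax are optional
        (ids are assigned in row order, bmax defaults to biomass).
        """
        n = len(df)
        ids = df["id"].to_numpy() if "id" in df else np.arange(n)
        bmax = df["bmax"].to_numpy() if "bmax" in df else df["biomass"].to_numpy()
        return cls(ids, df["x"].to_numpy(), df["y"].to_numpy(),
                   df["age"].to_numpy(), df["biomass"].to_numpy(), bmax)

    def to_csv(self, path) -> None:
        self.to_dataframe()[["x", "y", "biomass", "age"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Population":
        return cls.from_dataframe(pd.read_csv(path))
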