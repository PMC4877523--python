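"""Quadrat dispersion indices and population-structure summaries.

The plot is tiled exhaustively with non-overlapping square quadrats and
living plants are counted per quadrat. Two classical aggregation
indices are computed from the count vector (sample variance s^2, mean
m):

* Index of Patchiness (Lloyd): IP = 1 + (s^2 - m)/m^2, the mean
  crowding divided by the mean; 1 for a Poisson (random) pattern,
  above 1 when clumped.
* Index of Cluster Size (David & Moore): ICS = s^2/m - 1; 0 under a
  Poisson pattern, growing with absolute clump size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Population

__all__ = ["QuadratCounts", "quadrat_counts", "index_of_patchiness",
           "index_of_cluster_size", "structure_summaries",
           "mortality_by_class", "UndefinedIndexError"]


class UndefinedIndexError(ValueError):
    """Raised when a dispersion index is requested for an empty pattern."""


@dataclass
class QuadratCounts:
    counts: np.ndarray       # per-quadrat plant counts (integers)
    quadrat_size: float      # quadrat side (m)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)


def quadrat_counts(pop: Population, quadrat_size: float,
                   plot_size) -> QuadratCounts:
    """Count living plants in an exhaustive tiling of the plot.

    plot_size is (Lx, Ly) in metres; quadrat_size must divide both.
    """
    Lx, Ly = (plot_size, plot_size) if np.isscalar(plot_size) else plot_size
    nqx = Lx / quadrat_size
    nqy = Ly / quadrat_size
    if abs(nqx - round(nqx)) > 1e-9 or abs(nqy - round(nqy)) > 1e-9:
        near = max(1, round(nqx))
        raise ValueError(
            f"quadrat_size {quadrat_size} does not divide the plot "
            f"({Lx} x {Ly} m); try {Lx / near:g}")
    nqx, nqy = int(round(nqx)), int(round(nqy))
    ix = np.floor(pop.x / quadrat_size).astype(np.int64)
    iy = np.floor(pop.y / quadrat_size).astype(np.int64)
    counts = np.bincount(iy * nqx + ix, minlength=nqx * nqy)
    return QuadratCounts(counts, quadrat_size)


def _moments(counts) -> tuple:
    if isinstance(counts, QuadratCounts):
        counts = counts.counts
    c = np.asarray(counts, dtype=np.float64)
    mean = c.mean()
    if mean == 0.0:
        raise UndefinedIndexError("dispersion index undefined: mean count is 0")
    var = c.var(ddof=1) if c.size > 1 else 0.0
    return mean, var


def index_of_patchiness(counts) -> float:
    """Lloyd's IP = 1 + (s^2 - m)/m^2 (mean crowding over mean)."""
    mean, var = _moments(counts)
    return 1.0 + (var - mean) / mean ** 2


def index_of_cluster_size(counts) -> float:
    """David-Moore ICS = s^2/m - 1 (variance-to-mean ratio minus one)."""
    mean, var = _moments(counts)
    return var / mean - 1.0


def structure_summaries(pop: Population, plot_area: float) -> dict:
    """Demographic summaries: age/biomass histograms (1-day and 1-gram
    bins, relative frequencies), means, seedling fraction (< 30 d) and
    plant density (m^-2). Empty populations yield an ``empty`` flag."""
    n = len(pop)
    if n == 0:
        return {"empty": True, "n": 0, "mean_age": np.nan,
                "mean_biomass": np.nan, "seedling_fraction": np.nan,
                "density": 0.0, "age_hist": None, "biomass_hist": None}
    age_edges = np.arange(0.0, np.ceil(pop.age.max()) + 2.0)
    b_edges = np.arange(0.0, np.ceil(pop.B.max()) + 2.0)
    age_hist, _ = np.histogram(pop.age, bins=age_edges)
    b_hist, _ = np.histogram(pop.B, bins=b_edges)
    return {
        "empty": False,
        "n": n,
        "mean_age": float(pop.age.mean()),
        "mean_biomass": float(pop.B.mean()),
        "seedling_fraction": float(np.count_nonzero(pop.age < 30.0)) / n,
        "density": n / plot_area,
        "age_hist": (age_edges, age_hist / n),
        "biomass_hist": (b_edges, b_hist / n),
    }


def mortality_by_class(pre_pop: Population, post_pop: Population,
                       age_bins, biomass_bins) -> pd.DataFrame:
    """Per-class death fractions across a simulation interval.

    Plants present in ``pre_pop`` are classified by their age and
    biomass at that time; a plant is dead if its id is absent from
    ``post_pop``. Returns a tidy frame with one row per (kind, class);
    empty classes report NaN, not zero.
    """
    survivors = set(post_pop.ids.tolist())
    dead = ~np.isin(pre_pop.ids, list(survivors))
    rows = []
    for kind, values, bins in (("age", pre_pop.age, age_bins),
                               ("biomass", pre_pop.B, biomass_bins)):
        bins = np.asarray(bins, dtype=np.float64)
        which = np.digitize(values, bins) - 1
        for k in range(len(bins) - 1):
            members = which == k
            n_members = int(np.count_nonzero(members))
            frac = (float(np.count_nonzero(dead & members)) / n_members
                    if n_members else np.nan)
            rows.append({"kind": kind, "lo": bins[k], "hi": bins[k + 1],
                         "n": n_members, "dead_fraction": frac})
    return pd.DataFrame(rows)
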